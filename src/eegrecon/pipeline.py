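"""End-to-end pipeline: data -> autoencoder -> features -> classifiers -> explanations.

Each stage reads its inputs from the run directory written by the previous
stage, so stages can be re-run independently; :func:`run_pipeline` chains
them all.  A single master seed fans out to per-stage seeds by fixed
offsets, recorded in the run manifest, and two runs with the same config
and seed produce byte-identical JSON reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .autoencoder import AeConfig, ConvAutoencoder, build_autoencoder, train_autoencoder
from .classify import CLASSIFIER_KINDS, SplitSpec, accuracy, evaluate, split_table, train_classifier
from .features import FeatureTable, extract_features
from .interpret import ImportanceReport, exact_shapley, permutation_importance
from .pca_baseline import fit_pca, pca_transform
from .signal_io import CLASSES, EegDataset, load_dataset, write_dataset
from .synthetic import SyntheticConfig, generate_dataset, reduced_contrast_config

# fixed seed offsets per stage (master seed + offset)
SEED_OFFSETS = {
    "synthetic": 0,
    "autoencoder": 1000,
    "split": 2000,
    "classifier": 3000,  # + index of the classifier kind
    "permutation": 4000,
    "background": 5000,
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    output_dir: str = "runs/run"
    seed: int = 0
    length: int = 4096
    reference_class: str = "interictal"
    data_source: str = "synthetic"  # "synthetic" | "directory"
    n_per_class: int = 100
    reduced_contrast: bool = False
    data_root: str | None = None
    class_map: dict[str, str] = field(
        default_factory=lambda: {"Z": "healthy", "F": "interictal", "S": "ictal"}
    )
    autoencoder: dict[str, Any] = field(default_factory=dict)
    pca_components: int = 10
    pca_normalized: int = 3
    split: dict[str, Any] = field(default_factory=dict)
    classifier_kinds: tuple[str, ...] = CLASSIFIER_KINDS
    classifier_hyperparams: dict[str, dict] = field(default_factory=dict)
    n_repeats: int = 30
    background_cap: int = 100

    def __post_init__(self) -> None:
        if self.reference_class not in CLASSES:
            raise ValueError(f"reference class {self.reference_class!r} not in {CLASSES}")
        unknown = [k for k in self.classifier_kinds if k not in CLASSIFIER_KINDS]
        if unknown:
            raise ValueError(f"unknown classifier kinds {unknown}; expected {CLASSIFIER_KINDS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def ae_config(self) -> AeConfig:
        return AeConfig(
            length=self.length,
            seed=self.seed + SEED_OFFSETS["autoencoder"],
            **{k: tuple(v) if k == "channels" else v for k, v in self.autoencoder.items()},
        )

    def synthetic_config(self) -> SyntheticConfig:
        kwargs = dict(
            n_per_class=self.n_per_class,
            length=self.length,
            seed=self.seed + SEED_OFFSETS["synthetic"],
        )
        if self.reduced_contrast:
            return reduced_contrast_config(**kwargs)
        return SyntheticConfig(**kwargs)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(seed=self.seed + SEED_OFFSETS["split"], **self.split)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_input_data(cfg: RunConfig) -> EegDataset:
    """Materialize the configured data source (synthetic or directory tree)."""
    if cfg.data_source == "synthetic":
        return generate_dataset(cfg.synthetic_config())
    if cfg.data_source == "directory":
        if not cfg.data_root:
            raise ValueError("data_source 'directory' requires data_root")
        return load_dataset(cfg.data_root, cfg.class_map, length=cfg.length)
    raise ValueError(f"unknown data_source {cfg.data_source!r}")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> Path:
    """Write the synthetic dataset as an ASCII directory-per-class tree."""
    out = Path(cfg.output_dir) / "data"
    data = generate_dataset(cfg.synthetic_config())
    write_dataset(out, data)
    return out

def stage_train_ae(cfg: RunConfig, data: EegDataset) -> ConvAutoencoder:
    reference = data.subset(cfg.reference_class)
    model = build_autoencoder(cfg.ae_config())
    train_autoencoder(model, reference)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.save(out / "autoencoder.npz")
    data.manifest().to_csv(out / "manifest.csv", index=False)
    return model


def stage_extract(cfg: RunConfig, model: ConvAutoencoder, data: EegDataset) -> FeatureTable:
    table = extract_features(model, data)
    table.to_csv(Path(cfg.output_dir) / "ae_features.csv")
    return table


def stage_pca(cfg: RunConfig, data: EegDataset) -> FeatureTable:
    model = fit_pca(data, k=cfg.pca_components)
    table = pca_transform(model, data)
    table.to_csv(Path(cfg.output_dir) / "pca_features.csv")
    return table


def stage_classify(cfg: RunConfig, tables: dict[str, FeatureTable]) -> dict:
    """Train and evaluate every classifier kind on every feature table."""
    spec = cfg.split_spec()
    summary: dict[str, dict] = {}
    reports = []
    models: dict[tuple[str, str], Any] = {}
    splits: dict[str, tuple[FeatureTable, FeatureTable]] = {}
    for feat_name, table in tables.items():
        train, test = split_table(table, spec)
        splits[feat_name] = (train, test)
        summary[feat_name] = {}
        for i, kind in enumerate(cfg.classifier_kinds):
            model = train_classifier(
                kind,
                train,
                seed=cfg.seed + SEED_OFFSETS["classifier"] + i,
                **cfg.classifier_hyperparams.get(kind, {}),
            )
            report = evaluate(model, test, train=train, name=kind)
            models[(feat_name, kind)] = model
            reports.append({"features": feat_name, **report.to_dict()})
            summary[feat_name][kind] = {
                "train_accuracy": report.train_accuracy,
                "test_accuracy": report.test_accuracy,
            }
    payload = {"summary": summary, "reports": reports}
    _write_json(Path(cfg.output_dir) / "evaluation.json", payload)
    return {"payload": payload, "models": models, "splits": splits}


def stage_interpret(cfg: RunConfig, models: dict, splits: dict) -> list[ImportanceReport]:
    """Permutation importance + exact Shapley on the AE feature models."""
    train, test = splits["ae"]
    bg = train
    if len(bg) > cfg.background_cap:
        rng = np.random.default_rng(cfg.seed + SEED_OFFSETS["background"])
        idx = np.sort(rng.choice(len(bg), size=cfg.background_cap, replace=False))
        bg = FeatureTable(bg.df.iloc[idx], list(bg.feature_names))
    reports = []
    for kind in cfg.classifier_kinds:
        model = models[("ae", kind)]
        perm = permutation_importance(
            model, test, n_repeats=cfg.n_repeats, seed=cfg.seed + SEED_OFFSETS["permutation"]
        )
        shap = exact_shapley(model, test, bg)
        reports.append(ImportanceReport(classifier=kind, permutation=perm, shapley=shap))
    _write_json(
        Path(cfg.output_dir) / "interpretability.json",
        {"reports": [r.to_dict() for r in reports]},
    )
    return reports


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the in-memory artifacts.

    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Any] = {}
    stages = [
        ("load", lambda: artifacts.update(data=load_input_data(cfg))),
        ("train-ae", lambda: artifacts.update(ae=stage_train_ae(cfg, artifacts["data"]))),
        (
            "extract",
            lambda: artifacts.update(
                ae_features=stage_extract(cfg, artifacts["ae"], artifacts["data"])
            ),
        ),
        ("pca", lambda: artifacts.update(pca_features=stage_pca(cfg, artifacts["data"]))),
        (
            "classify",
            lambda: artifacts.update(
                classify=stage_classify(
                    cfg, {"ae": artifacts["ae_features"], "pca": artifacts["pca_features"]}
                )
            ),
        ),
        (
            "interpret",
            lambda: artifacts.update(
                importance=stage_interpret(
                    cfg, artifacts["classify"]["models"], artifacts["classify"]["splits"]
                )
            ),
        ),
    ]
    for name, step in stages:
        try:
            step()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
    _write_json(
        out / "run.json",
        {
            "seed": cfg.seed,
            "seed_offsets": SEED_OFFSETS,
            "data_source": cfg.data_source,
            "n_records": len(artifacts["data"]),
            "reference_class": cfg.reference_class,
            "classifier_kinds": list(cfg.classifier_kinds),
        },
    )
    return artifacts
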