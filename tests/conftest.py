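"""Shared fixtures.

The expensive artifacts — a 200-epoch autoencoder training and two full
pipeline runs — are session-scoped so every test that needs them shares
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegrecon import (
    AeConfig,
    EegDataset,
    SyntheticConfig,
    build_autoencoder,
    extract_features,
    generate_dataset,
    train_autoencoder,
)
from eegrecon.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_dataset() -> EegDataset:
    """300 synthetic records (100 per class) at default generator settings."""
    return generate_dataset(SyntheticConfig(n_per_class=100, seed=0))


@pytest.fixture(scope="session")
def trained_ae(default_dataset):
    """Autoencoder trained 200 epochs on the first 75 interictal records."""
    train = EegDataset(default_dataset.subset("interictal").records[:75])
    model = build_autoencoder(AeConfig(seed=0))
    return train_autoencoder(model, train)


@pytest.fixture(scope="session")
def heldout_features(trained_ae, default_dataset):
    """Reconstruction features for the 25 held-out records of each class."""
    held = EegDataset(
        [
            r
            for label in ("healthy", "interictal", "ictal")
            for r in default_dataset.subset(label).records[75:]
        ]
    )
    return extract_features(trained_ae, held)


@pytest.fixture(scope="session")
def pipeline_default(tmp_path_factory):
    """Full pipeline run at default generator parameters, seed 1."""
    out = tmp_path_factory.mktemp("run_default")
    cfg = RunConfig(output_dir=str(out), seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def pipeline_reduced_contrast(tmp_path_factory):
    """Full pipeline run on the reduced-contrast generator, seed 1."""
    out = tmp_path_factory.mktemp("run_hard")
    cfg = RunConfig(output_dir=str(out), seed=1, reduced_contrast=True)
    return run_pipeline(cfg)


@pytest.fixture()
def small_config(tmp_path):
    """A scaled-down run configuration for fast pipeline-level tests."""
    return RunConfig(
        output_dir=str(tmp_path / "run"),
        seed=3,
        length=512,
        n_per_class=12,
        autoencoder={"epochs": 8, "batch_size": 8},
        pca_components=5,
        n_repeats=5,
        background_cap=30,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
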