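"""Reconstruction-quantification features: MSE, ORSR and cosine similarity.

Each signal x and its autoencoder reconstruction x_hat are compared with
three indicators, which together form the feature vector fed to the
classifiers:

* ``mse``  — mean squared error, (1/n) sum (x_i - x_hat_i)^2
* ``orsr`` — original-to-reconstructed signal ratio in dB,
  10 log10(sum x_i^2 / sum x_hat_i^2); 0 dB means equal energy
* ``cs``   — cosine similarity, the normalized inner product; 1 means
  identical direction (higher = more similar)

Signals of the autoencoder's training class reconstruct almost perfectly
(mse ~ 0, orsr ~ 0 dB, cs ~ 1); off-class signals diverge on all three.
Features are computed on normalized signals — the model's input/output
space — not raw amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autoencoder import ConvAutoencoder
from .signal_io import EegDataset

AE_FEATURES = ["mse", "orsr", "cs"]


def _check_pair(x: np.ndarray, xhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape or x.ndim != 1:
        raise ValueError(f"signals must be 1-D and equal length, got {x.shape} vs {xhat.shape}")
    if x.size == 0:
        raise ValueError("signals are empty")
    return x, xhat


def compute_mse(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared error between a signal and its reconstruction."""
    x, xhat = _check_pair(x, xhat)
    return float(np.mean((x - xhat) ** 2))


def compute_orsr(x: np.ndarray, xhat: np.ndarray) -> float:
    """Original-to-reconstructed signal ratio in dB.

    ``10 * log10(sum x^2 / sum xhat^2)``; positive when the original
    carries more energy than the reconstruction.
    """
    x, xhat = _check_pair(x, xhat)
    ex = float(np.dot(x, x))
    er = float(np.dot(xhat, xhat))
    if ex == 0.0 or er == 0.0:
        raise ValueError("degenerate energy: one of the signals is all zero")
    return float(10.0 * np.log10(ex / er))


def compute_cs(x: np.ndarray, xhat: np.ndarray) -> float:
    """Cosine similarity, clamped to [-1, 1] against float overshoot."""
    x, xhat = _check_pair(x, xhat)
    nx = float(np.linalg.norm(x))
    nr = float(np.linalg.norm(xhat))
    if nx == 0.0 or nr == 0.0:
        raise ValueError("zero-norm signal: cosine similarity undefined")
    return float(np.clip(np.dot(x, xhat) / (nx * nr), -1.0, 1.0))


@dataclass
class FeatureTable:
    """Per-record feature vectors with class labels.

    ``df`` has columns ``record_id``, ``label`` plus ``feature_names``
    in order.
    """

    df: pd.DataFrame
    feature_names: list[str] = field(default_factory=lambda: list(AE_FEATURES))

    def __post_init__(self) -> None:
        required = ["record_id", "label", *self.feature_names]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.df = self.df[required].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        """(n, d) feature matrix."""
        return self.df[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        """Label vector, aligned with :attr:`x`."""
        return self.df["label"].to_numpy()

    def class_medians(self) -> pd.DataFrame:
        """Median of every feature per class."""
        return self.df.groupby("label", sort=True)[self.feature_names].median()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, feature_names: list[str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        if feature_names is None:
            feature_names = [c for c in df.columns if c not in ("record_id", "label")]
        return cls(df=df, feature_names=feature_names)


def extract_features(model: ConvAutoencoder, data: EegDataset) -> FeatureTable:
    """Reconstruct every record and tabulate (mse, orsr, cs) per record."""
    rows = []
    for rec in data:
        try:
            xhat = model.reconstruct(rec)
            rows.append(
                {
                    "record_id": rec.record_id,
                    "label": rec.label,
                    "mse": compute_mse(rec.samples, xhat),
                    "orsr": compute_orsr(rec.samples, xhat),
                    "cs": compute_cs(rec.samples, xhat),
                }
            )
        except ValueError as exc:
            raise ValueError(f"record {rec.record_id}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["record_id", "label", *AE_FEATURES])
    return FeatureTable(df=df, feature_names=list(AE_FEATURES))
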