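"""PCA feature extraction baseline.

The comparison arm of the study: centered principal component analysis on
the matrix of normalized signals, 10 components by default, all records
(all three classes pooled) used for the fit — the conventional
unsupervised baseline, in contrast to the one-class autoencoder.  The
classifiers consume all 10 component scores; the first 3 components can be
min-max normalized separately for distribution plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import FeatureTable
from .signal_io import EegDataset


@dataclass
class PcaModel:
    """Fitted PCA: mean signal, orthonormal components, explained variance.

    The sign of each component is fixed so its largest-magnitude loading is
    positive, making the fit deterministic.
    """

    mean: np.ndarray  # (L,)
    components: np.ndarray  # (k, L), orthonormal rows
    explained_variance: np.ndarray  # (k,), non-increasing

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return [f"pc{i + 1}" for i in range(self.k)]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(components.shape[0]), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_pca(data: EegDataset, k: int = 10) -> PcaModel:
    """Fit centered PCA with ``k`` components on the signal matrix."""
    n = len(data)
    if n <= k:
        raise ValueError(f"need more than k={k} records to fit PCA, got {n}")
    x = data.matrix()
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x)
    return PcaModel(
        mean=pca.mean_,
        components=_fix_signs(pca.components_),
        explained_variance=pca.explained_variance_,
    )


def pca_transform(model: PcaModel, data: EegDataset) -> FeatureTable:
    """Project records onto the components; one score column per PC."""
    x = data.matrix()
    if x.shape[1] != model.mean.size:
        raise ValueError(
            f"record length {x.shape[1]} does not match PCA length {model.mean.size}"
        )
    scores = (x - model.mean) @ model.components.T
    df = pd.DataFrame(scores, columns=model.feature_names)
    df.insert(0, "label", data.labels())
    df.insert(0, "record_id", [r.record_id for r in data])
    return FeatureTable(df=df, feature_names=model.feature_names)


def normalize_pcs(table: FeatureTable, m: int = 3) -> FeatureTable:
    """Min-max scale the first ``m`` PC columns to [0, 1] (for plotting)."""
    if m > len(table.feature_names):
        raise ValueError(f"m={m} exceeds feature count {len(table.feature_names)}")
    df = table.df.copy()
    for col in table.feature_names[:m]:
        lo, hi = df[col].min(), df[col].max()
        if hi == lo:
            raise ValueError(f"PC column {col!r} is constant; cannot min-max scale")
        df[col] = (df[col] - lo) / (hi - lo)
    return FeatureTable(df=df, feature_names=list(table.feature_names))
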