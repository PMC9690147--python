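"""Model interpretability: permutation importance and exact Shapley values.

Permutation importance measures each feature's contribution as the mean
accuracy drop when that column is shuffled, averaged over repeats.

Shapley values are computed *exactly* by enumerating all 2^d feature
coalitions — feasible because the reconstruction representation has only
d = 3 features — with the interventional value function: the value of a
coalition S for a sample z is the mean model output over background rows b
of f(z_S combined with b_complement).  The efficiency axiom holds by
construction: per sample and class, the attributions sum to the model
output minus the mean background output.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .features import FeatureTable

MAX_EXACT_FEATURES = 10


@dataclass
class PermutationImportanceResult:
    """Mean/sd accuracy drop per feature over shuffling repeats."""

    feature_names: list[str]
    mean: np.ndarray  # (d,)
    sd: np.ndarray  # (d,)
    n_repeats: int

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_repeats": self.n_repeats,
        }


@dataclass
class ShapleyResult:
    """Exact per-sample, per-class Shapley attributions.

    ``values`` has shape (n_samples, n_features, n_classes);
    ``baseline`` (n_classes,) is the mean model output over the background.
    """

    feature_names: list[str]
    class_order: list[str]
    values: np.ndarray
    baseline: np.ndarray
    prediction: np.ndarray  # (n_samples, n_classes) model output on the samples

    @property
    def mean_abs(self) -> np.ndarray:
        """(d, c) mean |Shapley| per feature per class."""
        return np.abs(self.values).mean(axis=0)


@dataclass
class ImportanceReport:
    """Combined interpretability report for one classifier."""

    classifier: str
    permutation: PermutationImportanceResult
    shapley: ShapleyResult

    @property
    def ranking(self) -> list[str]:
        return rank_features(self)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "permutation": self.permutation.to_dict(),
            "shapley_mean_abs": {
                feat: {
                    cls: float(self.shapley.mean_abs[i, j])
                    for j, cls in enumerate(self.shapley.class_order)
                }
                for i, feat in enumerate(self.shapley.feature_names)
            },
            "shapley_baseline": self.shapley.baseline.tolist(),
            "ranking": self.ranking,
        }


def permutation_importance(
    model, table: FeatureTable, n_repeats: int = 30, seed: int = 0
) -> PermutationImportanceResult:
    """Accuracy drop per independently shuffled feature column.

    Deterministic for a fixed seed.  A feature the model never consults
    yields an importance of exactly zero.
    """
    if len(table) < 2:
        raise ValueError("permutation importance needs at least 2 rows")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    res = _sk_permutation_importance(
        model,
        table.x,
        table.y,
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return PermutationImportanceResult(
        feature_names=list(table.feature_names),
        mean=res.importances_mean,
        sd=res.importances_std,
        n_repeats=n_repeats,
    )


def _coalition_values(model, z: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Value v(S) of every coalition for every sample.

    Returns (2^d, n_samples, n_classes); coalition S is encoded as the
    bitmask of its member features.
    """
    n, d = z.shape
    m = background.shape[0]
    values = None
    for mask in range(2 ** d):
        member = np.array([(mask >> j) & 1 for j in range(d)], dtype=bool)
        hybrid = np.broadcast_to(background, (n, m, d)).copy()
        hybrid[:, :, member] = z[:, None, member]
        proba = model.predict_proba(hybrid.reshape(n * m, d))
        if values is None:
            values = np.empty((2 ** d, n, proba.shape[1]))
        values[mask] = proba.reshape(n, m, -1).mean(axis=1)
    return values


def exact_shapley(model, table: FeatureTable, background: FeatureTable) -> ShapleyResult:
    """Interventional Shapley values by full coalition enumeration.

    For each sample, feature j's attribution is the exactly weighted sum of
    its marginal contributions v(S + j) - v(S) over all coalitions S not
    containing j, with the standard weight |S|! (d - |S| - 1)! / d!.
    """
    d = len(table.feature_names)
    if d > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{d} features: 2^d coalition enumeration is infeasible; "
            "use a sampling approximation (out of scope here)"
        )
    if len(background) == 0:
        raise ValueError("background table is empty")
    if list(background.feature_names) != list(table.feature_names):
        raise ValueError("background features do not match table features")
    z = table.x
    v = _coalition_values(model, z, background.x)
    n, n_classes = v.shape[1], v.shape[2]
    weights = [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    phi = np.zeros((n, d, n_classes))
    for mask in range(2 ** d):
        size = bin(mask).count("1")
        for j in range(d):
            if mask & (1 << j):
                continue
            phi[:, j, :] += weights[size] * (v[mask | (1 << j)] - v[mask])
    class_order = [str(c) for c in model.classes_]
    return ShapleyResult(
        feature_names=list(table.feature_names),
        class_order=class_order,
        values=phi,
        baseline=v[0].mean(axis=0) if n else np.zeros(n_classes),
        prediction=v[2 ** d - 1],
    )


def rank_features(report: ImportanceReport | ShapleyResult) -> list[str]:
    """Features sorted by class-averaged mean |Shapley|, descending.

    Ties are broken alphabetically.
    """
    shap = report.shapley if isinstance(report, ImportanceReport) else report
    scores = shap.mean_abs.mean(axis=1)
    order = sorted(zip(shap.feature_names, scores), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order]
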