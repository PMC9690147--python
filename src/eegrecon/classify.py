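"""Ensemble classification of feature tables with a 75/25 split protocol.

Three off-the-shelf tree ensembles — random forest, AdaBoost (decision
stumps) and gradient boosting — are trained on a feature table and scored
with confusion matrices and overall/per-class accuracy.  The split is
random, stratified by class so per-class test counts stay balanced.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .features import FeatureTable
from .signal_io import CLASSES

CLASSIFIER_KINDS = ("random_forest", "adaboost", "gradient_boosting")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition settings (default 75% train, stratified)."""

    train_fraction: float = 0.75
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass
class EvalReport:
    """Confusion matrix and accuracies for one classifier on one split.

    ``confusion`` rows are true classes, columns predicted, both in
    ``class_order``.
    """

    classifier: str
    class_order: list[str]
    confusion: np.ndarray  # (c, c) int
    train_accuracy: float
    test_accuracy: float
    per_class_recall: dict[str, float]

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if (self.confusion < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        total = int(self.confusion.sum())
        acc = np.trace(self.confusion) / total if total else float("nan")
        if total and abs(acc - self.test_accuracy) > 1e-9:
            raise ValueError("test_accuracy inconsistent with confusion matrix trace")

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "per_class_recall": dict(self.per_class_recall),
        }


def split_table(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Random disjoint, exhaustive train/test partition of a feature table."""
    df = table.df
    if spec.stratified:
        counts = df["label"].value_counts()
        singletons = sorted(counts[counts < 2].index)
        if singletons:
            raise ValueError(f"classes with a single row cannot be stratified: {singletons}")
    train_df, test_df = train_test_split(
        df,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=df["label"] if spec.stratified else None,
        shuffle=True,
    )
    names = list(table.feature_names)
    return FeatureTable(train_df, names), FeatureTable(test_df, names)


_HYPERPARAM_DEFAULTS = {
    "random_forest": {"n_estimators": 100},
    "adaboost": {"n_estimators": 100, "learning_rate": 1.0},
    "gradient_boosting": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
}


def train_classifier(kind: str, train: FeatureTable, seed: int = 0, **hyperparams):
    """Fit one of the three ensemble kinds on a training table.

    Returns a fitted sklearn estimator exposing ``predict`` and
    ``predict_proba``.  Hyperparameters default to the standard library
    settings (100 estimators; stumps for AdaBoost; depth-3 trees, learning
    rate 0.1 for gradient boosting) and can be overridden by keyword.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}")
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    params = {**_HYPERPARAM_DEFAULTS[kind], **hyperparams}
    if kind == "random_forest":
        model = RandomForestClassifier(random_state=seed, **params)
    elif kind == "adaboost":
        model = AdaBoostClassifier(random_state=seed, **params)
    else:
        model = GradientBoostingClassifier(random_state=seed, **params)
    model.fit(train.x, y)
    model.feature_names_ = list(train.feature_names)
    return model


def accuracy(model, table: FeatureTable) -> float:
    """Fraction of rows predicted correctly."""
    return float(np.mean(model.predict(table.x) == table.y))


def evaluate(
    model, test: FeatureTable, train: FeatureTable | None = None, name: str | None = None
) -> EvalReport:
    """Score a fitted classifier on a test table.

    ``train`` (optional) is re-scored to report training accuracy alongside.
    """
    if len(test) == 0:
        raise ValueError("test table is empty")
    expected = getattr(model, "feature_names_", None)
    if expected is not None and list(test.feature_names) != expected:
        raise ValueError(
            f"feature names {list(test.feature_names)} do not match training "
            f"features {expected}"
        )
    order = [c for c in CLASSES if c in set(test.y) | set(model.classes_)]
    pred = model.predict(test.x)
    cm = confusion_matrix(test.y, pred, labels=order)
    test_acc = float(np.trace(cm) / cm.sum())
    row_tot = cm.sum(axis=1)
    recall = {
        c: (float(cm[i, i] / row_tot[i]) if row_tot[i] else float("nan"))
        for i, c in enumerate(order)
    }
    return EvalReport(
        classifier=name or type(model).__name__,
        class_order=order,
        confusion=cm,
        train_accuracy=accuracy(model, train) if train is not None else float("nan"),
        test_accuracy=test_acc,
        per_class_recall=recall,
    )
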