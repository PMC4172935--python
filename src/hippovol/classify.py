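"""Majority-voting ensemble of SVM, MLP and pruned decision tree.

The feature vector per subject is (GM volume, WM volume, CSF volume, left
hippocampal area, right hippocampal area); the class labels are +1 for
Alzheimer's disease and -1 for controls.  Three base classifiers are
trained — an RBF-kernel SVM with C and gamma tuned by inner cross-validated
grid search, a 2-hidden-layer / 3-neurons-per-layer multilayer perceptron
with learning rate 0.3, and a pruned univariate decision tree — and the
ensemble labels a subject +1 exactly when strictly more than half of the
base votes are +1 (ties resolve to -1, the control class).

Evaluation is stratified k-fold cross-validation (default 10 folds):
per-fold training includes the inner hyperparameter search and the feature
standardization statistics, so no information leaks from test folds.  Test
predictions are pooled over folds into a confusion matrix per classifier,
from which accuracy, specificity (true-negative rate on controls) and
sensitivity (true-positive rate on patients) are reported as percentages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

__all__ = [
    "FEATURE_SUBSETS",
    "FeatureTable",
    "SVMConfig",
    "MLPConfig",
    "TreeConfig",
    "ClassifierConfig",
    "ConfusionCounts",
    "Metrics",
    "ClassifierOutcome",
    "EvaluationReport",
    "FittedEnsemble",
    "majority_vote",
    "train_base_classifiers",
    "predict_ensemble",
    "compute_metrics",
    "crossvalidate",
    "evaluate_all_subsets",
]

logger = logging.getLogger(__name__)

AD = 1
CONTROL = -1

ALL_FEATURES = ["vol_gm", "vol_wm", "vol_csf", "left_area", "right_area"]

# The eight feature configurations evaluated: each feature alone, the three
# tissue volumes combined, both hippocampal areas combined, and all five.
FEATURE_SUBSETS: dict[str, list[str]] = {
    "gm": ["vol_gm"],
    "wm": ["vol_wm"],
    "csf": ["vol_csf"],
    "gm+wm+csf": ["vol_gm", "vol_wm", "vol_csf"],
    "left": ["left_area"],
    "right": ["right_area"],
    "left+right": ["left_area", "right_area"],
    "all": ALL_FEATURES,
}

BASE_CLASSIFIERS = ("svm", "mlp", "tree")


@dataclass
class FeatureTable:
    """A labelled (or unlabelled) subject-by-feature table.

    ``frame`` must carry the five feature columns; ``label`` (+1/-1) is
    required for training/evaluation and optional at predict time.
    ``subset`` names the feature configuration in use.
    """

    frame: pd.DataFrame
    subset: str = "all"

    def __post_init__(self) -> None:
        if self.subset not in FEATURE_SUBSETS:
            raise ValidationError(
                f"unknown feature subset {self.subset!r}; "
                f"choose from {sorted(FEATURE_SUBSETS)}"
            )
        if len(self.frame) == 0:
            raise ValidationError("feature table must be non-empty")
        missing = [c for c in FEATURE_SUBSETS[self.subset] if c not in self.frame]
        if missing:
            raise ValidationError(f"feature table missing columns {missing}")
        feats = self.features
        if not np.all(np.isfinite(feats)) or np.any(feats < 0):
            raise ValidationError("features must be finite and >= 0")
        if self.has_labels:
            bad = set(self.frame["label"].unique()) - {AD, CONTROL}
            if bad:
                raise ValidationError(f"labels must be +1/-1, got extras {bad}")

    @classmethod
    def from_csv(cls, path, subset: str = "all") -> "FeatureTable":
        return cls(pd.read_csv(path), subset=subset)

    @property
    def has_labels(self) -> bool:
        return "label" in self.frame.columns

    @property
    def features(self) -> np.ndarray:
        return self.frame[FEATURE_SUBSETS[self.subset]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValidationError("feature table has no label column")
        return self.frame["label"].to_numpy(dtype=int)

    def with_subset(self, subset: str) -> "FeatureTable":
        return FeatureTable(self.frame, subset=subset)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SVMConfig:
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    inner_cv_folds: int = 3

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValidationError("SVM grids must be non-empty")
        if min(self.c_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise ValidationError("SVM grid values must be positive")
        if self.inner_cv_folds < 2:
            raise ValidationError("inner_cv_folds must be >= 2")


@dataclass(frozen=True)
class MLPConfig:
    hidden_layers: int = 2
    neurons_per_layer: int = 3
    learning_rate: float = 0.3
    momentum: float = 0.2
    max_epochs: int = 500

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValidationError("MLP architecture must be >= 1x1")


@dataclass(frozen=True)
class TreeConfig:
    """Pruned univariate decision tree (C4.5-style confidence factor).

    The confidence factor in (0, 0.5] controls pessimistic-pruning strength
    (smaller -> heavier pruning).  It is mapped monotonically onto
    cost-complexity pruning: alpha = 0.02 * (0.5/cf - 1), so cf = 0.5 means
    no pruning and the conventional cf = 0.25 gives alpha = 0.02.
    """

    confidence_factor: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.confidence_factor <= 0.5):
            raise ValidationError("confidence_factor must be in (0, 0.5]")

    @property
    def ccp_alpha(self) -> float:
        return 0.02 * (0.5 / self.confidence_factor - 1.0)


@dataclass(frozen=True)
class ClassifierConfig:
    svm: SVMConfig = field(default_factory=SVMConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    standardize: bool = True


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion matrix counts with AD (+1) as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValidationError("y_true and y_pred must have the same length")
        return cls(
            tp=int(np.sum((y_true == AD) & (y_pred == AD))),
            fn=int(np.sum((y_true == AD) & (y_pred == CONTROL))),
            tn=int(np.sum((y_true == CONTROL) & (y_pred == CONTROL))),
            fp=int(np.sum((y_true == CONTROL) & (y_pred == AD))),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    """Accuracy / specificity / sensitivity, as percentages.

    Specificity or sensitivity is None when its denominator is zero (no
    controls / no patients in the evaluation set).
    """

    accuracy: float
    specificity: float | None
    sensitivity: float | None


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, specificity and sensitivity (in %) from confusion counts."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics from all-zero counts")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    sensitivity = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return Metrics(accuracy, specificity, sensitivity)


def majority_vote(votes: list[int]) -> int:
    """+1 iff strictly more than half of the votes are +1, else -1.

    With the three base classifiers this is plain majority; ties at even
    vote counts resolve to -1 (control).
    """
    if len(votes) == 0:
        raise ValidationError("majority_vote requires at least one vote")
    bad = set(votes) - {AD, CONTROL}
    if bad:
        raise ValidationError(f"votes must be +1/-1, got {bad}")
    n = len(votes)
    return AD if sum(v == AD for v in votes) > n / 2 else CONTROL


def _maybe_scaled(steps: list, standardize: bool) -> Pipeline:
    if standardize:
        steps = [("scale", StandardScaler())] + steps
    return Pipeline(steps)


@dataclass
class FittedEnsemble:
    """The fitted (SVM, MLP, tree) triple bound to a feature subset."""

    models: dict[str, object]
    subset: str

    def predict_bases(self, rows: FeatureTable) -> dict[str, np.ndarray]:
        if rows.subset != self.subset:
            raise ValidationError(
                f"models fitted on subset {self.subset!r} cannot predict "
                f"subset {rows.subset!r}"
            )
        X = rows.features
        return {
            name: np.asarray(model.predict(X), dtype=int)
            for name, model in self.models.items()
        }


def train_base_classifiers(
    train: FeatureTable, config: ClassifierConfig | None = None, seed: int = 0
) -> FittedEnsemble:
    """Fit the SVM, MLP and tree on a training table.

    The SVM's C and gamma are chosen by stratified inner cross-validated
    grid search on the training rows only; when standardization is enabled
    the scaler is part of each model's pipeline so its statistics come from
    the training rows of each (inner) fold.  Non-convergence of the MLP is
    logged as a warning; the model is still returned.
    """
    config = config or ClassifierConfig()
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training set must contain both classes")
    min_class = int(counts.min())

    svc = SVC(kernel="rbf")
    if min_class >= 2:
        inner_k = min(config.svm.inner_cv_folds, min_class)
        inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        grid = {
            "svc__C": list(config.svm.c_grid),
            "svc__gamma": list(config.svm.gamma_grid),
        }
        svm = GridSearchCV(
            _maybe_scaled([("svc", svc)], config.standardize),
            grid,
            cv=inner,
            scoring="accuracy",
            n_jobs=None,
        )
    else:
        logger.warning(
            "too few members per class for inner CV; using default C=1, "
            "gamma='scale'"
        )
        svm = _maybe_scaled([("svc", svc)], config.standardize)

    mlp = _maybe_scaled(
        [
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(config.mlp.neurons_per_layer,)
                    * config.mlp.hidden_layers,
                    solver="sgd",
                    learning_rate_init=config.mlp.learning_rate,
                    momentum=config.mlp.momentum,
                    max_iter=config.mlp.max_epochs,
                    random_state=seed,
                ),
            )
        ],
        config.standardize,
    )

    tree = _maybe_scaled(
        [
            (
                "tree",
                DecisionTreeClassifier(
                    criterion="entropy",
                    ccp_alpha=config.tree.ccp_alpha,
                    random_state=seed,
                ),
            )
        ],
        config.standardize,
    )

    X = train.features
    models: dict[str, object] = {}
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        for name, model in (("svm", svm), ("mlp", mlp), ("tree", tree)):
            try:
                model.fit(X, y)
            except ConvergenceWarning:
                logger.warning("%s did not converge; keeping the model", name)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(X, y)
            models[name] = model
    return FittedEnsemble(models=models, subset=train.subset)


def predict_ensemble(models: FittedEnsemble, rows: FeatureTable) -> np.ndarray:
    """Majority-vote prediction per row from the three base classifiers."""
    base = models.predict_bases(rows)
    stacked = np.vstack([base[name] for name in BASE_CLASSIFIERS])
    return np.array(
        [majority_vote(list(stacked[:, i])) for i in range(stacked.shape[1])],
        dtype=int,
    )


@dataclass
class ClassifierOutcome:
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class EvaluationReport:
    """Pooled cross-validation outcome for the bases and the ensemble."""

    outcomes: dict[str, ClassifierOutcome]
    fold_assignments: np.ndarray
    k: int
    seed: int
    subset: str
    predictions: dict[str, np.ndarray] = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable metric table."""

        def fmt(v: float | None) -> str:
            return "   --" if v is None else f"{v:5.1f}"

        lines = [
            f"Stratified {self.k}-fold cross-validation "
            f"(subset={self.subset!r}, seed={self.seed})",
            f"{'classifier':<12}{'ACC%':>8}{'SPE%':>8}{'SEN%':>8}"
            f"{'tp':>5}{'fn':>5}{'tn':>5}{'fp':>5}",
        ]
        for name in (*BASE_CLASSIFIERS, "ensemble"):
            o = self.outcomes[name]
            m, c = o.metrics, o.counts
            lines.append(
                f"{name:<12}{m.accuracy:8.2f}{fmt(m.specificity):>8}"
                f"{fmt(m.sensitivity):>8}{c.tp:5d}{c.fn:5d}{c.tn:5d}{c.fp:5d}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out: dict = {"k": self.k, "seed": self.seed, "subset": self.subset}
        out["classifiers"] = {}
        for name, o in self.outcomes.items():
            out["classifiers"][name] = {
                "counts": asdict(o.counts),
                "accuracy": o.metrics.accuracy,
                "specificity": o.metrics.specificity,
                "sensitivity": o.metrics.sensitivity,
            }
        out["fold_assignments"] = self.fold_assignments.tolist()
        return out


def crossvalidate(
    table: FeatureTable,
    k: int = 10,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the bases and the ensemble.

    Every subject lands in exactly one test fold; hyperparameter tuning and
    standardization happen inside each training fold.  Test predictions are
    pooled over folds into one confusion matrix per classifier
    (micro-average).  If a class has fewer than k members, k is reduced to
    that count with a warning (k >= 2 always).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    config = config or ClassifierConfig()
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("cross-validation requires both classes")
    min_class = int(counts.min())
    if min_class < k:
        if min_class < 2:
            raise ValidationError(
                "each class needs at least 2 members for cross-validation"
            )
        logger.warning("reducing k from %d to %d (smallest class)", k, min_class)
        k = min_class

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n = len(table)
    fold_assignments = np.full(n, -1, dtype=int)
    pooled: dict[str, np.ndarray] = {
        name: np.zeros(n, dtype=int) for name in (*BASE_CLASSIFIERS, "ensemble")
    }
    X_dummy = np.zeros((n, 1))
    for fold, (train_idx, test_idx) in enumerate(skf.split(X_dummy, y)):
        fold_assignments[test_idx] = fold
        train_tab = FeatureTable(table.frame.iloc[train_idx], subset=table.subset)
        test_tab = FeatureTable(table.frame.iloc[test_idx], subset=table.subset)
        fitted = train_base_classifiers(train_tab, config, seed=seed)
        base = fitted.predict_bases(test_tab)
        for name in BASE_CLASSIFIERS:
            pooled[name][test_idx] = base[name]
        pooled["ensemble"][test_idx] = predict_ensemble(fitted, test_tab)

    outcomes = {}
    for name, preds in pooled.items():
        c = ConfusionCounts.from_predictions(y, preds)
        outcomes[name] = ClassifierOutcome(counts=c, metrics=compute_metrics(c))
    return EvaluationReport(
        outcomes=outcomes,
        fold_assignments=fold_assignments,
        k=k,
        seed=seed,
        subset=table.subset,
        predictions=pooled,
    )


def evaluate_all_subsets(
    table: FeatureTable,
    k: int = 10,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Metric matrix over all eight feature subsets and four classifiers.

    Returns a tidy DataFrame with columns subset, classifier, accuracy,
    specificity, sensitivity (percentages).
    """
    rows = []
    for subset in FEATURE_SUBSETS:
        report = crossvalidate(table.with_subset(subset), k=k, config=config, seed=seed)
        for name, o in report.outcomes.items():
            rows.append(
                {
                    "subset": subset,
                    "classifier": name,
                    "accuracy": o.metrics.accuracy,
                    "specificity": o.metrics.specificity,
                    "sensitivity": o.metrics.sensitivity,
                }
            )
    return pd.DataFrame(rows)
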