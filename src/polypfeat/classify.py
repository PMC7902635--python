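"""Classifiers and the cross-validated seven-metric evaluation harness.

Two classifiers are provided: a least-squares support vector machine (LSSVM,
Suykens formulation — the equality-constrained dual collapses to one linear
system) with an RBF kernel, and a single-hidden-layer multilayer perceptron.
Evaluation uses stratified five-fold cross-validation with per-fold feature
standardization (fit on the training split only) and reports accuracy,
sensitivity, specificity, precision, recall, F-measure and G-mean, per fold
and as mean +/- std.  The positive class is the neoplastic one (label 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import InvalidInputError

METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "recall",
    "f_measure",
    "g_mean",
)

KKT_RESIDUAL_TOL = 1e-8


@dataclass
class ClassifierSpec:
    """Which classifier to train and with what parameters."""

    kind: str = "mlp"  # "mlp" | "lssvm"
    params: dict = field(default_factory=dict)


class LSSVM:
    """Least-squares SVM with RBF kernel ``exp(-gamma_k ||x - z||^2)``.

    Training solves the KKT system ``[[0, 1^T], [1, K + I/gamma]] [b; a] =
    [0; y]`` with labels in {-1, +1}.  ``gamma`` is the regularization
    weight; ``gamma_k=None`` uses the median-pairwise-distance heuristic.
    """

    def __init__(self, gamma: float = 10.0, gamma_k: float | None = None):
        if gamma <= 0:
            raise InvalidInputError("gamma must be positive")
        self.gamma = float(gamma)
        self.gamma_k = gamma_k

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = pairwise_distances(A, B, metric="sqeuclidean")
        return np.exp(-self.gamma_k_ * d2)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InvalidInputError("LSSVM requires exactly two classes in y")
        self.classes_ = classes
        t = np.where(y == classes[1], 1.0, -1.0)
        if self.gamma_k is None:
            d = pairwise_distances(X, X)
            med = np.median(d[np.triu_indices_from(d, k=1)])
            self.gamma_k_ = 1.0 / (2.0 * med * med) if med > 0 else 1.0
        else:
            self.gamma_k_ = float(self.gamma_k)
        n = X.shape[0]
        K = self._kernel(X, X)
        ridge = 1.0 / self.gamma
        for attempt in range(6):
            A = np.zeros((n + 1, n + 1))
            A[0, 1:] = 1.0
            A[1:, 0] = 1.0
            A[1:, 1:] = K + np.eye(n) * ridge
            rhs = np.concatenate([[0.0], t])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                ridge *= 10.0
                continue
            if np.abs(A @ sol - rhs).max() < KKT_RESIDUAL_TOL:
                break
            ridge *= 10.0
        else:
            raise InvalidInputError("LSSVM system remained singular")
        self.bias_ = float(sol[0])
        self.coef_ = sol[1:]
        self.X_ = X
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._kernel(np.asarray(X, dtype=float), self.X_) @ self.coef_ + self.bias_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def train_lssvm(
    X: np.ndarray,
    y: np.ndarray,
    gamma: float | None = None,
    gamma_k: float | None = None,
    seed: int = 0,
) -> LSSVM:
    """Train an LSSVM; ``gamma=None`` selects it by inner 3-fold grid search."""
    if gamma is not None:
        return LSSVM(gamma=gamma, gamma_k=gamma_k).fit(X, y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise InvalidInputError("LSSVM requires exactly two classes in y")
    best, best_acc = None, -1.0
    n_inner = min(3, *np.bincount(pd.factorize(y)[0]))
    if n_inner < 2:
        return LSSVM(gamma=10.0, gamma_k=gamma_k).fit(X, y)
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    for g in (0.1, 1.0, 10.0, 100.0):
        accs = []
        for tr, te in skf.split(X, y):
            model = LSSVM(gamma=g, gamma_k=gamma_k).fit(X[tr], y[tr])
            accs.append(float(np.mean(model.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best, best_acc = g, acc
    return LSSVM(gamma=best, gamma_k=gamma_k).fit(X, y)


def default_hidden_size(n_features: int, n_classes: int = 2) -> int:
    return math.ceil((n_features + n_classes) / 2)


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden_spec: tuple[int, ...] | None = None,
    seed: int = 0,
    max_iter: int = 400,
) -> MLPClassifier:
    """Train a feed-forward network with one hidden layer (seeded).

    The default hidden size is ``ceil((n_features + n_classes) / 2)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise InvalidInputError("training labels contain a single class")
    if hidden_spec is None:
        hidden_spec = (default_hidden_size(X.shape[1], np.unique(y).size),)
    if len(hidden_spec) == 0 or any(h < 1 for h in hidden_spec):
        raise InvalidInputError("hidden layer spec must contain positive sizes")
    model = MLPClassifier(
        hidden_layer_sizes=tuple(hidden_spec),
        random_state=seed,
        max_iter=max_iter,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    model.converged_flag_ = model.n_iter_ < max_iter
    return model


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is neoplastic (label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive=1) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos = y_true == positive
        pred_pos = y_pred == positive
        return cls(
            tp=int(np.sum(pos & pred_pos)),
            tn=int(np.sum(~pos & ~pred_pos)),
            fp=int(np.sum(~pos & pred_pos)),
            fn=int(np.sum(pos & ~pred_pos)),
        )


def metrics(counts: ConfusionCounts) -> dict:
    """The seven evaluation metrics; undefined ratios report 0 with a flag."""
    if counts.total <= 0:
        raise InvalidInputError("empty confusion counts")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    rec = sens
    f_meas = ratio(2 * prec * rec, prec + rec, "f_measure")
    out = {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": rec,
        "f_measure": f_meas,
        "g_mean": math.sqrt(sens * spec),
        "undefined": tuple(flags),
    }
    return out


@dataclass
class EvalReport:
    """Per-fold metric table plus mean and std across folds."""

    per_fold: pd.DataFrame
    mean: dict
    std: dict
    fold_assignment: np.ndarray
    classifier: ClassifierSpec

    def to_text(self) -> str:
        lines = [f"classifier: {self.classifier.kind}"]
        for m in METRIC_NAMES:
            lines.append(
                f"{m:>12s}: {100 * self.mean[m]:6.2f} (+/-{100 * self.std[m]:5.2f}) %"
            )
        return "\n".join(lines)


def _train_by_spec(spec: ClassifierSpec, X, y, seed: int):
    if spec.kind == "mlp":
        return train_mlp(X, y, seed=seed, **spec.params)
    if spec.kind == "lssvm":
        return train_lssvm(X, y, seed=seed, **spec.params)
    raise InvalidInputError(f"unknown classifier kind {spec.kind!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold evaluation with per-fold standardization."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    spec = spec or ClassifierSpec()
    counts = np.bincount(y, minlength=2)
    if np.min(counts[np.nonzero(counts)]) < n_folds:
        raise InvalidInputError(
            f"every class needs at least {n_folds} samples for {n_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    assignment = np.empty(y.size, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignment[te] = fold
        scaler = StandardScaler().fit(X[tr])
        model = _train_by_spec(spec, scaler.transform(X[tr]), y[tr], seed=seed + fold)
        pred = model.predict(scaler.transform(X[te]))
        row = metrics(ConfusionCounts.from_predictions(y[te], pred))
        row.pop("undefined")
        row["fold"] = fold
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return EvalReport(
        per_fold=per_fold,
        mean={m: float(per_fold[m].mean()) for m in METRIC_NAMES},
        std={m: float(per_fold[m].std(ddof=1)) for m in METRIC_NAMES},
        fold_assignment=assignment,
        classifier=spec,
    )
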