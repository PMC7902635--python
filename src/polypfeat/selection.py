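"""Fuzzy-entropy feature ranking and the accuracy-vs-dimension sweep.

Each feature is scored on its own: per-sample fuzzy memberships to each
class are computed with the inverse-distance (fuzzy c-means style) rule on
sigma-standardized distances to the class centers, and the mutual
information between the induced fuzzy partition and the class labels is
``MI(f; C) = H(f) + H(C) - H(f, C)`` with possibility-weighted joint and
marginal entropies.  Features are ranked by decreasing MI; a sweep over
nested top-k subsets (k = 6, 12, ..., m) under shared cross-validation
folds picks the dimension with peak accuracy, ties going to the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierSpec, cross_validate
from .errors import InvalidInputError

DEFAULT_RHO = 2.0
DEFAULT_EPSILON = 1e-10
MIN_SWEEP_DIM = 6


@dataclass(frozen=True)
class FuzzyMembership:
    """Row-normalized membership of each sample in each class (T x c)."""

    mu: np.ndarray
    rho: float
    epsilon: float
    degenerate: bool = False


@dataclass(frozen=True)
class RankedFeatures:
    """Per-feature mutual information and the descending-MI ordering."""

    mi: np.ndarray
    order: np.ndarray
    degenerate: np.ndarray

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass(frozen=True)
class SweepResult:
    candidate_ks: tuple[int, ...]
    accuracy_at_k: tuple[float, ...]
    selected_k: int
    selected_indices: np.ndarray


def fuzzy_membership(
    feature_values: np.ndarray,
    labels: np.ndarray,
    rho: float = DEFAULT_RHO,
    epsilon: float = DEFAULT_EPSILON,
) -> FuzzyMembership:
    """Membership of every sample in every class for one scalar feature.

    The distance of sample k to class i is the absolute difference to the
    class-i mean, standardized by the feature's global standard deviation;
    memberships follow the inverse-distance rule with fuzzifier exponent
    ``2 / (rho - 1)`` and are normalized to sum to 1 per sample.
    """
    if rho <= 1:
        raise InvalidInputError("fuzzification parameter rho must exceed 1")
    v = np.asarray(feature_values, dtype=float).ravel()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("need at least two classes")
    if any(np.sum(y == c) < 1 for c in classes):
        raise InvalidInputError("every class needs at least one sample")
    sigma = v.std()
    if sigma == 0:
        # constant feature: no information; uniform memberships, flagged
        mu = np.full((v.size, classes.size), 1.0 / classes.size)
        return FuzzyMembership(mu=mu, rho=rho, epsilon=epsilon, degenerate=True)
    centers = np.array([v[y == c].mean() for c in classes])
    d = np.abs(v[:, None] - centers[None, :]) / sigma
    w = (d + epsilon) ** (-2.0 / (rho - 1.0))
    mu = w / w.sum(axis=1, keepdims=True)
    return FuzzyMembership(mu=mu, rho=rho, epsilon=epsilon)


def _feature_mi(values: np.ndarray, labels: np.ndarray, rho, epsilon) -> tuple[float, bool]:
    fm = fuzzy_membership(values, labels, rho, epsilon)
    if fm.degenerate:
        return 0.0, True
    y = np.asarray(labels)
    classes = np.unique(y)
    T = y.size

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    # joint possibility of (fuzzy set i, class j)
    joint = np.stack([fm.mu[y == c].sum(axis=0) / T for c in classes], axis=1)
    h_joint = entropy(joint.ravel())
    h_f = entropy(fm.mu.sum(axis=0) / T)
    h_c = entropy(np.array([np.mean(y == c) for c in classes]))
    return h_f + h_c - h_joint, False


def fuzzy_mi(
    X: np.ndarray,
    y: np.ndarray,
    rho: float = DEFAULT_RHO,
    epsilon: float = DEFAULT_EPSILON,
) -> RankedFeatures:
    """Rank every feature column of X by fuzzy mutual information with y.

    Degenerate (zero-variance) features receive MI = 0 and are flagged.
    Ranking is by decreasing MI with stable index tie-breaking.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mi = np.empty(X.shape[1])
    degenerate = np.zeros(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        mi[j], degenerate[j] = _feature_mi(X[:, j], y, rho, epsilon)
    order = np.argsort(-mi, kind="stable")
    return RankedFeatures(mi=mi, order=order, degenerate=degenerate)


def candidate_dimensions(m: int, k_step: int = MIN_SWEEP_DIM) -> tuple[int, ...]:
    """The swept dimensions {k_step, 2 k_step, ..., m} (m appended if off-grid)."""
    if m < k_step:
        raise InvalidInputError(f"need at least {k_step} features to sweep")
    ks = list(range(k_step, m + 1, k_step))
    if ks[-1] != m:
        ks.append(m)
    return tuple(ks)


def sweep_dimensions(
    X: np.ndarray,
    y: np.ndarray,
    ranking: RankedFeatures,
    classifier_spec: ClassifierSpec | None = None,
    k_step: int = MIN_SWEEP_DIM,
    n_folds: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Cross-validated accuracy over nested top-k feature subsets.

    The same seeded folds are reused for every k, so the comparison across
    dimensions is free of fold-resampling noise.  The selected k maximizes
    mean accuracy; exact ties break toward the smaller dimension.
    """
    X = np.asarray(X, dtype=float)
    ks = candidate_dimensions(X.shape[1], k_step)
    accs = []
    for k in ks:
        cols = ranking.top(k)
        report = cross_validate(X[:, cols], y, classifier_spec, n_folds, seed)
        accs.append(report.mean["accuracy"])
    best = max(accs)
    selected_k = next(k for k, a in zip(ks, accs) if a >= best - 1e-12)
    return SweepResult(
        candidate_ks=ks,
        accuracy_at_k=tuple(accs),
        selected_k=selected_k,
        selected_indices=ranking.top(selected_k),
    )
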