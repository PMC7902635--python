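"""Statistical screening of descriptor families.

Before classification, each descriptor family is screened with (i) a
fixed-effects two-way ANOVA (factors: class and transform filter, no
interaction) on a per-sample scalar summary of the descriptor, (ii) Pearson
correlation between family summaries to detect redundant families, and
(iii) per-feature-set independent two-sample t-tests.  A family passes the
gate iff the class factor is significant at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import InvalidInputError, UnbalancedDesignError

ALPHA = 0.05
CORRELATION_THRESHOLD = 0.8


@dataclass(frozen=True)
class AnovaResult:
    p_class: float
    f_class: float
    df_class: int
    p_filter: float | None
    f_filter: float | None
    df_filter: int | None
    df_resid: int

    @property
    def passes_gate(self) -> bool:
        return self.p_class < ALPHA


def descriptor_summary(vectors: np.ndarray) -> np.ndarray:
    """Scalar dependent variable per sample: the descriptor-vector mean."""
    return np.atleast_2d(np.asarray(vectors, dtype=float)).mean(axis=1)


def anova_two_way(values, class_factor, filter_factor=None) -> AnovaResult:
    """Fixed-effects ANOVA of scalar summaries on class (+ optional filter).

    With a single filter level (or none) the model reduces to a one-way
    ANOVA on the class factor and the filter effect is reported as absent.
    """
    values = np.asarray(values, dtype=float)
    cls = np.asarray(class_factor)
    if np.unique(cls).size < 2:
        raise InvalidInputError("class factor needs at least 2 levels")
    filt = None if filter_factor is None else np.asarray(filter_factor)
    if filt is not None and np.unique(filt).size < 2:
        filt = None
    df = pd.DataFrame({"v": values, "cls": cls})
    if filt is None:
        for level in np.unique(cls):
            if np.sum(cls == level) < 2:
                raise UnbalancedDesignError("need >= 2 samples per class cell")
        model = smf.ols("v ~ C(cls)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        return AnovaResult(
            p_class=float(tab.loc["C(cls)", "PR(>F)"]),
            f_class=float(tab.loc["C(cls)", "F"]),
            df_class=int(tab.loc["C(cls)", "df"]),
            p_filter=None,
            f_filter=None,
            df_filter=None,
            df_resid=int(tab.loc["Residual", "df"]),
        )
    df["filt"] = filt
    counts = df.groupby(["cls", "filt"]).size()
    full = np.unique(cls).size * np.unique(filt).size
    if len(counts) < full or (counts < 2).any():
        raise UnbalancedDesignError("every (class, filter) cell needs >= 2 samples")
    model = smf.ols("v ~ C(cls) + C(filt)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    return AnovaResult(
        p_class=float(tab.loc["C(cls)", "PR(>F)"]),
        f_class=float(tab.loc["C(cls)", "F"]),
        df_class=int(tab.loc["C(cls)", "df"]),
        p_filter=float(tab.loc["C(filt)", "PR(>F)"]),
        f_filter=float(tab.loc["C(filt)", "F"]),
        df_filter=int(tab.loc["C(filt)", "df"]),
        df_resid=int(tab.loc["Residual", "df"]),
    )


def anova_per_dimension(X, class_factor, filter_factor=None) -> AnovaResult:
    """Family-level ANOVA via per-dimension tests with Bonferroni control.

    Each feature dimension is tested separately (two-way when a filter
    factor with >= 2 levels is given, one-way otherwise) and the family
    p-value is the smallest per-dimension p times the dimension count,
    capped at 1.  This keeps the family-wise error at the nominal level
    while letting any single strongly class-separating dimension gate the
    family in; a scalar-summary ANOVA can mask such dimensions when their
    class effects have opposing signs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    cls = np.asarray(class_factor)
    filt = None if filter_factor is None else np.asarray(filter_factor)
    if filt is not None and np.unique(filt).size < 2:
        filt = None
    if filt is None:
        if np.unique(cls).size < 2:
            raise InvalidInputError("class factor needs at least 2 levels")
        for level in np.unique(cls):
            if np.sum(cls == level) < 2:
                raise UnbalancedDesignError("need >= 2 samples per class cell")
        groups = [X[cls == level] for level in np.unique(cls)]
        f_stat, p = stats.f_oneway(*groups, axis=0)
        f_stat = np.atleast_1d(f_stat)
        p = np.atleast_1d(p)
        # constant dimensions yield NaN; they carry no class information
        p = np.where(np.isnan(p), 1.0, p)
        f_stat = np.where(np.isnan(f_stat), 0.0, f_stat)
        j = int(np.argmin(p))
        return AnovaResult(
            p_class=float(min(1.0, m * p[j])),
            f_class=float(f_stat[j]),
            df_class=int(np.unique(cls).size - 1),
            p_filter=None,
            f_filter=None,
            df_filter=None,
            df_resid=int(X.shape[0] - np.unique(cls).size),
        )
    results = [anova_two_way(X[:, j], cls, filt) for j in range(m)]
    best = min(results, key=lambda r: r.p_class)
    p_filt = min(1.0, m * min(r.p_filter for r in results))
    return AnovaResult(
        p_class=float(min(1.0, m * best.p_class)),
        f_class=best.f_class,
        df_class=best.df_class,
        p_filter=float(p_filt),
        f_filter=max(r.f_filter for r in results),
        df_filter=best.df_filter,
        df_resid=best.df_resid,
    )


@dataclass(frozen=True)
class CorrelationReport:
    names: tuple[str, ...]
    r: pd.DataFrame
    high_flags: pd.DataFrame
    threshold: float

    def is_flagged(self, a: str, b: str) -> bool:
        return bool(self.high_flags.loc[a, b])


def pearson_matrix(
    family_summaries: dict[str, np.ndarray],
    threshold: float = CORRELATION_THRESHOLD,
) -> CorrelationReport:
    """Pearson r between named summary vectors of equal length.

    Zero-variance vectors yield undefined (NaN) correlations, reported as
    missing and never flagged.
    """
    names = tuple(family_summaries)
    arrs = {k: np.asarray(v, dtype=float).ravel() for k, v in family_summaries.items()}
    lengths = {v.size for v in arrs.values()}
    if len(lengths) != 1:
        raise InvalidInputError("summary vectors must have equal length")
    if lengths.pop() < 3:
        raise InvalidInputError("need at least 3 paired observations")
    df = pd.DataFrame(arrs)
    r = df.corr(method="pearson")  # NaN where a vector has zero variance
    for name in names:
        if arrs[name].std() == 0:
            r.loc[name, :] = np.nan
            r.loc[:, name] = np.nan
    flags = r.abs().ge(threshold) & r.notna()
    return CorrelationReport(names=names, r=r, high_flags=flags, threshold=threshold)


@dataclass(frozen=True)
class TTestReport:
    rows: pd.DataFrame  # index: feature-set name; columns: t, p, df


def t_test_features(
    X: np.ndarray,
    y: np.ndarray,
    feature_sets: dict[str, np.ndarray] | None = None,
    welch: bool = False,
) -> TTestReport:
    """Independent two-sample t-test per feature set.

    Each sample is summarized by the mean over the set's features, then the
    two class groups are compared with a pooled-variance t-test (``welch``
    switches to the unequal-variance form).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidInputError("t-test requires exactly two classes")
    if any(np.sum(y == c) < 2 for c in classes):
        raise InvalidInputError("every class needs at least 2 samples")
    if feature_sets is None:
        feature_sets = {"all": np.arange(X.shape[1])}
    rows = {}
    for name, cols in feature_sets.items():
        summary = X[:, np.asarray(cols, dtype=int)].mean(axis=1)
        a = summary[y == classes[0]]
        b = summary[y == classes[1]]
        res = stats.ttest_ind(a, b, equal_var=not welch)
        rows[name] = {"t": float(res.statistic), "p": float(res.pvalue), "df": float(res.df)}
    return TTestReport(rows=pd.DataFrame(rows).T)
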