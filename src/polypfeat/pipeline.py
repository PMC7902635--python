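"""High-level orchestration: feature extraction over a dataset, the
statistics gate, and the selection + evaluation phase, shared by the CLI,
the acceptance script and the end-to-end tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import nsct, selection, stats_gate
from .classify import ClassifierSpec, EvalReport, cross_validate
from .errors import InvalidInputError
from .gfd import gfd_descriptor, gfd_feature_names
from .imaging import BinaryMask, load_image, load_mask

logger = logging.getLogger("polypfeat")

SCHEMES = ("GFD", "F1", "F2", "combined")


def extract_vector(scheme: str, img, mask: BinaryMask | None, filters, level_vector):
    if scheme == "GFD":
        if mask is None:
            raise InvalidInputError("GFD features require a mask")
        d = gfd_descriptor(mask)
        return feat.FeatureVector(
            values=d.values, scheme="GFD", names=tuple(gfd_feature_names())
        )
    if scheme == "F1":
        return feat.f1_features(img, filters, level_vector)
    if scheme == "F2":
        return feat.f2_features(img, filters, level_vector)
    if scheme == "combined":
        if mask is None:
            raise InvalidInputError("combined features require a mask")
        return feat.combined_features(img, mask, filters, level_vector)
    raise InvalidInputError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def extract_table(
    images,
    masks,
    labels,
    scheme: str = "combined",
    filter_pair: tuple[str, str] = feat.DEFAULT_FILTER_PAIR,
    level_vector=feat.DEFAULT_LEVEL_VECTOR,
) -> pd.DataFrame:
    """Feature table (one row per image + label column) for in-memory data."""
    filters = nsct.build_filters(*filter_pair)
    vectors = []
    for i, img in enumerate(images):
        vectors.append(extract_vector(scheme, img, masks[i], filters, level_vector))
        logger.info("extracted %s features for image %d/%d", scheme, i + 1, len(images))
    return feat.assemble_table(vectors, labels)


def extract_table_from_manifest(
    manifest: str | Path,
    scheme: str = "combined",
    filter_pair: tuple[str, str] = feat.DEFAULT_FILTER_PAIR,
    level_vector=feat.DEFAULT_LEVEL_VECTOR,
) -> pd.DataFrame:
    """Feature table from a CSV manifest with image, mask, label columns.

    Unreadable rows are skipped with a logged warning.
    """
    manifest = Path(manifest)
    rows = pd.read_csv(manifest)
    if rows.empty:
        raise InvalidInputError(f"manifest {manifest} lists no images")
    filters = nsct.build_filters(*filter_pair)
    vectors, labels, skipped = [], [], 0
    for _, row in rows.iterrows():
        try:
            img = load_image(manifest.parent / row["image"])
            mask = load_mask(manifest.parent / row["mask"]) if "mask" in row else None
            vectors.append(extract_vector(scheme, img, mask, filters, level_vector))
            labels.append(int(row["label"]))
        except Exception as exc:  # noqa: BLE001 - row-level robustness
            skipped += 1
            logger.warning("skipping %s: %s", row.get("image"), exc)
    if skipped:
        logger.warning("%d rows skipped during extraction", skipped)
    if not vectors:
        raise InvalidInputError("no readable rows in manifest")
    return feat.assemble_table(vectors, labels)


@dataclass
class GateReport:
    anova: dict[str, stats_gate.AnovaResult]
    correlation: stats_gate.CorrelationReport

    def to_text(self) -> str:
        lines = ["family   p_class   p_filter  gate"]
        for name, res in self.anova.items():
            pf = "NA" if res.p_filter is None else f"{res.p_filter:.4f}"
            lines.append(
                f"{name:8s} {res.p_class:8.4f}  {pf:>8s}  "
                f"{'in' if res.passes_gate else 'out'}"
            )
        return "\n".join(lines)


def run_gate(tables: dict[str, pd.DataFrame], dv: str = "per_dimension") -> GateReport:
    """ANOVA per descriptor family plus the cross-family correlation matrix.

    ``tables`` maps family name -> feature table; every table must carry the
    same labels in the same order.  ``dv`` selects the ANOVA dependent
    variable: ``"per_dimension"`` (default) tests every feature dimension
    with Bonferroni family-wise control, ``"mean"`` uses the per-sample
    descriptor-vector mean as a scalar DV.  Correlations between families
    always use the descriptor-vector mean summaries.
    """
    if dv not in ("per_dimension", "mean"):
        raise InvalidInputError("dv must be 'per_dimension' or 'mean'")
    anova = {}
    summaries = {}
    for name, df in tables.items():
        X, y, _ = feat.split_table(df)
        summaries[name] = stats_gate.descriptor_summary(X)
        if dv == "mean":
            anova[name] = stats_gate.anova_two_way(summaries[name], y)
        else:
            anova[name] = stats_gate.anova_per_dimension(X, y)
    correlation = stats_gate.pearson_matrix(summaries)
    return GateReport(anova=anova, correlation=correlation)


@dataclass
class SelectEvalResult:
    ranking: selection.RankedFeatures
    sweep: selection.SweepResult
    report_full: EvalReport
    report_selected: EvalReport
    feature_names: list[str]

    @property
    def selected_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.sweep.selected_indices]


def select_and_evaluate(
    table: pd.DataFrame,
    classifier_spec: ClassifierSpec | None = None,
    rho: float = selection.DEFAULT_RHO,
    epsilon: float = selection.DEFAULT_EPSILON,
    k_step: int = selection.MIN_SWEEP_DIM,
    n_folds: int = 5,
    seed: int = 0,
) -> SelectEvalResult:
    """Fuzzy-entropy ranking, the k sweep, and final CV evaluation."""
    X, y, names = feat.split_table(table)
    spec = classifier_spec or ClassifierSpec()
    ranking = selection.fuzzy_mi(X, y, rho, epsilon)
    sweep = selection.sweep_dimensions(X, y, ranking, spec, k_step, n_folds, seed)
    report_full = cross_validate(X, y, spec, n_folds, seed)
    report_selected = cross_validate(
        X[:, sweep.selected_indices], y, spec, n_folds, seed
    )
    return SelectEvalResult(
        ranking=ranking,
        sweep=sweep,
        report_full=report_full,
        report_selected=report_selected,
        feature_names=names,
    )
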