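"""Sub-band distribution fitting and feature-vector assembly.

Texture and color are summarized by fitting a distribution to the NSCT
coefficients of each sub-band of each YCbCr plane:

* F1 — zero-mean generalized Gaussian density
  ``f(x) = beta / (2 alpha Gamma(1/beta)) exp(-(|x|/alpha)**beta)``
  fitted by maximum likelihood; the (alpha, beta) pair per sub-band.
* F2 — first-order statistics; the (mu, sigma) pair per sub-band.

With the default level vector [1, 2, 2] each plane yields 11 sub-bands, so
three planes give 33 coefficient sets and a 66-entry feature vector.  The
combined vector concatenates the 36-entry shape descriptor with the F1
vector of the (pyrexc, pkva) filter pair: 102 entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, psi

from . import nsct
from .errors import DegenerateDistributionError, InvalidInputError
from .gfd import gfd_descriptor, gfd_feature_names
from .imaging import BinaryMask, rgb_to_ycbcr

DEFAULT_LEVEL_VECTOR = (1, 2, 2)
DEFAULT_FILTER_PAIR = ("pyrexc", "pkva")
CHANNELS = ("Y", "Cb", "Cr")

BETA_MIN, BETA_MAX = 0.1, 10.0


@dataclass(frozen=True)
class GGDParams:
    """Generalized Gaussian scale alpha, shape beta and fit log-likelihood."""

    alpha: float
    beta: float
    loglik: float
    converged: bool = True


@dataclass(frozen=True)
class NormalParams:
    mu: float
    sigma: float


def _ggd_loglik(x_abs: np.ndarray, alpha: float, beta: float) -> float:
    n = x_abs.size
    return float(
        n * (np.log(beta) - np.log(2 * alpha) - gammaln(1.0 / beta))
        - np.sum((x_abs / alpha) ** beta)
    )


def _ggd_alpha_hat(x_abs: np.ndarray, beta: float) -> float:
    return float((beta * np.mean(x_abs ** beta)) ** (1.0 / beta))


def _ggd_score(x_abs: np.ndarray, log_abs: np.ndarray, beta: float) -> float:
    """Profile-likelihood estimating equation for the shape parameter.

    Root of ``1 + psi(1/b)/b - sum(|x|^b log|x|)/sum(|x|^b)
    + log((b/n) sum(|x|^b)) / b = 0`` (the scale profiled out).
    """
    xb = x_abs ** beta
    sb = xb.sum()
    return (
        1.0
        + psi(1.0 / beta) / beta
        - float(np.dot(xb, log_abs)) / sb
        + np.log(beta * sb / x_abs.size) / beta
    )


def fit_ggd(samples: np.ndarray, center: bool = True) -> GGDParams:
    """Maximum-likelihood fit of the zero-mean generalized Gaussian.

    Samples are mean-centered first (``center=True``).  The shape parameter
    is found by bracketed root finding of the profile estimating equation on
    [0.1, 10]; if no sign change exists, a profile-likelihood grid search is
    used and the result flagged ``converged=False``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 30:
        raise InvalidInputError("need at least 30 samples to fit a GGD")
    if center:
        x = x - x.mean()
    if np.all(x == 0) or x.std() == 0:
        raise DegenerateDistributionError("constant sample has no GGD fit")
    x_abs = np.abs(x)
    # exact zeros contribute nothing to sum(|x|^b log|x|); mask them out
    nz = x_abs > 0
    x_nz = x_abs[nz]
    log_nz = np.log(x_nz)

    def score(beta: float) -> float:
        return _ggd_score(x_nz, log_nz, beta)

    converged = True
    lo, hi = BETA_MIN, BETA_MAX
    try:
        f_lo, f_hi = score(lo), score(hi)
        if np.sign(f_lo) != np.sign(f_hi):
            beta = brentq(score, lo, hi, xtol=1e-10)
        else:
            raise ValueError
    except ValueError:
        converged = False
        grid = np.linspace(lo, hi, 200)
        lls = [
            _ggd_loglik(x_nz, _ggd_alpha_hat(x_nz, b), b) for b in grid
        ]
        beta = float(grid[int(np.argmax(lls))])
    alpha = _ggd_alpha_hat(x_nz, beta)
    return GGDParams(
        alpha=alpha,
        beta=float(beta),
        loglik=_ggd_loglik(x_nz, alpha, beta),
        converged=converged,
    )


def fit_normal(samples: np.ndarray) -> NormalParams:
    """Sample mean and (ddof=1) standard deviation."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise InvalidInputError("need at least 2 samples to fit a normal")
    return NormalParams(mu=float(x.mean()), sigma=float(x.std(ddof=1)))


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature values plus the scheme and provenance that produced them."""

    values: np.ndarray
    scheme: str  # GFD | F1 | F2 | combined
    names: tuple[str, ...]
    provenance: dict | None = None

    def __len__(self) -> int:
        return self.values.size


def _decompose_channels(img, filters, level_vector):
    ycc = rgb_to_ycbcr(img)
    return [
        nsct.nsct_decompose(plane, filters, level_vector) for plane in ycc.planes()
    ]


def _subband_feature_vector(img, filters, level_vector, fit, param_names, scheme):
    values, names = [], []
    for channel, subbands in zip(
        CHANNELS, _decompose_channels(img, filters, level_vector)
    ):
        for idx, plane in enumerate(subbands.planes()):
            pars = fit(plane.ravel())
            for pname, val in zip(param_names, pars):
                values.append(val)
                names.append(f"{scheme.lower()}_{channel}_s{idx:02d}_{pname}")
    return FeatureVector(
        values=np.array(values),
        scheme=scheme,
        names=tuple(names),
        provenance={
            "filter_pair": (filters.pyramid_name, filters.directional_name),
            "level_vector": list(level_vector),
        },
    )


def f1_features(
    img: np.ndarray,
    filters: nsct.FilterPair | None = None,
    level_vector=DEFAULT_LEVEL_VECTOR,
) -> FeatureVector:
    """GGD (alpha, beta) per sub-band per YCbCr plane; 66 entries by default.

    Channel-major, sub-bands ordered lowpass -> finest, (alpha, beta)
    adjacent.
    """
    filters = filters or nsct.build_filters(*DEFAULT_FILTER_PAIR)

    def fit(coeffs):
        p = fit_ggd(coeffs)
        return p.alpha, p.beta

    return _subband_feature_vector(
        img, filters, level_vector, fit, ("alpha", "beta"), "F1"
    )


def f2_features(
    img: np.ndarray,
    filters: nsct.FilterPair | None = None,
    level_vector=DEFAULT_LEVEL_VECTOR,
) -> FeatureVector:
    """Normal (mu, sigma) per sub-band per YCbCr plane; 66 entries by default."""
    filters = filters or nsct.build_filters(*DEFAULT_FILTER_PAIR)

    def fit(coeffs):
        p = fit_normal(coeffs)
        return p.mu, p.sigma

    return _subband_feature_vector(
        img, filters, level_vector, fit, ("mu", "sigma"), "F2"
    )


def combined_features(
    img: np.ndarray,
    mask: BinaryMask,
    filters: nsct.FilterPair | None = None,
    level_vector=DEFAULT_LEVEL_VECTOR,
) -> FeatureVector:
    """Shape + texture + color: GFD(36) followed by F1(66); 102 entries."""
    shape = gfd_descriptor(mask)
    texture = f1_features(img, filters, level_vector)
    return FeatureVector(
        values=np.concatenate([shape.values, texture.values]),
        scheme="combined",
        names=tuple(gfd_feature_names()) + texture.names,
        provenance=texture.provenance,
    )


# ---------------------------------------------------------------------------
# Feature tables

LABEL_COLUMN = "label"
SCHEMA_VERSION = 1


def assemble_table(vectors: list[FeatureVector], labels: list[int]) -> pd.DataFrame:
    """Stack feature vectors into a table with a trailing ``label`` column.

    Labels are class codes: 0 = non-neoplastic (C1), 1 = neoplastic (C2).
    """
    if len(vectors) != len(labels):
        raise InvalidInputError("one label per feature vector required")
    if not vectors:
        raise InvalidInputError("empty feature table")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise InvalidInputError("feature vectors have inconsistent columns")
    df = pd.DataFrame([v.values for v in vectors], columns=list(names))
    df[LABEL_COLUMN] = np.asarray(labels, dtype=int)
    if df.isna().any().any():
        raise InvalidInputError("feature table contains missing entries")
    return df


def split_table(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (X, y, feature_names) from a feature table."""
    if LABEL_COLUMN not in df.columns:
        raise InvalidInputError(f"table lacks a {LABEL_COLUMN!r} column")
    cols = [c for c in df.columns if c != LABEL_COLUMN]
    return df[cols].to_numpy(float), df[LABEL_COLUMN].to_numpy(int), cols


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None):
    """Write a feature table as CSV plus a JSON sidecar with the schema."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "columns": list(df.columns),
        "n_rows": int(len(df)),
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
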