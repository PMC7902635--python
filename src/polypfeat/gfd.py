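"""Generic Fourier Descriptor (GFD).

A region-based shape descriptor: the binary polyp mask is resampled on a
centroid-anchored polar raster, a 2-D Fourier transform is taken on that
raster (the modified polar Fourier transform, MPFT), and the retained
low-frequency coefficient magnitudes are normalized so the descriptor is
invariant to translation (centroid anchoring), rotation (magnitudes of the
angular transform) and scale (DC normalized by the bounding-circle area in
sample measure, all other entries by the DC magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateShapeError, InvalidInputError
from .imaging import BinaryMask, PolarSample, polar_resample

DEFAULT_RADIAL_FREQ = 4
DEFAULT_ANGULAR_FREQ = 9


@dataclass(frozen=True)
class MPFTGrid:
    """Complex MPFT coefficients indexed by (radial, angular) frequency."""

    coeffs: np.ndarray  # R_f x A_f complex
    R_f: int
    A_f: int


def mpft(sample: PolarSample, R_f: int, A_f: int) -> MPFTGrid:
    """Modified polar Fourier transform of a polar raster.

    ``coeffs[p, s] = sum_j sum_i f(j, i) exp(-2 pi i (j p / R + i s / T))``
    with ``j`` the ring index and ``i`` the angular index — a plain 2-D DFT
    on the polar grid, so the (0, 0) coefficient is the sum of the samples.
    """
    if R_f < 1 or A_f < 1:
        raise InvalidInputError("frequency counts must be >= 1")
    if R_f > sample.R or A_f > sample.T:
        raise InvalidInputError(
            f"retained frequencies ({R_f}, {A_f}) exceed sampling resolution "
            f"({sample.R}, {sample.T})"
        )
    j = np.arange(sample.R)[:, None]
    p = np.arange(R_f)[None, :]
    e_r = np.exp(-2j * np.pi * j * p / sample.R)
    i = np.arange(sample.T)[:, None]
    s = np.arange(A_f)[None, :]
    e_a = np.exp(-2j * np.pi * i * s / sample.T)
    coeffs = e_r.T @ sample.values.astype(complex) @ e_a
    return MPFTGrid(coeffs=coeffs, R_f=R_f, A_f=A_f)


@dataclass(frozen=True)
class ShapeDescriptor:
    """Normalized MPFT magnitudes, radial-major, length ``R_f * A_f``."""

    values: np.ndarray
    R_f: int
    A_f: int

    def __len__(self) -> int:
        return self.values.size


def gfd_descriptor(
    mask: BinaryMask,
    R_f: int = DEFAULT_RADIAL_FREQ,
    A_f: int = DEFAULT_ANGULAR_FREQ,
    R: int = 64,
    T: int = 64,
    area: str = "samples",
) -> ShapeDescriptor:
    """Shape descriptor of a binary mask (default 4 x 9 = 36 entries).

    Entry 0 is ``|MPFT(0,0)|`` divided by the area of the mask's bounding
    circle; the remaining entries are ``|MPFT(p,s)| / |MPFT(0,0)|`` in
    radial-major order.  With ``area="samples"`` (default) the bounding
    circle is measured in polar-raster samples (``R * T``, the number of
    samples it contains), which keeps entry 0 independent of image scale;
    ``area="pixels"`` uses the pixel-domain circle area ``pi * r_max**2``.
    """
    if area not in {"samples", "pixels"}:
        raise InvalidInputError("area must be 'samples' or 'pixels'")
    sample = polar_resample(mask, R=R, T=T)
    grid = mpft(sample, R_f, A_f)
    mags = np.abs(grid.coeffs)
    dc = mags[0, 0]
    if dc == 0:
        raise DegenerateShapeError("MPFT DC term vanishes; shape has no support")
    denom = float(R * T) if area == "samples" else np.pi * sample.ring_radius ** 2
    values = mags.ravel() / dc
    values[0] = dc / denom
    return ShapeDescriptor(values=values, R_f=R_f, A_f=A_f)


def gfd_feature_names(R_f: int = DEFAULT_RADIAL_FREQ, A_f: int = DEFAULT_ANGULAR_FREQ):
    """Column names tracing each entry to its (radial, angular) frequency."""
    return [f"gfd_r{p}_a{s}" for p in range(R_f) for s in range(A_f)]
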