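"""Nonsubsampled contourlet transform (NSCT).

The transform combines a nonsubsampled pyramid (NSP) — an a-trous two-channel
lowpass/bandpass split iterated on the lowpass branch — with a nonsubsampled
directional filter bank (NSDFB) that splits each bandpass plane into
``2**depth`` wedge-shaped directional sub-bands.  Because no branch is ever
downsampled, every sub-band has the size of the input and the decomposition
commutes exactly with circular shifts.

All 2-D kernels are zero-phase and are synthesized from 1-D halfband
prototypes expressed as Chebyshev polynomials in ``x = cos(w)``; the McClellan
transform substitutes a 2-D frequency map for ``cos(w)``, which preserves the
1-D Bezout identity ``H0*G0 + H1*G1 = 1`` coefficient-for-coefficient.  With
periodic boundary handling this makes decompose -> reconstruct an identity up
to floating-point round-off, for every filter pair and pyramid depth.

Supported filter names follow the common naming of the contourlet literature:
pyramids ``"9-7"`` (Cohen-Daubechies-Feauveau 9/7 pair) and ``"pyrexc"``
(maximally-flat pair with two vanishing moments and exchanged highpass
filters); fan filters ``"pkva"`` (Lagrange/ladder halfband) and ``"sinc"``
(windowed ideal halfband).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from scipy.signal import convolve2d

from .errors import InvalidInputError

PYRAMID_NAMES = ("9-7", "pyrexc")
DIRECTIONAL_NAMES = ("sinc", "pkva")

# Centered CDF 9/7 analysis (9-tap) and synthesis (7-tap) lowpass filters,
# normalized to unit DC gain.  Their zero-phase product is a halfband filter,
# which is the property the pyramid construction relies on.
_CDF97_H0 = np.array(
    [
        0.03782845550726404, -0.02384946501955684, -0.11062440441843718,
        0.37740285561283066, 0.8526986790088938, 0.37740285561283066,
        -0.11062440441843718, -0.02384946501955684, 0.03782845550726404,
    ]
) / np.sqrt(2.0)
_CDF97_G0 = np.array(
    [
        -0.06453888262869706, -0.04068941760916406, 0.41809227322161724,
        0.7884856164055829, 0.41809227322161724, -0.04068941760916406,
        -0.06453888262869706,
    ]
) / np.sqrt(2.0)

# McClellan frequency maps (zero-phase 3x3 kernels).  _MAP_PYR sends
# cos(w) -> -1 + (1+cos w1)(1+cos w2)/2 (near-circular lowpass contours);
# _MAP_DIA sends cos(w) -> (cos w1 + cos w2)/2 (diamond contours).
_MAP_PYR = np.array([[1.0, 2.0, 1.0], [2.0, -4.0, 2.0], [1.0, 2.0, 1.0]]) / 8.0
_MAP_DIA = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]) / 4.0


def _embed(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center a zero-phase kernel inside a larger odd-sized array."""
    out = np.zeros(shape)
    r0 = (shape[0] - kernel.shape[0]) // 2
    c0 = (shape[1] - kernel.shape[1]) // 2
    out[r0 : r0 + kernel.shape[0], c0 : c0 + kernel.shape[1]] = kernel
    return out


def _taps_to_cosine_series(taps: np.ndarray) -> np.ndarray:
    """Cosine-series coefficients c_k with H(w) = sum c_k cos(kw)."""
    taps = np.asarray(taps, dtype=float)
    if taps.size % 2 != 1 or not np.allclose(taps, taps[::-1], atol=1e-12):
        raise InvalidInputError("zero-phase prototype must be odd-length symmetric")
    mid = taps.size // 2
    c = taps[mid:].copy()
    c[1:] *= 2.0
    return c


def _cosine_series_to_2d(series: np.ndarray, freq_map: np.ndarray) -> np.ndarray:
    """McClellan transform: substitute a 2-D map for cos(w) in a cosine series.

    Uses the Chebyshev recurrence T_k(M) = 2 M * T_{k-1}(M) - T_{k-2}(M)
    evaluated with 2-D convolutions on zero-phase kernels.
    """
    deg = len(series) - 1
    mr = freq_map.shape[0] // 2
    mc = freq_map.shape[1] // 2
    shape = (2 * deg * mr + 1, 2 * deg * mc + 1) if deg > 0 else (1, 1)
    out = np.zeros(shape)
    t_prev = np.ones((1, 1))  # T_0
    out += series[0] * _embed(t_prev, shape)
    if deg == 0:
        return out
    t_cur = freq_map.copy()  # T_1
    out += series[1] * _embed(t_cur, shape)
    for k in range(2, deg + 1):
        t_next = 2.0 * convolve2d(t_cur, freq_map, mode="full")
        t_next -= _embed(t_prev, t_next.shape)
        out += series[k] * _embed(t_next, shape)
        t_prev, t_cur = t_cur, t_next
    return out


def _modulate_series(series: np.ndarray) -> np.ndarray:
    """Frequency shift by pi: cos(kw) -> cos(k(w+pi)) = (-1)^k cos(kw)."""
    out = series.copy()
    out[1::2] *= -1.0
    return out


def _poly_to_series(power_coeffs: list[float]) -> np.ndarray:
    """Ascending power-basis polynomial in x = cos(w) -> cosine series."""
    return _cheb.poly2cheb(np.asarray(power_coeffs, dtype=float))


def _pyramid_prototypes(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """1-D (h0, h1, g0, g1) cosine series satisfying h0*g0 + h1*g1 = 1."""
    if name == "9-7":
        h0 = _taps_to_cosine_series(_CDF97_H0)
        g0 = _taps_to_cosine_series(_CDF97_G0)
        # Complementary channel by modulation; both highpass filters vanish
        # at DC because the lowpass pair vanishes at the Nyquist frequency.
        h1 = _modulate_series(g0)
        g1 = _modulate_series(h0)
    elif name == "pyrexc":
        # Maximally-flat halfband p^2 (1 + 2q) with p = (1+x)/2, q = (1-x)/2,
        # factored as h0 = p^2, g0 = 2 - x and q^2 (1 + 2p) split between the
        # two highpass filters; "exc" exchanges the highpass pair so that the
        # longer factor sits on the analysis side.
        h0 = _poly_to_series([0.25, 0.5, 0.25])       # ((1+x)/2)^2
        g0 = _poly_to_series([2.0, -1.0])             # 1 + 2q
        h1 = _poly_to_series([1.0, -0.5, -0.5])       # q (2 + x)
        g1 = _poly_to_series([0.5, -0.5])             # q
    else:
        raise InvalidInputError(
            f"unknown pyramid filter {name!r}; expected one of {PYRAMID_NAMES}"
        )
    _check_bezout(h0, h1, g0, g1)
    return h0, h1, g0, g1


def _fan_prototype(name: str) -> np.ndarray:
    """1-D halfband lowpass prototype (transition at w = pi/2)."""
    if name == "pkva":
        # Lagrange (Deslauriers-Dubuc) maximally-flat halfband of order 3,
        # the interpolating prototype underlying the ladder fan filters.
        return _poly_to_series([0.5, 15 / 16, 0.0, -10 / 16, 0.0, 3 / 16])
    if name == "sinc":
        # Hamming-windowed ideal halfband; only odd taps are nonzero, so the
        # complementary-channel identity holds exactly.
        n = np.arange(-9, 10)
        taps = np.where(n == 0, 0.5, np.sin(np.pi * n / 2) / (np.pi * np.where(n == 0, 1, n)))
        taps = taps * np.hamming(taps.size)
        taps[1::2] = 0.0  # enforce exact halfband structure
        taps[taps.size // 2] = 0.5
        return _taps_to_cosine_series(taps)
    raise InvalidInputError(
        f"unknown directional filter {name!r}; expected one of {DIRECTIONAL_NAMES}"
    )


def _check_bezout(h0, h1, g0, g1, tol: float = 1e-10) -> None:
    ident = _cheb.chebadd(_cheb.chebmul(h0, g0), _cheb.chebmul(h1, g1))
    target = np.zeros_like(ident)
    target[0] = 1.0
    if not np.allclose(ident, target, atol=tol):
        raise AssertionError("pyramid prototypes violate the Bezout identity")


@dataclass(frozen=True)
class FilterPair:
    """Analysis/synthesis kernels for one (pyramid, directional) combination.

    ``h0/h1`` and ``g0/g1`` are the pyramid analysis and synthesis kernels;
    ``u0/u1`` are the fan analysis kernels and ``v0/v1`` the fan synthesis
    kernels (the fan pair is complementary, ``u0 + u1 = delta``, so synthesis
    reduces to deltas).
    """

    pyramid_name: str
    directional_name: str
    h0: np.ndarray = field(repr=False)
    h1: np.ndarray = field(repr=False)
    g0: np.ndarray = field(repr=False)
    g1: np.ndarray = field(repr=False)
    u0: np.ndarray = field(repr=False)
    u1: np.ndarray = field(repr=False)
    v0: np.ndarray = field(repr=False)
    v1: np.ndarray = field(repr=False)


def build_filters(pyramid_name: str, directional_name: str) -> FilterPair:
    """Construct the 2-D kernel set for one (pyr, dir) filter combination."""
    h0s, h1s, g0s, g1s = _pyramid_prototypes(pyramid_name)
    h0 = _cosine_series_to_2d(h0s, _MAP_PYR)
    h1 = _cosine_series_to_2d(h1s, _MAP_PYR)
    g0 = _cosine_series_to_2d(g0s, _MAP_PYR)
    g1 = _cosine_series_to_2d(g1s, _MAP_PYR)

    fan = _fan_prototype(directional_name)
    diamond = _cosine_series_to_2d(fan, _MAP_DIA)
    u0 = _modulate_rows(diamond)
    u1 = -u0.copy()
    u1[u0.shape[0] // 2, u0.shape[1] // 2] += 1.0  # complementary: delta - u0
    delta = np.ones((1, 1))
    return FilterPair(
        pyramid_name=pyramid_name,
        directional_name=directional_name,
        h0=h0, h1=h1, g0=g0, g1=g1,
        u0=u0, u1=u1, v0=delta, v1=delta.copy(),
    )


def _modulate_rows(kernel: np.ndarray) -> np.ndarray:
    """Shift the 2-D frequency response by pi along the row axis."""
    rows = np.arange(kernel.shape[0]) - kernel.shape[0] // 2
    return kernel * ((-1.0) ** rows)[:, None]


def _upsample(kernel: np.ndarray, step: int) -> np.ndarray:
    """A-trous (zero-insertion) upsampling by an integer factor."""
    if step == 1:
        return kernel
    kh, kw = kernel.shape
    out = np.zeros(((kh - 1) * step + 1, (kw - 1) * step + 1))
    out[::step, ::step] = kernel
    return out


def _quincunx_upsample(kernel: np.ndarray) -> np.ndarray:
    """Upsample kernel taps on the quincunx lattice n -> Q n, Q = [[1,1],[-1,1]]."""
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    r = rh + rw
    out = np.zeros((2 * r + 1, 2 * r + 1))
    ii, jj = np.nonzero(np.ones_like(kernel))
    out[r + (ii - rh) + (jj - rw), r + (jj - rw) - (ii - rh)] = kernel[ii, jj]
    return out


def _kernel_fft(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    kh, kw = kernel.shape
    if kh > h or kw > w:
        raise InvalidInputError(
            f"plane of shape {shape} is smaller than the {kernel.shape} kernel"
        )
    pad = np.zeros(shape)
    pad[:kh, :kw] = kernel
    pad = np.roll(pad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.rfft2(pad)


def _circ_conv_fft(plane_fft: np.ndarray, kernel: np.ndarray, shape) -> np.ndarray:
    return np.fft.irfft2(plane_fft * _kernel_fft(kernel, shape), s=shape)


def circular_convolve(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase circular 2-D convolution (periodic boundary)."""
    plane = np.asarray(plane, dtype=float)
    return _circ_conv_fft(np.fft.rfft2(plane), kernel, plane.shape)


@dataclass
class SubbandSet:
    """All NSCT sub-bands of one plane.

    ``lowpass`` is the coarsest approximation; ``bandpass[i]`` lists the
    directional sub-bands of pyramid stage ``i`` ordered coarse -> fine, each
    with ``2**level_vector[i]`` planes of the input size.
    """

    lowpass: np.ndarray
    bandpass: list[list[np.ndarray]]
    level_vector: list[int]
    pyramid_name: str
    directional_name: str

    def planes(self) -> list[np.ndarray]:
        """All sub-band planes, lowpass first, then coarse -> fine."""
        out = [self.lowpass]
        for group in self.bandpass:
            out.extend(group)
        return out

    @property
    def n_subbands(self) -> int:
        return 1 + sum(len(g) for g in self.bandpass)


def subband_count(level_vector: list[int]) -> int:
    """Sub-band count 1 + sum(2**L_i) for a directional level vector."""
    return 1 + int(sum(2 ** int(l) for l in level_vector))


def _dfb_analysis_kernels(filters: FilterPair, depth: int) -> list[np.ndarray]:
    """Equivalent analysis kernels of the NSDFB tree at the given depth."""
    if depth == 0:
        return [np.ones((1, 1))]
    if depth == 1:
        return [filters.u0, filters.u1]
    if depth == 2:
        u0q = _quincunx_upsample(filters.u0)
        u1q = _quincunx_upsample(filters.u1)
        kernels = []
        for first in (filters.u0, filters.u1):
            for second in (u0q, u1q):
                kernels.append(convolve2d(first, second, mode="full"))
        return kernels
    raise InvalidInputError("directional depth > 2 is not supported")


def nsct_decompose(
    plane: np.ndarray,
    filters: FilterPair,
    level_vector: list[int] | tuple[int, ...] = (1, 2, 2),
) -> SubbandSet:
    """Decompose a real plane into 1 lowpass + directional bandpass sub-bands.

    ``level_vector[i]`` is the NSDFB depth applied to the bandpass plane of
    pyramid stage ``i``, ordered coarse -> fine; the default ``[1, 2, 2]``
    yields 11 sub-bands grouped 1 + 2 + 4 + 4.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise InvalidInputError("expected a 2-D real plane")
    levels = [int(l) for l in level_vector]
    if len(levels) < 1 or any(l < 0 for l in levels):
        raise InvalidInputError("level vector must contain non-negative depths")
    shape = plane.shape
    n_stages = len(levels)

    # Iterate the a-trous split fine -> coarse; stage s uses kernels
    # upsampled by 2**s.  Bandpass of the first split holds the finest scale.
    groups_fine_to_coarse: list[list[np.ndarray]] = []
    low = plane
    for s in range(n_stages):
        step = 2 ** s
        low_fft = np.fft.rfft2(low)
        band = _circ_conv_fft(low_fft, _upsample(filters.h1, step), shape)
        low = _circ_conv_fft(low_fft, _upsample(filters.h0, step), shape)
        depth = levels[n_stages - 1 - s]  # level vector is coarse -> fine
        band_fft = np.fft.rfft2(band)
        group = [
            _circ_conv_fft(band_fft, k, shape)
            for k in _dfb_analysis_kernels(filters, depth)
        ]
        groups_fine_to_coarse.append(group)

    return SubbandSet(
        lowpass=low,
        bandpass=groups_fine_to_coarse[::-1],
        level_vector=levels,
        pyramid_name=filters.pyramid_name,
        directional_name=filters.directional_name,
    )


def nsct_reconstruct(subbands: SubbandSet, filters: FilterPair) -> np.ndarray:
    """Invert :func:`nsct_decompose`; exact up to floating-point round-off."""
    if (
        subbands.pyramid_name != filters.pyramid_name
        or subbands.directional_name != filters.directional_name
    ):
        raise InvalidInputError(
            "sub-band set was produced with a different filter pair"
        )
    levels = subbands.level_vector
    n_stages = len(levels)
    for i, group in enumerate(subbands.bandpass):
        if len(group) != 2 ** levels[i]:
            raise InvalidInputError("sub-band group sizes do not match level vector")
    shape = subbands.lowpass.shape

    low = subbands.lowpass
    for s in range(n_stages - 1, -1, -1):
        step = 2 ** s
        depth = levels[n_stages - 1 - s]
        group = subbands.bandpass[n_stages - 1 - s]
        # The fan synthesis filters are deltas (complementary analysis pair),
        # so NSDFB synthesis is the plain sum of the directional planes.
        band = np.sum(group, axis=0) if depth > 0 else group[0]
        low = circular_convolve(low, _upsample(filters.g0, step)) + circular_convolve(
            band, _upsample(filters.g1, step)
        )
    return low
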