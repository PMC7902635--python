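"""Image I/O, color conversion, mask segmentation and polar raster sampling.

These are the primitives feeding the two descriptor stages: YCbCr planes for
the contourlet texture/color features and centroid-anchored polar samples of
the binary polyp mask for the Fourier shape descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import InvalidInputError, SegmentationError

MIN_SIDE = 32

# ITU-R BT.601 full-range RGB <-> YCbCr conversion.
_RGB2YCBCR = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168735892, -0.331264108, 0.5],
        [0.5, -0.418687589, -0.081312411],
    ]
)
_CHROMA_OFFSET = np.array([0.0, 128.0, 128.0])


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Validate an H x W x 3 8-bit RGB image and return it as uint8."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidInputError(
            f"expected an H x W x 3 RGB image, got shape {pixels.shape}"
        )
    if pixels.shape[0] < MIN_SIDE or pixels.shape[1] < MIN_SIDE:
        raise InvalidInputError(
            f"image sides must be >= {MIN_SIDE}, got {pixels.shape[:2]}"
        )
    return pixels.astype(np.uint8, copy=False)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an H x W x 3 uint8 array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return as_rgb_image(arr)


@dataclass(frozen=True)
class YCbCrImage:
    """Luma (texture) plane Y and chroma (color) planes Cb, Cr."""

    y: np.ndarray
    cb: np.ndarray
    cr: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    def planes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.y, self.cb, self.cr


def rgb_to_ycbcr(img: np.ndarray) -> YCbCrImage:
    """Convert 8-bit RGB to full-range BT.601 YCbCr planes (float)."""
    img = as_rgb_image(img)
    ycc = img.astype(float) @ _RGB2YCBCR.T + _CHROMA_OFFSET
    return YCbCrImage(y=ycc[:, :, 0], cb=ycc[:, :, 1], cr=ycc[:, :, 2])


def ycbcr_to_rgb(img: YCbCrImage) -> np.ndarray:
    """Inverse BT.601 conversion, clipped back to uint8."""
    ycc = np.stack(img.planes(), axis=-1) - _CHROMA_OFFSET
    rgb = ycc @ np.linalg.inv(_RGB2YCBCR).T
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class BinaryMask:
    """Segmented polyp region with centroid (row, col) and pixel area."""

    mask: np.ndarray
    centroid: tuple[float, float]
    area: int

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "BinaryMask":
        mask = np.asarray(mask).astype(bool)
        if mask.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise InvalidInputError("mask has no foreground pixels")
        return cls(
            mask=mask,
            centroid=(float(rows.mean()), float(cols.mean())),
            area=int(rows.size),
        )

    @property
    def bounding_radius(self) -> float:
        """Radius of the enclosing circle centered at the centroid."""
        rows, cols = np.nonzero(self.mask)
        m, n = self.centroid
        return float(np.sqrt((rows - m) ** 2 + (cols - n) ** 2).max())


def load_mask(path: str | Path) -> BinaryMask:
    """Read a mask from a single-channel image (nonzero = foreground) or
    from run-length text (first line ``H W``, then ``start length`` pairs in
    row-major order, 0-based)."""
    path = Path(path)
    if path.suffix.lower() in {".txt", ".rle"}:
        lines = path.read_text().split()
        h, w = int(lines[0]), int(lines[1])
        flat = np.zeros(h * w, dtype=bool)
        vals = [int(v) for v in lines[2:]]
        for start, length in zip(vals[::2], vals[1::2]):
            flat[start : start + length] = True
        return BinaryMask.from_array(flat.reshape(h, w))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask.from_array(arr > 0)


def segment_polyp(img: np.ndarray, n_clusters: int = 2, seed: int = 0) -> BinaryMask:
    """Segment the bright polyp region of a ground-truth-marked image.

    K-means (``n_clusters`` intensity clusters, 10 restarts, fixed seed) on
    the gray intensity, keeping the cluster of highest mean intensity, then
    the largest connected component with holes filled.
    """
    img = as_rgb_image(img)
    gray = img.astype(float).mean(axis=2)
    if np.ptp(gray) == 0:
        raise SegmentationError("constant image: intensity clusters are degenerate")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(gray.reshape(-1, 1)).reshape(gray.shape)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    fg = labels == bright
    comps, n_comp = ndimage.label(fg)
    if n_comp == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n_comp + 1))
    largest = comps == (1 + int(np.argmax(sizes)))
    return BinaryMask.from_array(ndimage.binary_fill_holes(largest))


@dataclass(frozen=True)
class PolarSample:
    """Mask values sampled on R concentric rings x T angles around the centroid."""

    values: np.ndarray  # R x T
    R: int
    T: int
    ring_radius: float


def polar_resample(mask: BinaryMask, R: int = 64, T: int = 64) -> PolarSample:
    """Sample the mask on a centroid-anchored polar raster.

    Ring ``j`` has radius ``j / (R - 1) * ring_radius`` (ring 0 is the
    centroid, ring R-1 lies on the mask's enclosing circle); angle ``i`` is
    ``2 pi i / T`` measured counter-clockwise from the +column axis.  Values
    are bilinearly interpolated; points outside the image read as 0.
    """
    if R < 1 or T < 1:
        raise InvalidInputError("R and T must be >= 1")
    m, n = mask.centroid
    r_max = mask.bounding_radius
    radii = np.linspace(0.0, r_max, R) if R > 1 else np.array([0.0])
    theta = 2.0 * np.pi * np.arange(T) / T
    rows = m + radii[:, None] * np.sin(theta)[None, :]
    cols = n + radii[:, None] * np.cos(theta)[None, :]
    values = ndimage.map_coordinates(
        mask.mask.astype(float), [rows, cols], order=1, mode="constant", cval=0.0
    )
    return PolarSample(values=values, R=R, T=T, ring_radius=float(r_max))
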