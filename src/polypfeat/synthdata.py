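"""Seeded generator of two-class synthetic polyp-like images and masks.

Each image holds one roughly elliptical bright region (the "polyp") on a
darker background.  The two classes differ in the three cues a clinician
uses and the descriptor stages quantify:

* boundary irregularity — class C2 (neoplastic) adds higher radial
  harmonics (h = 2..8) of total amplitude ``boundary_irregularity`` to the
  smooth low-order (h = 2, 3) boundary both classes share;
* surface texture — C2 overlays an oriented cosine grating of contrast
  ``texture_anisotropy`` (8-bit intensity units) with jittered orientation,
  on top of the isotropic smooth texture both classes share;
* color — C2's region is chroma-shifted (red raised, blue lowered) by
  ``chroma_shift`` intensity units.

With all three knobs at zero the classes are distributionally identical.
Every image is fully determined by ``(seed, class_id, index)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .imaging import BinaryMask

LABEL_NAMES = {0: "C1", 1: "C2"}  # non-neoplastic / neoplastic

_BASE_HARMONICS = (2, 3)
_BASE_AMPLITUDE = 0.03
_IRREGULAR_HARMONICS = tuple(range(2, 9))
_REGION_LUMA = 165.0
_BACKGROUND_LUMA = 60.0
# per-channel offsets giving the region a pink and the background a dark red tint
_REGION_TINT = (25.0, -5.0, -20.0)
_BACKGROUND_TINT = (15.0, -5.0, -10.0)
_GRATING_ORIENT_DEG = 30.0
_ORIENT_JITTER_DEG = 15.0


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters; the class-contrast knobs are all >= 0."""

    size: int = 96
    n_per_class: int = 60
    boundary_irregularity: float = 0.12
    texture_anisotropy: float = 6.0
    chroma_shift: float = 5.0
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise InvalidInputError("image size must be >= 32")
        if self.n_per_class < 1:
            raise InvalidInputError("need at least one image per class")
        for knob in ("boundary_irregularity", "texture_anisotropy", "chroma_shift", "noise_sigma"):
            if getattr(self, knob) < 0:
                raise InvalidInputError(f"{knob} must be >= 0")


def null_spec(spec: SynthSpec) -> SynthSpec:
    """The matching null generator: all class-contrast knobs at zero."""
    return replace(spec, boundary_irregularity=0.0, texture_anisotropy=0.0, chroma_shift=0.0)


def _region_radius(rng, spec: SynthSpec, class_id: int):
    """Radial profile r(theta) = r0 (1 + sum_h a_h cos(h theta + phi_h))."""
    r0 = spec.size * rng.uniform(0.20, 0.27)
    harmonics, amps, phases = [], [], []
    share = rng.uniform(0.3, 1.0, size=len(_BASE_HARMONICS))
    share /= share.sum()
    for h, s in zip(_BASE_HARMONICS, share):
        harmonics.append(h)
        amps.append(_BASE_AMPLITUDE * s)
        phases.append(rng.uniform(0, 2 * np.pi))
    extra = rng.uniform(0.3, 1.0, size=len(_IRREGULAR_HARMONICS))
    extra /= extra.sum()
    for h, s in zip(_IRREGULAR_HARMONICS, extra):
        amp = (spec.boundary_irregularity if class_id == 1 else 0.0) * s
        harmonics.append(h)
        amps.append(amp)
        phases.append(rng.uniform(0, 2 * np.pi))
    total_amp = _BASE_AMPLITUDE + (spec.boundary_irregularity if class_id == 1 else 0.0)
    if r0 * (1 + total_amp) > spec.size / 2 - 4:
        raise InvalidInputError("polyp region would exceed the image bounds")
    return r0, np.array(harmonics), np.array(amps), np.array(phases)


def generate_image(spec: SynthSpec, class_id: int, index: int):
    """One (image, mask, label) triple, deterministic in (seed, class, index)."""
    if class_id not in (0, 1):
        raise InvalidInputError("class_id must be 0 (C1) or 1 (C2)")
    if index < 0 or index >= spec.n_per_class:
        raise InvalidInputError("index out of range for the spec")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(class_id), int(index)])
    )
    n = spec.size
    r0, harmonics, amps, phases = _region_radius(rng, spec, class_id)
    jitter = (n / 2 - 4) - r0 * (1 + _BASE_AMPLITUDE + spec.boundary_irregularity)
    jitter = min(max(jitter, 0.0), 0.06 * n)
    cy = n / 2 + rng.uniform(-jitter, jitter)
    cx = n / 2 + rng.uniform(-jitter, jitter)

    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dy = rows - cy
    dx = cols - cx
    theta = np.arctan2(dy, dx)
    radius = np.sqrt(dy * dy + dx * dx)
    r_theta = r0 * (
        1.0
        + np.sum(
            amps[:, None, None]
            * np.cos(harmonics[:, None, None] * theta[None] + phases[:, None, None]),
            axis=0,
        )
    )
    mask = radius <= r_theta

    # shared isotropic smooth texture (lowpass-filtered noise)
    region_tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), 3.5)
    region_tex *= 10.0 / max(region_tex.std(), 1e-12)
    bg_tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), 5.0)
    bg_tex *= 6.0 / max(bg_tex.std(), 1e-12)

    luma = np.where(mask, _REGION_LUMA + region_tex, _BACKGROUND_LUMA + bg_tex)

    if class_id == 1 and spec.texture_anisotropy > 0:
        ang = np.deg2rad(
            _GRATING_ORIENT_DEG + rng.uniform(-_ORIENT_JITTER_DEG, _ORIENT_JITTER_DEG)
        )
        wavelength = rng.uniform(6.0, 9.0)
        grating = np.cos(
            2 * np.pi * (rows * np.cos(ang) + cols * np.sin(ang)) / wavelength
        )
        luma = luma + np.where(mask, spec.texture_anisotropy * grating, 0.0)

    img = np.empty((n, n, 3))
    for ch in range(3):
        tint = np.where(mask, _REGION_TINT[ch], _BACKGROUND_TINT[ch])
        img[:, :, ch] = luma + tint
    if class_id == 1 and spec.chroma_shift > 0:
        img[:, :, 0] += np.where(mask, spec.chroma_shift, 0.0)
        img[:, :, 2] -= np.where(mask, spec.chroma_shift, 0.0)

    img += rng.normal(0.0, spec.noise_sigma, (n, n, 3))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, BinaryMask.from_array(mask), class_id


def generate_arrays(spec: SynthSpec):
    """All images of the dataset in memory: lists (images, masks, labels)."""
    images, masks, labels = [], [], []
    for class_id in (0, 1):
        for index in range(spec.n_per_class):
            img, mask, label = generate_image(spec, class_id, index)
            images.append(img)
            masks.append(mask)
            labels.append(label)
    return images, masks, labels


def generate_dataset(spec: SynthSpec, outdir: str | Path) -> Path:
    """Write PNG images, PNG masks and a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InvalidInputError(f"cannot create output directory {outdir}: {exc}")
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "mask", "label"])
        for class_id in (0, 1):
            for index in range(spec.n_per_class):
                img, mask, label = generate_image(spec, class_id, index)
                stem = f"{LABEL_NAMES[class_id].lower()}_{index:03d}"
                img_path = outdir / f"img_{stem}.png"
                mask_path = outdir / f"mask_{stem}.png"
                iio.imwrite(img_path, img)
                iio.imwrite(mask_path, (mask.mask * np.uint8(255)))
                writer.writerow([img_path.name, mask_path.name, label])
    return manifest
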