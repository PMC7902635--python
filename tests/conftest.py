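"""Shared fixtures: synthetic benchmark data and parametric masks.

Everything is generated programmatically and seeded; session scope keeps
the expensive feature-extraction work shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from polypfeat import pipeline, synthdata
from polypfeat.imaging import BinaryMask


@pytest.fixture(scope="session")
def bench_spec():
    return synthdata.SynthSpec(seed=5, n_per_class=15)


@pytest.fixture(scope="session")
def bench_data(bench_spec):
    """30 synthetic images/masks/labels at the default class contrast."""
    return synthdata.generate_arrays(bench_spec)


@pytest.fixture(scope="session")
def bench_combined_table(bench_data):
    imgs, masks, labels = bench_data
    return pipeline.extract_table(imgs, masks, labels, scheme="combined")


@pytest.fixture(scope="session")
def bench_f2_table(bench_data):
    imgs, masks, labels = bench_data
    return pipeline.extract_table(imgs, masks, labels, scheme="F2")


def ellipse_mask(shape, center, radii, angle=0.0):
    """Boolean ellipse mask; angle rotates the axes (radians, CCW)."""
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dy = rows - center[0]
    dx = cols - center[1]
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def star_mask(shape, center, r0, amp, n_points, phase=0.0):
    """Star-shaped mask r(theta) = r0 (1 + amp cos(n theta + phase))."""
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dy = rows - center[0]
    dx = cols - center[1]
    theta = np.arctan2(dy, dx)
    return np.sqrt(dy * dy + dx * dx) <= r0 * (1 + amp * np.cos(n_points * theta + phase))


@pytest.fixture
def disk_mask():
    m = ellipse_mask((96, 96), (48, 48), (20, 20))
    return BinaryMask.from_array(m)
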