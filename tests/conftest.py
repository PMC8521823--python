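"""Shared fixtures: phantoms at the study conditions, disk images, helpers.

Phantom fixtures are session-scoped (generation plus segmentation is the
expensive part of the suite) and must never be mutated by tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from spheroquant import (
    ChannelImage,
    LinearRampByDepth,
    SpheroidPhantomParams,
    StepByDepth,
    generate_phantom,
)


def rasterized_disk(radius_px: int, pad: int = 6, value: float = 100.0):
    """A constant-intensity disk image and its boolean mask.

    The mask holds pixels whose centre lies within ``radius_px`` of the
    geometric centre of an odd-sized canvas.
    """
    size = 2 * (radius_px + pad) + 1
    c = radius_px + pad
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    mask = (rr - c) ** 2 + (cc - c) ** 2 <= radius_px**2
    return value * mask.astype(np.float64), mask, (float(c), float(c))


def brute_force_distance(point, perimeter_coords):
    """Independent oracle: explicit min over perimeter pixel coordinates."""
    d = np.hypot(
        perimeter_coords[:, 0] - point[0], perimeter_coords[:, 1] - point[1]
    )
    return float(d.min())


@pytest.fixture(scope="session")
def default_phantom():
    """The default study conditions: 300 nuclei, necrotic core, seed 1."""
    params = SpheroidPhantomParams(seed=1)
    image, truth = generate_phantom(params)
    return params, image, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Segmentation-recovery conditions: 300 bright nuclei (SNR >= 5),
    centre separation >= 2 nucleus diameters, effectively no necrotic core."""
    params = SpheroidPhantomParams(
        seed=7,
        necrotic_core_radius_um=1.0,
        min_separation_um=20.0,  # 2 x the 10 um nucleus diameter
    )
    image, truth = generate_phantom(params)
    return params, image, truth


@pytest.fixture(scope="session")
def profile_phantom():
    """Profile-recovery conditions: 800 nuclei, a linear surface-to-core
    hypoxia gradient, step dead-cell probability 0.8 (shallower than 50 um)
    / 0.1 (deeper), uniform infiltration density."""
    params = SpheroidPhantomParams(
        seed=3,
        n_nuclei=800,
        min_separation_um=10.0,
        necrotic_core_radius_um=1.0,
        hypoxia_gradient=LinearRampByDepth(
            surface_level=20.0, core_level=160.0,
            onset_depth_um=0.0, ramp_um=300.0,
        ),
        draq7_positive_prob=StepByDepth(50.0, 0.8, 0.1),
        pbmc_count=600,
    )
    image, truth = generate_phantom(params)
    return params, image, truth


@pytest.fixture
def small_phantom():
    """A quick, small phantom for per-test use (function scope, mutable)."""
    params = SpheroidPhantomParams(
        seed=11,
        spheroid_radius_um=150.0,
        n_nuclei=120,
        min_separation_um=14.0,
        necrotic_core_radius_um=40.0,
        pbmc_count=40,
    )
    image, truth = generate_phantom(params)
    return params, image, truth


@pytest.fixture
def two_disk_image():
    """Two fused disks (radius 10 px, centres 15 px apart) for declumping."""
    size = 64
    img = np.zeros((size, size))
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for cr, ccol in ((32.0, 24.0), (32.0, 39.0)):
        img[np.hypot(rr - cr, cc - ccol) <= 10.0] = 100.0
    return ChannelImage("DAPI", img, 1.0), [(32.0, 24.0), (32.0, 39.0)]
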