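"""Shared fixtures: small, fast synthetic scenes with known ground truth."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from ringprofiler import (
    ImageFrame,
    NoiseSpec,
    SyntheticRingSpec,
    generate_ring_image,
)

NO_NOISE = NoiseSpec.NONE


@pytest.fixture(scope="session")
def small_spec() -> SyntheticRingSpec:
    """A compact ring scene (2048 um field at 8 um/px) for fast unit tests."""
    return SyntheticRingSpec(
        image_size_px=(256, 256),
        microns_per_pixel=8.0,
        ring_diameter_um=1200.0,
        ring_thickness_um=260.0,
        n_branches=12,
        seed=0,
    )


@pytest.fixture(scope="session")
def coarse_study_spec() -> SyntheticRingSpec:
    """The study-scale scene sampled coarsely (3584 um field at 8 um/px)."""
    return SyntheticRingSpec(image_size_px=(448, 448), microns_per_pixel=8.0, seed=0)


@pytest.fixture(scope="session")
def clean_ring(small_spec):
    """Noiseless branch-free ring frame plus its ground truth."""
    return generate_ring_image(replace(small_spec, n_branches=0), NO_NOISE)


@pytest.fixture(scope="session")
def noisy_ring(small_spec):
    return generate_ring_image(small_spec, NoiseSpec(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def frame_of(pixels, mpp=1.0) -> ImageFrame:
    return ImageFrame(np.asarray(pixels, dtype=np.float64), microns_per_pixel=mpp)
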