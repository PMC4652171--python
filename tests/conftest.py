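"""Shared fixtures: phantoms at full and reduced grid resolution.

Session scope keeps the expensive full-resolution phantom to a single
generation per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from strokemap.phantoms import PhantomSpec, make_brain_phantom
from strokemap.projection import project_volume
from strokemap.segmentation import brain_mask, segment_volume


#: Reduced-resolution template for tests that need many volumes.
SMALL_KWARGS = dict(
    grid_shape=(48, 48, 48),
    brain_semi_axes=(35.0, 42.0, 32.0),
)


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=42)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return make_brain_phantom(default_spec)


@pytest.fixture(scope="session")
def default_thresholds(default_phantom):
    return segment_volume(default_phantom)


@pytest.fixture(scope="session")
def default_map(default_spec, default_phantom, default_thresholds):
    bmask = brain_mask(default_phantom, default_thresholds)
    return project_volume(default_phantom, bmask, default_spec.projection_geometry())


@pytest.fixture()
def small_spec() -> PhantomSpec:
    return PhantomSpec(seed=7, **SMALL_KWARGS)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
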