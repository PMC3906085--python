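"""Shared fixtures: phantoms and pipeline products reused across test modules.

Everything is generated at test time from the phantom module; heavyweight
products (segmented masks, meshes, profiles) are session-scoped so the suite
pays for each pipeline stage once.
"""

from __future__ import annotations

import numpy as np
import pytest

from vessel_csa.phantom import PhantomSpec, generate_phantom
from vessel_csa.preprocess import PSFModel, wiener_deconvolve
from vessel_csa.segmentation import detect_seeds, largest_component, region_grow

SEED = 0  # suite-wide phantom seed


@pytest.fixture(scope="session")
def tube_spec() -> PhantomSpec:
    """Straight circular tube, r = 2 mm, default blur and noise."""
    return PhantomSpec(profile="circle", profile_params=(2.0,), seed=SEED)


@pytest.fixture(scope="session")
def tube_phantom(tube_spec):
    return generate_phantom(tube_spec)


@pytest.fixture(scope="session")
def clean_tube_phantom():
    """Same tube without blur or noise: sharp analytic edges."""
    spec = PhantomSpec(
        profile="circle", profile_params=(2.0,), psf_sigma=0.0, noise_sigma=0.0, seed=SEED
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def tube_mask(tube_phantom):
    """Segmented lumen of the default noisy tube (deconvolved first, as the
    pipeline does)."""
    vol, _ = tube_phantom
    dec = wiener_deconvolve(vol, PSFModel(0.6), 0.002)
    return largest_component(region_grow(dec, detect_seeds(dec, 350.0)))


@pytest.fixture(scope="session")
def helix_spec() -> PhantomSpec:
    """Half-turn helix tube (radius 6 mm, pitch 24 mm) with default blur/noise."""
    return PhantomSpec(
        centerline="helix",
        centerline_params={"radius": 6.0, "pitch": 24.0, "turns": 0.5, "center": (16.0, 10.0, 3.0)},
        profile="circle",
        profile_params=(2.0,),
        shape=(56, 64, 48),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def helix_phantom(helix_spec):
    return generate_phantom(helix_spec)


@pytest.fixture(scope="session")
def helix_mask(helix_phantom):
    vol, _ = helix_phantom
    dec = wiener_deconvolve(vol, PSFModel(0.6), 0.002)
    return largest_component(region_grow(dec, detect_seeds(dec, 350.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
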