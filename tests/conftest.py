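"""Shared fixtures: small, fast phantoms.

Test phantoms are deliberately smaller than a real mouse (shorter body,
coarser voxels) so the suite runs in seconds; all metrics are computed
from the voxel size, so correctness is independent of resolution.
"""

import dataclasses

import pytest

from myoct.phantom import PhantomSpec, generate_phantom


TINY = PhantomSpec(
    body_length=32.0,
    body_radii=(6.5, 5.5),
    fat_fraction=0.2,
    bone_fraction=0.05,
    voxel_size=0.4,
    noise_sd=0.0,
    seed=0,
)

SMALL = PhantomSpec(
    body_length=45.0,
    body_radii=(7.0, 5.5),
    fat_fraction=0.25,
    bone_fraction=0.05,
    voxel_size=0.3,
    noise_sd=15.0,
    seed=0,
)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Zero-noise, zero-lipid miniature phantom spec."""
    return TINY


def make_phantom(**overrides):
    """A tiny phantom with spec fields overridden."""
    return generate_phantom(dataclasses.replace(TINY, **overrides))


@pytest.fixture(scope="session")
def tiny_phantom():
    """Zero-noise tiny phantom with lipid in muscle and liver."""
    return make_phantom(muscle_lipid_fraction=0.3, liver_lipid_fraction=0.3)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Tiny phantom with 15 HU Gaussian noise."""
    return make_phantom(noise_sd=15.0, muscle_lipid_fraction=0.2, liver_lipid_fraction=0.2, seed=11)
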