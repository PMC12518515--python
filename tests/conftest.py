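"""Shared fixtures: small geometries and pre-settled cables."""

from __future__ import annotations

import numpy as np
import pytest

from eesim.anatomy import SpinalCordSpec, build_populations, build_volume
from eesim.cable import StimulusProtocol, discretize_fiber


@pytest.fixture(scope="session")
def fast_spec() -> SpinalCordSpec:
    """0.2 mm voxel geometry used for desk-scale solves."""
    return SpinalCordSpec(voxel_size=0.2, bath_margin=3.0, z_margin=1.5)


@pytest.fixture(scope="session")
def fast_model(fast_spec):
    return build_volume(fast_spec)


@pytest.fixture(scope="session")
def small_population(fast_spec):
    return build_populations(fast_spec, n_per_pool=8, seed=7)


@pytest.fixture(scope="session")
def straight_xyz() -> np.ndarray:
    z = np.linspace(0.0, 12.0, 241)
    return np.c_[np.zeros_like(z), np.zeros_like(z), z]


@pytest.fixture(scope="session")
def motor_cable(straight_xyz):
    return discretize_fiber(straight_xyz, 9.0, "motor")


@pytest.fixture(scope="session")
def sensory_cable(straight_xyz):
    return discretize_fiber(straight_xyz, 9.0, "sensory")


def point_source_ve(cable, offset_mm=1.0, sigma=0.5):
    """Extracellular mV/uA of a point source ``offset_mm`` above mid-fiber."""
    src = np.array([0.0, offset_mm, cable.xyz[:, 2].mean()])
    r = np.linalg.norm(cable.xyz - src, axis=1)
    return 1e-6 / (4 * np.pi * sigma * r * 1e-3) * 1e3


@pytest.fixture(scope="session")
def default_protocol():
    return StimulusProtocol()
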