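"""Shared fixtures: head models and leadfields built once per session."""

import numpy as np
import pytest

import izbench


@pytest.fixture(scope="session")
def sensors():
    """Default 204-channel planar-gradiometer helmet."""
    return izbench.build_sensor_array()


@pytest.fixture(scope="session")
def grid_head(sensors):
    """Default volume grid (10 mm spacing, brain stops 12 mm under scalp)."""
    space = izbench.build_volume_source_space(90.0, 10.0, 12.0)
    leadfield = izbench.sphere_leadfield(space, sensors)
    labels = izbench.assign_lobes(space)
    return space, leadfield, labels


@pytest.fixture(scope="session")
def shell_head(sensors):
    """100-point cortical-like shell space with its leadfield."""
    space = izbench.build_cortical_like_source_space(100, 90.0, (55.0, 80.0), seed=4)
    leadfield = izbench.sphere_leadfield(space, sensors)
    return space, leadfield


@pytest.fixture(scope="session")
def fixtures():
    return izbench.load_paper_tables()


def tangential_unit(rng: np.random.Generator, location: np.ndarray) -> np.ndarray:
    """Random unit vector orthogonal to the radius at ``location``."""
    radial = location / np.linalg.norm(location)
    v = rng.standard_normal(3)
    v -= (v @ radial) * radial
    while np.linalg.norm(v) < 0.2:
        v = rng.standard_normal(3)
        v -= (v @ radial) * radial
    return v / np.linalg.norm(v)


@pytest.fixture(scope="session")
def cortical_band_indices(grid_head):
    """Grid points at cortically plausible depths (0.45-0.92 head radius)."""
    space, _, _ = grid_head
    radii = np.linalg.norm(space.points, axis=1)
    return np.flatnonzero(
        (radii >= 0.45 * space.head_radius) & (radii <= 0.92 * space.head_radius)
    )
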