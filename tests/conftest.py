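"""Shared fixtures and the independent segmentation oracle.

The oracle deliberately avoids the reaction-diffusion code path: it
thresholds at the water/background midpoint, labels connected components
(6-connectivity) and assigns each component to the nearest nominal sphere
center.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import mrdistort as md


def oracle_segmentation(volume: md.Volume, spec: md.PhantomSpec) -> dict:
    """Midpoint-threshold + connected-components reference segmentation.

    Returns a mapping grid_index -> boolean voxel mask.
    """
    midpoint = (spec.water_gray + spec.background_gray) / 2
    mask = volume.data > midpoint
    lab, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    centers = {gi: c for gi, c in spec.iter_spheres()}
    out = {}
    sp = np.asarray(volume.spacing)
    org = np.asarray(volume.origin)
    for ci in range(1, n + 1):
        comp = lab == ci
        world = org + np.array(ndimage.center_of_mass(comp)) * sp
        gi = min(centers, key=lambda g: np.linalg.norm(centers[g] - world))
        out[gi] = comp
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


def rd_masks(label_map: md.BallLabelMap) -> dict:
    """Grid-index -> boolean mask view of a reaction-diffusion label map."""
    return {
        gi: label_map.labels == lab for lab, gi in label_map.label_to_index.items()
    }


@pytest.fixture(scope="session")
def small_spec() -> md.PhantomSpec:
    """A 2x2x2 corner of the grid: cheap but keeps sphere-sphere contacts."""
    return md.PhantomSpec(grid_shape=(2, 2, 2), omitted_indices=frozenset())


@pytest.fixture(scope="session")
def small_volume(small_spec) -> md.Volume:
    return md.rasterize(small_spec, 2.0, supersampling=4)


@pytest.fixture(scope="session")
def small_label_map(small_spec, small_volume) -> md.BallLabelMap:
    seeds = md.seed_from_grid(small_spec, small_volume)
    return md.evolve(small_volume, seeds)


@pytest.fixture(scope="session")
def small_descriptors(small_volume, small_label_map):
    return md.describe_scan(small_volume, small_label_map)


@pytest.fixture(scope="session")
def default_spec_session() -> md.PhantomSpec:
    return md.default_spec()


@pytest.fixture(scope="session")
def full_volume(default_spec_session) -> md.Volume:
    """The full 338-sphere reference phantom at the 2 mm working resolution."""
    return md.rasterize(default_spec_session, 2.0, supersampling=4)


@pytest.fixture(scope="session")
def full_label_map(default_spec_session, full_volume) -> md.BallLabelMap:
    seeds = md.seed_from_grid(default_spec_session, full_volume)
    return md.evolve(full_volume, seeds)


@pytest.fixture(scope="session")
def full_descriptors(full_volume, full_label_map):
    return md.describe_scan(full_volume, full_label_map)


def segment_scan(volume: md.Volume, spec: md.PhantomSpec):
    """Segment + describe in one step (pipeline helper for tests)."""
    seeds = md.seed_from_grid(spec, volume)
    label_map = md.evolve(volume, seeds)
    return md.describe_scan(volume, label_map)
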