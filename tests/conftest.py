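"""Shared fixtures: small phantoms generated programmatically at test time."""

import numpy as np
import pytest

from leafvox.phantom import (
    PhantomSpec,
    generate_leaf_phantom,
    generate_slab_phantom,
    two_stoma_symmetric_spec,
)
from leafvox.stack_io import DEFAULT_LEGEND, LabeledStack

L = DEFAULT_LEGEND


@pytest.fixture(scope="session")
def small_slab_spec():
    """4-stoma slab at desk scale (~60x96x60 voxels)."""
    return PhantomSpec(
        leaf_thickness_um=80.0,
        epidermis_thickness_um=8.0,
        spongy_target_porosity=0.30,
        stoma_pitch_um=30.0,
        stoma_radius_um=3.0,
        lateral_extent_um=(60.0, 60.0),
    )


@pytest.fixture(scope="session")
def small_slab(small_slab_spec):
    return generate_slab_phantom(small_slab_spec)


@pytest.fixture(scope="session")
def two_stoma_slab():
    spec = two_stoma_symmetric_spec(
        leaf_thickness_um=60.0,
        epidermis_thickness_um=6.0,
        spongy_target_porosity=0.25,
        stoma_pitch_um=30.0,
        stoma_radius_um=3.0,
    )
    return generate_slab_phantom(spec)


@pytest.fixture(scope="session")
def small_leaf_spec():
    return PhantomSpec(
        leaf_thickness_um=120.0,
        epidermis_thickness_um=8.0,
        palisade_fraction=0.5,
        palisade_radius_top_um=5.0,
        palisade_radius_bottom_um=7.0,
        palisade_pitch_um=16.0,
        spongy_target_porosity=0.30,
        stoma_pitch_um=45.0,
        stoma_radius_um=3.0,
        lateral_extent_um=(90.0, 90.0),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_leaf(small_leaf_spec):
    return generate_leaf_phantom(small_leaf_spec)


def make_stack(volume, voxel=1.0, oriented=True):
    return LabeledStack(
        volume=np.asarray(volume, dtype=np.uint8),
        voxel_size_um=voxel,
        legend=L,
        oriented=oriented,
    )


@pytest.fixture()
def cell_matrix():
    """Factory: solid mesophyll-cell volume of a given shape."""

    def _make(shape, voxel=1.0):
        return np.full(shape, L.mesophyll_cell, dtype=np.uint8)

    return _make
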