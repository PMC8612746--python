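"""Shared fixtures: small phantoms and property tables."""

import numpy as np
import pytest

from fdhddot.phantom import (
    TISSUES,
    HeadPhantom,
    TissueProperties,
    build_layered_slab,
    default_property_table,
)


@pytest.fixture(scope="session")
def default_slab():
    """Default five-layer slab (120 x 120 x 60 mm, 2 mm voxels)."""
    return build_layered_slab()


@pytest.fixture(scope="session")
def tiny_slab():
    """Small heterogeneous slab for brute-force oracles (20x20x15 voxels)."""
    return build_layered_slab(
        lateral_extent=(40.0, 40.0), depth_extent=30.0, voxel_size=2.0
    )


def uniform_phantom(mua, musp, shape, voxel_size):
    """Homogeneous phantom with one optical property at both wavelengths."""
    table = default_property_table()
    for wl in (690, 850):
        table[("gray", wl)] = TissueProperties("gray", mua, musp, wl)
    labels = np.full(shape, TISSUES.index("gray"), dtype=np.uint8)
    return HeadPhantom(voxel_size=voxel_size, labels=labels, properties=table)


@pytest.fixture(scope="session")
def homogeneous_block():
    """Homogeneous medium (mua 0.02, musp 1.0) for Green's-function checks;
    0.8 mm voxels keep the discrete dispersion well inside the oracle
    tolerance."""
    return uniform_phantom(0.02, 1.0, (125, 125, 88), 0.8)


@pytest.fixture(scope="session")
def homogeneous_props():
    return TissueProperties("gray", 0.02, 1.0, 850)
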