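"""Shared fixtures: small random grids and the standard study phantoms
(60 mm cube, 30 mm-radius sphere) with their lattices and synthetic doses.

Expensive phantom plans are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import latticeforge as lf


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240612)


@pytest.fixture()
def small_grid() -> lf.VoxelGrid:
    return lf.VoxelGrid((10, 10, 10), (1.0, 1.0, 1.0))


def random_mask(grid: lf.VoxelGrid, rng: np.random.Generator, p: float = 0.4) -> lf.Mask:
    return lf.Mask(grid, rng.random(grid.shape) < p)


@pytest.fixture(scope="session")
def default_spec() -> lf.LatticeSpec:
    return lf.LatticeSpec()


@pytest.fixture(scope="session")
def cube_gtv() -> lf.Mask:
    """60 mm cube tumor at 1 mm isotropic voxels, centered at world 0."""
    gtv, _ = lf.make_phantom(lf.PhantomSpec(shape="box", semi_axes_mm=(30, 30, 30)))
    return gtv


@pytest.fixture(scope="session")
def sphere_gtv() -> lf.Mask:
    """30 mm-radius sphere tumor at 1 mm isotropic voxels."""
    gtv, _ = lf.make_phantom(
        lf.PhantomSpec(shape="sphere", semi_axes_mm=(30, 30, 30), margin_mm=15)
    )
    return gtv


@pytest.fixture(scope="session")
def cube_plan(cube_gtv, default_spec):
    """Full synthesized plan on the cube phantom: (vortexes, structures, dose)."""
    vortexes = lf.build_lattice(cube_gtv, default_spec)
    union, _ = lf.rasterize_vortexes(vortexes, cube_gtv.grid)
    structures = lf.derive_structures(cube_gtv, union, default_spec)
    dose = lf.synthesize_dose(structures, vortexes, lf.DoseModelParams(seed=0))
    return vortexes, structures, dose


@pytest.fixture(scope="session")
def isolated_vortex_plan(default_spec):
    """A 12 mm-radius sphere holds exactly one vortex: the isolated-peak
    closed-form geometry (neighbor lattice points fall outside)."""
    gtv, _ = lf.make_phantom(
        lf.PhantomSpec(shape="sphere", semi_axes_mm=(12, 12, 12), margin_mm=15)
    )
    vortexes = lf.build_lattice(gtv, default_spec)
    assert len(vortexes) == 1
    union, _ = lf.rasterize_vortexes(vortexes, gtv.grid)
    structures = lf.derive_structures(gtv, union, default_spec)
    return vortexes, structures
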