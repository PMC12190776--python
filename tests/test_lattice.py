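"""Vortex lattice generation: placement rule, pruning, derived structures."""

import numpy as np
import pytest

import latticeforge as lf
from latticeforge.errors import (
    DomainError,
    GuidelineWarning,
    ParameterError,
    StructureError,
)
from latticeforge.lattice import rasterize_one_vortex


def brute_force_accept(gtv: lf.Mask, center: np.ndarray, radius: float) -> bool:
    """Reference acceptance: the candidate point lies in a set voxel and no
    unset voxel center (grid exterior included) is closer than `radius`."""
    grid = gtv.grid
    idx = np.round(grid.world_to_index(center)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        return False
    if not gtv.values[tuple(idx)]:
        return False
    # scan every voxel center in a box around the candidate, plus the pad ring
    lo = np.floor(grid.world_to_index(center - radius - 2)).astype(int)
    hi = np.ceil(grid.world_to_index(center + radius + 2)).astype(int)
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            for k in range(lo[2], hi[2] + 1):
                inside_grid = (
                    0 <= i < grid.shape[0]
                    and 0 <= j < grid.shape[1]
                    and 0 <= k < grid.shape[2]
                )
                is_set = inside_grid and gtv.values[i, j, k]
                if not is_set:
                    p = grid.index_to_world(np.array([i, j, k]))
                    if np.sum((p - center) ** 2) < radius**2 - 1e-9:
                        return False
    return True


class TestBuildLattice:
    def test_cube_27_vortexes(self, cube_gtv, default_spec):
        """A 60 mm cube holds a full 3×3×3 lattice at 15 mm pitch."""
        vortexes = lf.build_lattice(cube_gtv, default_spec)
        assert len(vortexes) == 27
        offsets = np.unique(np.round(vortexes.centers_mm))
        assert set(offsets) == {-15.0, 0.0, 15.0}

    def test_sphere_19_vortexes(self, sphere_gtv, default_spec):
        """A 30 mm-radius sphere keeps the center, 6 face and 12 edge
        neighbors; the 8 cube corners at 15√3 ≈ 26 mm are rejected."""
        vortexes = lf.build_lattice(sphere_gtv, default_spec)
        assert len(vortexes) == 19

    def test_matches_brute_force_acceptance(self, sphere_gtv, default_spec):
        """Every lattice candidate in the bounding box is accepted exactly
        when the reference full-scan rule accepts it."""
        vortexes = lf.build_lattice(sphere_gtv, default_spec)
        accepted = {tuple(np.round(c, 3)) for c in vortexes.centers_mm}
        pq = np.arange(-2, 3)
        for p in pq:
            for q in pq:
                for r in pq:
                    center = 15.0 * np.array([p, q, r], dtype=float)
                    expected = brute_force_accept(sphere_gtv, center, 5.0)
                    assert (tuple(np.round(center, 3)) in accepted) == expected

    def test_tiny_gtv_yields_empty_set(self, default_spec):
        gtv, _ = lf.make_phantom(
            lf.PhantomSpec(shape="sphere", semi_axes_mm=(4, 4, 4), margin_mm=6)
        )
        vortexes = lf.build_lattice(gtv, default_spec)
        assert len(vortexes) == 0

    def test_empty_gtv_rejected(self, default_spec):
        g = lf.VoxelGrid((5, 5, 5), (1, 1, 1))
        with pytest.raises(DomainError):
            lf.build_lattice(lf.Mask(g, np.zeros(g.shape, bool)), default_spec)

    def test_oar_pruning_deletes_intersecting_spheres(self, cube_gtv, default_spec):
        """A slab OAR through the central lattice plane removes its 9 vortexes."""
        oar_values = np.zeros(cube_gtv.grid.shape, bool)
        x = cube_gtv.grid.axis_coords(0)
        oar_values[np.abs(x) <= 2.0, :, :] = True
        oar = lf.Mask(cube_gtv.grid, oar_values)
        pruned = lf.build_lattice(cube_gtv, default_spec, [oar])
        assert len(pruned) == 18
        assert not np.any(np.isclose(pruned.centers_mm[:, 0], 0.0))

    def test_oar_margin_prunes_more(self, cube_gtv):
        oar_values = np.zeros(cube_gtv.grid.shape, bool)
        x = cube_gtv.grid.axis_coords(0)
        oar_values[np.abs(x) <= 2.0, :, :] = True
        oar = lf.Mask(cube_gtv.grid, oar_values)
        n_margin = len(
            lf.build_lattice(cube_gtv, lf.LatticeSpec(oar_margin_mm=9.0), [oar])
        )
        n_plain = len(lf.build_lattice(cube_gtv, lf.LatticeSpec(), [oar]))
        assert n_margin <= n_plain

    def test_erosion_never_increases_count(self, sphere_gtv, default_spec):
        n_full = len(lf.build_lattice(sphere_gtv, default_spec))
        eroded = lf.erode_mask(sphere_gtv, 5.0)
        assert len(lf.build_lattice(eroded, default_spec)) <= n_full

    def test_scaling_preserves_count(self, default_spec):
        """Doubling every linear dimension (phantom, pitch, diameter) leaves
        the vortex count unchanged."""
        small, _ = lf.make_phantom(
            lf.PhantomSpec(shape="sphere", semi_axes_mm=(30, 30, 30),
                           margin_mm=10)
        )
        big, _ = lf.make_phantom(
            lf.PhantomSpec(shape="sphere", semi_axes_mm=(60, 60, 60),
                           spacing_mm=(2, 2, 2), margin_mm=20)
        )
        doubled = lf.LatticeSpec(sphere_diameter_mm=20, grid_pitch_mm=30)
        assert len(lf.build_lattice(big, doubled)) == len(
            lf.build_lattice(small, default_spec)
        )

    def test_deterministic(self, sphere_gtv, default_spec):
        a = lf.build_lattice(sphere_gtv, default_spec)
        b = lf.build_lattice(sphere_gtv, default_spec)
        assert np.array_equal(a.centers_mm, b.centers_mm)
        assert np.array_equal(a.anchor_mm, b.anchor_mm)

    def test_accepted_centers_have_clearance(self, cube_gtv, default_spec):
        """Distance-to-boundary at every accepted center is >= the radius."""
        vortexes = lf.build_lattice(cube_gtv, default_spec)
        dist = lf.distance_to_boundary(cube_gtv)
        for c in vortexes.centers_mm:
            idx = tuple(np.round(cube_gtv.grid.world_to_index(c)).astype(int))
            assert dist[idx] >= vortexes.radius_mm - 1.0  # voxel-sample slack


class TestVortexSet:
    def test_pitch_violation_rejected(self):
        with pytest.raises(ParameterError):
            lf.VortexSet(
                centers_mm=np.array([[0, 0, 0], [5, 0, 0]]),
                radius_mm=5.0,
                anchor_mm=np.zeros(3),
                pitch_mm=15.0,
            )

    def test_off_lattice_center_rejected(self):
        with pytest.raises(ParameterError):
            lf.VortexSet(
                centers_mm=np.array([[0, 0, 0], [15, 7.3, 0]]),
                radius_mm=5.0,
                anchor_mm=np.zeros(3),
                pitch_mm=15.0,
            )


@pytest.fixture(scope="module")
def coarse_sphere():
    gtv, _ = lf.make_phantom(
        lf.PhantomSpec(shape="sphere", semi_axes_mm=(30, 30, 30),
                       spacing_mm=(3, 3, 3), margin_mm=9)
    )
    return gtv


class TestSearchAnchor:
    def test_dominates_centroid_anchor(self, coarse_sphere, default_spec):
        n_centroid = len(lf.build_lattice(coarse_sphere, default_spec))
        searched = lf.build_lattice(
            coarse_sphere, lf.LatticeSpec(offset_search=True)
        )
        assert len(searched) >= n_centroid

    def test_matches_exhaustive_offset_oracle(self, coarse_sphere):
        """The searched count equals the maximum over the full offset grid."""
        spec = lf.LatticeSpec()
        from latticeforge.lattice import (
            _accept,
            _candidate_lattice,
            _outside_shell_tree,
        )
        from latticeforge.grid import centroid as mask_centroid

        base = mask_centroid(coarse_sphere)
        tree = _outside_shell_tree(coarse_sphere)
        best = 0
        for ox in np.arange(0, 15, 3.0):
            for oy in np.arange(0, 15, 3.0):
                for oz in np.arange(0, 15, 3.0):
                    anchor = base + np.array([ox, oy, oz])
                    cands = _candidate_lattice(coarse_sphere, anchor, 15.0)
                    best = max(best, int(_accept(coarse_sphere, tree, cands, 5.0).sum()))
        searched = lf.build_lattice(coarse_sphere, lf.LatticeSpec(offset_search=True))
        assert len(searched) == best

    def test_translation_by_one_pitch_preserves_count(self, coarse_sphere, default_spec):
        translated = lf.Mask(
            lf.VoxelGrid(
                coarse_sphere.grid.shape,
                coarse_sphere.grid.spacing,
                origin=tuple(o + 15.0 for o in coarse_sphere.grid.origin),
            ),
            coarse_sphere.values,
        )
        assert len(lf.build_lattice(translated, default_spec)) == len(
            lf.build_lattice(coarse_sphere, default_spec)
        )


class TestRasterize:
    def test_single_sphere_volume(self):
        g = lf.VoxelGrid((13, 13, 13), (1, 1, 1), origin=(-6, -6, -6))
        m = rasterize_one_vortex(np.zeros(3), 5.0, g)
        assert lf.volume_cc(m) == pytest.approx(4 / 3 * np.pi * 0.5**3, rel=0.03)

    def test_vortexes_disjoint_and_union_consistent(self, cube_gtv, cube_plan):
        vortexes, structures, _ = cube_plan
        union, per_vortex = lf.rasterize_vortexes(vortexes, cube_gtv.grid)
        total = sum(m.count for m in per_vortex)
        assert total == union.count  # pairwise disjoint at pitch >= diameter
        acc = np.zeros(cube_gtv.grid.shape, bool)
        for m in per_vortex:
            acc |= m.values
        assert np.array_equal(acc, union.values)

    def test_empty_set_empty_mask(self, small_grid):
        empty = lf.VortexSet(
            centers_mm=np.empty((0, 3)), radius_mm=5.0,
            anchor_mm=np.zeros(3), pitch_mm=15.0,
        )
        union, per = lf.rasterize_vortexes(empty, small_grid)
        assert union.is_empty and per == []


class TestDerivedStructures:
    def test_volume_conservation_exact(self, cube_plan):
        _, structures, _ = cube_plan
        assert lf.volume_cc(structures.vortex_union) + lf.volume_cc(
            structures.valley
        ) == pytest.approx(lf.volume_cc(structures.lrtv), abs=1e-12)
        assert np.array_equal(
            structures.peripheral.values,
            structures.ptv.values & ~structures.lrtv.values,
        )

    def test_peripheral_against_brute_force_dilation(self, rng):
        from test_grid import brute_force_dilate

        g = lf.VoxelGrid((16, 16, 16), (2, 2, 2))
        values = np.zeros(g.shape, bool)
        values[5:11, 5:11, 5:11] = True
        gtv = lf.Mask(g, values)
        spec = lf.LatticeSpec(ptv_margin_mm=6.0)
        structures = lf.derive_structures(
            gtv, lf.Mask(g, np.zeros(g.shape, bool)), spec
        )
        expected_ptv = brute_force_dilate(gtv, 6.0)
        assert np.array_equal(structures.ptv.values, expected_ptv)
        assert np.array_equal(structures.peripheral.values, expected_ptv & ~values)

    def test_zero_margin_empty_peripheral(self, cube_gtv):
        spec = lf.LatticeSpec(ptv_margin_mm=0.0)
        st = lf.derive_structures(
            cube_gtv, lf.Mask(cube_gtv.grid, np.zeros(cube_gtv.grid.shape, bool)), spec
        )
        assert st.peripheral.is_empty

    def test_containment_violation_rejected(self, cube_gtv, default_spec):
        outside = np.zeros(cube_gtv.grid.shape, bool)
        outside[0, 0, 0] = True  # far corner, outside the cube
        with pytest.raises(StructureError):
            lf.derive_structures(cube_gtv, lf.Mask(cube_gtv.grid, outside), default_spec)


class TestVortexRatio:
    def test_full_overlap_is_100(self, cube_gtv):
        with pytest.warns(GuidelineWarning):
            assert lf.vortex_ratio(cube_gtv, cube_gtv) == pytest.approx(100.0)

    def test_warns_above_guideline(self, small_grid):
        full = lf.Mask(small_grid, np.ones(small_grid.shape, bool))
        half = lf.Mask(small_grid, np.arange(1000).reshape(10, 10, 10) < 200)
        with pytest.warns(GuidelineWarning):
            lf.vortex_ratio(half, full)

    def test_below_packing_bound(self, cube_plan, default_spec):
        _, structures, _ = cube_plan
        ratio = lf.vortex_ratio(structures.vortex_union, structures.lrtv)
        assert 0 < ratio <= lf.packing_bound_pct(default_spec)
        assert lf.packing_bound_pct(default_spec) == pytest.approx(15.51, abs=0.01)

    def test_empty_lrtv_rejected(self, small_grid):
        empty = lf.Mask(small_grid, np.zeros(small_grid.shape, bool))
        with pytest.raises(DomainError):
            lf.vortex_ratio(empty, empty)
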