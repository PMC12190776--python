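"""Dense vortex lattice generation inside a tumor volume.

The planning convention implemented here: the lattice target volume (LRTV)
is the GTV itself (no inward contraction).  High-dose spheres ("vortexes",
default 10 mm diameter) are placed with their centers on a cubic grid
(default 15 mm pitch) anchored at the GTV centroid.  A candidate is
accepted only when its sphere lies *entirely* within the GTV — i.e. the
continuous distance from the center to the nearest outside voxel center is
at least the sphere radius — and is deleted when its sphere intersects an
organ at risk (optionally expanded by a safety margin).  The valley is the
LRTV outside the vortex union; the PTV is the GTV expanded isotropically
(default 10 mm); the peripheral volume is PTV ∖ LRTV.

Everything here is deterministic: identical inputs give identical lattices.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    DomainError,
    GuidelineWarning,
    ParameterError,
    StructureError,
)
from .grid import (
    Mask,
    VoxelGrid,
    centroid,
    dilate_mask,
    mask_difference,
    mask_union,
    volume_cc,
)

__all__ = [
    "LatticeSpec",
    "VortexSet",
    "StructureSet",
    "build_lattice",
    "search_anchor",
    "rasterize_vortexes",
    "rasterize_one_vortex",
    "derive_structures",
    "vortex_ratio",
    "packing_bound_pct",
]

log = logging.getLogger(__name__)

_EPS_MM = 1e-6


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice geometry and prescription parameters.

    sphere_diameter_mm : vortex sphere diameter (default 10 mm)
    grid_pitch_mm      : cubic center-to-center lattice pitch (default 15 mm);
                         must be >= the diameter so spheres never overlap
    ptv_margin_mm      : isotropic GTV→PTV expansion (default 10 mm)
    prescription_dose_gy : per-fraction vortex prescription (default 12 Gy)
    oar_margin_mm      : expansion applied to organs at risk before the
                         sphere-deletion test (default 0 mm)
    offset_search      : when True, the lattice anchor is optimized over one
                         pitch cell instead of fixed at the GTV centroid
    """

    sphere_diameter_mm: float = 10.0
    grid_pitch_mm: float = 15.0
    ptv_margin_mm: float = 10.0
    prescription_dose_gy: float = 12.0
    oar_margin_mm: float = 0.0
    offset_search: bool = False

    def __post_init__(self) -> None:
        if self.sphere_diameter_mm <= 0:
            raise ParameterError("sphere_diameter_mm must be > 0")
        if self.grid_pitch_mm < self.sphere_diameter_mm:
            raise ParameterError(
                "grid_pitch_mm must be >= sphere_diameter_mm (non-overlapping spheres)"
            )
        if self.ptv_margin_mm < 0:
            raise ParameterError("ptv_margin_mm must be >= 0")
        if self.prescription_dose_gy <= 0:
            raise ParameterError("prescription_dose_gy must be > 0")
        if self.oar_margin_mm < 0:
            raise ParameterError("oar_margin_mm must be >= 0")

    @property
    def radius_mm(self) -> float:
        return self.sphere_diameter_mm / 2.0


@dataclass
class VortexSet:
    """An ordered set of vortex sphere centers on one cubic lattice."""

    centers_mm: np.ndarray          # (n, 3) world mm
    radius_mm: float
    anchor_mm: np.ndarray           # (3,) lattice anchor, world mm
    pitch_mm: float

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers_mm, dtype=float).reshape(-1, 3)
        anchor = np.asarray(self.anchor_mm, dtype=float).reshape(3)
        if self.radius_mm <= 0:
            raise ParameterError("radius_mm must be > 0")
        if self.pitch_mm <= 0:
            raise ParameterError("pitch_mm must be > 0")
        if centers.shape[0] > 1:
            tree = cKDTree(centers)
            d, _ = tree.query(centers, k=2)
            if d[:, 1].min() < self.pitch_mm - _EPS_MM:
                raise ParameterError(
                    f"pairwise center distance {d[:, 1].min():.6f} mm < pitch"
                )
        if centers.shape[0]:
            frac = (centers - anchor) / self.pitch_mm
            if not np.allclose(frac, np.round(frac), atol=1e-6):
                raise ParameterError("all centers must sit on the anchored cubic lattice")
        self.centers_mm = centers
        self.anchor_mm = anchor

    def __len__(self) -> int:
        return self.centers_mm.shape[0]


@dataclass
class StructureSet:
    """Named masks on one shared grid with enforced set-algebra relations:
    valley = lrtv ∖ vortex_union, peripheral = ptv ∖ lrtv, vortex ⊆ lrtv ⊆ ptv."""

    lrtv: Mask                      # identical to the GTV by construction
    vortex_union: Mask
    valley: Mask
    ptv: Mask
    peripheral: Mask
    oars: list[Mask] = field(default_factory=list)

    def __post_init__(self) -> None:
        masks = [self.lrtv, self.vortex_union, self.valley, self.ptv, self.peripheral]
        if any(m.grid != self.lrtv.grid for m in masks) or any(
            o.grid != self.lrtv.grid for o in self.oars
        ):
            raise StructureError("all structure masks must share one grid")
        if not self.lrtv.contains(self.vortex_union):
            raise StructureError("vortex_union must be contained in the LRTV")
        if not self.ptv.contains(self.lrtv):
            raise StructureError("LRTV must be contained in the PTV")
        if np.any(self.valley.values != (self.lrtv.values & ~self.vortex_union.values)):
            raise StructureError("valley must equal lrtv \\ vortex_union voxelwise")
        if np.any(self.peripheral.values != (self.ptv.values & ~self.lrtv.values)):
            raise StructureError("peripheral must equal ptv \\ lrtv voxelwise")

    @property
    def gtv(self) -> Mask:
        return self.lrtv


# ---------------------------------------------------------------------------
# candidate acceptance machinery
# ---------------------------------------------------------------------------

def _outside_shell_tree(gtv: Mask) -> cKDTree:
    """KD-tree over the centers of unset voxels adjacent to the mask (grid
    exterior included via a one-voxel pad), i.e. the voxels realizing the
    nearest-outside distance for any interior point."""
    padded = np.pad(gtv.values, 1, mode="constant", constant_values=False)
    shell = ndimage.binary_dilation(padded, structure=np.ones((3, 3, 3), bool)) & ~padded
    idx = np.argwhere(shell) - 1  # back to unpadded index space (may be -1 / n)
    pts = gtv.grid.index_to_world(idx)
    return cKDTree(pts)


def _candidate_lattice(gtv: Mask, anchor: np.ndarray, pitch: float) -> np.ndarray:
    """All cubic-lattice points within the world bounding box of the mask."""
    idx = np.argwhere(gtv.values)
    lo = gtv.grid.index_to_world(idx.min(axis=0))
    hi = gtv.grid.index_to_world(idx.max(axis=0))
    ranges = []
    for a in range(3):
        pmin = math.ceil((lo[a] - anchor[a]) / pitch - 1e-9)
        pmax = math.floor((hi[a] - anchor[a]) / pitch + 1e-9)
        ranges.append(np.arange(pmin, pmax + 1))
    if any(r.size == 0 for r in ranges):
        return np.empty((0, 3))
    pqr = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    return anchor + pitch * pqr


def _accept(
    gtv: Mask, tree: cKDTree, candidates: np.ndarray, radius: float
) -> np.ndarray:
    """Boolean acceptance: the candidate lies in the mask and its distance
    to the nearest outside voxel center is >= radius.

    The shell tree measures the distance to the outside voxels only; the
    in-mask test (nearest voxel is set) disambiguates candidates that are
    far from the boundary on the *outside*.  For any radius larger than
    half the voxel diagonal the conjunction equals "distance from the
    candidate to the full unset voxel set >= radius".
    """
    if candidates.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    idx = np.round(gtv.grid.world_to_index(candidates)).astype(int)
    shape = np.asarray(gtv.grid.shape)
    in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
    inside = np.zeros(candidates.shape[0], dtype=bool)
    ii = idx[in_grid]
    inside[in_grid] = gtv.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    d, _ = tree.query(candidates)
    return inside & (d >= radius - _EPS_MM)


def build_lattice(
    gtv: Mask,
    spec: LatticeSpec,
    oars: list[Mask] | tuple[Mask, ...] = (),
) -> VortexSet:
    """Place vortex spheres on the cubic lattice inside the GTV.

    The lattice is anchored at the GTV mask centroid (or at the anchor found
    by :func:`search_anchor` when ``spec.offset_search``).  A lattice point
    is accepted when the closed sphere of ``spec.radius_mm`` around it lies
    entirely within the GTV, then deleted when that sphere intersects any
    OAR mask expanded by ``spec.oar_margin_mm``.  Deterministic; centers are
    returned in lexicographic lattice order.
    """
    if gtv.is_empty:
        raise DomainError("cannot build a lattice in an empty GTV")
    for oar in oars:
        if oar.grid != gtv.grid:
            raise StructureError("OAR masks must share the GTV grid")

    if spec.offset_search:
        anchor = search_anchor(gtv, spec)
    else:
        anchor = centroid(gtv)

    tree = _outside_shell_tree(gtv)
    candidates = _candidate_lattice(gtv, anchor, spec.grid_pitch_mm)
    accepted = candidates[_accept(gtv, tree, candidates, spec.radius_mm)]

    # OAR pruning: delete spheres intersecting any (expanded) OAR
    if accepted.shape[0] and oars:
        keep = np.ones(accepted.shape[0], dtype=bool)
        for oar in oars:
            if oar.is_empty:
                continue
            expanded = dilate_mask(oar, spec.oar_margin_mm)
            oar_tree = cKDTree(_set_centers(expanded))
            d, _ = oar_tree.query(accepted)
            keep &= d > spec.radius_mm + _EPS_MM
        accepted = accepted[keep]

    # lexicographic lattice order for determinism
    if accepted.shape[0]:
        pqr = np.round((accepted - anchor) / spec.grid_pitch_mm).astype(int)
        order = np.lexsort((pqr[:, 2], pqr[:, 1], pqr[:, 0]))
        accepted = accepted[order]
    else:
        log.warning("GTV too small (or too close to OARs) for any vortex sphere")

    return VortexSet(
        centers_mm=accepted,
        radius_mm=spec.radius_mm,
        anchor_mm=anchor,
        pitch_mm=spec.grid_pitch_mm,
    )


def _set_centers(mask: Mask) -> np.ndarray:
    return mask.grid.index_to_world(np.argwhere(mask.values))


def search_anchor(gtv: Mask, spec: LatticeSpec) -> np.ndarray:
    """Deterministic lattice-anchor optimization.

    Offsets on a sub-grid of step = min voxel spacing over one pitch cell
    ``[0, pitch)³`` (relative to the GTV centroid) are scored by accepted
    vortex count; ties are broken by (a) larger minimum center distance to
    the GTV boundary, then (b) lexicographically smallest offset.
    """
    if gtv.is_empty:
        raise DomainError("cannot search an anchor in an empty GTV")
    base = centroid(gtv)
    pitch = spec.grid_pitch_mm
    step = min(gtv.grid.spacing)
    offsets_1d = np.arange(0.0, pitch - 1e-9, step)
    tree = _outside_shell_tree(gtv)

    best = None  # (count, min_clearance, neg_offset_tuple, anchor)
    for ox in offsets_1d:
        for oy in offsets_1d:
            for oz in offsets_1d:
                anchor = base + np.array([ox, oy, oz])
                candidates = _candidate_lattice(gtv, anchor, pitch)
                if candidates.shape[0] == 0:
                    continue
                acc = _accept(gtv, tree, candidates, spec.radius_mm)
                d, _ = tree.query(candidates)
                count = int(acc.sum())
                clearance = float(d[acc].min()) if count else -np.inf
                key = (count, clearance, (-ox, -oy, -oz))
                if best is None or key > best[0]:
                    best = (key, anchor)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# rasterization and derived structures
# ---------------------------------------------------------------------------

def rasterize_one_vortex(center_mm: np.ndarray, radius_mm: float, grid: VoxelGrid) -> Mask:
    """Voxel-center-in-closed-sphere rasterization of a single vortex."""
    values = np.zeros(grid.shape, dtype=bool)
    center = np.asarray(center_mm, dtype=float)
    lo = np.maximum(np.ceil(grid.world_to_index(center - radius_mm) - 1e-9), 0).astype(int)
    hi = np.minimum(
        np.floor(grid.world_to_index(center + radius_mm) + 1e-9),
        np.asarray(grid.shape) - 1,
    ).astype(int)
    if np.any(hi < lo):
        return Mask(grid, values)
    coords = [grid.axis_coords(a)[lo[a]: hi[a] + 1] - center[a] for a in range(3)]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    values[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = (
        d2 <= radius_mm**2 + 1e-9
    )
    return Mask(grid, values)


def rasterize_vortexes(
    vortexes: VortexSet, grid: VoxelGrid
) -> tuple[Mask, list[Mask]]:
    """Rasterize every vortex; returns (union mask, per-vortex masks).

    Per-vortex masks are pairwise disjoint whenever pitch >= diameter, and
    their voxelwise OR equals the union mask.
    """
    per_vortex = [
        rasterize_one_vortex(c, vortexes.radius_mm, grid) for c in vortexes.centers_mm
    ]
    union = Mask(grid, np.zeros(grid.shape, dtype=bool))
    for m in per_vortex:
        union = mask_union(union, m)
    return union, per_vortex


def derive_structures(
    gtv: Mask,
    vortex_union: Mask,
    spec: LatticeSpec,
    oars: list[Mask] | tuple[Mask, ...] = (),
) -> StructureSet:
    """Derive valley / PTV / peripheral from the GTV and the vortex union."""
    if not gtv.contains(vortex_union):
        raise StructureError("vortex_union must be contained in the GTV")
    valley = mask_difference(gtv, vortex_union)
    ptv = dilate_mask(gtv, spec.ptv_margin_mm)
    peripheral = mask_difference(ptv, gtv)
    return StructureSet(
        lrtv=gtv,
        vortex_union=vortex_union,
        valley=valley,
        ptv=ptv,
        peripheral=peripheral,
        oars=list(oars),
    )


def vortex_ratio(vortex_union: Mask, lrtv: Mask) -> float:
    """Vortex-to-LRTV volume ratio in percent; warns above the 10% guideline."""
    if lrtv.is_empty:
        raise DomainError("vortex ratio undefined for an empty LRTV")
    ratio = 100.0 * volume_cc(vortex_union) / volume_cc(lrtv)
    if ratio > 10.0:
        warnings.warn(
            f"vortex-to-LRTV ratio {ratio:.2f}% exceeds the 10% guideline",
            GuidelineWarning,
            stacklevel=2,
        )
    return ratio


def packing_bound_pct(spec: LatticeSpec) -> float:
    """Infinite-lattice packing fraction (percent): the supremum of the
    vortex-to-LRTV ratio for this sphere diameter and pitch
    (≈15.5% for 10 mm spheres on a 15 mm cubic grid)."""
    return 100.0 * (4.0 * math.pi / 3.0) * spec.radius_mm**3 / spec.grid_pitch_mm**3
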