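"""Phantom tumor masks and synthetic lattice-like dose grids.

The dose model stands in for a TPS-optimized plan so every downstream
metric is testable without clinical data.  It is an analytic superposition:

    dose(x) = [ B + Σ_v (P − B) · exp(−‖x − c_v‖² / (2σ²)) ] · w(x)

with valley base B (Gy), vortex peak P (Gy), Gaussian peak width σ (mm),
and an exterior weight w(x) = 1 inside the LRTV and
exp(−dist_to_LRTV(x)/λ) outside it (falloff length λ, mm), evaluated over
the whole grid.  At an isolated vortex center the dose is exactly P;
far (≫σ) from every center inside the LRTV it approaches B.  Optional
zero-mean Gaussian voxel noise (clipped at 0 Gy) is seeded and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .grid import DoseGrid, Mask, VoxelGrid, distance_to_mask
from .lattice import StructureSet, VortexSet

__all__ = [
    "DoseModelParams",
    "PhantomSpec",
    "OarSpec",
    "make_phantom",
    "synthesize_dose",
    "dose_model_at",
]


@dataclass(frozen=True)
class DoseModelParams:
    """Parameters of the analytic lattice dose model.

    peak_dose_gy          : dose at an isolated vortex center (default the
                            12 Gy per-fraction prescription)
    peak_sigma_mm         : Gaussian width of each vortex peak (default 4 mm;
                            at 15 mm pitch neighboring peaks then contribute
                            < 0.1% at a center)
    valley_base_gy        : asymptotic in-target valley dose (default 5 Gy,
                            the intended valley dose level)
    exterior_falloff_mm   : exponential falloff length outside the LRTV
                            (default 10 mm, tuned so the peripheral mean
                            lands in the 2-5 Gy guideline band)
    additive_noise_sd_gy  : per-voxel Gaussian noise SD (default 0)
    seed                  : RNG seed for the noise (ignored when SD is 0)
    """

    peak_dose_gy: float = 12.0
    peak_sigma_mm: float = 4.0
    valley_base_gy: float = 5.0
    exterior_falloff_mm: float = 10.0
    additive_noise_sd_gy: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.peak_dose_gy > self.valley_base_gy >= 0:
            raise ParameterError("need peak_dose_gy > valley_base_gy >= 0")
        if self.peak_sigma_mm <= 0:
            raise ParameterError("peak_sigma_mm must be > 0")
        if self.exterior_falloff_mm <= 0:
            raise ParameterError("exterior_falloff_mm must be > 0")
        if self.additive_noise_sd_gy < 0:
            raise ParameterError("additive_noise_sd_gy must be >= 0")


@dataclass(frozen=True)
class OarSpec:
    """A simple organ-at-risk primitive placed next to/inside the phantom."""

    kind: str                      # "sphere" | "slab"
    center_mm: tuple[float, float, float]
    size_mm: float                 # sphere radius, or slab half-thickness (x-normal)

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "slab"):
            raise ParameterError(f"unknown OAR kind {self.kind!r}")
        if self.size_mm <= 0:
            raise ParameterError("OAR size_mm must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic tumor phantom description.

    shape        : "sphere" | "ellipsoid" | "box" | "union" (union of random
                   ellipsoids drawn from ``seed``)
    semi_axes_mm : ellipsoid semi-axes (a sphere uses equal ones); for "box"
                   the HALF side lengths; for "union" the envelope scale
    spacing_mm   : voxel spacing (default 1 mm isotropic)
    margin_mm    : empty border kept around the shape (room for the PTV
                   expansion and the exterior dose falloff; default 25 mm)
    n_components : ellipsoid count for "union" (default 3)
    oars         : optional OAR primitives
    seed         : shape randomization seed ("union" only)

    The grid has an odd voxel count per axis and its origin is chosen so
    that the shape center is exactly a voxel center at world (0, 0, 0).
    """

    shape: str = "sphere"
    semi_axes_mm: tuple[float, float, float] = (30.0, 30.0, 30.0)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 25.0
    n_components: int = 3
    oars: tuple[OarSpec, ...] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "box", "union"):
            raise ParameterError(f"unknown phantom shape {self.shape!r}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ParameterError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ParameterError("spacing must be positive")
        if self.margin_mm < 0:
            raise ParameterError("margin_mm must be >= 0")
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")


def _phantom_grid(spec: PhantomSpec) -> VoxelGrid:
    shape, origin = [], []
    for a in range(3):
        half = spec.semi_axes_mm[a] + spec.margin_mm
        n_half = int(np.ceil(half / spec.spacing_mm[a]))
        shape.append(2 * n_half + 1)
        origin.append(-n_half * spec.spacing_mm[a])
    return VoxelGrid(tuple(shape), tuple(spec.spacing_mm), tuple(origin))


def _world_axes(grid: VoxelGrid):
    return [grid.axis_coords(a) for a in range(3)]


def _ellipsoid_values(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    x, y, z = _world_axes(grid)
    u = ((x - center[0]) / semi_axes[0]) ** 2
    v = ((y - center[1]) / semi_axes[1]) ** 2
    w = ((z - center[2]) / semi_axes[2]) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0 + 1e-12


def make_phantom(spec: PhantomSpec) -> tuple[Mask, list[Mask]]:
    """Build the GTV mask (and OAR masks) described by ``spec``.

    Deterministic given the seed; analytic-shape volumes match the voxel
    volume within voxelization error.
    """
    grid = _phantom_grid(spec)
    x, y, z = _world_axes(grid)

    if spec.shape in ("sphere", "ellipsoid"):
        values = _ellipsoid_values(grid, (0.0, 0.0, 0.0), spec.semi_axes_mm)
    elif spec.shape == "box":
        u = np.abs(x) <= spec.semi_axes_mm[0] + 1e-12
        v = np.abs(y) <= spec.semi_axes_mm[1] + 1e-12
        w = np.abs(z) <= spec.semi_axes_mm[2] + 1e-12
        values = u[:, None, None] & v[None, :, None] & w[None, None, :]
    else:  # union of ellipsoids
        rng = np.random.default_rng(spec.seed)
        values = _ellipsoid_values(grid, (0.0, 0.0, 0.0), spec.semi_axes_mm)
        for _ in range(spec.n_components - 1):
            center = rng.uniform(-0.4, 0.4, size=3) * np.asarray(spec.semi_axes_mm)
            axes = rng.uniform(0.4, 0.9, size=3) * np.asarray(spec.semi_axes_mm)
            values |= _ellipsoid_values(grid, center, axes)

    gtv = Mask(grid, values)
    if gtv.is_empty:
        raise ParameterError("degenerate phantom: no voxel center falls inside the shape")

    oar_masks = []
    for oar in spec.oars:
        if oar.kind == "sphere":
            ov = _ellipsoid_values(grid, oar.center_mm, (oar.size_mm,) * 3)
        else:  # slab normal to x
            ov = np.zeros(grid.shape, dtype=bool)
            sel = np.abs(x - oar.center_mm[0]) <= oar.size_mm + 1e-12
            ov[sel, :, :] = True
        oar_masks.append(Mask(grid, ov))
    return gtv, oar_masks


# ---------------------------------------------------------------------------
# dose synthesis
# ---------------------------------------------------------------------------

def _peak_field(grid: VoxelGrid, vortexes: VortexSet, params: DoseModelParams) -> np.ndarray:
    """Σ_v exp(−‖x − c_v‖²/(2σ²)) accumulated over local ±6σ bounding boxes."""
    sigma = params.peak_sigma_mm
    reach = 6.0 * sigma
    out = np.zeros(grid.shape, dtype=float)
    shape = np.asarray(grid.shape)
    for c in vortexes.centers_mm:
        lo = np.maximum(np.ceil(grid.world_to_index(c - reach)), 0).astype(int)
        hi = np.minimum(np.floor(grid.world_to_index(c + reach)), shape - 1).astype(int)
        if np.any(hi < lo):
            continue
        coords = [grid.axis_coords(a)[lo[a]: hi[a] + 1] - c[a] for a in range(3)]
        d2 = (
            coords[0][:, None, None] ** 2
            + coords[1][None, :, None] ** 2
            + coords[2][None, None, :] ** 2
        )
        out[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] += np.exp(
            -d2 / (2.0 * sigma**2)
        )
    return out


def dose_model_at(
    points_mm: np.ndarray, vortexes: VortexSet, params: DoseModelParams
) -> np.ndarray:
    """Closed-form in-target dose at arbitrary points (valley base plus the
    Gaussian peak sum; no exterior weight — valid inside the LRTV)."""
    pts = np.asarray(points_mm, dtype=float).reshape(-1, 3)
    total = np.full(pts.shape[0], params.valley_base_gy)
    amp = params.peak_dose_gy - params.valley_base_gy
    for c in vortexes.centers_mm:
        d2 = np.sum((pts - c) ** 2, axis=1)
        total += amp * np.exp(-d2 / (2.0 * params.peak_sigma_mm**2))
    return total


def synthesize_dose(
    structures: StructureSet,
    vortexes: VortexSet,
    params: DoseModelParams,
) -> DoseGrid:
    """Synthesize a lattice-like dose grid for the given plan geometry."""
    grid = structures.lrtv.grid
    base = params.valley_base_gy + (
        params.peak_dose_gy - params.valley_base_gy
    ) * _peak_field(grid, vortexes, params)

    weight = np.ones(grid.shape, dtype=float)
    outside = ~structures.lrtv.values
    if outside.any() and not structures.lrtv.is_empty:
        dist = distance_to_mask(structures.lrtv)
        weight[outside] = np.exp(-dist[outside] / params.exterior_falloff_mm)

    dose = base * weight
    if params.additive_noise_sd_gy > 0:
        rng = np.random.default_rng(params.seed)
        dose = dose + rng.normal(0.0, params.additive_noise_sd_gy, size=dose.shape)
        dose = np.clip(dose, 0.0, None)
    return DoseGrid(grid, dose)
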