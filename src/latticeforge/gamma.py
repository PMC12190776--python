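"""Gamma-index comparison of two dose grids (default criteria 3%/3 mm).

For each reference voxel above the low-dose cutoff,

    γ(r_ref) = min over r_eval of sqrt( (ΔD/dose_tol)² + (|Δr|/dist_tol)² )

where ΔD is the difference between the reference dose and the evaluated
dose trilinearly interpolated at the search position.  The search covers a
ball of ``search_radius_factor × dist_tol`` around the voxel on a regular
sub-voxel step of ``dist_tol / search_step_divisor``.  The dose tolerance
is global by default (a percentage of the normalization dose — the
prescription, or the reference global maximum); a local-tolerance variant
is available.  A point passes when γ ≤ 1.

Two independent routes are provided: :func:`gamma_index` walks candidate
displacements sorted by distance and retires voxels as soon as the pure
distance term alone exceeds their running minimum (exact, just faster),
while :func:`gamma_index_exhaustive` performs the plain full search per
voxel at a finer default step and exists as the reference implementation
to validate the fast route against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError, ParameterError
from .grid import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_index", "gamma_index_exhaustive"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma comparison criteria.

    dose_tolerance_pct    : dose tolerance, percent of the normalization dose
    distance_tolerance_mm : distance-to-agreement tolerance (mm)
    normalization         : "prescription" (uses ``prescription_gy``) or
                            "global-max" (reference maximum)
    prescription_gy       : normalization dose for the prescription mode
    low_dose_cutoff_pct   : reference voxels below this percent of the
                            normalization dose are excluded (NaN)
    local                 : when True, the dose tolerance is a percentage of
                            the local reference dose instead of global
    search_radius_factor  : search ball radius in units of distance_tolerance
    search_step_divisor   : sub-voxel search step = dist_tol / divisor
    """

    dose_tolerance_pct: float = 3.0
    distance_tolerance_mm: float = 3.0
    normalization: str = "prescription"
    prescription_gy: float = 12.0
    low_dose_cutoff_pct: float = 10.0
    local: bool = False
    search_radius_factor: float = 3.0
    search_step_divisor: int = 10

    def __post_init__(self) -> None:
        if self.dose_tolerance_pct <= 0 or self.distance_tolerance_mm <= 0:
            raise ParameterError("tolerances must be > 0")
        if self.normalization not in ("prescription", "global-max"):
            raise ParameterError("normalization must be 'prescription' or 'global-max'")
        if self.normalization == "prescription" and self.prescription_gy <= 0:
            raise ParameterError("prescription_gy must be > 0")
        if not 0 <= self.low_dose_cutoff_pct < 100:
            raise ParameterError("low_dose_cutoff_pct must be in [0, 100)")
        if self.search_radius_factor <= 0 or self.search_step_divisor < 1:
            raise ParameterError("invalid search parameters")

    def normalization_dose(self, reference: DoseGrid) -> float:
        if self.normalization == "prescription":
            return self.prescription_gy
        return float(reference.values.max())


@dataclass
class GammaResult:
    """Per-voxel gamma (NaN below the cutoff) and the pass rate over the
    evaluated voxels.  ``pass_rate_pct`` is None when nothing was evaluated."""

    gamma: np.ndarray
    pass_rate_pct: float | None
    n_evaluated: int


def _prepare(reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria):
    if reference.grid != evaluated.grid:
        raise GridMismatchError("reference and evaluated dose must share one grid")
    norm = criteria.normalization_dose(reference)
    cutoff = criteria.low_dose_cutoff_pct / 100.0 * norm
    eval_mask = reference.values >= cutoff
    if criteria.local:
        dd = criteria.dose_tolerance_pct / 100.0 * reference.values[eval_mask]
        dd = np.maximum(dd, 1e-12)
    else:
        dd = np.full(int(eval_mask.sum()), criteria.dose_tolerance_pct / 100.0 * norm)
    return eval_mask, dd


def _offsets_mm(criteria: GammaCriteria, step_divisor: int) -> tuple[np.ndarray, np.ndarray]:
    """All displacement vectors (mm) within the search ball, plus their
    squared distance terms (|r|/dist_tol)², sorted by distance; the zero
    offset comes first."""
    dtol = criteria.distance_tolerance_mm
    step = dtol / step_divisor
    radius = criteria.search_radius_factor * dtol
    k = int(np.floor(radius / step))
    ax = step * np.arange(-k, k + 1)
    off = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    r2 = np.sum(off**2, axis=1)
    keep = r2 <= radius**2 + 1e-12
    off, r2 = off[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return off[order], r2[order] / dtol**2


def _result(gamma2_flat, eval_mask, shape) -> GammaResult:
    gamma = np.full(shape, np.nan)
    gamma[eval_mask] = np.sqrt(gamma2_flat)
    n = int(eval_mask.sum())
    if n == 0:
        return GammaResult(gamma=gamma, pass_rate_pct=None, n_evaluated=0)
    pass_rate = 100.0 * float(np.count_nonzero(gamma2_flat <= 1.0 + 1e-9)) / n
    return GammaResult(gamma=gamma, pass_rate_pct=pass_rate, n_evaluated=n)


def gamma_index(
    reference: DoseGrid, evaluated: DoseGrid, criteria: GammaCriteria = GammaCriteria()
) -> GammaResult:
    """Gamma comparison with distance-sorted search and early retirement.

    Exact under the stated discretization: candidate positions form the full
    regular ball; a voxel stops searching only when no remaining (more
    distant) candidate could lower its γ.
    """
    eval_mask, dd = _prepare(reference, evaluated, criteria)
    shape = reference.grid.shape
    if not eval_mask.any():
        return _result(np.empty(0), eval_mask, shape)

    spacing = np.asarray(reference.grid.spacing)
    base_idx = np.argwhere(eval_mask).astype(float)
    ref_flat = reference.values[eval_mask]
    gamma2 = ((evaluated.values[eval_mask] - ref_flat) / dd) ** 2

    offsets, dist_terms = _offsets_mm(criteria, criteria.search_step_divisor)
    ev = evaluated.values
    nmax = np.asarray(shape, dtype=float) - 1.0

    chunk = 64
    for start in range(1, offsets.shape[0], chunk):  # offset 0 already done
        stop = min(start + chunk, offsets.shape[0])
        active = gamma2 > dist_terms[start]
        if not active.any():
            break
        act_idx = np.flatnonzero(active)
        bact = base_idx[act_idx]
        ref_act = ref_flat[act_idx]
        dd_act = dd[act_idx]
        for j in range(start, stop):
            pos = bact + offsets[j] / spacing
            valid = np.all((pos >= 0.0) & (pos <= nmax), axis=1)
            if not valid.any():
                continue
            vals = ndimage.map_coordinates(ev, pos[valid].T, order=1)
            cand = ((vals - ref_act[valid]) / dd_act[valid]) ** 2 + dist_terms[j]
            tgt = act_idx[valid]
            np.minimum.at(gamma2, tgt, cand)
    return _result(gamma2, eval_mask, shape)


def gamma_index_exhaustive(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria = GammaCriteria(),
    step_divisor: int = 20,
    voxel_indices: np.ndarray | None = None,
) -> GammaResult:
    """Plain full-search gamma (reference implementation).

    Evaluates every candidate displacement for every voxel with no early
    termination, at a finer default search step.  ``voxel_indices`` (an
    ``(n, 3)`` integer array) restricts the computation to a subset of
    reference voxels; voxels outside the subset are NaN and excluded from
    the pass rate.
    """
    eval_mask, _ = _prepare(reference, evaluated, criteria)
    shape = reference.grid.shape
    if voxel_indices is not None:
        sub = np.zeros(shape, dtype=bool)
        vi = np.asarray(voxel_indices, dtype=int)
        sub[vi[:, 0], vi[:, 1], vi[:, 2]] = True
        eval_mask = eval_mask & sub
    if not eval_mask.any():
        return _result(np.empty(0), eval_mask, shape)
    dd = (
        criteria.dose_tolerance_pct / 100.0 * reference.values[eval_mask]
        if criteria.local
        else np.full(
            int(eval_mask.sum()),
            criteria.dose_tolerance_pct / 100.0 * criteria.normalization_dose(reference),
        )
    )
    dd = np.maximum(dd, 1e-12)

    spacing = np.asarray(reference.grid.spacing)
    nmax = np.asarray(shape, dtype=float) - 1.0
    offsets, dist_terms = _offsets_mm(criteria, step_divisor)
    off_idx = offsets / spacing

    base_idx = np.argwhere(eval_mask).astype(float)
    ref_flat = reference.values[eval_mask]
    gamma2 = np.empty(base_idx.shape[0])
    for i in range(base_idx.shape[0]):
        pos = base_idx[i] + off_idx
        valid = np.all((pos >= 0.0) & (pos <= nmax), axis=1)
        vals = ndimage.map_coordinates(evaluated.values, pos[valid].T, order=1)
        g2 = ((vals - ref_flat[i]) / dd[i]) ** 2 + dist_terms[valid]
        gamma2[i] = g2.min()
    return _result(gamma2, eval_mask, shape)
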