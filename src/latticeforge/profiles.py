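"""Line-profile analysis of 2D dose planes: extraction, spline fitting,
and peak/valley detection with the profile peak-to-valley ratio (PVDR).

A profile is sampled by bilinear interpolation along a segment of a 2D
dose plane (planes are pulled out of a 3D grid by axis + slice index).
A cubic smoothing spline is fitted (default smoothing 0 = interpolating,
C² between knots); extrema of the fitted curve are located on a dense
evaluation grid (one tenth of the sample step) and filtered by prominence
to suppress noise ripples.  Peaks and valleys alternate by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, signal

from .errors import DomainError, ParameterError
from .grid import DoseGrid

__all__ = [
    "DoseProfile",
    "Extremum",
    "ExtremaResult",
    "extract_plane",
    "extract_profile",
    "fit_profile_spline",
    "find_peaks_valleys",
    "profile_pvdr",
]

_PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class DoseProfile:
    """Dose samples along a line: positions (mm along the segment) and Gy."""

    positions_mm: np.ndarray
    doses_gy: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float)
        dose = np.asarray(self.doses_gy, dtype=float)
        if pos.ndim != 1 or pos.shape != dose.shape:
            raise ParameterError("positions and doses must be equal-length 1D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ParameterError("positions must be strictly increasing")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "doses_gy", dose)

    @property
    def sample_step_mm(self) -> float:
        return float(np.diff(self.positions_mm).mean())


def extract_plane(dose: DoseGrid, plane: str, index: int):
    """Pull one 2D plane out of a 3D dose grid.

    ``plane`` is "axial" (fixed z), "coronal" (fixed y) or "sagittal"
    (fixed x).  Returns ``(values2d, spacing2, origin2)`` for the two
    remaining axes in their original order.
    """
    if plane not in _PLANE_AXES:
        raise ParameterError(f"plane must be one of {sorted(_PLANE_AXES)}")
    axis = _PLANE_AXES[plane]
    if not 0 <= index < dose.grid.shape[axis]:
        raise DomainError(f"slice index {index} out of range for axis {axis}")
    values = np.take(dose.values, index, axis=axis)
    keep = [a for a in range(3) if a != axis]
    spacing2 = tuple(dose.grid.spacing[a] for a in keep)
    origin2 = tuple(dose.grid.origin[a] for a in keep)
    return values, spacing2, origin2


def extract_profile(
    plane_values: np.ndarray,
    spacing_mm: tuple[float, float],
    p0_mm: tuple[float, float],
    p1_mm: tuple[float, float],
    n_samples: int,
    origin_mm: tuple[float, float] = (0.0, 0.0),
) -> DoseProfile:
    """Sample the plane at ``n_samples`` equally spaced positions on the
    segment [p0, p1] (world mm) by bilinear interpolation."""
    plane_values = np.asarray(plane_values, dtype=float)
    if plane_values.ndim != 2:
        raise ParameterError("plane must be a 2D array")
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    if np.allclose(p0, p1):
        raise ParameterError("profile endpoints must differ")
    if n_samples < 2:
        raise ParameterError("need at least 2 samples")
    spacing = np.asarray(spacing_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    nmax = np.asarray(plane_values.shape, dtype=float) - 1.0
    for p in (p0, p1):
        idx = (p - origin) / spacing
        if np.any(idx < -1e-9) or np.any(idx > nmax + 1e-9):
            raise DomainError(f"profile endpoint {tuple(p)} mm lies outside the plane")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0 + t[:, None] * (p1 - p0)
    idx = ((pts - origin) / spacing).T
    idx = np.clip(idx, 0.0, nmax[:, None])
    doses = ndimage.map_coordinates(plane_values, idx, order=1)
    positions = t * np.linalg.norm(p1 - p0)
    return DoseProfile(positions_mm=positions, doses_gy=doses)


def fit_profile_spline(profile: DoseProfile, smoothing: float = 0.0):
    """Cubic smoothing spline through the profile samples.

    ``smoothing`` is the FITPACK residual bound (sum of squared residuals);
    0 gives the interpolating cubic spline, which reproduces polynomials up
    to degree 3 exactly.  Returns a callable evaluable at arbitrary mm
    positions.
    """
    if profile.positions_mm.size < 4:
        raise ParameterError("spline fitting needs at least 4 samples")
    if smoothing < 0:
        raise ParameterError("smoothing must be >= 0")
    return interpolate.UnivariateSpline(
        profile.positions_mm, profile.doses_gy, k=3, s=smoothing
    )


@dataclass(frozen=True)
class Extremum:
    position_mm: float
    value_gy: float
    kind: str  # "peak" | "valley"


@dataclass(frozen=True)
class ExtremaResult:
    """Alternating peaks and valleys of a fitted profile, in position order."""

    extrema: tuple[Extremum, ...]

    @property
    def peaks(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "peak"]

    @property
    def valleys(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "valley"]


def _enforce_alternation(extrema: list[Extremum]) -> list[Extremum]:
    """Keep the more extreme of any run of same-kind neighbors."""
    out: list[Extremum] = []
    for e in extrema:
        if out and out[-1].kind == e.kind:
            if e.kind == "peak":
                if e.value_gy > out[-1].value_gy:
                    out[-1] = e
            else:
                if e.value_gy < out[-1].value_gy:
                    out[-1] = e
        else:
            out.append(e)
    return out


def find_peaks_valleys(
    curve,
    x_range_mm: tuple[float, float],
    sample_step_mm: float,
    min_prominence_gy: float = 1.2,
) -> ExtremaResult:
    """Locate local maxima and minima of a fitted curve.

    The curve is evaluated on a dense grid (``sample_step_mm / 10``) over
    ``x_range_mm``; extrema with prominence below ``min_prominence_gy``
    (default 10% of the 12 Gy prescription) are discarded, then alternation
    is enforced.
    """
    if min_prominence_gy < 0:
        raise ParameterError("min_prominence_gy must be >= 0")
    x0, x1 = x_range_mm
    if not x1 > x0:
        raise ParameterError("x_range must be increasing")
    step = sample_step_mm / 10.0
    xs = np.arange(x0, x1 + step / 2, step)
    ys = np.asarray(curve(xs), dtype=float)
    ipk, _ = signal.find_peaks(ys, prominence=min_prominence_gy)
    ivl, _ = signal.find_peaks(-ys, prominence=min_prominence_gy)
    extrema = sorted(
        [Extremum(float(xs[i]), float(ys[i]), "peak") for i in ipk]
        + [Extremum(float(xs[i]), float(ys[i]), "valley") for i in ivl],
        key=lambda e: e.position_mm,
    )
    return ExtremaResult(extrema=tuple(_enforce_alternation(extrema)))


def profile_pvdr(extrema: ExtremaResult) -> float | None:
    """Profile PVDR = 100 × (mean valley value)/(mean peak value); None when
    either list is empty (reported explicitly, not an error)."""
    peaks = extrema.peaks
    valleys = extrema.valleys
    if not peaks or not valleys:
        return None
    mean_peak = float(np.mean([e.value_gy for e in peaks]))
    if mean_peak <= 0:
        return None
    return 100.0 * float(np.mean([e.value_gy for e in valleys])) / mean_peak
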