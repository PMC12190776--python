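"""Plan dosimetry: DVHs, per-structure dose statistics, plan metrics,
guideline checks, and cohort statistics.

Conventions, stated once and used everywhere:

* V(d) is the percent of a structure's volume receiving at least d Gy;
  D(p) is the highest dose d with V(d) >= p (the p-th percent "covered"
  dose).  Both are computed on raw voxel values, no histogram smoothing.
* VPDR (valley-to-peak dose ratio) is 100 x (valley mean)/(vortex mean),
  computed from mean doses; guideline band 50-80%.
* Cohort SD is the sample SD (n-1); the median of an even-sized column is
  the mean of the two central order statistics.  These conventions
  reproduce the reference cohort's printed summary rows.
* Guideline violations are warnings in reports, never hard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, GuidelineWarning, GridMismatchError, ParameterError
from .grid import DoseGrid, Mask, volume_cc
from .io import TABLE_COLUMNS, load_table1  # noqa: F401  (re-exported fixture loader)
from .lattice import LatticeSpec, StructureSet, vortex_ratio

__all__ = [
    "DoseStats",
    "DVH",
    "PlanMetrics",
    "CoverageResult",
    "TTestResult",
    "CorrResult",
    "dose_stats",
    "dvh",
    "volume_at_dose",
    "dose_at_volume",
    "coverage_check",
    "vpdr",
    "evaluate_plan",
    "cohort_summary",
    "paired_t_test",
    "pearson_corr",
    "metrics_to_frame",
    "load_table1",
]


def _structure_doses(dose: DoseGrid, mask: Mask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise GridMismatchError("dose and mask must share one grid")
    if mask.is_empty:
        raise DomainError("dose statistics over an empty mask are undefined")
    return dose.values[mask.values]


@dataclass(frozen=True)
class DoseStats:
    """Summary statistics of the dose within one structure."""

    mean_gy: float
    median_gy: float
    min_gy: float
    max_gy: float
    n_voxels: int


def dose_stats(dose: DoseGrid, mask: Mask) -> DoseStats:
    vals = _structure_doses(dose, mask)
    return DoseStats(
        mean_gy=float(vals.mean()),
        median_gy=float(np.median(vals)),
        min_gy=float(vals.min()),
        max_gy=float(vals.max()),
        n_voxels=int(vals.size),
    )


def volume_at_dose(dose: DoseGrid, mask: Mask, d_gy: float) -> float:
    """V(d): percent of the structure receiving >= d Gy."""
    vals = _structure_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(vals >= d_gy)) / vals.size


def dose_at_volume(dose: DoseGrid, mask: Mask, p_pct: float) -> float:
    """D(p): the highest dose d with V(d) >= p (0 < p <= 100)."""
    if not 0 < p_pct <= 100:
        raise ParameterError("p_pct must be in (0, 100]")
    vals = np.sort(_structure_doses(dose, mask))[::-1]
    k = math.ceil(p_pct / 100.0 * vals.size)
    return float(vals[k - 1])


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    bin_edges_gy: np.ndarray
    cum_volume_pct: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_gy, dtype=float)
        cum = np.asarray(self.cum_volume_pct, dtype=float)
        if edges.ndim != 1 or edges.size != cum.size:
            raise ParameterError("bin edges and cumulative volumes must align")
        if np.any(np.diff(cum) > 1e-9):
            raise ParameterError("cumulative DVH must be monotone non-increasing")
        object.__setattr__(self, "bin_edges_gy", edges)
        object.__setattr__(self, "cum_volume_pct", cum)


def dvh(dose: DoseGrid, mask: Mask, structure: str = "", bin_width_gy: float = 0.05) -> DVH:
    """Cumulative DVH sampled on a uniform dose axis from 0 past the max."""
    vals = _structure_doses(dose, mask)
    top = float(vals.max()) + bin_width_gy
    edges = np.arange(0.0, top + bin_width_gy, bin_width_gy)
    cum = 100.0 * (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVH(structure=structure, bin_edges_gy=edges, cum_volume_pct=cum)


# ---------------------------------------------------------------------------
# prescription rules and plan metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageResult:
    """The vortex prescription rule: 95% of the vortex volume must receive
    95% of the prescription dose."""

    passed: bool
    v95_pct: float
    threshold_gy: float


def coverage_check(
    dose: DoseGrid, vortex_union: Mask, prescription_gy: float
) -> CoverageResult:
    threshold = 0.95 * prescription_gy
    v = volume_at_dose(dose, vortex_union, threshold)
    return CoverageResult(passed=v >= 95.0, v95_pct=v, threshold_gy=threshold)


def vpdr(valley_mean_gy: float, vortex_mean_gy: float) -> float:
    """Valley-to-peak dose ratio in percent; warns outside the 50-80% band."""
    if vortex_mean_gy <= 0:
        raise DomainError("vortex mean dose must be > 0")
    ratio = 100.0 * valley_mean_gy / vortex_mean_gy
    if not 50.0 <= ratio <= 80.0:
        warnings.warn(
            f"VPDR {ratio:.1f}% is outside the 50-80% guideline band",
            GuidelineWarning,
            stacklevel=2,
        )
    return ratio


@dataclass
class PlanMetrics:
    """One plan's metric row (the per-case table schema), plus guideline
    flags.  Dose fields are None when the corresponding structure is empty
    (degenerate plans are reported, not crashed on)."""

    case_id: str
    lrtv_cc: float
    vortex_cc: float
    valley_cc: float
    vortex_ratio_pct: float
    vortex_dose_gy: float | None
    valley_dose_gy: float | None
    vpdr_pct: float | None
    peripheral_dose_gy: float | None
    flags: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def evaluate_plan(
    dose: DoseGrid,
    structures: StructureSet,
    spec: LatticeSpec,
    case_id: str = "plan",
    oar_dose_limits_gy: dict[int, float] | None = None,
) -> PlanMetrics:
    """Assemble every plan metric and guideline flag from a dose grid and a
    structure set.

    Guideline flags recorded: vortex-to-LRTV ratio <= 10%, VPDR in 50-80%,
    peripheral mean dose in 2-5 Gy, the 95%/95% vortex coverage rule, and —
    when ``oar_dose_limits_gy`` maps OAR indices to max-dose limits — a
    per-OAR max-dose check.
    """
    notes: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GuidelineWarning)
        ratio = vortex_ratio(structures.vortex_union, structures.lrtv)

    def _mean_or_none(mask: Mask, name: str) -> float | None:
        if mask.is_empty:
            notes.append(f"{name} is empty; its dose metrics are undefined")
            return None
        return dose_stats(dose, mask).mean_gy

    vortex_mean = _mean_or_none(structures.vortex_union, "vortex union")
    valley_mean = _mean_or_none(structures.valley, "valley")
    peripheral_mean = _mean_or_none(structures.peripheral, "peripheral volume")

    vpdr_pct: float | None = None
    if vortex_mean is not None and valley_mean is not None and vortex_mean > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", GuidelineWarning)
            vpdr_pct = vpdr(valley_mean, vortex_mean)

    flags: dict[str, bool | None] = {
        "vortex_ratio_le_10pct": ratio <= 10.0,
        "vpdr_in_50_80pct": None if vpdr_pct is None else 50.0 <= vpdr_pct <= 80.0,
        "peripheral_in_2_5_gy": (
            None if peripheral_mean is None else 2.0 <= peripheral_mean <= 5.0
        ),
    }
    if structures.vortex_union.is_empty:
        flags["coverage_95_95"] = None
    else:
        cov = coverage_check(dose, structures.vortex_union, spec.prescription_dose_gy)
        flags["coverage_95_95"] = cov.passed
        flags["coverage_v95_pct"] = cov.v95_pct

    if oar_dose_limits_gy:
        for idx, limit in oar_dose_limits_gy.items():
            oar = structures.oars[idx]
            if oar.is_empty:
                flags[f"oar{idx}_max_le_limit"] = None
            else:
                mx = dose_stats(dose, oar).max_gy
                flags[f"oar{idx}_max_le_limit"] = mx <= limit
                flags[f"oar{idx}_max_gy"] = mx

    return PlanMetrics(
        case_id=case_id,
        lrtv_cc=volume_cc(structures.lrtv),
        vortex_cc=volume_cc(structures.vortex_union),
        valley_cc=volume_cc(structures.valley),
        vortex_ratio_pct=ratio,
        vortex_dose_gy=vortex_mean,
        valley_dose_gy=valley_mean,
        vpdr_pct=vpdr_pct,
        peripheral_dose_gy=peripheral_mean,
        flags=flags,
        notes=notes,
    )


def metrics_to_frame(metrics: list[PlanMetrics] | PlanMetrics) -> pd.DataFrame:
    """PlanMetrics rows as a DataFrame in the canonical table schema."""
    if isinstance(metrics, PlanMetrics):
        metrics = [metrics]
    rows = [
        {c: getattr(m, c) for c in TABLE_COLUMNS}
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean, sample SD (n-1; 0 for a single row), median
    (mid-mean for even n), min and max over all numeric metric columns."""
    if len(table) < 1:
        raise DomainError("cohort summary of an empty table is undefined")
    cols = [c for c in table.columns if c != "case_id"]
    data = {}
    for c in cols:
        v = np.asarray(table[c], dtype=float)
        sd = 0.0 if v.size == 1 else float(np.std(v, ddof=1))
        data[c] = {
            "mean": float(v.mean()),
            "sd": sd,
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return pd.DataFrame(data).loc[["mean", "sd", "median", "min", "max"]]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired Student t-test with n-1 degrees of freedom.

    A zero-variance difference vector is reported explicitly as degenerate
    (t = 0, p = 1 when the means agree; t = ±inf, p = 0 otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ParameterError("need two equal-length 1D vectors with n >= 3")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("values must be finite")
    diff = a - b
    n = diff.size
    if np.std(diff, ddof=1) == 0:
        if diff.mean() == 0:
            return TTestResult(t=0.0, p=1.0, df=n - 1, degenerate=True)
        return TTestResult(
            t=math.copysign(math.inf, diff.mean()), p=0.0, df=n - 1, degenerate=True
        )
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=n - 1)


def pearson_corr(x, y) -> CorrResult:
    """Pearson correlation with the two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ParameterError("need two equal-length 1D vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("values must be finite")
    res = stats.pearsonr(x, y)
    return CorrResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)
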