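# Methods

## Background and scope

Lattice radiation therapy (LRT) is a spatially fractionated technique for
bulky tumors: instead of a uniform dose, the plan delivers an array of
small high-dose spheres ("vortexes") inside the tumor, separated by
deliberately lower-dose "valleys". `latticeforge` implements the planning
geometry and plan-evaluation side of a *dense* LRT protocol:

* the lattice target volume (LRTV) is the gross tumor volume (GTV) itself —
  no inward contraction;
* vortexes are 10 mm-diameter spheres whose centers sit on a cubic grid of
  15 mm pitch (so the in-plane diagonal neighbor distance is 15√2 ≈ 21 mm);
* a vortex is kept only when its sphere lies entirely within the GTV, and
  deleted when it intersects an organ at risk (OAR), optionally expanded by
  a safety margin;
* valley = LRTV ∖ vortex union; PTV = GTV expanded isotropically by 10 mm;
  peripheral volume = PTV ∖ LRTV;
* prescription is 12 Gy per fraction to the vortexes, evaluated as
  V(0.95·D_Rx) ≥ 95% over the vortex union; plan-quality guidelines are a
  vortex-to-LRTV volume ratio ≤ 10%, a valley-to-peak dose ratio (VPDR,
  100·valley mean/vortex mean) of 50–80%, and a peripheral mean dose of
  2–5 Gy.

Inverse IMRT optimization, monitor units, DICOM-RT parsing, image
registration and measured QA workflows are out of scope; the package
evaluates geometry and dose grids, it does not produce deliverable plans.

## Grid and mask model

Grids are axis-aligned rasters with anisotropic mm spacing; voxel *centers*
carry the geometry and indices are 0-based. Masks combine only on an
identical grid — there is no implicit resampling, so every set-algebra
identity (valley + vortex = LRTV, peripheral = PTV ∖ LRTV) holds
voxel-exactly by construction rather than approximately after interpolation.
All morphology is metric: margins and boundary distances use exact
Euclidean distance transforms in mm (`scipy.ndimage.distance_transform_edt`
with the spacing as sampling), so "this sphere lies entirely inside" has a
voxel-size-independent meaning. The world outside the grid counts as
outside every structure.

A voxel belongs to a rasterized sphere iff its center is within the radius.
This convention converges to the analytic volume as spacing shrinks
(checked at 2/1/0.5 mm) and is trivially oracle-checkable.

## Lattice placement

Candidates are every cubic-lattice point inside the GTV bounding box, with
the lattice anchored at the GTV mask centroid. Acceptance is evaluated on
the continuous metric: the candidate must lie in a set voxel and its
distance to the nearest outside voxel center (KD-tree over the boundary
shell, grid exterior included) must be at least the sphere radius. OAR
pruning removes any accepted center whose sphere reaches an OAR mask that
has first been expanded by `oar_margin_mm` (default 0 — the clinical rule
is qualitative, so the margin is exposed as a parameter). Everything is
deterministic; centers are reported in lexicographic lattice order.

Because no anchor rule exists in clinical practice (the grid is positioned
manually), an optional deterministic anchor search is provided: offsets on
a sub-grid of step = min voxel spacing over one pitch cell, scored by
vortex count, ties broken by larger minimum boundary clearance and then by
lexicographically smallest offset.

Reference closed forms used in the tests: a 60 mm cube holds exactly 3³ =
27 vortexes; a 30 mm-radius sphere holds 19 (center + 6 face + 12 edge
neighbors; the 8 cube-corner points at 15√3 ≈ 26 mm exceed the 25 mm
clearance limit). The vortex-to-LRTV ratio can never exceed the
infinite-lattice packing fraction 100·(4π/3)·r³/pitch³ ≈ 15.5%.

## Synthetic dose model

Clinical LRT doses come from inverse IMRT optimization, which this package
does not perform. To make every downstream metric testable, doses are
synthesized analytically:

dose(x) = [B + Σ_v (P − B)·exp(−‖x − c_v‖²/2σ²)] · w(x),

with w = 1 inside the LRTV and w = exp(−dist_to_LRTV/λ) outside it.
Defaults: peak P = 12 Gy (the prescription), valley base B = 5 Gy (the
intended valley level), peak width σ = 4 mm, exterior falloff λ = 10 mm
(chosen so the peripheral mean lands inside the 2–5 Gy band), optional
seeded Gaussian voxel noise (default 0, clipped at 0 Gy).

Properties that make the model a useful oracle: at an isolated vortex
center the dose is exactly P (at 15 mm pitch a neighbor contributes
exp(−15²/32) ≈ 8.6×10⁻⁴ of the peak amplitude, negligible); at points ≥ 3σ
from a single center the dose is within 7·e^(−4.5)/5 ≈ 1.6% of B — note
that in a *dense* lattice interior the lattice sum at ~13 mm from eight
centers reaches ~6–7% of B, so the 5% closed-form recovery check is run on
the isolated-vortex phantom; and as σ → ∞ relative to the sphere radius the
vortex mean tends to P (within 1% at σ = 50 mm).

What the model does not emulate: optimizer-shaped dose (real vortex mean
doses sit at ~99% of prescription, whereas a σ = 4 mm Gaussian sphere mean
is ≈ 80% of peak — synthesized plans therefore *fail* the V95 coverage rule
by design honesty, not by bug), beam geometry, heterogeneity corrections,
and measurement noise structure. Passing tests demonstrate correctness of
the metrics pipeline on known ground truth, not clinical plan quality.

## Dosimetry conventions

V(d) is the percent of structure volume with dose ≥ d; D(p) is the largest
d with V(d) ≥ p, computed on sorted raw voxel values (no histogram
smoothing; the DVH type is for reporting). VPDR uses mean doses, matching
the per-case reference table. Cohort summaries use the sample SD (n−1) and
the mid-mean median convention — both choices reproduce the published
summary rows of the packaged 22-case table. The paired two-sided Student
t-test is used for the per-case dose comparisons (the three dose metrics
are repeated measures on the same plans); Pearson correlation uses the
two-sided t-approximation p-value. Degenerate cases (zero-variance
differences, empty structures) are reported explicitly instead of raising.

The packaged fixture (`data/table1.csv`) stores the published per-case
values verbatim, including their internal rounding inconsistencies
(`valley_cc ≠ lrtv_cc − vortex_cc` for several cases, a TPS-voxelization
artifact of the source data). Internally generated plans always satisfy
the exact set-difference definition; the fixture is never regenerated.

## Gamma index

Global gamma with prescription-dose normalization (12 Gy default) and a 10%
low-dose cutoff; local-tolerance and global-max normalization are options.
The search minimizes √((ΔD/dose_tol)² + (|Δr|/dist_tol)²) over a regular
displacement ball of radius 3×dist_tol with sub-voxel step dist_tol/10 and
trilinear interpolation of the evaluated dose; positions outside the grid
are skipped. Both grids must share one grid (resampling is out of scope).

Two independent routes exist: the production route sorts displacements by
distance and retires a voxel once the pure distance term exceeds its
running minimum (this is exact — no remaining candidate can improve it),
and an exhaustive per-voxel full search at a finer default step
(dist_tol/20) kept as the reference implementation. On identical candidate
sets the two agree bit-for-bit; the acceptance run compares them on a
random smooth 12³ pair over a deterministic 100-voxel subsample to stay
inside desk-scale runtimes.

## Profile analysis

Profiles are sampled by bilinear interpolation along a segment of a 2D
plane pulled from the 3D grid by axis + slice index. The fit is a cubic
smoothing spline (FITPACK); the default smoothing of 0 interpolates and
reproduces polynomials up to degree 3 to machine precision. Extrema are
located on a dense evaluation grid (sample step/10) and filtered by
prominence (default 1.2 Gy = 10% of the prescription) to suppress noise
ripples; alternation is enforced by keeping the more extreme of same-kind
neighbors. Profile PVDR = 100·(mean valley value)/(mean peak value). On
synthesized lattices the profile PVDR tracks the volumetric VPDR within
~10% in the default regime — a consistency check, not an equality, since a
1D diagonal samples the valley differently than the volume average.

## Problem sizes and determinism

The standard phantoms are a 60 mm cube and a 30 mm-radius sphere at 1 mm
isotropic voxels (≈1.4M and ≈0.75M voxels), the isolated-vortex phantom is
a 12 mm-radius sphere, and gamma comparisons run on 12³ grids at 2 mm
spacing — sizes chosen so the full suite and the acceptance script run in
well under a minute and a quarter hour respectively on a single core. The
only stochastic component anywhere is the optional dose noise plus the
random fields used in QA checks; one integer seed drives all of it, and the
default zero-noise pipeline is bit-for-bit reproducible.

## Known limitations

* Axis-aligned grids only; no resampling, no oblique orientations, no
  DICOM-RT I/O.
* The synthetic dose model is a stand-in for optimizer output (see above);
  guideline checks on synthesized plans characterize the model, not a TPS.
* `search_anchor` optimizes vortex count only; clinical anchor choice may
  weigh OAR geometry.
* OAR pruning uses sphere-vs-voxel-center distance; a sphere grazing a
  voxel cell corner without reaching its center is not counted as an
  intersection (sub-voxel effect, bounded by half the voxel diagonal).
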