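# Methods

## Scope and assumptions

The package models a section of basal cell membrane spanning one grating
groove as a linear elastic (Euler–Bernoulli) beam, freely supported on the
two adjacent ridge tops, deflecting under a uniformly distributed load.
The substrate is treated as rigid (Spurr's-resin-grade stiffness); the
substrate bending angle θ_S is an inherent fabrication slope of the ridge
edge, not a load response. Surface tension is neglected — over the
sub-micron to few-micron spans considered, bending stiffness dominates.
Large-deflection (geometrically nonlinear) elasticity and viscoelasticity
are out of scope, as is any mechanistic model of membrane–substrate
adhesion: the θ_M(θ_S) relation is purely empirical.

## Beam model (`beam`)

The displacement polynomial v(x) combines a uniform-load term scaled by
q/24EI with two end-rotation terms. The implementation returns
downward-positive magnitudes, so measured deflections d are non-negative;
the mid-span relation d/L = (q/24EI)·L³/16 + θ_M/4 takes θ_M in radians
(required for d/L to be dimensionless). Degree-valued angles in
measurement records are converted at the module boundary.

Two internal conventions deserve note:

* **Load ratio.** The deflection data constrain only the combination
  q/24EI (m⁻³). `BeamParameters` carries q and EI when known and derives
  the ratio, or carries the ratio alone straight from a fit.
  `fit_load_ratio` regresses (d/L − θ_M/4) on L³/16 through the origin —
  the model has no constant term, so fitting an intercept would
  contradict its structure. A free-intercept fit is available as a
  diagnostic only (computed in centred closed form; the raw design matrix
  is numerically singular at x ~ 1e-19 m³). A negative fitted slope is
  flagged, never clamped.
* **Energy bookkeeping.** `strain_energy` implements U = q²L⁵/240EI, the
  stored energy of a uniformly loaded simply-supported span, and is
  verified against quadrature of M²/2EI with M = qx(L−x)/2. The
  deflection polynomial's load term has the fixed-end (clamped) shape
  while the energy formula uses the simply-supported moment; both are
  implemented exactly as stated and the tension is documented here rather
  than "corrected", since each is used only in its own role (profile
  shape vs. rigidity estimation). Estimating EI from a stated bending
  energy is exposed as the algebraic inversion q²L⁵/240U; the choice of U
  for a lipid bilayer is left to the caller.

## Angle relation (`angles`)

θ_M rises linearly with θ_S up to a knee b (adhesion holds the membrane
against the sloped ridge edge), then decays exponentially with scale c
(the substrate falls away too steeply for adhesion to beat the membrane's
restoring force). The decay branch's prefactor is the product a·b, which
makes the curve continuous at the knee by construction; points exactly at
θ_S = b are residual-neutral and assigned to the linear branch.

Fitting is joint nonlinear least squares over (a, b, c), multi-started
from knee candidates b₀ ∈ {10°, 15°, …, 70°} crossed with decay starts
c₀ ∈ {2°, 5°, 15°}, with a profiled through-origin slope as the a start;
the objective is non-smooth in b, and the multi-start reliably escapes
the local minima a single solve can stall in. The fit is deterministic
for fixed input. If the best solution places no data beyond its knee, the
decay scale is unidentifiable: the result is flagged, c is reported as
NaN, and a and b fall back to the linear-branch fit. Residuals are
unweighted — no replicate structure is assumed for the input pairs.

## Phase diagram (`phase`)

Composing the two relations gives d/L over the (L, θ_S) plane. The
d/L = level contour (default level 0.05) is extracted algebraically per
θ_S — the cubic load term inverts in closed form,
L* = [16(level − θ_M/4)/ratio]^⅓ — rather than by marching squares on the
grid; the grid exists only for the colormap. Three summary numbers:

* critical width L* at θ_M = 0 (bending at every substrate angle above it);
* low critical angle degrees(4·level)/a, where the θ_M/4 term alone
  reaches the level as L → 0 on the linear branch;
* high critical angle b + c·ln(radians(a·b)/(4·level)), where the decay
  branch re-crosses the level.

The printed decay is continuous, so the high crossing falls at ≈49° for
the study constants even though the two-regime description places the
changeover at the 44° knee; a `hard_step` option zeroes θ_M beyond the
knee for users who prefer the abrupt reading. The continuous equations
are the default on the principle that fitted equations take precedence
over prose descriptions of them.

## Profile measurement (`profiles`)

Contact points A and B are the last/first membrane vertices whose
vertical clearance above the substrate is within ε_contact (default 1% of
the substrate relief height — traced polylines never touch exactly). The
groove crossing is the membrane's widest off-contact run whose underlying
substrate dips well below the contact line, which distinguishes it from
tolerance-scale micro-separations on ridge tops. L = |AB|; d is the
maximum perpendicular distance from AB on the groove side (for a tilted
AB this is the line-referenced reading, which is what a distance measured
"from the line" means); θ_M and θ_S come from local tangents at A and B,
measured at both endpoints and averaged, with per-endpoint values kept.

Tangents are estimated by fitting a low-order polynomial (default cubic)
to a window of points (default arc length 5% of L, minimum 3 points) in
the AB frame and evaluating its derivative **at the endpoint**. An
average window direction (chord or fitted line) is biased low by the
curvature of the deflection curve — its slope falls linearly toward
mid-span, so a 5% window underestimates θ_M by ~5% — while the endpoint
derivative of a cubic tracks the true tangent to well under 1%. On
heavily jittered traces the cubic's derivative amplifies noise; the fit
degree and window are configurable (degree 1 with a wider window is the
robust fallback).

The morphometrics follow the standard definitions: the equimomental
ellipse shares the polygon's area and second central area moments
(shoelace-integral moments, eigen-decomposition; a solid ellipse with
semi-axes p ≥ q has central moments πp³q/4 and πpq³/4, giving semi-axes
2√(λ/A)); elongation is the axis ratio minus one; a cell is aligned when
its elongation is ≥ 4 and its long axis lies strictly within 15° of the
grating axis (difference taken mod 180° and folded to [0°, 90°]).
Bending-angle segmentation uses half-open bins at 15°/30°/45°, the upper
group being θ_M ≥ 45°.

## Synthetic data (`synthetic`)

The generator emulates the study's measurement tables so the pipeline is
testable without the original TEM data:

* **Gap widths** are drawn per grating class from Normal(spacing − line
  width, pooled SD), truncated positive, using the measured grating
  dimensions (350 nm/500 nm/1 µm/2 µm/10 µm classes; e.g. the 2 µm class
  has gap 3906 − 1983 = 1923 nm). The 10 µm class is generated on request
  but excluded from model fits by default — its spans are far outside the
  deflection model's regime and the bending dataset covers 350 nm–2 µm.
* **Angles**: θ_S uniform on [0°, 70°] (the observed substrate-angle
  range); θ_M is the piecewise relation plus Gaussian noise (default SD
  2°), floored at 0 to respect the record invariant. d/L is the beam
  relation evaluated at the record's own (noisy) θ_M plus Gaussian noise
  (default SD 0.01), truncated at 0; because generation and fitting use
  the same θ_M, the load-ratio regression stays unbiased.
* **Defaults** are the study conditions: load ratio 1.2 × 10¹⁷ m⁻³,
  (a, b, c) = (0.8433, 44°, 4.397°), 112 records per class (14 cells × 8
  membrane–ridge pairs). The noise SDs are assumptions — the study
  reports only SD bars, not a noise model — and are config-exposed.
* **Profiles**: two ridges whose tops are straight facets descending
  toward the gap at θ_S, flanking the gap; the membrane rests on the
  facets and crosses along the deflection polynomial with symmetric end
  rotations. The end-slope coefficient is tan(θ_M), making the geometric
  tangent angle at the contacts exactly the requested θ_M (the
  small-angle identification tan θ ≈ θ made exact, so
  generator→measurement round trips close). Deflections exceeding the
  ridge height are clipped at the groove floor and flagged. Ground truth
  is stored in profile metadata.
* **Cell outlines** are ellipse-boundary polygons with sampled axis
  ratios and orientations, ground truth retained.

What the generator does **not** emulate: TEM imaging physics, sectioning
compression, stain contrast, membrane roughness beyond white y-jitter,
correlated noise within cells, or any dependence of noise on groove
width. Passing tests therefore demonstrate correctness of the estimators
under the assumed noise model, not robustness to real TEM artefacts.

## Numerical choices and problem sizes

Angle fits use `scipy.optimize.least_squares` with xtol = ftol = 1e-12
and positivity bounds; the exponential's argument is clipped at 0 on the
branch whose values are discarded, purely to avoid spurious overflow.
Synthetic recovery checks use 200 records (50 per bending class) — the
scale of the study's per-class sampling — and fixed seeds; at that size
the load-ratio estimate has ~2.5% standard error under the default noise,
so the 5% recovery check is a ~2σ criterion. Property tests sample
parameter space with seeded/derandomised generators. All randomness flows
through `numpy.random.default_rng` from explicit seeds; identical
configuration yields byte-identical CSV/JSON output.

## Known limitations

* The displacement polynomial's load term and the strain-energy formula
  embody different support conventions (see above); both are intentional.
* The EI arithmetic from a stated membrane bending energy does not
  reproduce every published rigidity estimate — the formula is exposed,
  and the energy input is the caller's responsibility.
* `measure_groove` assumes one groove per profile with the membrane
  spanning it; multi-groove traces must be split upstream, and membranes
  that sag into contact with the groove floor are not measurable (the
  spanning check raises).
* The piecewise angle relation is empirical; extrapolation beyond the
  fitted θ_S range (0–70°) relies on the exponential tail's shape.
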