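# Methods

## Problem and scope

The package models the saliva film in the labial vestibule of a lower
central incisor carrying an orthodontic bracket, with and without an
archwire, during one swallow, and quantifies how the appliance reshapes
the near-wall flow in the 2-mm band around the bracket base (regions BO
occlusal, BG gingival, BL/BR lateral). In parallel it reproduces the
clinical statistics of the same study design: log₁₀ CFU bacterial loads
per site at baseline (T0, before bonding), one week after bonding (T1)
and one week after archwire placement (T2), and longitudinal gingival
index (GI) and pocket depth (PD) comparisons.

Everything runs on synthetic inputs. The geometry is a parametric stand-in
for a patient-specific CT reconstruction, and the cohorts are drawn
around published group means and SDs; consequently the flow metrics are
meaningful as *patterns and orderings* (which sites are fast or slow,
where vortices form, how the archwire shifts speeds), not as
patient-exact values.

## Geometry

A rectangular slab of saliva, default 10 × 10 × 1.4 mm (0.14 ml), rests
on the tooth plane z = 0; x runs mesio-distally, y occluso-gingivally
(occlusal = +y). The bracket is a rectangular prism, default
2.4 × 3.0 × 1.0 mm, centred on the surface. Only the bracket width
(2.4 mm), the archwire diameter (0.014 inch) and the film volume
(0.14 ml) are externally fixed; the slab extents, bracket height and
thickness are package defaults chosen so the bracket leaves at least the
2-mm metric band on every side, the film volume matches 0.14 ml, and the
wire (axis at z = 1.2 mm) clears the bracket's labial face while staying
inside the film. All of these are config-exposed.

Solids are discretised on a uniform Cartesian grid (default cell
0.2 mm) by marking every cell whose centre lies inside the prism or the
wire cylinder — an immersed-obstacle representation replacing a
body-fitted tetrahedral mesh at desk scale. The metric band is the
square-cornered offset rectangle: surface cells outside the footprint
with axis gaps dx, dy ≤ 2 mm. Each band cell belongs to the side of its
nearest bracket edge (smaller axis gap); corner cells with equal gaps go
to the lateral regions. With the discretized footprint of W × H mm the
band area identity (W+4)(H+4) − W·H holds exactly under this rule.

## Flow solver

Incompressible Navier–Stokes with ρ = 1000 kg/m³ and μ = 1.0 mPa·s
(water-like; saliva's effective viscosity is config-exposed), gravity
neglected. At the problem's Reynolds number (ρ·U·d/μ ≈ 4×10² with
U = 0.172 m/s, d = 2.4 mm) the flow is laminar-transitional, so the
solver runs laminar; a constant eddy-viscosity multiplier is available
instead of a two-equation turbulence closure, which is out of scope.

Discretisation: staggered (MAC) grid, explicit first-order upwind
advection, explicit central diffusion, Chorin pressure projection. The
pressure-Poisson system (homogeneous Neumann on every prescribed-velocity
boundary, one pinned cell against the nullspace) is assembled once per
geometry and factorised sparsely (LU), so each step's projection is exact
to machine precision; the nominal relative tolerance 10⁻⁸ is enforced as
a post-hoc residual check. Time steps adapt to dt ≤ 0.4·h/max|v| and
dt ≤ h²/(6ν) — the three-dimensional explicit-diffusion limit, slightly
stricter than the 0.25·h²/ν one would use in 1-D.

Boundary conditions: the swallow enters through the upstream y face and
leaves through the opposite face, both prescribed the uniform signed
speed U(t) = peak·sin(πt/T) (half-sine, T = 0.25 s, peak 0.172 m/s);
prescribing the same value on both faces conserves volume identically.
Tooth, bracket, wire and the remaining walls are impermeable and
free-slip (zero shear), the "frictionless" idealisation; a no-slip mode
is config-exposed for sensitivity runs and per-axis wall overrides
support validation cases (e.g. no-slip plates for channel flow). The
anatomical reading of "the saliva enters and exits through the upper
boundary" is ambiguous; this package interprets the swallow as a
through-flow along the occluso-gingival axis, upstream face chosen by
flow direction.

Validation, all in the test suite: exact global mass balance; divergence
at solver precision; steady body-force-driven plane channel flow matches
the Poiseuille parabola within 2 % (0.3 % at 16 cells across the gap);
projection agrees with a dense linear-algebra solve of the same system on
a small grid; mirror-image geometries give mirror-image cycles; halving
the cell size from 0.4 to 0.2 mm (the default) changes regional average
speeds by less than 10 %.

## Flow metrics

All metrics read the first fluid cell layer above the tooth plane (the
sampling height is not externally specified; one layer is the finest
available). Per region and flow direction:

* **Average velocity** — area-weighted regional mean of the time-averaged
  near-wall speed over the cycle.
* **Low-velocity area** — area with speed ≤ 0.005 m/s (v_max/100 with
  v_max = 0.5 m/s; the threshold, not v_max, is operative), evaluated on
  the mid-cycle field where the inflow runs at the characteristic rate.
  Under the free-slip default the near-wall speed scales with the bulk
  and these areas are essentially zero on the default geometry — the
  published patches arise from the wall boundary layer, which the
  frictionless idealisation removes; the no-slip sensitivity mode
  restores a slow patch in the gingival recirculation core.
* **Vortex area** — connected components (4-connectivity) of positive
  2-D Q-criterion, Q = (‖Ω‖² − ‖S‖²)/2 of the tangential velocity
  gradient, threshold ε_Q = 10⁻⁶ s⁻². Values under solid cells are
  replaced by the nearest fluid value before differencing (zero-gradient
  extrapolation consistent with free-slip) to avoid spurious wall shear.
  Swallow-level vortex metrics are evaluated on the **end-of-cycle
  residual field**: while the pulse is active the separated shear layers
  attached to the bracket corners merge into one rotation-positive sheet,
  whereas after the inflow decays only closed recirculation survives.
  On the default geometry under a gingival swallow this leaves a vortex
  pair gingival to the bracket (intersecting BG, never BO), the
  direction-specific pattern the analysis is built around. Residual
  swirl is also the physically relevant quantity for retention: saliva
  trapped in it circulates at vanishing net speed, extending clearance
  half-time.
* **Direction combination** — arithmetic mean of the two directions for
  speeds and low-velocity areas; maximum for vortex areas (vortex
  formation is direction-specific, so averaging would halve a
  one-direction phenomenon).

Areas are cell counts × cell area with no sub-cell interpolation;
convergence under refinement is tested rather than interpolated away.

## Clinical statistics

CFU estimation follows bench practice: serial 10-fold dilutions, 50 µl
aliquots ("50 µm" in the source protocol is read as a microlitre typo),
plates countable only below 300 colonies, first countable plate used.
The estimate is log₁₀(count·10ᵏ/0.05) per ml of transport medium (1 ml
per sample, so per-sample values are numerically equal). Summaries use
the sample SD (n−1). Sites are compared pairwise within patients (six
ordered pairs) with the paired *t*-test; GI longitudinally with the
Wilcoxon signed-rank test (zeros dropped, mid-ranks for ties, exact
2ⁿ enumeration for n ≤ 12, tie-corrected normal approximation with 0.5
continuity correction above), PD with the paired *t*; p < 0.05 is the
significance threshold, with no multiple-testing correction by design.
Degenerate cells (zero variance) render as NaN p-values instead of
aborting a report. The per-site n is patients (27), not teeth.

## Synthetic generators

* **Cohorts** — every group draw is mean + sd·(√ρ_w·z_patient +
  √(1−ρ_w)·ε) with a shared standard-normal patient effect per variable
  family, giving within-patient correlation ρ_w (default 0.5, free
  parameter — the true cross-site covariance is unknowable from group
  summaries) while preserving group means and SDs exactly in
  expectation. GI is generated continuously and clipped to [0, 3]
  (published GI means are averages of an ordinal index; an
  ordinal-rounding mode exists), PD floored at 0. Defaults are the
  published group parameters: baseline 8.6332 ± 0.0207, the T1/T2
  per-site CFU table, and the GI/PD table; n = 27.
* **Plating** — Poisson counts with expectation density·0.05·10⁻ᵏ.
  Together with the estimator the pipeline recovers log₁₀ density within
  ±0.15 when the first countable plate's expectation is mid-range;
  near the 300-colony cutoff the next plate may hold only ~30 colonies,
  where ±0.15 is a ≈2σ Poisson statement rather than a guarantee.
* **Analytic fields** — uniform, linear shear, plane Poiseuille and
  Lamb–Oseen vortex (v_θ = Γ/(2πr)(1−e^(−r²/r_c²))) evaluated at the
  staggered locations; these are the independent oracles for the solver
  and metric tests (e.g. the low-velocity area of a Lamb–Oseen core
  against the closed-form disc radius).

What passing tests do **not** show about real data: the synthetic
geometry has a flat tooth surface, a plain prism bracket (no wings,
slots or ligatures) and free-slip walls, so absolute speeds and areas are
not patient-comparable; the cohort generator assumes Gaussian group
distributions and a single-factor correlation structure; plating assumes
perfect dilution and Poisson counting.

## Problem sizes and runtimes

The default flow case is 50 × 50 × 7 cells (0.2 mm) and ~700 adaptive
steps per 0.25 s swallow, a few seconds per run; the test suite's
refinement check uses a 0.4 mm/0.2 mm pair on a 1.6 mm film so both
resolutions divide all extents. Statistical recovery tests use n = 27
and n = 10⁴ cohorts. The acceptance script (4 swallow simulations, the
channel validation, table identities and recovery measures) completes in
about a minute on one CPU.

## Known limitations

No turbulence closure, free surface, saliva rheology or moving mucosa;
vortex identification is 2-D near-wall, not a 3-D core-line method; areas
are cell-counted; the low-velocity metric is sensitive to the wall-slip
idealisation as noted above; GI ordinality is only approximated; printed
p-values of the source tables are not reproduced (they require the
patient-level raw data), only the arithmetic identities among published
means are.
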