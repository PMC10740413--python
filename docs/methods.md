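# Methods

This note records the models, numerical choices and conventions behind
`inkflow`, and what the synthetic-data generators do and do not emulate.

## Constitutive model and fitting

Inks are modelled as time-independent power-law fluids,
`eta = K * gamma_dot^(n-1)`, over the measured window 1–100 s⁻¹.  Yield
stress, thixotropy and temperature dependence are deliberately out of
scope; the 30 °C measurement condition is carried as an annotation on
curves, not modelled.  Fitting is unweighted OLS of log η on log γ̇:
standard for data spanning decades, exactly linear in the parameters, and
an exact inverse of the generator on noise-free curves (round-trip
recovery is tested to 1e-9 relative).  Goodness of fit is the R² of the
log–log line.

## Response-surface models

The Box–Behnken constructor emits a deterministic run order (factor pairs
lexicographically, sign combinations (−,−), (−,+), (+,−), (+,+), centre
replicates last), which fixes all downstream seeds and hashes.  Models
are fitted in **uncoded** (wt%) units by default because the shipped
final polynomials are printed in uncoded units; coded-unit fitting is
available (`uncoded=False`) and is used for effect ranking, where
orthogonality makes standardized effects comparable.

Diagnostics follow the classical partition: per-term partial F = t²
against F(1, dfe); lack of fit separates pure error (within replicate
groups, here the 5 centre points) from model misfit; predicted R² comes
from PRESS via the leave-one-out hat-matrix identity `e_i/(1−h_ii)`,
verified in tests against explicit refit-and-predict loops to 1e-8.  With
a perfect fit (zero residual variance) t-statistics degenerate; nonzero
coefficients are reported as infinitely significant and exactly-zero ones
as null effects.  A constant response is flagged (`zero_variance`) and
its R² reported as 0.

Backward elimination removes, per iteration, the highest-p term with
p > 0.05 — skipping linear terms while any surviving square or
interaction contains them, and never the intercept — unless the removal
would *decrease* predicted R², in which case the term is retained for its
predictive value.  Calibration on synthetic 17-run data generated from
the shipped n-polynomial (which omits the Gel·SA and SA·MC interactions)
shows the removed set is always a subset of the truly-absent
interactions, and exactly equals it in ~64% of replicates at every noise
scale: the retention veto fires on a genuinely null term in the remaining
~36%.  Tests freeze those calibrated rates.

The K polynomial's printed coefficients evaluate to 1000× the tabulated
Pa·s values at all five validation compositions (they were evidently
exported in mPa·s), so the stored model applies an explicit 10⁻³ output
scale; tests confirm the factor at every composition.  Prediction
accuracy uses `1 − |pred − meas| / pred`: normalising by the prediction
reproduces the published K-accuracy column cell by cell, whereas
normalising by the measurement does not; the published n-accuracy column
is not reproducible from the table's own rounded entries under either
convention and is not asserted.

## Nozzle flow

The lubrication approximation treats each axial station of the slender
channel as locally fully developed pipe flow — appropriate for the small
taper angles and creeping-flow Reynolds numbers of syringe extrusion.
Entrance/exit losses and extrudate swell are not modelled; the slow-start
toolpath scheme compensates the real start-up transient rather than
simulating it.

Default geometry: barrel R 4.8 mm × 10 mm, conical transition
4.8 → 0.125 mm over 20 mm, needle cylinder R 0.125 mm × 12.7 mm — a 3 mL
syringe front end with a half-inch 25 G cannula (ID 0.25 mm).  The needle
length dominates the resistance and places the mid-box ink
(n = 0.575, K = 55 Pa·s) at 0.28 µL/s under 250 kPa, inside the 0–4 µL/s
window expected for printable inks of this family; a much shorter exit
would predict unphysically high corner-case velocities.  Geometry is
fully configurable.

Numerics: interface units are mm / kPa / µL·s⁻¹ with SI internally;
conical segments use fixed-panel composite Simpson quadrature (2048 axial
panels), agreeing with a 10⁶-slice midpoint oracle to ~1e-10 relative;
flow-rate inversion brackets log Q in [1e-6, 1e3] µL/s with doubling
expansion (60-step cap) and solves by Brent to 1e-12 relative, so
pressure-drop/flow round trips hold to 1e-8; exit profiles are evaluated
on 1025 radial points and integrate back to the solver's Q to better than
1e-4.

## Surrogate and regimes

Latin-hypercube sampling uses `scipy.stats.qmc` (one point per equal
stratum per axis, seeded).  The surrogate is a one-hidden-layer tanh
network (default 8 units) with L2 penalty 1e-5, trained by L-BFGS on
standardized inputs; three seed-derived restarts are run and the lowest
training loss kept, making training deterministic under the seed.  The
target is **log Q**: flow rate is positive and spans ~4 decades over the
box, and the log target cuts held-out error by an order of magnitude
versus raw Q (median over seeds: MAE ≈ 0.05%, RMSE ≈ 0.15% of the
observed range, against the <1% acceptance bound).  A thin-plate-spline
RBF interpolant is available behind the same interface.  MAE/RMSE are
reported raw (µL/s) and as % of the observed test-set flow-rate range —
the paper-style "%" figures have no stated basis, so the range convention
is documented here rather than assumed silently.

k-means (k = 3, k-means++ with fixed seed, 10 inits) runs on standardized
(n, K, Q); clusters are relabelled canonically by ascending mean Q, so
"high-viscosity" is always the low-flow group.  Calibration shows the
(n = 0.45, K = 100 Pa·s) corner always lands in the high-viscosity regime
and that regime has the smallest within-cluster flow variance.  Because Q
scales near-proportionally with pressure, the standardized partition is
essentially pressure-invariant — cross-pressure boundary drift is not
asserted.  The surrogate and solver surfaces agree to ~0.05% of range on
average; the worst pointwise deviation (calibrated bound 15%) always sits
at the steep low-n/low-K corner, where the flow surface is steepest and
LHS training density vanishes.

## Toolpaths

Coordinates are right-handed mm, part origin at the lower-left of layer
0, z = layer × 0.2 mm, segments axis-aligned.  Every travel→print
transition inserts one slow-start segment of length v₀·t₀ (default
1 mm/s × 0.1 s = 0.1 mm) which *counts toward* the designed stroke
length; with t₀ = 0 strokes are single segments.  Perimeter frames print
before infill; grid infill alternates 0°/90° between layers (the
generalized alternation; solid fill keeps one orientation); fill short
edges stop exactly D₂ = 0.3 mm from the frame (default inside the
validated 0.2–0.3 mm window), with lateral frame-to-fill spacing 0.5 mm
and line spacing 0.8 mm.  Travel speed defaults to 30 mm/s.  Extrusion
toggling is modelled as instantaneous — the physical lag is what t₀
compensates.  Bookkeeping assumes the extrudate is drawn into a uniform
cylinder, so segment volume = Q × duration and diameter follows
`d = 2√(Q/(πv))`; totals conserve volume to 1e-9 relative.  Coordinates
are snapped to 1 nm so the G-code export (9-decimal fixed point, F in
mm/min, M101/M103 extrusion toggles, layer and slow-start comments)
re-imports to an identical path.

## Synthetic data

Generators emulate the measurement *protocols*, with truth taken from the
shipped response polynomials: 21-point endpoint-inclusive log-uniform
shear sweeps over 1–100 s⁻¹ with multiplicative log-normal viscosity
noise (σ_log = 0.03 default — instrument error scales with reading);
17-run design responses with additive Gaussian noise (σ_n = 0.005,
σ_K = 2 Pa·s defaults, chosen so synthetic validation accuracies land in
the high-90s%/~80% ranges real measurements show); and solver-backed flow
datasets in the 300-train/50-test layout.  All generators are
deterministic under their seed, and noise-free outputs are exact fixed
points of the corresponding fitting stages.  They do **not** emulate
instrument artifacts (plate inertia, slip, evaporation), batch-to-batch
material variability, or any disagreement between the quasi-1D solver and
a full CFD of the real channel — so passing tests certify internal
consistency of the pipeline, not agreement with new laboratory
measurements.

## Problem sizes

Default study sizes — 17-run design, 300 + 50 flow solves, 20×20 regime
grids, 200–500-replicate calibration loops — run in seconds on one CPU;
the full test suite takes well under a minute.  The brute-force oracles
(10⁶-slice quadrature, explicit leave-one-out refits) run inside the test
suite itself.

## Known limitations

* The lubrication solver ignores entrance effects and die swell; absolute
  flow rates for a *real* nozzle depend on the measured channel, which is
  configurable but defaults to a nominal footprint.
* The published models are interpolations over the design cube;
  compositions outside Gel 6–10 / SA 3–5 / MC 2–4 wt% trigger
  extrapolation warnings.
* Printed coefficients are rounded to 3–4 significant figures, limiting
  agreement with tabulated predictions to ~2 decimals.
* The toolpath planner covers axis-aligned rectangular parts and single
  strokes; it is a process-scheme generator, not a general slicer.
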