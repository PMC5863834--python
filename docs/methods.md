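# Methods

## The method in brief

A stenosed vessel segment's mean pressure drop obeys, to good
approximation, the quadratic law Δp̄ = f·Q̄ + s·Q̄², with a viscous
coefficient `f` and an expansion-loss coefficient `s`. The package
traces a lesion's pressure–flow curve by solving steady flow under a
series of boundary conditions, fits `(f, s)` by constrained least
squares, and derives the integral indices S1 and S2 (areas under the
curve up to 1 and 2 ml/s). The four quantities `f, s, S1, S2` grade the
lesion's flow resistance without requiring a hyperemic operating point.

## The reduced-order flow engine

The original formulation of this method drives a 3-D finite-volume CFD
solver. This package deliberately replaces it with a reduced-order
engine in which every segment obeys the quadratic law with
geometry-derived coefficients:

* **Viscous coefficient.** f = ∫ 8πμ / A(s)² ds along the centerline,
  evaluated by composite trapezoidal quadrature on the area profile's
  samples. For a uniform tube this is exactly Poiseuille's
  128 μL/(πD⁴). Internal working units are mmHg, ml/s, mm and mm²;
  conversions from cP and kg/m³ to SI and back are centralized in
  `pfcurve.units` with 1 mmHg = 133.322 Pa.
* **Expansion loss.** A Young–Tsai-type throat/reference contrast term
  s = kt · (1 + γ·e_throat) · (ρ/2) · (1/A_min − 1/A_ref)², where
  A_min is the minimal lumen area (MLA), A_ref the reference lumen
  area, and e_throat the eccentricity index at the MLA location. The
  constant `kt = 1.52` and the eccentricity multiplier coefficient
  `γ = gamma_ecc = 0.25` are **engine parameters of this package**, not
  measured quantities: they preserve the qualitative pattern that
  losses grow steeply with area stenosis and that eccentric throats
  lose more than concentric ones at equal AS%, but absolute pressure
  drops are not calibrated against any 3-D solver. Both are
  configurable on `FluidProperties`.
* **Network solve.** Branched trees carry a lumped resistance at every
  outlet. Unknowns are the terminal flows; internal flows follow from
  conservation, and every root-to-terminal path must balance
  p_in − Σ(f_i·Q_i + s_i·Q_i|Q_i|) − R_t·Q_t = p_ref. A Newton
  iteration on the terminal flows, initialized from the linearized
  (s = 0) resistor network, with damping factor 0.5 on overshooting
  steps, non-negative step clipping, and at most 200 iterations,
  converges to a residual below 1e-11 mmHg (typically 3–6 iterations).
  The downstream reference pressure defaults to p_ref = 0 mmHg.

What the engine does **not** model: turbulence, pulsatility, flow-
dependent (Reynolds-number) loss coefficients, wall compliance, and 3-D
secondary flow. Its purpose is to exercise the *method* — sweep, fit,
indices, reporting — at desk scale with exactly the quadratic structure
the fit estimates.

## Geometry

Idealized stenosis models are built from a reference tube (default
diameter 3 mm) with a uniform throat realizing the requested area
stenosis over a stricture of two reference diameters, linear area
tapers of half a reference diameter at each end, and uniform
proximal/distal sections of two reference diameters. AS% is defined as
100 × (1 − MLA/A_ref); the reference area is the mean over a window
immediately proximal to the lesion start plane (default 3 mm,
configurable), so idealized constructions round-trip their AS% exactly.
The axial taper shape and the lengths of the uniform sections are
package choices — the downstream coefficients depend only weakly on
them (the throat dominates both integrals). Eccentricity is carried as
a per-sample scalar index in [0, 1] rather than a full cross-section
shape; its only hemodynamic effect is the (1 + γ·e) multiplier on the
expansion loss.

## Sweep protocols

* **Patient mode:** inlet fixed at 88 mmHg; total distal microvascular
  resistance 240 mmHg·s/ml at rest, then 87.5, 75, 62.5, 50, 37.5 and
  25% of it — seven steady solves. The total resistance is distributed
  across outlets by a form–function rule: outlet conductance scales
  with equivalent diameter to the power k = 2.6 (configurable), with
  the parallel combination normalized to the total exactly. For
  single-outlet models the rule is inert.
* **Idealized mode:** single vessel, outlet at 0 mmHg, inlet pressure
  stepped 0.5 : 0.5 : 11 mmHg inclusive — 22 solves.

The lesion's pressure drop is extracted between its start and end
planes: the accumulated viscous integral over the lesion window plus
the expansion loss, which is lumped at the MLA position when reporting
intra-segment pressure profiles (only the start–end difference enters
the fit).

## Curve fitting

The quadratic law is linear in (f, s), so the least-squares problem
through the origin is solved exactly by non-negative linear least
squares (active-set NNLS); non-negativity is enforced because both
coefficients are physical losses. An iterative bounded
nonlinear-least-squares mode exists for parity with iterative
estimation practice and agrees with the direct solution to ~1e-8 or
better. RMSE is reported on the fitted points. The
reduced-simulation-count analysis refits on fixed fraction subsets
(7, 4 = {100, 75, 50, 25}%, 3 = {100, 62.5, 25}%, 2 = {100, 25}%) and
evaluates RMSE against all seven points.

## Cohort analysis

Severity groups partition AS% as severe (> 70), middle ([50, 70]) and
mild (< 50); the method's source grouping leaves (49, 50) and (69, 70]
unassigned, and the closed middle interval is this package's
documented closure. Correlations are sample Pearson r with two-sided
p-values from the exact t transform (n − 2 df); the report carries
signed r and |r| side by side because the resistance indices
anti-correlate with MLA and FFR by physiology.

## Synthetic cohorts and virtual FFR

No patient geometries ship with the package. The synthetic generator
draws idealized lesions with AS% uniform on [30, 95] (a clinically
interesting span from mild to critical), shape eccentric with
probability 0.5, and reference diameter uniform on [2.5, 4] mm —
typical proximal coronary calibers. Each lesion uses the random
substream (seed, index), so cohorts are bitwise reproducible and
per-lesion draws are independent of n. An optional multiplicative
Gaussian noise on the pressure drops (σ = 0.02, truncated at ±3σ,
applied after the solve) emulates the departure of a full 3-D solver
from the exact quadratic law and makes the subset-RMSE analysis
non-degenerate.

The **virtual FFR** is a test fixture, not a clinical quantity: the
distal-to-proximal pressure ratio (p_in − Δp̄_lesion)/p_in at the
sweep's lowest-resistance condition (25% of 240 mmHg·s/ml), standing in
for hyperemia. It decreases monotonically with severity by
construction.

Because the synthetic lesions are single idealized vessels solved by
the same engine that the fit inverts, passing tests demonstrate the
*method's* internal consistency and statistical behavior — exact
recovery without noise, graceful degradation with noise, the expected
correlation signs and strengths — not agreement with 3-D CFD or with
clinical measurements on real anatomy.

## Numerical choices and identifiability

* Profiles are sampled at ≥ 50 points per lesion; trapezoidal
  quadrature on these samples matches closed forms to ~1e-6 relative
  or better.
* Tie-breaks: the MLA is the first minimum within the lesion window;
  degenerate (zero-drop) solves return zero flow; a profile whose MLA
  is not below its reference area is treated as unstenosed (s = 0).
* Under 2% multiplicative drop noise, the *curve* is well identified:
  fitted predicted drops stay within 10% of the noiseless drops across
  the sweep's flow range for essentially all lesions, and `f` stays
  within 10% for > 99% of them. The coefficient `s` alone is weakly
  identified for mild lesions, whose quadratic term is a small share of
  the drop over the patient sweep's narrow flow range (~0.3–1.5 ml/s);
  tests therefore assert recovery of the curve and of `f`, not of `s`
  in isolation.
* Problem sizes in the test suite and the acceptance script — 200 noise
  replicates for the subset-RMSE study, a 40-lesion noiseless cohort
  for the correlation study, 100 random trees for conservation — were
  chosen as the smallest sizes at which the Monte-Carlo statements are
  stable across seeds.

## Known limitations

* Loss coefficients are flow-independent; real stenoses show weak
  Reynolds-number dependence of both terms.
* The eccentricity multiplier is a single scalar factor; real eccentric
  jets interact with curvature and branching.
* Lesions spanning a junction are not supported; lesion bounds must lie
  within one segment.
* No diagnostic cut-offs for f, s, S1 or S2 are provided — none are
  established.
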