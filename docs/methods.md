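# Methods

## The model

Erythropoiesis is represented by five age-structured population classes —
BFU-E, CFU-E, erythroblasts, marrow reticulocytes and circulating
erythrocytes — each governed by a linear transport equation

    ∂y_i/∂t + v_i(E) ∂y_i/∂x = κ_i(x; E) y_i        on Ω_i = (x̲_i, x̄_i),

with boundary influx g_i coupling consecutive classes.  Maturity boundaries
are fixed at 0, 3, 8, 13 and 15.5 days for the marrow classes; circulating
cells restart at age 0 and live to the patient-specific RBC lifespan
(37.7–115.8 days in dialysis patients).  EPO acts at three points:

* `alpha2(E) = mu1 / (1 + exp(mu2 E − mu3))` — CFU-E apoptosis, suppressed by
  EPO (net growth κ₂ = β₂ − α₂);
* `nu(E) = (mu4 − mu5)/(1 + exp(−mu6 E + mu7)) + mu5` — maturation velocity
  of marrow reticulocytes (only class 4 has a non-unit velocity; flux
  continuity divides the influx density by ν and multiplies the outflux);
* `alpha5(x; E) = alpha5_0 + χ_[neo_window](x) · H(tau_E − E) · min(mu8/E^mu9, mu10)`
  — neocytolysis: young circulating cells (default ages 0–14 d) are
  selectively destroyed when EPO falls below the threshold `tau_E = 80`.

The committed stem-cell influx `S0` enters class 1 at rate `S0` (units of
1e8 cells/day; all densities carry that scaling internally).  The observables
are the total RBC count `P(t) = ∫ y5 dx` and the hemoglobin concentration
`Hgb = P · MCH / (c_tbv · 1e10)` with `MCH = 29 pg` and `c_tbv` in ml.

**EPO units.** Concentrations are carried in U/l (numerically mU/ml): the
exogenous pool obeys `dE_ex/dt = u/(c_tbv/1000) − λ E_ex` with `u` in U/day
and `λ = log 2 / T_half` (default half-life 0.3 d).  This is the only unit
reading under which the dose cap `u_max = 1000 U/day` (steady-state gain
≈ 87 U/l) can move a patient across the neocytolysis threshold of 80, given
endogenous levels of 20–300.  The concentration under a piecewise-constant
schedule has an exponential closed form, used everywhere (never numerical
ODE integration); its gradient in the rates is exact, rate-independent, and
evaluated with non-positive exponents only.

**Regularization.** The neocytolysis switch is non-smooth in E.  Both the
Heaviside step and the capped min are replaced by a C² sixth-degree
polynomial smoothing `H_eps` with band ε (default 1.0 U/l).  The arguments
of the capped min live on the mortality-rate scale (≈ mu10 = 0.05/day), so
its band is `min(ε, mu10/2)`: reusing the concentration-scale ε there would
put every reachable value inside the band and collapse the regularized rate
onto the constant cap.  Outside these bands the smoothed rate equals the
non-smooth one exactly, and it converges pointwise as ε → 0 off a
measure-ε set.

## Synthetic patients

Clinical per-patient parameter estimation is out of scope; the `patients`
module generates synthetic records instead.  What the generator emulates:
endogenous EPO profiles relative to the neocytolysis threshold (high
200–300, near-threshold 60–80, low 20–60 U/l), the measured dialysis RBC
lifespan range, and moderate (±20–30 %) inter-patient variation of the rate
parameters around the default record (sigmoid midpoints near E = 150 U/l so
both EPO channels retain slope over the reachable range).  Every record
passes two calibration criteria, each a steady-state solve of the whole
lineage: (a) uncontrolled Hgb in 7–9.5 g/dl — enforced exactly by rescaling
S0, which is legitimate because the dynamics are linear in the densities;
(b) sustained maximum-rate dosing must raise steady Hgb above 12 g/dl
(controllability) — a pure check whose failure is an explicit error.

What the generator does **not** emulate: parameter drift over time,
measurement noise, iron limitation, model-patient mismatch.  Passing tests
therefore demonstrate the controller under a perfectly known plant — the
in-silico setting — and say nothing about robustness to misestimated
parameters.

## Discretization

Each class is normalized to ξ ∈ [0,1] and expanded in shifted Legendre
polynomials `e_j(ξ) = L_j(−1+2ξ)/√w`, j = 0..N−1 (default N = 15), which are
orthogonal under the w-weighted inner product with ‖e_j‖² = 1/(2j+1).  The
approximating operator

    A_N(E) φ = −(v/w) φ′ + P_N(κ(h(·); E) φ) − δ_N φ(0)

uses the exact Legendre derivative expansion, the discrete delta representer
`δ_N = Σ e_j(0)/‖e_j‖² e_j` (Riesz representer of evaluation at the inflow
boundary), and Galerkin projection of the reaction term.  All
E-dependence is scalar: `A_i(E) = A0_i + c_i(E)·A1_i`, where c is α₂, ν or
the neocytolysis intensity and A1 is −I, the advection matrix, or the fixed
indicator-projection matrix of the neocytolysis window (assembled once by
Gauss quadrature split at the window edge).  Matrices are cached per
patient; assembly per time step is a scalar-times-matrix update.

Time stepping is implicit Euler with the classes solved consecutively 1→5:
each class solves `(I − dt·A_i(E(t+dt))) y^{new} = y^{old} + dt·g_i(t+dt)·d_i`
with the influx taken from the already-updated upstream class at the new
time and E evaluated by the closed form at the step end (fully implicit
coefficients).  The equilibrium used as initial condition solves the
time-invariant balance exactly, so it is also an exact fixed point of the
discrete flow.  The inner loops (forward scan and adjoint sweep) are
numba-compiled; identical inputs give bit-identical trajectories.

Numerical notes: the spectral steady state of class 1 reproduces the
analytic `S0·e^{β₁x}` to ~1e-16 at N = 15 with spectral decay in N;
projection quadrature uses Gauss–Legendre of order ≥ 2N per smooth panel,
subdivided at indicator edges; the total population equals `√w₅·y₅,₀`
(only the constant mode carries mass) and matches quadrature of the
reconstructed density to 1e-10.  Convergence in dt is first order; measured
Richardson ratios are cleanest on the CFU-E class, because a dose step sends
a transported profile kink through the velocity-modulated classes 4–5 that
keeps them pre-asymptotic at desk-scale steps.

## Dose optimization

On a prediction horizon of M rate intervals the cost is

    J(u) = ½ Σ γ_j u_j² + (σ_Ω/2) ∫ z(t)² dt + (σ_f/2) z(t_f)²,

with the population deviation expressed on the hemoglobin scale,
`z = r (P − P^d)`, `r = 2·MCH/(c_tbv·1e10)` (so z is twice the Hgb
deviation in g/dl), `P^d` from the target Hgb 10.5 g/dl, and dimensionless
weights `σ_Ω = 1e4/(MΔt)`, `σ_f = 1e3`, `γ_j = c_γ·Δt/(MΔt)`.  Expressing
the tracking term in raw cell counts would make it dominate the control term
by tens of orders of magnitude and render c_γ inert; on the z scale,
c_γ ≈ 0.1 sits exactly at the dose/tracking trade-off (tight tracking),
while c_γ = 100 visibly sacrifices the target — the intended behavior of the
individualized penalty.  Only c_γ is chosen per patient.

The gradient follows discretize-then-optimize: the adjoint of the implicit
Euler/Galerkin scheme itself is swept backward (classes 5→1, multipliers
coupled through the influx constraints, the tracking source entering the
erythrocyte equation's leading coefficient), and per-interval components are
assembled through the exact concentration sensitivities.  The gradient is
therefore exact for the discrete cost; central finite differences agree to
the FD truncation floor (≲1e-6 relative at h = 0.02 U/day).

The box-constrained problem (0 ≤ u ≤ u_max, default 1000 U/day) is solved by
projected BFGS with Armijo backtracking (sufficient decrease 1e-4, factor
0.5, ≤ 40 backtracks), controls rescaled by u_max, inverse-Hessian reset to
a scaled identity (s'y/y'y) whenever the active set changes, stopping at
projected-gradient ∞-norm ≤ 1e-6·(1+|J|) or an iteration cap.  The problem
is markedly ill-conditioned (the cumulative-dose direction carries most of
the curvature): full convergence takes ~200 iterations, matching an
L-BFGS-B reference to 7 digits in J.  Inside the closed loop an additional
stagnation stop (relative cost decrease < 1e-6 on two consecutive steps)
cuts this to a few dozen iterations with no measurable effect on tracking
(< 0.01 g/dl in the final-month mean).

## Closed loop

The receding-horizon loop updates the rate every Δt (default daily; 1–28 d
supported), with the prediction horizon tied to the period: 28 d for
Δt ≤ 7, 42 d for Δt ≤ 21, 56 d for Δt = 28 — long enough to span the
~2-week marrow transit delay.  Only the first interval of each open-loop
optimum is applied; the plant (same discretization as the prediction model)
advances one period; the controller re-measures the full state perfectly —
including post-bleed states, which overwrite its initial condition — and
the next solve is warm-started by shifting the previous optimum.  The
horizon may extend past the final time T.  Scenario events (bleeds as
uniform multiplicative shocks to the circulating class only; missed doses
as zero-rate actuations; dosing errors as rate overrides) act on the plant
without the controller's foreknowledge.  γ_j scales with the days per
constant period so c_γ penalizes control effort equally across update
frequencies.

For sweep summaries, "oscillation amplitude" is half the peak-to-peak Hgb
range over the final eight weeks — the stationary oscillation around its own
level.  (The maximum deviation from the setpoint is a different quantity: it
mixes oscillation with the small steady bias each update period carries, and
is not monotone across the horizon-rule switch between weekly and biweekly
updates.)

Defaults for the study runs: T = 168 d, Δt = 1 d, M = 28, c_γ = 0.1,
u_max = 1000 U/day, N = 15, integration step dt = 0.2 d (transient fidelity
≤ 0.06 g/dl against a dt = 0.005 reference; steady states exact).  These are
the package's desk-scale problem sizes; `simulate` retains dt = 0.01 d for
open-loop studies.

## Known limitations

* Perfect-measurement, no-mismatch setting: robustness to parameter error or
  noisy Hgb is untested by design (robust MPC is out of scope).
* First-order time integration; transported kinks after abrupt dose changes
  degrade the observed order in the downstream classes at coarse dt.
* The open-loop problem is non-convex (several local minima may exist); the
  solver returns a stationary point, warm starts bias successive solves
  toward the same basin.
* Bleeds shock circulating cells only; marrow involvement of real
  hemorrhage is not modelled.
* Synthetic patients are calibrated to the anemic band by construction; the
  generator does not reproduce any real patient's parameter vector.
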