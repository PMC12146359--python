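# Methods

## Model

The population is split into aggressors `A`, susceptibles `S` and
gender-specific victim compartments `V_M`, `V_F` (millions of people;
time in calendar years).  Aggressors follow logistic growth with rate
`r_A` (1/year) and carrying capacity `k_A` (millions) and are uncoupled
from the rest of the system; susceptibles follow logistic growth
(`r_S`, `k_S`) minus a mass-action drain `(β_M + β_F) A S`, where `β`
(1/(million·year)) is the rate at which aggressor–susceptible contact
produces victims of each gender.  Victims leave by death (natural or
violent) at per-capita rates `α_M`, `α_F` (1/year).  Assumptions worth
stating plainly: homogeneous mixing, both sexes pooled within `A` and
`S`, no explicit births/deaths outside the victim compartments, no
flow from victims back to aggressors, and bilinear interactions
throughout.  These choices trade realism for identifiability from a
14-point annual series.

Two intervention variants extend the base system from a configurable
*recovery year* onward (hard switch, exact state handover, no ramp):
female victims return to the susceptible pool at rate `γ_F`, and
aggressors are rehabilitated into susceptibles at rate `δ_A`.  Both
terms transfer mass only: the relevant column sums of the right-hand
side are unchanged, which the test suite asserts as an algebraic
identity.

One parameter object carries all ten rates with `γ_F = δ_A = 0`
defaults, so the base model is the shared special case.

## Data and scenarios

The bundled dataset is the annual count of people treated in medical
units in Mexico for injuries by intentionality (family / non-family /
self-inflicted), by sex, 2010–2023.  Counts are persons; the models
work in millions (counts / 1e6).  Aggressors and susceptibles are not
observed; fitting targets for them are percentage scenarios of the
total national population (default 20%/40%; the 40/20 and 5/30
variants are constructible by config), linearly interpolated between
census anchors and linearly extrapolated beyond them (limited to −5/+15
years).  Census anchors are a *config input*, not package constants:
the interpolation the original analysis used is not published, and
linear through the 2010/2015/2020 census figures is the assumption made
here.

## Estimation

Stage 1 fits `(r_A, k_A, A0)` to the aggressor target series by
bounded least squares on the logistic closed form.  Stage 2 freezes
those three values and estimates `(r_S, k_S, β_M, β_F, α_M, α_F)` plus
the initial conditions `(S0, V_M0, V_F0)` by trust-region least squares
(`scipy.optimize.least_squares`, finite-difference Jacobian) on the
integrated trajectory over the fit years (2010–2022), holding 2023 out
for validation.

Choices that the source analysis left open, decided here:

* **Residual composition.** Stacked blocks S, V_M, V_F, each divided
  by its data mean (configurable: `none|mean|std`).  Without
  normalization the ~50-million susceptible block drowns the
  ~0.1-million victim blocks.
* **A0 is frozen in stage 2.**  The aggressor series is not part of the
  stage-2 objective, so re-optimizing A0 there is unconstrained — β can
  absorb any rescaling of A — and on real data A0 drifts to its bound.
  S0/V_M0/V_F0 are optimized within [0.25×, 4×] of the first
  observation.
* **Bounds.**  Death rates capped at 1/year (unbounded fits admit
  degenerate extreme-mortality solutions), β in [1e-10, 0.1],
  `r_S ∈ [1e-6, 2]`, `k_S` within [0.5×, 50×] the largest observed S.
* **Multistart.**  Default 8 starts: a data-driven heuristic (k_S at
  1.2× the series maximum, r_S at the stage-1 growth rate, β from the
  quasi-equilibrium balance `β ≈ α·mean(V)/mean(A·S)`) plus Latin
  hypercube draws in log space, seeded.  Integration failures during a
  trial are penalized, not fatal.  Fits are bit-for-bit reproducible
  given (config, seed).

Identifiability caveat: the susceptible/aggressor series sit far from
saturation over a 13-year window, so `k_S` (and in stage 1, `k_A`) are
weakly identified from noisy data — the Monte-Carlo tests document
median `k` errors of tens of percent under 5% observation noise in
slow-growth worlds, against ~2% when the series actually approaches
its plateau.  The victim-side rates `β` and `α`, the quantities the
substantive conclusions rest on, are robust (median |bias| < 10% at 5%
noise).

## Equilibria and stability

With `δ_A = 0` the fixed point is closed-form: `A* = k_A`,
`S* = k_S (1 − (β_M+β_F) k_A / r_S)` (clamped at 0),
`V_M* = β_M k_A S*/α_M`, `V_F* = β_F k_A S*/(α_F+γ_F)`.  With
rehabilitation, `A* = k_A (1 − δ_A/r_A)` and `S*` solves a scalar
balance equation: the nontrivial root is closed-form when `δ_A = 0`
and otherwise found by a 1000-point sign scan plus bisection
(xtol 1e-12) on [0, 2k_S], with the bracket doubled (and flagged in
the report) in the rare strong-rehabilitation regime where `S*`
exceeds 2k_S.  Every reported equilibrium is residual-checked
(rhs max-norm < 1e-10) and classified by the eigenvalues of the
analytic 4×4 Jacobian.

The victim ratio identity `V_F*/V_M* = β_F α_M / (β_M (α_F + γ_F))`
(independent of the k's and S*) yields the asymptotic parity threshold
`γ_F* = α_M β_F / β_M − α_F`.  A finite-horizon counterpart — the
smallest `γ_F` reaching `V_F ≤ V_M` within a configurable number of
years after the switch — is computed by bisection on `γ_F/α_F`; when
even the bracket top cannot close the gap the result says so rather
than raising.  "Parity" itself is not defined in the source analysis;
both definitions are reported.

## Numerics

* Integrator: `solve_ivp` with DOP853, rtol 1e-10 / atol 1e-12 by
  default (exposed per call).  At these tolerances the aggressor
  component agrees with the logistic closed form to ~1e-15 relative
  over 24 years, comfortably inside the 1e-8 oracle bound the tests
  assert.
* Nonnegativity: components in [−1e-10, 0) are clamped to zero;
  anything lower raises an integration error (never silent NaN).  The
  rhs kernel clamps its inputs before forming the mass-action product
  so solver undershoot cannot flip flux signs.
* The projection sampler uses a 0.1-year grid; the recovery switch is a
  grid point shared by both regimes, so trajectories are exactly
  continuous there.

## Synthetic generator

The generator integrates the chosen variant from true parameters,
samples annual victim counts (none / multiplicative lognormal /
Poisson), optionally applies a reporting-fraction window emulating the
2020–2022 underreporting pattern, rounds to integer persons, and emits
a table in the national-data layout.  Defaults are the published
family-violence parameter set, the 20/40 scenario percentages of the
2010 census population, 2010–2023 annual observations, and lognormal
sigma 0.05 when noise is requested.

Because the scenario construction defines `A_obs` and `S_obs` as
percentages of one population trajectory, a percentage-built synthetic
world cannot be exactly model-generated (the model's S/A ratio is not
constant), and victims-only fitting has an exact scaling degeneracy
(`k_S → c k_S, S0 → c S0, β → β/c` leaves `β A S` invariant).  The
generator therefore emits a population trajectory derived from the
aggressor solution (`pop = A/pct_aggressor`, annual anchors) and the
recovery harness targets the model's own susceptible series, making
the noiseless pipeline an exact fixed point — which is what the
recovery tests assert (all eight parameters to <1%, trajectory to
0.1%).  What a green harness does **not** establish: robustness to the
real data's structural misspecification (percentage-scenario targets,
underreporting, the 2020 dip); those are probed separately by the
underreporting-window test and the real-data holdout checks, not by
parameter recovery.

The harness runs its noisy replicates with a single heuristic-start
fit (multistart=1) to stay inside test-time budgets; the noiseless
identifiability checks keep multiple starts.

## Known limitations

* The published parameter tables print β to 1–2 significant figures, so
  closed-form saturation levels land within ~2% of the published
  family-violence values and ~10% for the non-family female value; the
  package does not attempt to reproduce published digits beyond that.
* The aggressor dynamics are exogenous (no feedback from victims or
  susceptibles), and self-inflicted violence violates the
  aggressor/susceptible split by construction — the model fits it worse
  than family violence, which the suite asserts as a negative control.
* No uncertainty quantification on fitted parameters (point estimates
  only), no age/state/institution structure, no stochastic dynamics.
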