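# Methods

## Scope and model structure

`thcpd` simulates the subjective effects of THC as a chain of three
models: a linear, perfusion-limited PBPK model producing total brain and
venous plasma concentrations of THC and 11-OH-THC; a direct
effect-compartment sigmoid-Emax model mapping brain exposure to the VAS
"feeling high" score; and an indirect-response (turnover) model mapping
brain exposure to the VAS "alertness" score. Both PD models are driven
by the **sum** of the two compounds' concentrations under an
equipotency assumption, and both use *total* (not unbound) brain tissue
concentration as the driving exposure.

### PK engine

Compartments: venous blood, arterial blood, lung, brain, liver and a
lumped rest-of-body tissue; the set is configuration-extensible, and the
tissue flows must sum to the cardiac output. Each tissue is perfusion
limited with emergent venous blood in equilibrium with the tissue via
the tissue:plasma partition coefficient Kp and the blood:plasma ratio.
Elimination is first order on the liver outflow plasma concentration; a
fixed molar fraction of cleared THC forms 11-OH-THC in the liver, which
is cleared by the same mechanism. Routes: IV bolus (instantaneous state
jump into venous blood), IV infusion (constant rate over a window), oral
(first-order depot into the portal/liver inflow, so first-pass
extraction emerges structurally), inhaled (first-order depot into the
lung compartment). Everything is linear in dose; nonlinear kinetics,
enterohepatic recirculation, food effects and permeability-limited brain
uptake are out of scope.

A degenerate **one-compartment mode** routes every dose into a single
well-stirred compartment. It exists for analytic verification (the IV
bolus solution is `C = D/V·e^(−CL/V·t)`) and for the
route-convergence property (oral/inhaled → IV as k_a → ∞), which cannot
hold in the full topology: with hepatic clearance active, steady-flow
AUC algebra makes the venous AUC depend on the entry site (an oral dose
passes the liver before reaching venous blood; an inhaled dose passes
the lung first), and that asymmetry is physiology, not error. The
convergence property is therefore stated — and tested — where all routes
share one entry compartment.

### Default PK fixture (non-authoritative)

The quantitative physiological dataset behind the published THC PBPK
model is not part of this package; the engine is fully
configuration-driven and ships with one documented desk-scale fixture:

| quantity | value | rationale |
|---|---|---|
| cardiac output | 390 L/h | 6.5 L/min adult |
| blood volumes (ven/art) | 3.5 / 1.5 L | round adult values |
| brain V, Q, Kp | 1.45 L, 45 L/h, 3.5 | Kp chosen so the post-distribution brain:plasma ratio sits in the reported 2–5× band (simulated ≈3.6×) |
| liver V, Q, Kp | 1.8 L, 90 L/h, 10 | lipophilic drug |
| rest V, Q, Kp | 62 L, 255 L/h, 3 | closes the flow balance; Vss of a few hundred litres |
| CL_THC (liver plasma) | 300 L/h | high extraction; simulated oral availability ≈0.13 with f_a 0.45 |
| fraction → 11-OH-THC | 0.25 | active metabolite appears at a sizeable fraction of parent after oral dosing |
| CL_11-OH-THC | 200 L/h | slightly more polar metabolite |

These constants are tuned **only** against coarse, stated properties
(brain:plasma 2–5×, low oral availability, inhaled absorption in
minutes) and are clearly labeled non-authoritative; any serious
application should supply its own `PKModelSpec`.

### PD models and parameters

| parameter | feeling high | alertness | unit |
|---|---|---|---|
| transfer / loss rate | k_e0 = 2 (both compounds) | k_out = 1 | 1/h |
| E_max | 80 mm | 90 % (inhibition of k_in) | |
| EC50 | 0.21 | 0.23 | µM |
| Hill | 1.8 | 1.9 | |
| baseline | 0 mm | 60 mm (k_in = baseline·k_out) | |
| CV (Emax / EC50) | 34% / 70% | 30% / 30% | |

The feeling-high Hill function is evaluated on the summed effect-site
concentration (sum first, then exponentiate), never per compound. The
alertness model is initialized at its steady state; a zero-dose
simulation holds the baseline exactly. The alertness maximal-inhibition
parameter is stored as a percent and converted to a fraction in exactly
one place (`AlertnessParams.e_max_fraction`). Trial configurations may
override the alertness baseline (some source trials use the placebo-arm
mean instead of the pre-dose score).

VAS scores are clipped to [0, 100] mm only at reporting boundaries
(CSV output, population summaries); the models themselves are naturally
bounded at population parameters. Individual log-normal Emax draws can
exceed the instrument range (or, for alertness, 100% inhibition); those
raw trajectories are clipped in the reported population outputs, which
is also why `AlertnessParams` constrains the maximal inhibition only to
be positive rather than ≤100%.

## Numerical methods

- PK: `scipy.integrate.solve_ivp` (LSODA), rtol 1e-8 / atol 1e-10 by
  default, integrated piecewise between dose events so boluses are exact
  state jumps and infusion windows are resolved. Negative states beyond
  the solver tolerance raise; they are never silently clipped. A
  mass-balance audit (administered = depots + in-system + eliminated for
  the parent; formed = in-system + eliminated for the metabolite) runs on
  every simulation and raises above 0.1% relative defect; in practice
  the defect is at machine precision.
- PD: both PD ODEs are linear given their forcing, so they are advanced
  with an exact exponential update under piecewise-linear forcing
  (`thcpd._ode.integrate_linear_decay`). Constant forcing — including
  the zero-dose steady state — is integrated with zero discretisation
  error; smooth forcing converges at second order in the refinement step
  (default 0.01 h, PCHIP interpolation of the concentration grid).
  Callable forcing (analytic oracles) uses solve_ivp at rtol 1e-11.
  The same update is vectorised across virtual subjects, which is what
  makes 500-subject studies run in well under a second.
- Population sampling: median-anchored log-normal,
  `X = m·exp(σZ)` with `σ² = ln(1+CV²)`. This respects the printed CVs,
  guarantees positivity (the source model's EC50 CV was itself reduced
  from 126% to 70% to avoid negative draws under its own sampler), and
  is the standard pharmacometric choice. Seeding: one integer seed feeds
  a `SeedSequence`; per-subject generators are spawned in subject order,
  so results are reproducible and subject i's draws do not depend on the
  population size beyond i.
- Dose–response sweeps reuse the same seed — hence the same virtual
  subjects — at every dose (a paired, crossover-style design). Combined
  with the pointwise monotonicity of the Hill transform this makes the
  mean peak/trough exactly monotone in dose at finite n, which is the
  property the dose–response contract states. Peaks and troughs are read
  off the sampling grid (default 0.05 h), not the continuous solution;
  trough ties break to the earliest time.
- Estimation: bounded nonlinear least squares (`scipy.optimize.
  least_squares`, trf) on the observed mean VAS trajectory, positive
  parameters searched in log10 space, Hill bounded to [0.5, 5], with a
  seeded Latin-hypercube multi-start (default 10) in place of manual
  optimization. Non-convergence of all starts flags the result instead
  of raising. `profile_loss` re-optimizes the remaining free parameters
  on a fixed grid of one parameter; on low-exposure data it exhibits the
  classic Emax–EC50 ridge (only E_max/EC50^h identified).
- Verification: fold checks use inclusive bounds (a ratio exactly at the
  threshold passes, matching how fold ranges are conventionally
  reported); feeling-high trials compare peaks, alertness trials compare
  troughs (the extreme excursion); percentile coverage linearly
  interpolates the band to the observed times and refuses to
  extrapolate. Percentile bands pool all subjects across trials by
  default (`summarize` can be applied to any subject subset to switch
  aggregations).

## Synthetic observed studies

`thcpd.synthetic` stands in for digitized literature VAS curves. It
forward-simulates the population mean under known true parameters (IIV
across the configured number of subjects, default 25), adds additive
Gaussian observation noise (default sd 3 mm — no noise model is stated
for the source data; this is the simplest defensible stand-in, and it is
configurable), and clips to the 0–100 mm scale, emitting the generating
truth alongside for recovery tests. The default sampling grid mimics
clinical density: every 10 min to 2 h, then hourly to 8 h. A two-peak
oral fixture adds a delayed absorption depot at a configurable meal
time; it exists to stress the verification statistics under structural
mismatch, not to be fit.

What passing tests on these data do and do not show: they demonstrate
internal consistency (the pipeline recovers its own generating
parameters, its bands cover its own noiseless mean) under the stated
noise and variability structure. They do not validate the PK fixture
against clinical concentrations, nor reproduce the published comparisons
against digitized trial data, and real VAS data carry placebo responses,
meal effects, serial correlation and reporting quirks that the additive
Gaussian model does not emulate.

## Problem sizes

Defaults used by the tests and examples: 20×25 = 500 subjects per
virtual study on a 0.05 h grid over 12 h; dose–response sweeps over
seven doses per route with 100 paired subjects; parameter-recovery
studies with 13–19 time points and 100 noise replicates at 4 optimizer
starts each; 10⁵ draws for the sampling-moment checks. These sizes keep
any single stage under about a minute on one CPU while leaving the
Monte-Carlo tolerances comfortably resolved.

## Known limitations

- The PK fixture is illustrative; no claim of concentration-level
  accuracy is made or tested beyond the coarse properties listed above.
- No placebo-effect model, no covariate (age/sex/weight) effects on PK
  or PD — demographics in `TrialDesign` are metadata only.
- Mean-curve (naive-pooled) estimation only; no mixed-effects or
  Bayesian machinery.
- The alertness model was built for inhaled-style exposure profiles;
  applying it across routes assumes route-independent PD, which is an
  assumption, not a result.
- Single-peak absorption per dose event; meal effects exist only as the
  synthetic stress fixture.
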