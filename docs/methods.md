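# Methods

## The model

Mycophenolic acid (MPA) undergoes pronounced enterohepatic recycling (EHR)
in rats: hepatic glucuronidation, biliary excretion of the glucuronide,
deconjugation by gut bacteria and re-absorption of the parent drug. In
plasma this shows up as secondary concentration peaks that defeat ordinary
mammillary models. The package implements route-specific compartmental
models that lump the metabolite steps into two amount compartments, bile
(`A_bile`) and gut (`A_gut`):

* **IV bolus** — central + peripheral disposition, plus bile and gut.
  The bolus initializes the central amount at the released dose.
* **Oral gavage** — the same disposition, fed by a depot with two parallel
  first-order outflows: `ka1` directly into the central compartment (a fast
  fraction) and `ka2` into a chain of `n_transit` identical transit
  compartments with common rate `k_tr` (a gamma-delayed slow fraction).
  The implied fast-release fraction is `ka1/(ka1+ka2)`; no separate
  dose-split parameter is introduced because none is identifiable from a
  plasma profile alone.
* **Supralingual patch** — no peripheral compartment (the tongue
  concentration profile is too flat to support one); the worn patch is a
  zero-order release of `released_fraction x dose` into the depot at a
  constant rate over `[t_lag, patch_duration]` (default 0.5 h to 4 h, the
  lag reflecting the delay before drug first reaches plasma and the end
  point the patch removal), then the same dual depot/transit absorption.

All rate processes are first order except the patch release and bile
emptying. Bile-to-gut transfer is parameterized by the emptying interval
`Tau` through the coefficient `GBr = 1/Tau`. The default (*continuous*)
emptying mode transfers at rate `A_bile/Tau`, the only form fully
determined by the reported parameters; it reproduces multiple plasma
peaks without needing an unstated trigger time. A *windowed* mode — one
constant-rate emptying episode of duration `Tau` starting at a
configurable time, clamped at zero bile — is available for sensitivity
analysis of that structural assumption.

Units: amounts ng/kg, volumes mL/kg, clearances mL/(kg·h), rates 1/h, so
concentrations are ng/mL and a 0.5 mg/kg dose is 5.0e5 ng/kg. All
clearances and volumes are apparent (CL/F, V/F).

## Simulation

With continuous bile emptying every model is a linear time-invariant
system with (at most) a piecewise-constant input, so the default simulator
propagates the state with matrix exponentials segment by segment — exact
to machine precision, unconditionally stable, and nonnegative by
construction (the rate matrix is Metzler). An LSODA path (rtol 1e-8,
atol 1e-10 ng/kg, integration segmented at the release-window
discontinuities) backs the windowed mode and serves as an independent
numerical cross-check; the test suite asserts the two paths agree.

## Error model and estimation

Observations follow a proportional error model
`C_obs = C_pred (1 + eps)`, `eps ~ N(0, sigma^2)`. Records below the
0.5 ng/mL limit of quantification are flagged BLQ and excluded from the
likelihood (a censored-likelihood treatment is out of scope). Fits are
per subject (naive-pooled fitting over several subjects is available as
an option); `sigma` is profiled analytically at its closed-form ML value
each evaluation, subject to a floor of 1e-6 proportional CV. The floor
matters only for noise-free (simulated) data, where the unfloored joint
ML is unbounded below as the fit becomes exact; with the floor, nested
models that both fit exactly tie on −2LL and AIC comparisons degrade
gracefully to the parsimony rule.

Structural parameters are optimized on the log scale (positivity and
conditioning) with L-BFGS-B from a multi-start design — the initial
guess plus seeded log-uniform perturbations up to a configurable factor
(default 10 starts, x/÷3) — and the best start is polished with a
Nelder-Mead pass. Fits are deterministic given the seed and the data.
Fixed design quantities (`n_transit` = 5, `t_lag` = 0.5 h, patch window,
released fraction 0.794, dose) are not estimated and not counted in
AIC = −2LL + 2p; p counts the estimated structural parameters plus sigma
(IV 8, oral 11, supralingual 9). Model selection treats an AIC reduction
of at least 2 as significant; near ties go to the more parsimonious
structure. Absolute −2LL/AIC values are implementation-specific (additive
constants differ across software), so only AIC differences and orderings
are meaningful.

## Synthetic cohorts

The generator reproduces the study design: IV n=5, oral n=3, patch n=3,
all at 0.5 mg/kg, with the route-specific sampling schedules (IV and oral
from 2–5 min to 48 h; patch from 1 h to 48 h with a 4.5 h draw just after
patch removal). Between-animal variability draws each parameter from a
lognormal matched by method of moments to the reported mean ± SD (all
parameters have positive support; a zero-truncated normal is available),
body weight from a truncated normal (379.8 ± 44.3 g). Residual noise is
multiplicative Gaussian with default sigma 0.15 — the study does not
report its estimated residual magnitude, and 0.15 is a typical
bioanalytical proportional CV within the ±15% assay acceptance band —
and post-noise values below the LLOQ (including negative ones) are
flagged BLQ but retained in files. A BLQ pre-dose record at t=0 is
always emitted and never fitted.

What the generator does **not** emulate: real assay heteroscedasticity
beyond a single proportional term, correlated within-animal residuals,
irregular actual (vs nominal) sampling times, and any inconsistency
between the reported parameter means and the reported AUCs (the means
are taken as given). Passing recovery tests on these cohorts therefore
demonstrates correctness of the estimation machinery under the stated
error model, not fidelity to the original animals; the printed AUCs,
half-lives and absolute AIC values of the study are inputs and context,
never reproduction targets.

## Non-compartmental analysis

AUC(0–48) uses the linear trapezoidal rule ("manual" NCA); BLQ records
are zeroed before the first quantifiable point and dropped afterwards;
if the end time falls between observations the profile is interpolated
linearly. Terminal half-life is ln2/|slope| of a log-linear OLS fit on
the last three quantifiable points, flagged unreliable when the tail is
not declining or R² < 0.8 — under strong recycling (and the patch's
flip-flop kinetics) this NCA half-life understates the true terminal
phase, which is why it is reported with a flag rather than asserted
against any expected value. Absolute bioavailability is
`100 x (AUC_test x Dose_iv) / (AUC_iv x Dose_test)` on mean AUCs. Dose
accounting converts the nominal mg/kg dose to micrograms via body weight
and reports patch residue and tongue retention as percentages of dose.

## Numerical choices and edge cases

* Solver: matrix-exponential propagation by default (exact); LSODA
  rtol 1e-8 / atol 1e-10 otherwise, with integration segmented at input
  discontinuities. Tiny negative amounts from rounding (< 1e-9 of dose)
  are clipped; material negativity raises.
* Optimizer: L-BFGS-B ftol 1e-8 on the −2LL, bounds 1e-4..1e4 on each
  parameter's natural scale; multimodality from the recycling peaks is
  handled by the multi-start design, not by a global optimizer.
* Degenerate inputs: zero rate constants are legal (they switch paths
  off and are used by the structural limit tests); volumes and `Tau`
  must be strictly positive; a fit demands at least as many quantifiable
  points as parameters.
* Identifiability: with very fast gut re-absorption the likelihood is
  flat in `k_gc`; recovery tests detect flatness (change in −2LL under a
  ±10% perturbation below 0.01, evaluated at a fixed reference residual
  scale of 0.1 so the criterion is meaningful on noise-free data) and
  exclude flat parameters from point-recovery assertions.
* Tie-break in model selection: among candidates within 2 AIC of the
  best, lowest parameter count wins, then lower AIC.

## Problem sizes

The shipped tests run the full study design at its natural sizes (5/3/3
subjects, 15–16 quantifiable samples each). Calibration checks use
simulated cohorts of 50–100 replicate subjects; the estimator-bias table
uses 50 replicates at sigma 0.10 with a single optimizer start per
subject, and the residual-coverage check pools 60 replicate subjects in
one naive-pooled fit. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances.

## Known limitations

* Per-animal parameters of the original study are unpublished; cohort
  defaults are the reported means ± SDs, so mean-of-ratio quantities
  (e.g. the reported EHR% for IV/oral) can differ from ratio-of-mean
  arithmetic by up to ~1 percentage point.
* The bile "zero-order" emptying construct of the original software is
  underdetermined by the published parameters; the continuous form is a
  modelling choice (see above), with the windowed mode for sensitivity.
* No mixed-effects estimation, no metabolite (MPAG) kinetics, no
  censored-BLQ likelihood, no covariate modelling, no standard errors on
  per-subject estimates.
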