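# Methods

`bleedrisk` implements the model-informed workflow used to design a
dose-modification rule for bleeding adverse events of a TGF-β/PD-L1
bifunctional fusion protein: a population pharmacokinetic (PK) model supplies
per-patient exposure metrics, logistic exposure-safety models quantify how
bleeding probability grows with exposure, and the two together are translated
into regimen-level probability and trough-target-attainment tables that
justify a 50% dose reduction on restart after severe bleeding. Because no
patient-level data are public, a synthetic-cohort generator reproduces the
study conditions so every stage runs and can be validated end to end.

## Structural PK model

Drug amounts follow a mammillary two-compartment model with zero-order
infusion input and linear elimination whose clearance varies smoothly with
time on treatment:

    dA1/dt = in(t) − CL(t)·C1 − Q·C1 + Q·C2
    dA2/dt = Q·C1 − Q·C2
    CL(t)  = CL0 · exp( Emax · t^γ / (T50^γ + t^γ) )

with `C1 = A1/V1`, `C2 = A2/V2` (mg, L, h; `A1/V1` is in µg/mL). The sigmoid
time-on-treatment clearance is the form commonly reported for
checkpoint-inhibitor-class biologics; `Emax < 0` encodes the usual slow
decline in clearance. Defaults: `Emax = −0.15`, `T50 = 1000 h`, `γ = 1`
(mild, ~14% eventual CL decrease), all configurable.

Two numerical paths coexist. `solve_concentration` integrates the ODEs with
LSODA per dosing segment (relative tolerance 1e-10; AUC carried as an extra
state, which makes the C_avg quadrature adaptive at the same tolerance). The
population path advances all patients of a cohort simultaneously with exact
closed-form two-compartment step updates, holding CL(t) at its mid-step value
(steps ≤ 12 h; exact for constant CL). The two paths agree to ≤ 1e-6
relative in the test suite, and the ODE path is checked against an
independently coded bi-exponential infusion solution.

## Exposure metrics and conventions

* `Cavg,SD` = AUC(0, τ)/τ after the first dose, with τ = 336 h (Q2W) or
  504 h (Q3W). Single-dose exposure is used deliberately: it avoids the
  confounding of longitudinal exposure changes with clinical course.
* Troughs are evaluated at end of interval (τ⁻), after dose 1
  (`ctrough_sd`) or at steady state (`ctrough_ss`), declared when successive
  troughs change by < 0.5%; failure to converge within 20 doses raises an
  explicit error rather than silently reporting the capped value.
* Time zero is the start of the first infusion; infusions last 1 h by
  default (a typical value for this administration route; configurable).

## Calibration of the shipped defaults

The published analysis reports geometric-mean `Cavg,SD` values of
178/89/136/273 µg/mL for 1200/600 mg Q2W and 1200/2400 mg Q3W; the PK
parameters behind them are not public. The shipped typical values are
anchored to two of these cells: `cl_base` and `v1` are adjusted by least
squares so the typical patient gives exactly 178 (1200 Q2W) and 136
(1200 Q3W) µg/mL, with `v2 = 1.0 L`, `q = 0.03 L/h` fixed. The anchor pair
itself pins the effective terminal half-life near 6.3 days, which is why the
central volume — not the intercompartmental clearance — is the useful second
degree of freedom: solutions that free `q` or `v2` instead collapse them
toward zero. Linearity of the system then reproduces the remaining two cells
(89 and 272 vs the printed 273, which is 2×136.5 before rounding) with no
further freedom.

Between-subject variability is lognormal on `cl_base` and `v1`
(uncorrelated). ω_V1 = 0.25 is a conventional value; ω_CL was tuned once,
by least squares against the two published trough-attainment anchors for a
single 1200 mg Q3W dose — ≈30.4% of patients ≥ 50 µg/mL at 504 h and ≈87.2%
at 336 h — giving ω_CL = 0.23 (24.4% and 82.5% at n = 40 000), and then
frozen. No ω reproduces both anchors exactly: moving from 30% exceedance at
504 h to 87% at 336 h in one lognormal population constrains the product of
variability and decay rate, and the Cavg anchors have already fixed the decay
rate. Both percentages stay within 10 points of the published values, which
is the fidelity the unpublished variability parameters allow.
`examples/calibrate_pk_defaults.py` reproduces this calibration.

Covariate effects (allometric weight on clearances and volumes, albumin and
CRP on clearance, antidrug-antibody status on clearance, albumin on central
volume) use power functions for continuous covariates normalized to their
reference values and proportional shifts for flags. The published model names
its covariates but not their forms or magnitudes; the shipped coefficients
are illustrative, deliberately modest, and configurable. Because continuous
covariates are drawn with median = reference, they leave the population
geometric mean essentially unchanged (the cohort geometric mean at
1200 mg Q2W stays within 3% of 178 µg/mL).

## Individual estimation (MAP empirical Bayes)

Given sparse concentration records, per-patient random effects are the mode
of the posterior combining the lognormal η prior with a Gaussian residual
model of combined proportional (20% CV) + additive (1 µg/mL) error.
Residual SDs are evaluated at the observed concentrations, so the weights do
not depend on η; this keeps the objective a weighted least squares plus
quadratic prior, makes noiseless data recover the generating η exactly, and
avoids the mode shift the σ(prediction) log-term would otherwise introduce.
Optimization is BFGS from η = 0 (gradient tolerance 1e-6); the posterior is
unimodal in the tested regimes, so a single start suffices. With 12 samples
over one interval and 10% proportional error, MAP estimates of the clearance
effect correlate with the truth at r > 0.9 over 200 simulated patients;
with 5-point clinical-style sampling, shrinkage lowers this to r ≈ 0.8.

## Synthetic cohort

The generator emulates the pooled analysis population (n = 936): mg/kg
dose-escalation arms (3–30 mg/kg Q2W), 500/1200/2400 mg flat Q2W arms and a
2400 mg Q3W arm, with the published arm sizes as defaults. Covariates are
drawn independently — lognormal for continuous variables (median and CV
chosen as oncology-typical values), Bernoulli for flags (Asian fraction
0.315 as published; others typical), and a four-level tumor type
(other/NSCLC/BTC/CC at 0.48/0.25/0.17/0.10). Real covariates are correlated
(weight with sex, albumin with CRP); independence is a deliberate
simplification — passing tests therefore validate the estimation machinery,
not the realism of joint covariate structure. A correlation hook was
considered and left out: nothing downstream currently consumes it.

Binary endpoints are drawn from configurable "true" logistic models in
`Cavg,SD`. Any-grade models use the published univariable slopes
(OR 1.66–1.67 per 100 µg/mL) with intercepts anchored to published
incidence/probability points; grade ≥ 3 models use half that slope (no
significant exposure association was detectable for them) with intercepts
matching the pooled incidences. Grade ≥ 3 flags are drawn conditionally on
the matching any-grade event with probability min(1, p₃/p_any), which
enforces the severity hierarchy row by row while preserving the marginal
grade ≥ 3 incidence wherever p₃ ≤ p_any (always true for the shipped
models).

## Exposure-safety modeling

Logistic regressions are maximum likelihood (statsmodels Newton scoring,
relative log-likelihood tolerance 1e-10); the exposure enters in µg/mL and
odds ratios are reported per 100 µg/mL — the scale chosen because it roughly
equals the exposure change of a 50% dose reduction from 1200 mg Q2W. CIs are
Wald (symmetric on the log scale, matching the published intervals). Quartile
incidence summaries use exact Clopper–Pearson intervals, boundaries at the
25/50/75th percentiles with ties to the lower bin, and plotting abscissae at
the 12.5/37.5/62.5/87.5th percentiles of the exposure distribution.

Covariate model reduction is backward elimination by likelihood-ratio test:
in each round the weakest candidate with p ≥ 0.05 is removed (categorical
factors as whole blocks, one LRT per factor), and the exposure term is never
a candidate — the analysis is exposure-safety by construction. Covariate
modeling runs only for endpoints whose univariable exposure relationship is
itself significant, mirroring the published screening logic. Separation is
detected explicitly (statsmodels' diagnostics plus a |β·sd(x)| > 15 guard on
the standardized scale) and raised as an error rather than reported as an
unstable OR; rank-deficient designs name the collinear columns.

## Dose evaluation and the decision table

Regimen probability tables evaluate the (fitted or table-anchored)
univariable model at each regimen's geometric-mean exposure — the typical
value when `n_sim = 0` (the geometric mean of a median-preserving lognormal
population), or exp(mean(log Cavg)) over a simulated population otherwise.
Delta-method CIs on the linear predictor are attached when a fitted
covariance is available and omitted (NaN) for a calibrated two-anchor model,
which carries none. Attainment tables report the percentage of simulated
patients with troughs ≥ 11 µg/mL (PD-L1 occupancy plus TGF-β1/β3
neutralization) and ≥ 50 µg/mL (TGF-β2 neutralization).

The bleeding-management logic is a first-match ordered rule table over the
event description (grade 1–4, tumoral origin, resolution by cycle end, rapid
hemoglobin drop, investigator-assessed risk, alternative explanation). Core
rules: grade 3 → interrupt and restart at 50% dose after resolution; grade 2
resolved to ≤ 1 by cycle end → continue at the RP2D; grade 2 unresolved but
manageable → consult the medical monitor; tumoral origin or high assessed
risk escalate severe events to permanent discontinuation. Combinations the
published guidance does not pin down (grade 4 specifics, low-grade tumoral
events, rapid hemoglobin drops at low grade) are encoded as separate,
configurable rules with conservative defaults and carry "[extrapolated]" in
their rationale strings. A terminal catch-all makes the table total; an
exhaustiveness test walks the full 128-combination cross-product.

## Reproducibility and problem sizes

Every stochastic stage takes its own named seed (cohort, outcomes, popPK,
fitting simulations) so one stage can be varied holding the others fixed;
`run_all` writes a manifest with the configuration hash and per-file SHA-256
checksums, and reruns are byte-identical. Default problem sizes — 936
patients, 2000 simulated patients per regimen for attainment, 500 outcome
replicates for recovery/coverage checks, 200 replicates for elimination
operating characteristics — were chosen so each check has comfortable
statistical resolution while the full suite runs in a few minutes on one
core.

## Known limitations

* Forward simulation + MAP only: there is no nonlinear mixed-effects
  estimation (FOCE/SAEM), so population parameters are inputs, not outputs.
* The generator's independent covariates and single-visit outcome structure
  cannot probe confounded covariate selection or longitudinal/recurrent-event
  questions (including immortal-time bias), which the underlying analysis
  itself defers.
* Grade ≥ 3 endpoints are rare (~4–9%); their univariable fits are retained
  for completeness but, as in the source analysis, are usually not
  significant at n = 936.
* Attainment percentages depend on variability parameters that are not
  public; the shipped ω values reproduce the published anchors only to
  within ~6 percentage points, and the tables should be read with that band
  in mind.
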