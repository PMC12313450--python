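# Methods

This note documents the models, defaults and numerical choices behind
`neopkpd`, and what the shipped test battery does and does not establish.

## Structural PK models

Drug disposition is a one- or two-compartment linear model with zero-order
(constant-rate) IV infusion input. All administrations, including clinical
"IV push", are modelled as 5-minute (0.0833 h) infusions. For individual
parameters the package uses the standard population-PK construction

    P_i = TV_P × Π_k f_k(covariates_i) × exp(η_i),   η_i ~ N(0, ω²_P)

with multiplicative covariate effects:

* **Allometric power** `(BW / BW_ref)^θ` on clearances (θ typically 0.75)
  and volumes (θ = 1), using birth weight — current weight is assumed equal
  to birth weight throughout the 48-h window, which is accurate at this age.
* **Sigmoid maturation** `PMA^γ / (PMA50^γ + PMA^γ)` on clearance, the
  conventional Hill-type fraction-of-mature-clearance function of
  postmenstrual age. It is bounded in (0, 1) and monotone increasing.
* **Linear** `1 + slope × (cov − ref)`, used for postnatal-age effects.

Time origin is birth: PNA(t) = t/24 days and PMA(t) = GA + t/168 weeks.
Because PMA changes by < 0.3 weeks over 48 h, covariates are evaluated once
per subject at a single reference time (default 24 h, the window midpoint)
and parameters are held constant; the error from ignoring within-window
maturation is far below the between-subject variability. Covariates outside
typical neonatal ranges are used as-is (the simulations deliberately
extrapolate to GA 24 weeks); a warning is logged.

### Bundled parameter sets

* `demo_model.yaml` — fully invented round numbers; the reference model for
  tests and diagnostics.
* `amoxicillin_onecpt_synthetic.yaml` — one compartment, PMA + PNA clearance
  maturation, allometry to birth weight.
* `benzylpenicillin_twocpt_synthetic.yaml` — two compartments, PMA clearance
  maturation, allometry to birth weight.

The two drug files reproduce the *structures* reported for the
best-performing published neonatal models of these drugs, but their numeric
typical values, variances and residual errors are **synthetic stand-ins**
chosen once from neonatal literature ranges (amoxicillin half-life ~5–12 h
across GA 24–42 weeks and V ≈ 0.65 L/kg; benzylpenicillin half-life ~2–5 h,
central V ≈ 0.45 L/kg). Any conclusion about the actual drugs requires
substituting estimates transcribed from a published model; the YAML schema
maps 1:1 onto the usual nonlinear mixed-effects parameterisation to make
that a config edit, not a code change.

## Simulation engine

The production path is the exact closed-form solution. Writing the
unit-bolus disposition as Σ A_i e^(−λ_i t) (for two compartments, λ are the
roots of λ² − (k10+k12+k21)λ + k10·k21 = 0), each infusion contributes the
standard rise/decay terms, and linearity makes superposition over dose
events exact — including overlapping infusions (rates add). An independent
reference path integrates the mass-balance ODEs piecewise between infusion
switch points with `scipy.solve_ivp` (LSODA, rtol 1e−10); the two paths
agree within 0.1% on randomized instances in the test battery, and a
vectorized variant evaluates thousands of BSV replicates of one subject in
a single call for the simulation-based diagnostics.

Default simulation grid: 0.05 h steps over [0, 48] h.

## Virtual population

500 subjects per whole GA week from 24 to 42 (N = 9500); GA within a
stratum is the whole-week value. Birth weight is drawn from a per-week
log-normal fitted to 3rd/50th/97th percentile values shipped as editable
config (`growth_reference.yaml`, a synthetic chart-shaped table); draws are
truncated to the 0.1st–99.9th percentile envelope. Postnatal growth
dynamics are not modelled — over a 48-h window only the birth-weight
distribution matters. Between-subject random effects are attached at
population generation, so different regimens evaluated on the same
population are compared subject-by-subject (paired design), which removes
Monte-Carlo noise from regimen contrasts.

## Regimens

The catalog (`regimens.yaml`) ships the DPF sepsis regimens (25 mg/kg
amoxicillin / 25,000 IU/kg benzylpenicillin; q12h below 2 kg, q8h from
2 kg), the optimized GA-banded benzylpenicillin regimen (30,000 IU/kg:
q12h GA < 28 w, q8h 28 ≤ GA < 36 w, q6h GA ≥ 36 w — GA exactly 36 is
assigned to the more frequent stratum) and continuous infusion of the
DPF-based daily dose with a 16.7% loading dose given over 5 min at the
start of the infusion. First administration is always at birth (t = 0).
Benzylpenicillin IU convert at 0.6 µg/IU (configurable). Further formulary
regimens can be added in the same YAML schema (mutually exclusive half-open
strata over birth weight, GA and PNA).

## Exposure metrics

* Unbound concentration = total × (1 − bound/100); fixed binding constants
  11.7% (amoxicillin) and 49.2% (benzylpenicillin), with sensitivity sweeps
  (5–15% and 40–60%) recomputing the full PTA grid per perturbed value.
* %fT>threshold uses strict inequality and linear interpolation of the
  bracketed crossing inside each grid step; agreement with a 0.001-h
  midpoint-sampling oracle is within 0.1 percentage points.
* **PTA window.** The efficacy window starts at the *end of the first
  infusion* (5 min) rather than at t = 0: concentration is exactly zero at
  birth, so a window anchored at t = 0 would make the 100%fT target
  unattainable for every regimen by construction. The 5-min exclusion
  changes lower targets by < 0.2 percentage points. A tolerance of 1e−9 on
  the attainment comparison absorbs roundoff so that a profile above
  threshold for the entire window attains exactly 100%.
* Toxicity duration is computed on **total** concentrations over the full
  [0, 48] h window (the thresholds originate from adult total-concentration
  reports) and summarized as median (IQR) within the four prematurity
  categories: extremely preterm (< 28 w), very preterm (28–< 32 w),
  moderate-to-late preterm (32–< 37 w), full term (≥ 37 w).
* Default MIC grid {0.125, 0.25, 1} mg/L for both drugs and %fT grid
  40–100% in steps of 10, with multipliers {1, 4}; all config-overridable.
  PTA is pooled over the population by default.

## Model evaluation

* **PRED** is the η = 0 prediction on each subject's own doses, covariates
  and sampling times; **IPRED** uses the MAP η that minimizes
  −2·[Σ_j log-likelihood under the combined proportional+additive residual
  model + log prior], optimized over η with multi-start L-BFGS-B (η = 0
  plus 4 seeded random starts, Nelder-Mead fallback, tol 1e−8) — robust for
  1–4-observation subjects, deterministic given the data.
* **Prediction errors**: PPE = 100(PRED−DV)/DV, APPE = |PPE|, P_k = share
  of APPE ≤ k. NRMSE is normalized by the mean observation (range
  normalization available); the normalization choice matters when comparing
  across datasets and is therefore recorded in the output.
* **pcVPC**: observations and each of N (default 1000) full-model
  replicates are rescaled by bin-median PRED (pcY = Y·medPRED/PRED); bins
  are quantile bins of time-after-most-recent-dose (default 4), which keeps
  bins interpretable when q8h and q12h subjects are mixed. Observed
  2.5/50/97.5 pc-percentiles are compared with their 95% simulation bands.
* **NPDE**: per subject, N replicate observation vectors are simulated
  under BSV + residual error; observed and simulated vectors are
  decorrelated with the empirical simulation mean and the Cholesky factor
  of the empirical simulation covariance; the rank-based pde is clamped to
  [1/(2N), 1−1/(2N)] and inverse-normal transformed. Global calibration is
  tested with a t-test (mean 0), a two-sided χ² test (variance 1) and
  Shapiro-Wilk normality.

## Synthetic study generator

Emulates a sparse opportunistic neonatal TDM study: default 95 subjects
split over the four prematurity categories at proportions 20/30.5/17.9/31.6%
(largest-remainder allocation by default, so the split is exactly
19/29/17/30 and tests are deterministic; multinomial optional), whole-week
GA uniform within each category, DPF dosing from birth, 1–4 samples per
subject (median 2) uniform within [1, 48] h, and combined
proportional+additive residual error on DV. Values below the assay-like
LLOQ (default 0.1 mg/L) are truncated to the LLOQ and flagged in a `BLQ`
column, never dropped. True η and individual parameters are returned for
recovery experiments.

What this generator does *not* emulate: TDM-driven (dose-anchored) sampling
times, gentamicin co-therapy records, covariate measurement error, or
deviations of actual administration times from the nominal schedule.
Passing diagnostics on self-simulated data therefore establishes internal
consistency of the machinery, not adequacy of any model for real patients.

## Desk-scale defaults and determinism

The acceptance script runs the PTA analyses at 100 subjects per GA week and
the simulation diagnostics at N = 500 replicates — small enough to complete
in well under a minute, large enough that the reported PTA values move by
well under one percentage point relative to the full-scale run. Every random
draw flows from a single `numpy` Generator seeded from the user-supplied
seed; identical configs and seeds give byte-identical output files.

## Known limitations

* Drug-specific parameter values are synthetic stand-ins (above); the
  package validates machinery, not drugs, until real estimates are loaded.
* Linear PK only; no nonlinear elimination, oral absorption, or
  time-varying clearance within the window beyond the covariate evaluation
  point.
* No population parameter estimation (FOCEI/SAEM); the evaluation module
  validates a *given* model.
* Toxicity thresholds are adult-derived totals; the unbound-threshold
  variant is available but not the default.
* The growth reference is sex-pooled and chart-shaped, not an official
  chart reproduction.
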