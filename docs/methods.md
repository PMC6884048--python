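# Methods

## Exposure model

Arterial PaO2 is a point process: one value per blood-gas draw, at
irregular times. The exposure metric is a threshold-exceedance area.
Between consecutive samples no more than 12 h apart the curve is linearly
interpolated; pairs further apart are untrusted and contribute nothing,
and time outside any trusted segment is treated as unexposed (zero
exceedance). Segments crossing the end of the potential-exposure window
are truncated there by interpolation. The area of each segment above the
boundary is closed-form — a trapezoid when both endpoints exceed it, a
triangle from the interpolated crossing point when one does — so no
numerical integration enters the pipeline; a fine-grid Riemann oracle is
used only in tests. The hyperoxemia dose divides the summed area by the
full window length W ∈ {24, 72, 120, 168} h regardless of observed
coverage, and the any-exposure indicator is `area > 0`.

Conventions worth noting: a value exactly at the boundary (13.3 kPa)
contributes no area; pre-admission samples (t < 0) are discarded; an
isolated supra-threshold sample with no neighbour within 12 h contributes
no area and therefore counts as unexposed. The boundary is kept in kPa
internally (1 kPa = 7.50062 mm Hg for display).

## Cohort construction

Inclusion requires age ≥ 18 y, ICU stay strictly longer than 24 h, no
treatment-limitation order, no CPR in the 24 h before admission, passing
data-quality flags, index (first) admission only, and complete model
covariates (complete-case analysis; the generator's missingness is ~0.4%).
Exclusions are attributed to the first failing criterion in a fixed order
(age, stay, limitation, CPR, QC, readmission, missingness) so the counts
always partition the input — a CONSORT-style log.

The window-W subset keeps episodes with stay ≥ W: every member is present
(and alive, since death is recorded at discharge) for the entire potential
exposure period, removing informative censoring by construction. Subsets
are nested by definition. `continuous_mv` is true when the closed-interval
union of ventilation episodes covers [0, W]; touching intervals merge.

## Outcome model

ICU death is modelled by a binary GLM (logit default; probit and cloglog
for robustness). The spike-at-zero exposure distribution is coded as a
continuous dose term (linear, for parsimony; a spline-on-dose diagnostic is
available via `ModelDefinition(dose_spline=True)`) plus an any-exposure
indicator; the two must be interpreted jointly. Age, weight and APACHE II
enter as restricted cubic splines — truncated-power basis, linear beyond
the boundary knots, nonlinear columns normalised by (t_k − t_1)², knots at
conventional quantiles (4 knots by default at 0.05/0.35/0.65/0.95). If the
indicator is constant (everyone exposed) it is dropped with a warning
rather than failing on rank deficiency.

Fitting is Fisher scoring (IRLS), convergence at max |Δβ| < 1e-8 within 25
iterations, observed-information covariance; a non-intercept coefficient
passing ±15 raises an explicit separation error, and non-convergence is
flagged, never silent. Optional exposure x respiratory-diagnosis and
exposure x ventilation interactions (both the dose and the indicator
component) carry a quadratic ridge penalty (λ/2)Σβ², applied after
standardising those columns so λ is scale-free. Effective degrees of
freedom are tr[(H+P)⁻¹H] with H the Fisher information at the optimum;
coefficient covariance is the sandwich (H+P)⁻¹H(H+P)⁻¹. AIC is −2 times
the *unpenalized* log-likelihood at the penalized estimate plus twice the
effective df (the variant is recorded in the model metadata), and λ is the
AIC minimiser over a geometric grid {0, 0.5, 1, …, 64}, ties to the
smallest. Per-term inference (Table-style odds-ratio summaries) uses Wald
chi-squares by default; likelihood-ratio tests are provided for nested
unpenalized fits, where their χ² calibration is exact.

## Validation

Discrimination is the concordance (c-index, equal to AUROC, ties counted
half), accuracy the Brier score, and calibration a logistic recalibration
of the outcome on the fitted linear predictor (slope) and on an
offset-fixed predictor (intercept). Precision-recall and average precision
come from scikit-learn. The optimism bootstrap repeats the *entire*
procedure — knot placement, penalty selection, fitting — on each of B
resamples, scores each refit on its own resample and on the original data,
and subtracts the mean train-test gap from the apparent metrics. Resamples
hitting separation are skipped and counted. The calibration curve applies
the corrected slope/intercept to the linear predictor and reports decile
bins plus a lowess smooth.

The default B is 500; the heavier test-suite checks use B = 200, which
leaves the Monte-Carlo error of the optimism estimate well below the
tolerances asserted.

## Counterfactual ATE

Plug-in g-computation on the fitted model: the counterfactual design sets
dose and indicator (and thus every interaction column built from them) to
zero, holding covariates fixed; the ATE is the mean risk difference in
percentage points. Episodes with zero observed exposure have bit-identical
designs under both scenarios, hence exactly equal risks — they sit on the
identity line of the risk-pair plot. This is a model-based contrast, not a
causal identification strategy: it inherits every assumption of the
outcome model.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, with
defaults frozen as the package's study conditions:

- **Stay**: log-normal, median 3.5 d, σ = 0.885 (IQR ≈ 2–6.6 d), clipped
  to [0.25, 45] d. Death occurs at discharge (no time-to-event structure).
- **Sampling**: first sample at 0.25–2 h, then log-normal gaps (median
  3 h, σ = 0.5) capped at 12 h; with probability 0.08 a gap is drawn
  uniform on 12.5–24 h instead, producing the untrusted >12 h gaps.
- **Latent PaO2**: per-episode mean — N(13.8, 2.5²) kPa, with a late-phase
  shift N(−0.3, 0.8²) after half the stay (oxygen weaning) — plus N(0,
  1.5²) sampling noise, clamped to [4, 60] kPa. A never-hyperoxemic 8% is
  clamped strictly below the boundary (the spike at zero). These values
  give a day-1 any-exposure prevalence near 73% rising to ~87% by day 7
  and day-1 median dose ≈ 0.3 kPa.
- **Covariates**: age N(62, 16²) clipped to [16, 95] (the <18 tail
  exercises the age exclusion), weight N(77, 20²), APACHE II rounded
  N(16, 6²), 60% male, 25% respiratory diagnosis, 18% prior dependency,
  45% surgical; 0–2 ventilation intervals per episode. Flags: 3%
  treatment limitation, 2% pre-admission CPR, 1% QC failure, 5%
  readmissions, 0.4% missing weight.
- **Outcome**: Bernoulli from a logistic model with intercept −4.1 (~5%
  ICU mortality), any-exposure log-OR ln 1.5, dose log-OR 0, and modest
  covariate effects; continuous covariates enter centred. The exposure
  terms entering the truth are computed by the package's own exposure
  engine on the generated samples over `outcome_window_h` (default 24 h),
  so the day-1 model is exactly correctly specified and recovery tests are
  not confounded by imputation error. A `los_per_day` coefficient
  (default 0) lets integration tests reproduce the rising death rate of
  longer-stay subsets.

What the generator does **not** emulate: site effects, readmission
correlation, pre-ICU oxygen exposure, informative death timing within the
stay, or time-varying illness severity. Passing tests therefore establish
the correctness and calibration of the *method* under its stated
assumptions, not the clinical conclusions one would draw from real data.

## Numerical and design choices

- All randomness flows from one integer seed (per-stage seeds spawned via
  `SeedSequence`); the same config is byte-identical on disk.
- The bootstrap of an 18-column model at ~550 events genuinely shrinks:
  its corrected calibration slope is ≈ 0.95, matching external validation
  on an independently generated cohort. The bootstrap self-consistency
  test therefore uses a correctly specified high-events-per-variable model
  (5 parameters, n = 10,000), where the true external slope is ≈ 1.
- Wald intervals use z = 1.96; p-values are two-sided χ²₁ tails.
- Test-suite problem sizes (100 recovery replicates at n = 20,000, 1,000
  LR replicates at n = 2,000, B = 200 bootstraps) are chosen so
  Monte-Carlo bounds are decisive at roughly two minutes of total compute.

## Known limitations

- The any-exposure flag derives from interpolated area, so a lone
  supra-threshold sample flanked by long gaps counts unexposed; with raw
  samples it would count exposed. Real analyses should check both codings.
- Spline effects have no single odds ratio; `term_odds_ratio` refuses them
  rather than reporting something misleading (use predicted-risk
  contrasts).
- Penalized-fit p-values use the sandwich covariance; for heavily
  penalized terms they are approximate by construction.
- The generator's two-interval ventilation scheme cannot produce
  continuous ventilation assembled from >2 abutting intervals, though the
  cohort builder's interval-union logic handles the general case.
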