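# Methods

`taustage` estimates patient-centered amyloid-PET (Centiloid) thresholds
that mark the transition from amyloidosis to tauopathy, stratified by sex
and age, and links the resulting tauopathy phases to the timing and speed of
cognitive decline. This note documents the models, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter.

## Pipeline overview

1. **Preprocessing.** Global amyloid SUVR is mapped to Centiloid by a
   tracer-specific linear calibration (configuration, not code; defaults are
   the published maps CL = 188.22·SUVR − 189.16 for florbetapir and
   CL = 157.15·SUVR − 151.87 for florbetaben). Aβ status is positive iff
   SUVR is *strictly* above the tracer cutoff (1.11 / 1.08). Aβ− subjects
   with a non-CN diagnosis are excluded, since their impairment cannot be
   attributed to AD pathology. Age groups are ≤65 / (65, 80] / >80 — the
   middle bracket is closed at 80 so the three groups partition all ages.

2. **Rates.** Per-subject annual rates of change (ROC) for each tau-PET ROI
   and for MMSE/ADAS-Cog11 come from a linear mixed model with random
   intercept and slope (REML, unstructured 2×2 random-effect covariance,
   time in years since each subject's first visit of that modality). The
   subject ROC is the fixed slope plus the conditional (BLUP) random-slope
   mode; a per-subject OLS option without pooling is also provided. If REML
   hits a variance boundary or fails, the fit falls back to ML and then to
   per-subject OLS, with the method recorded on the fit object. A perfect-fit
   shortcut detects (numerically) noise-free data and returns the exact
   per-subject slopes directly.

3. **Interaction analysis.** All regressions of rates on covariates are
   Huber M-estimates: IRLS with tuning constant c = 1.345, scale from the
   normalized MAD of the residuals (centred at zero), iterated to a relative
   coefficient change < 1e−8 (max 100 iterations), p-values asymptotic
   normal with Huber's corrected covariance. The sex-stratified model is
   `roc ~ centiloid + age + centiloid×age + apoe4 [+ cohort]` with age
   mean-centred within the stratum before forming the product (pure
   conditioning; the interaction coefficient is unchanged). The small family
   of global interaction tests is Bonferroni-corrected (family size 4 by
   default: two sexes × two cohorts); regional parcel-wise maps are
   Benjamini–Hochberg-corrected within cohort × sex. The percentile-window
   analysis places nine overlapping age windows [P(k−10), P(k+10)] at the
   deciles k = 10…90 of the stratum's age distribution — this is the reading
   that yields exactly nine groups spanning the 10th–90th percentiles — and
   reports the Huber Centiloid slope per window with a percentile bootstrap
   95% CI (default 1000 case resamples). Because adjacent windows share half
   their subjects, window slopes are positively correlated; single-cohort
   window *trends* are therefore noisy, and absence of an age effect should
   be judged on the average trend over replications, not one draw.

4. **Thresholds.** Tauopathy severity cutoffs live on the rate scale:
   cutoff(z) = mean + z·SD of the temporal meta-ROI ROC in the CN Aβ−
   reference stratum (sample SD, n−1; z = 2 / 2.5 / 3 for mild / moderate /
   severe). The reference is pooled across cohorts, with cohort entering
   every stratum model as a covariate. Within each sex (and sex × age)
   stratum, `roc ~ centiloid + apoe4 + cohort` is case-resampled (default
   1000 replicates); each replicate's predicted mean-rate line over a
   Centiloid grid (covariates fixed at stratum means — the marginal mean
   under a linear model) yields a pointwise 2.5/97.5-percentile band. The
   threshold for a severity is the smallest grid value at which the *upper*
   band reaches the cutoff; the threshold's CI comes from the distribution
   of per-replicate crossings (replicates that never cross are excluded and
   their fraction reported; a CI with <50% crossing replicates is flagged
   unreliable). By construction the 2.5th crossing percentile and the
   upper-band crossing are dual estimates; they can disagree by less than a
   grid step and the CI is clamped to contain the point estimate. The grid
   is [0, 150] Centiloid at 0.01 steps by default, matching the two-decimal
   reporting precision; non-crossing is a valid outcome, not an error.
   Percentile bootstrap (not BCa) is used throughout: it matches the
   plain-95%-CI construction and keeps the analytic oracle simple.

5. **Staging.** A subject whose Centiloid equals or exceeds a stratum
   threshold counts as above it (consistent with the ≥-crossing rule), giving
   binary flags and a gradual four-level phase. Group differences in scalar
   outcomes are tested by ANCOVA (nested-model F) with Tukey HSD on
   covariate-adjusted means via the studentized-range distribution; with no
   covariates this reduces exactly to one-way ANOVA + classic Tukey
   (tested against both oracles).

6. **Progression model.** Normalized disease scores (MMSE reversed and
   divided by 30; ADAS-Cog11 divided by 70; clipped to [0, 1]) follow

       y_ij = p0 + (1 − p0) · σ( v · exp(ξ_i) · (t_ij − t0 − τ_i) )

   with population midpoint t0 (years) and steepness v (1/year), per-subject
   time-shift τ_i ~ N(0, σ_τ²) (positive = later onset) and log-acceleration
   ξ_i ~ N(0, σ_ξ²), and Gaussian observation noise. Fitting alternates a
   joint MAP update of all subject parameters (L-BFGS-B with analytic
   gradients; the objective separates by subject) with a population step for
   (t0, v) and damped hyper-parameter updates (damping 0.4, 12 sweeps) — a
   deterministic stochastic-approximation-EM-style scheme. t0 is identified
   against the τ prior mean of zero, v against the ξ prior mean.
   Initialisation regresses the pooled logit-transformed scores on time.
   Default priors σ_τ = 3 years, σ_ξ = 0.3 (updated during fitting unless
   frozen); the noise floor is 1e−3 on the normalized scale. Personalization
   uses 10-fold cross-validation: each subject's (τ̂, ξ̂) comes only from the
   fold in which they were held out. Flat cohorts (v collapsing below 1e−3)
   abort with a message rather than returning meaningless shifts. Parameter
   recovery on simulated data (200 subjects, 4 visits, noise SD 0.02)
   reaches r ≈ 0.99 for τ and ≈ 0.95 for ξ.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, with
ground truth retained for recovery tests:

- **Demographics.** Age truncated-normal (default 73 ± 8 on [50, 95]); sex
  Bernoulli(0.5); APOE ε4 carriage 0.45; education truncated-normal
  (16 ± 2.5 years); two cohort labels (0.7 / 0.3).
- **Amyloid.** A two-component Centiloid mixture: Aβ− truncated-normal
  (5 ± 8) and Aβ+ uniform on [25, 140] (p = 0.6), mapped back to
  tracer-specific SUVR through the inverse calibration so that downstream
  classification is consistent.
- **Tau rates.** r_i = b0 + [slope_sex + interaction_sex·(age_i − 75)]·CL_i
  + N(0, 0.01), with b0 = 0.002 SUVR/yr, slope 3.0e−4 (men) and 4.5e−4
  (women) SUVR/yr per Centiloid, and interaction −9.8e−6 (men) / 0 (women)
  SUVR/yr per Centiloid per year. The female slope is 1.5× the male slope
  and the male interaction is negative, so the generator's defaults encode
  the two qualitative findings the pipeline must detect: women transition at
  lower amyloid, and younger men accumulate faster. Magnitudes were chosen
  to sit in the range of reported temporal meta-ROI change rates
  (≈0.01–0.06 SUVR/yr at high amyloid). Observed SUVR adds per-visit
  N(0, 0.02) measurement noise on a linear trajectory (3 visits, 1.5 years
  apart by default). Optional toggles: visit-time jitter, heteroscedastic
  rate noise, and a gross-outlier fraction with inflated rate noise for
  robustness experiments.
- **Cognition.** Latent onset ties to tau: τ_i = −4·z(rank of r_i) + N(0, 1)
  years, so faster accumulators decline earlier; ξ_i ~ N(0, 0.25). Scores
  follow the logistic latent-time model (t0 = 12 years, v = 0.3/yr) with
  normalized-scale noise 0.03, then map to MMSE (clipped to [0, 30]) and
  ADAS-Cog11 (clipped to [0, 70]).

What the generator does **not** emulate: real marginal distributions of any
cohort, tracer-specific measurement-error structure, nonlinear tau
trajectories, dropout/missingness, practice effects on cognition, or
off-target tau-PET binding. Passing tests therefore demonstrate that the
estimators recover the structure they target under the assumed data model —
not that the printed thresholds of any particular study would be reproduced,
which would require the original restricted data.

## Problem sizes used in tests

The test suite runs simulation-based checks at sizes chosen to give stable
verdicts: band-coverage calibration uses 200 simulations of n = 300 with 500
bootstrap replicates; robustness uses 100 paired contaminated replicates of
n = 300; ordering checks use 50 seeds of n = 500 cohorts with 200 bootstrap
replicates on a 0.2-Centiloid grid; the phase–cognition power check uses 50
seeds of n = 1000 cohorts with 5 CV folds and 6 EM sweeps; progression
recovery uses 200 subjects with 4 visits. `scripts/acceptance.py` recomputes
the same quantities from scratch at comparable sizes.

## Known limitations

- Threshold CIs condition on the fitted band model being linear in
  Centiloid; curvature in the true amyloid–tau-rate relation would bias both
  the threshold and its CI.
- The progression model is univariate (one instrument at a time, ADAS-Cog11
  by default) and assumes a shared population curve shape; floor/ceiling
  behaviour outside the logistic range is absorbed into noise.
- Small strata (n < 30) are reported but not estimated; with very high Aβ+
  prevalence the CN Aβ− reference can become small, which widens severity
  cutoffs' sampling error (a minimum of 20 reference subjects is enforced).
- MixedLM boundary fits fall back to unpooled slopes; with two visits per
  subject and large noise this loses shrinkage efficiency.
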