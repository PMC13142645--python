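# Methods

This note documents the models, conventions and design choices behind
`fcbag`, in the order the pipeline runs them. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic cohort generator

The generator (`fcbag.synthetic`) produces ROI time series, metadata and
clinical scores under a fully known generative model, so that every
downstream stage has a recovery test. It emulates:

- **Connectivity template.** A single Wishart-derived correlation matrix
  shared by all subjects, blended as `0.8 * W + 0.2 * J` (W a random
  correlation matrix, J all-ones) so the mean off-diagonal is ≈ 0.2 —
  positive-dominant functional connectivity without modelling anatomy.
- **Age signal.** A fraction `frac_age_edges` (default 0.3) of edges
  drifts linearly with *effective age* in Fisher-z space at
  `age_slope` (default 0.01 z/year), with random sign per edge. Working
  in z-space keeps back-transformed correlations inside (−1, 1).
- **Diagnosis effect.** Cases' effective age is
  `age + bag_shift_years`; subject-level heterogeneity `bag_sd`
  (default 5 years) is added for everyone. `bag_sd` is needed because
  clinical scores are defined as correlated with the true BAG; with a
  purely group-level shift the within-group BAG variance would be zero
  and the correlation undefined. Five years is a typical dispersion for
  functional brain-age deviations in adult cohorts.
- **Site effects.** Additive per-site, per-edge offsets
  (`site_shift_sd`, z units) and multiplicative factors on the residual
  noise (`exp(N(0, site_scale_sd))`), matching the location/scale form
  ComBat assumes.
- **Nuisance effects.** Per-edge sex offsets (`sex_effect`) and motion
  loadings (`fd_effect` per unit of mean FD). Mean FD is log-normal and
  mildly age-correlated (r ≈ 0.2), reproducing the motion confound the
  pipeline must remove.
- **Clinical scores.** For each variable,
  `score_z = -loading * z(true BAG) + sqrt(1 - loading^2) * noise`, so a
  more-negative BAG (younger-appearing brain) goes with higher symptom
  scores; performance measures (DSST, categorical fluency) flip sign.
  Patient-only measures (PANSS, NSS, illness duration, medication dose)
  are missing for controls. Variable means/SDs are set to plausible
  clinical ranges (e.g. PANSS total 60 ± 15) and matter only for
  display: every analysis rank-transforms them.
- **Follow-up visit.** For cases, a subject-level true BAG change
  Δ = baseline − follow-up ~ N(`delta_bag_mean`, `delta_bag_sd`) shifts
  the effective age; clinical change scores correlate with Δ at
  −`coupling` (a BAG increase accompanies a symptom decrease). Time
  series are regenerated at the shifted age from dedicated substreams.

One global seed (`numpy.random.SeedSequence`) fans out to a cohort-level
stream and per-subject substreams, so individual subjects are bit-stable
under cohort subsetting, and a follow-up visit never perturbs baseline
draws.

Per-subject correlation matrices are projected to the nearest positive
semi-definite correlation matrix by eigenvalue clipping at 1e-8 with
diagonal renormalization (deterministic), and time series are drawn from
a zero-mean multivariate normal. What the generator does **not**
emulate: haemodynamics, autocorrelated BOLD noise, realistic atlas
geometry, scanner drift, or non-linear age trajectories. Passing tests
therefore demonstrate correct recovery of injected linear-Gaussian
structure, not performance on real fMRI.

## Connectome features

Time series are detrended (per-column OLS line), z-scored with sample SD
(ddof = 1), correlated (Pearson), and vectorized as the row-major lower
triangle; a 39-region parcellation yields 741 edges. Raw correlations
are the default feature; a Fisher-z flag is exposed because the exact
placement of the standardization step is a legitimate modelling choice.
The module is region-count agnostic — atlas identity is metadata.

## ComBat harmonization

`fit_combat` implements parametric empirical-Bayes ComBat: per-feature
least squares on [site indicators + age, sex, mean FD], standardization
by the pooled residual variance, then per-site normal/inverse-gamma
shrinkage of location (γ*) and scale (δ*²) with iterated moment-matching
updates (tolerance 1e-4 on the max parameter change, 100 iterations
max). `apply_combat` removes (γ*, δ*) and re-adds grand and covariate
effects, so the model fitted on the healthy-reference pool can be
applied to held-out clinical data; an unseen site is rejected rather
than refit — the reference pool must contain subjects from every
clinical site. A single-site pool is accepted with a warning and applies
as the identity (no batch contrast exists). Covariates are used as
given (sex coded 0/1, nothing standardized internally) for transparency.
After harmonization, sex and mean FD are residualized out of the
features; age is deliberately left in — it is the prediction target, and
age adjustment happens later at the BAG level.

## Brain-age modelling

Nested cross-validation: outer `RepeatedStratifiedKFold` (default 5
folds × 5 repeats; the analysis drivers and acceptance run use 5 × 2)
stratified by age decade (`floor(age/10)`, decades smaller than the fold
count merged with the nearest decade), inner K-fold (default 3) for
hyperparameter selection. The search is a seeded random sampler over
per-family distributions (log-uniform for penalties and kernel widths);
the optimizer is pluggable, and a seeded default keeps the whole
benchmark deterministic. Scale-sensitive families (SVR, penalized linear
models) are wrapped with a train-fold `StandardScaler`, so scaling never
sees test subjects. The winner is the family with the lowest mean outer
MAE; its refit uses the hyperparameters of its best outer fold.

Metrics: per-fold MAE, RMSE, R², Pearson r; t-based 95% CIs over folds
for MAE/RMSE/R², and a Fisher-z interval (±1.96/√(n−3)) for the pooled
r. Bias correction (`pred = a + b·age`) is fitted on the winner's pooled
out-of-fold predictions, not on in-sample refit predictions, because
in-sample fits understate the regression-to-mean slope; predictions are
corrected as `(raw − a)/b`, which by construction restores a unit slope
of corrected prediction on age over the reference sample.

## Matching

Propensity scores from a maximum-likelihood logistic regression of
diagnosis on age and sex (perfect separation rejected). Greedy 1:1
nearest-neighbour matching without replacement on the propensity logit,
smaller group first in descending logit order (ties by subject id; a
tie in group size resolves to the case group), caliper 0.3 SD of the
pooled logit scores. Sex is a covariate only, not a hard stratum.

## Statistics

- **BAG residualization**: OLS on [1, sex, mean FD, age, age²], residuals
  z-scored with sample SD in the pooled analysis sample.
- **Group model**: OLS of BAG z on intercept, diagnosis, sex, centered
  age, centered age², centered mean FD and site dummies (reference =
  alphabetically first site), with HC3 robust covariance
  `(X'X)^-1 X' diag(e²/(1−h)²) X (X'X)^-1` and t inference on n − p
  degrees of freedom (conservative at these sample sizes). The model is
  a Gaussian linear model: the outcome is a continuous z-score, so a
  binomial family would be ill-defined.
- **Per-site contrasts**: Welch t with Satterthwaite df on within-site
  z-scores; Cohen's d with pooled SD; Hedges' g = d·(1 − 3/(4N − 9)).
- **Rank-INT**: average ranks, probabilities r/(n+1) (strictly inside
  (0,1)), z = √2·erfinv(2p−1), rescaled to unit sample SD; missing
  values excluded pairwise and preserved as NaN.
- **FDR**: Benjamini–Hochberg per family — all cross-sectional clinical
  associations together, longitudinal associations separately, post-hoc
  contrasts separately. Complete-case analysis per association with the
  per-variable n reported; fewer than 10 complete cases skips the
  variable with a warning.
- **Post-hoc split**: patients at least 0.5 SD younger- vs
  older-appearing on BAG z, middle band excluded, Welch per clinical
  variable; inference skipped when either group has < 3 members.

## Calibrated case-shift evaluation

The group-recovery evaluation states the injected case effect in SD
units of the pipeline's own BAG scale, which depends on model error and
is not knowable before training. The evaluation therefore calibrates by
design: pass 1 runs the full pipeline with a zero shift and measures the
control residualized-BAG dispersion σ (years); pass 2 regenerates the
cohort with `bag_shift_years = 0.6·σ` — identical seeds, so controls and
all other draws are unchanged — and re-applies the already-fitted
harmonizer and brain-age model. The procedure is deterministic given one
seed and involves no iteration against the outcome.

## Problem sizes

Default analysis and acceptance runs use 400-subject cohorts (39
regions, 200 timepoints, two sites), a 5 × 2 outer CV with a 3-fold
inner search (budget 8) over the ridge / RBF-SVR (and, in the
acceptance run, elastic-net) families, 25 replicates for the type-I
check and 300 subjects for the longitudinal analysis. These sizes give
stable estimates for the injected effect magnitudes while keeping a full
run to seconds–minutes on one CPU; all sizes are plain config fields.
The longitudinal acceptance check runs on generator-truth BAG — the
coupling and its sign are properties of the change-score statistics, and
the prediction-noise attenuation path is exercised separately by the
end-to-end workflow tests.

## Known limitations

- The ComBat implementation is parametric-prior only (no nonparametric
  priors, no GAM age trends, no longitudinal ComBat).
- Matching is greedy, 1:1, without replacement; optimal matching is out
  of scope.
- The generator's linear age drift makes age prediction easier than on
  real rs-fMRI; absolute MAEs on synthetic cohorts are not comparable to
  real-data MAEs.
- Longitudinal inference uses simple change-score regressions, not
  mixed-effects models.
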