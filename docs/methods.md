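# Methods

This note documents the models implemented in `tractage`, the synthetic
data they are validated on, the numerical choices that were genuinely open,
and what the passing test suite does and does not establish.

## The analysis

The pipeline estimates a subject's "white-matter brain age" from along-tract
diffusion profiles and interprets the gap to chronological age (PAD) as an
individual marker of accelerated white-matter change. Its stages are
independent, serializable estimators:

**Feature pipeline** (`TractFeaturePipeline`). Input is a connectogram: a
76 × 100 × 7 array (tracts × normalized steps × diffusion indices). Stages,
in order: (1) 1-D Gaussian smoothing along steps, per tract and index —
the kernel is normalized, so constants pass through unchanged; (2) per-cell
standardization with mean/SD estimated on the training cohort only and
frozen thereafter — test subjects and patients are transformed with training
statistics, never their own, so no information flows from evaluation cohorts
into the feature definition; (3) a per-cell ordinary least-squares fit
`value ~ 1 + age + age²` on the training cohort; the p-value of the
model-vs-intercept F test with (2, n−3) degrees of freedom becomes the step
weight `w_s = −log₁₀ max(p_s, p_floor)`; (4) per tract and index, the
100 steps collapse to the weighted average `Σ w_s x_s / Σ w_s`, giving 532
features.

Open choices and their resolutions:

* *Weight normalization.* Raw −log₁₀ p weights are renormalized to sum to 1
  per tract×index (a true weighted mean). Exposed as
  `normalize_weights`; because the reduction divides by `Σ w_s`, the toggle
  only matters for serialized weight values, not for the features.
* *The F test* is the overall model test (2 numerator df), the plainest
  reading of a GLM with age and age² regressors. Sex is not in the weighting
  GLM; it enters only the age model.
* *p-value floor* 1e-300 keeps `−log₁₀ p` finite when p underflows.
* *Kernel width* defaults to σ = 2 steps with 3σ truncation and reflecting
  boundaries; the width of the original kernel is not documented anywhere,
  so it is configurable.
* *Order*: smoothing → normalization → weighting → reduction.

**Compression** (`SparseAutoencoder`). One sigmoid hidden layer of 179
units, linear output, trained full-batch by L-BFGS (up to `epochs = 1600`
iterations) on the loss

    J = ½·mean((x̂ − x)²) + β · mean_j KL(ρ ‖ ρ̂_j) + ½·λ·(‖W₁‖² + ‖W₂‖²)

with sparsity target ρ = 0.05, sparsity weight β = 1, weight decay
λ = 1e-4. Inputs are column-standardized on the training set (frozen). The
optimizer is a deterministic quasi-Newton method; the contract is the loss
definition plus seeded bit-reproducibility, not a specific named optimizer.
The reconstruction rate is defined as variance-explained percent of the
(standardized) reconstruction, since "reconstruction rate" has no standard
definition.

The λ default deserves a note. Against a per-element mean squared error,
λ = 1e-4 is a strong ridge penalty: it costs several points of *training*
reconstruction (the default model explains roughly 85–90% of training
variance on synthetic cohorts, against a ~97% linear PCA-179 optimum).
Pilot experiments with λ ≤ 1e-6 showed why it must stay: a 190k-parameter
model trained on 300 subjects memorizes their noise — held-out
reconstruction collapses, held-out age predictions acquire a multi-year
bias, and injected disease effects are attenuated in the compact space. The
test suite therefore asserts the regularized training reconstruction floor
(≥ 80%) rather than a near-100% figure, and separately asserts held-out
behaviour. On highly correlated real data this trade-off is far milder.

**Brain-age model** (`BrainAgeModel`). GPR of age on compact features plus a
binary sex column (M = 1). Kernel: constant × squared-exponential + white
noise (rational-quadratic optional); hyperparameters by marginal-likelihood
maximization with 3 seeded restarts (`normalize_y` on). Evaluation follows
the original design: the encoder and feature statistics are fitted once on
the full training cohort, and 10-fold CV (seeded shuffled partition; pooled
out-of-fold predictions) cross-validates the GPR stage only. That makes the
CV numbers optimistic whenever the encoder can adapt to training noise; the
independent test set is the honest generalization estimate, and both are
reported. No post-hoc PAD bias correction is applied; instead age is
regressed out in the downstream correlation analyses, and the
regression-to-the-mean diagnostic (Pearson r between PAD and age) is
reported with the CV metrics.

**Normative model** (`NormativeModel`). Per sex and per tract×index feature:
μ(age) by quadratic regression; σ(age), by default, from a quadratic fit to
log absolute residuals, back-transformed with the half-normal bias
correction `E[log|Z|] = −(γ + log 2)/2` and a √(n/(n−3)) degrees-of-freedom
inflation, so that for Gaussian residuals the curve estimates σ without
systematic bias. A sliding ±w-year window SD is available as a sensitivity
alternative. Queries outside the fitted age span raise — never silent
extrapolation. z-scores are computed on the 532 weighted-average features
(the same grid the attribution uses), not on raw 100-step profiles.

Calibration expectation: the per-cell error of ẑ's mean on held-out healthy
subjects scales like √(p/n) of the normative fit (p = 3 parameters per sex),
i.e. ≈ 0.09 z-units at n = 524. Individual cells therefore wander a few
hundredths-to-tenths around zero even for a perfectly specified model; the
calibration tests assert the across-cell aggregates (mean of per-cell means
within ±0.1, mean of per-cell SDs within [0.9, 1.1] at n = 2000 held-out)
and that both aggregates shrink as the normative cohort grows.

**Group analysis** (`analysis`). ANCOVA is the extra-sum-of-squares F test
of the group factor over covariates (age, sex, handedness), df =
(groups−1, n − groups − covariates); post hoc pairwise tests are Welch t by
default (pooled optional) with p × 3 Bonferroni, capped at 1. The
mass-univariate stage runs a one-sample t per z cell with Benjamini–Hochberg
adjustment across all 532 cells (Bonferroni optional; BH is the default
because 532 simultaneous cells make Bonferroni severely conservative), plus
the one-sample effect size d = mean(z)/SD(z). "Top 5% of effect size" is
ceil(0.05 × 532) = 27 cells by |d| with ties broken in canonical feature
order; restricting to significant cells first is an option. PCA attribution
centers the patients × selected-cells matrix, takes the first right singular
vector (sign oriented so the PAD regression slope is positive), and reports
squared-loading contributions normalized to 100% (absolute-loading
normalization is an option — the two disagree only in weighting, both sum to
100%). Clinical correlations residualize PAD and the clinical variable on
the confounders by OLS and use Pearson when both residual sets pass
Shapiro–Wilk at α = 0.05, Spearman otherwise; the percentile bootstrap
resamples subjects, keeps the full-sample method fixed across replicates,
skips zero-variance replicates (warning above 10%), and is fully seeded. An
optional |standardized value| > 2.5 outlier exclusion is off by default.

## The synthetic generator

`make_study_suite` emulates a six-cohort study: training (n = 300, ages
18–92 with a lifespan mixture of 49% under 40 / 20.7% 40–60 / 30.3% over
60), independent test (n = 40), normative (n = 524, ages 7–92), and three
age- and sex-matched study groups (37 controls, 18 + 17 patients with exact
male counts 17/10/9), with clinical covariates at the scale of published
unilateral-MTLE case series (onset
12.5 ± 6.7 vs 14.5 ± 5.6 y, duration 25.5 ± 9.3 vs 22.9 ± 7.7 y, seizure
frequency 1.09 ± 1.31 vs 1.56 ± 1.73 per month, 2.7 vs 2.4 drug classes).
Group age-matching is enforced by sorted-interleaved assignment from a
pooled draw, so group means agree within fractions of a year by
construction.

Each cell value is an exact polynomial in age plus noise:

    value = baseline(t,s,k) + slope(t,s,k)·age + curvature(t,k)·age²
          + sex_offset(t,k)·[M] + latent + subject(t,k) + step(t,s,k)

* Baselines are 3-harmonic cosine series over steps around index-typical
  levels (GFA 0.45, AD 1.25, RD 0.55, MD 0.80, NG 0.45, NGO 0.30, NGP 0.40),
  smooth like real tract profiles.
* Age slopes carry canonical aging directions (diffusivities up; anisotropy
  and non-Gaussianity down), magnitudes 0.002–0.006 per year with about a
  third of cells flat (so the age weights are informative), modulated along
  the tract so mid-bundle steps carry most age signal (so the weighting is
  non-trivial).
* Twelve shared latent factors (N(0,1) scores × fixed N(0,1) loadings,
  scale 0.018) emulate the strong low-rank covariation of real tract
  features; without them compression would have nothing real to compress.
* Noise defaults: subject random effect SD 0.04 per tract×index, step noise
  SD 0.04. The population structure (baselines, slopes, loadings) is frozen
  under a fixed internal seed and shared by all cohorts; per-cohort seeds
  control only subject-level randomness, and identical (config, seed) is
  bit-identical.

Disease effects (`inject_lesion`) shift every step of selected tracts by
`delta_k × severity × population_SD`, where severity is a deterministic
non-negative linear function of age of onset (earlier → worse), illness
duration and seizure frequency. The default topography targets UF_R,
FS_OFC_R, IFOF_L, ILF_L and PerpF_R with deltas RD +1.0, MD +0.9, AD +0.4,
GFA −0.8, NGP −0.5 (the canonical degeneration pattern, aligned with the
generator's aging directions so lesions read as "older"). The default
coupling uses case-series-scale coefficients; `strong_lesion_spec()` raises the
seizure-frequency coupling to 3.0 severity units per seizure/month and is
the setting under which the recovery tests operate (pilot-measured PAD
response: roughly 0.8 years per severity unit).

**What the generator does not emulate.** Real acquisition artifacts, site
effects, heteroscedastic or non-Gaussian noise, spatially correlated step
noise within a tract, nonlinear age trajectories beyond quadratic,
lesion effects that vary along a tract, and any coupling between brain and
covariates other than the specified lesion model. Passing tests therefore
demonstrate that the implementation recovers the parameters of *this* model
class at realistic sample sizes — not that the method is robust to the
messiness of real diffusion MRI.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the staged pipeline
derives per-stage seeds from one global seed through a documented
SeedSequence/CRC32 scheme, and a rerun with the same config reproduces every
CSV artifact byte for byte. The test suite runs the full-scale study
(300/40/524/37/18/17) once per session and reuses the trained stack;
simulation-based checks use 100 replicates for lesion/clinical recovery and
power, 200 for false-discovery calibration, 2000 held-out subjects for
normative calibration, and scaled-down cohorts for the pipeline/CLI
round-trip tests — sizes chosen as the smallest at which the targeted
effects are comfortably resolvable.

## Known limitations

* The 76-tract registry is a plausible reconstruction of an atlas that is
  not publicly enumerated; names, not anatomy, are what the package defines.
* CV of the GPR stage inherits whatever optimism the upstream full-training
  encoder fit introduces (see above); compare against the test-set metrics.
* The normative σ model assumes log-linear-in-(1, age, age²) dispersion;
  strongly heteroscedastic data should use the windowed alternative.
* The bootstrap keeps the Pearson/Spearman choice fixed across replicates;
  method uncertainty is not propagated into the CI.
* With 17-subject patient groups the clinical-correlation analyses are
  power-limited at realistic couplings, exactly as the worked example shows.
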