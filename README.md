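# tractage

White-matter brain age from along-tract diffusion profiles.

`tractage` is a tested, reusable implementation of a white-matter brain-age
analysis for researchers who work with tractometry: it takes per-subject
**3-D connectograms** — diffusion-index values sampled along 76 predefined
white matter tract bundles (100 normalized steps per tract, 7 indices: GFA,
AD, RD, MD, NG, NGO, NGP) — and produces predicted brain age, **PAD**
(predicted age difference) scores, normative z-score deviation maps,
tract-level attribution of PAD, and confound-adjusted clinical correlations.
Because tract-profile datasets of this kind are rarely shareable, the package
ships a first-class synthetic cohort generator with the statistical structure
the analysis assumes (age trends, sex offsets, shared latent variation,
injectable tract-specific disease effects), so the entire pipeline is
reproducible end to end without any data download.

## The model

1. **Feature pipeline.** Each 100-step profile is smoothed with a normalized
   1-D Gaussian kernel; each (tract, step, index) cell is standardized with
   training-cohort statistics that are then frozen; a per-cell GLM
   `value ~ 1 + age + age²` gives the model F-test p-value and the step
   weight `w_s = −log₁₀ p_s`; each tract×index profile collapses to its
   weighted average, yielding **532 = 76 × 7** features per subject.
2. **Compression.** A single-hidden-layer sparse autoencoder
   (sigmoid hidden layer, linear output, loss
   `MSE + β·KL(ρ‖ρ̂) + λ‖W‖²`, full-batch quasi-Newton optimization)
   compresses 532 features to **179** compact features; the reconstruction
   rate is variance-explained percent, `100·(1 − Σ‖x−x̂‖²/Σ‖x−x̄‖²)`.
3. **Brain age.** Gaussian-process regression of age on compact features +
   sex, kernel `σ²·RBF(ℓ) + σₙ²·δ`, hyperparameters by seeded marginal-
   likelihood maximization. `PAD = predicted − chronological age`; model
   quality is Pearson *r*, RMSE and MAE from pooled out-of-fold predictions
   of a seeded 10-fold cross-validation and from an independent test set.
4. **Normative model.** Per sex and per tract×index feature, quadratic-in-age
   population mean μ(age) and dispersion σ(age) fitted on a healthy cohort;
   a subject's deviation is `z = (x − μ_sex(age)) / σ_sex(age)`.
5. **Group analysis.** ANCOVA of PAD over study groups (controlling age, sex,
   handedness) with Bonferroni-corrected Welch t tests post hoc; one-sample
   t tests of each z cell with Benjamini–Hochberg adjustment and effect size
   `d = mean(z)/SD(z)`; the top 5% of cells by |d| (ceil(0.05·532) = 27)
   enter a PCA whose first component is regressed on PAD and decomposed into
   tract/index contribution percentages (squared loadings); clinical
   variables correlate with PAD after OLS residualization on age, sex and
   drug-class count, Pearson or Spearman by a Shapiro–Wilk normality gate,
   with percentile-bootstrap confidence intervals.

## Worked example

The snippet below builds the full study at its default scale (300 training,
40 test, 524 normative subjects; 37 controls and 18 + 17 patients with
lesions injected into five tracts of the right-lateralized group) and runs
the complete analysis (a few minutes on one CPU):

```python
import numpy as np
import tractage as ta
from tractage.age_model import add_sex_feature, compute_metrics, cross_validate_10fold
from tractage.analysis import (ancova_pad, bootstrap_correlation,
                               mass_univariate_z, pca_attribution,
                               select_top_features)
from tractage.preprocess import TractFeaturePipeline

suite = ta.make_study_suite(seed=1)
train_c, train_t = suite["train"]

pipe = TractFeaturePipeline().fit(train_c, train_t["age"].to_numpy())
F = {g: pipe.transform(c) for g, (c, _) in suite.items()}
enc = ta.SparseAutoencoder(random_state=0).fit(F["train"])
X = {g: add_sex_feature(enc.transform(F[g]), t["sex"].to_numpy())
     for g, (_, t) in suite.items()}

ages = train_t["age"].to_numpy()
model = ta.BrainAgeModel(random_state=0).fit(X["train"], ages)
cv, _ = cross_validate_10fold(X["train"], ages, seed=11)
test = compute_metrics(suite["test"][1]["age"], model.predict(X["test"]))
# ... PAD per group, ANCOVA, normative z-scores, attribution, correlations
```

Running the full script (`docs/` shows each step) prints:

```
feature width: 532, compact width: 179
encoder reconstruction rate: 86.5%
10-fold CV:  r=0.998  RMSE=1.28 y  MAE=1.02 y
test set:    r=0.986  RMSE=4.25 y  MAE=3.24 y
control  mean PAD = +0.52 y (SD 2.46)
lmtle    mean PAD = +2.24 y (SD 2.60)
rmtle    mean PAD = +4.11 y (SD 3.25)
ANCOVA group effect: F(2,66) = 12.76, p = 2.1e-05
selected features: 27; PC1 explains 64.7% of their variance; PAD ~ PC1 R^2 = 0.00
top tract contributions: PerpF_R 25.4%, ILF_L 22.5%, FS_OFC_R 19.7%
PAD ~ seizure frequency (pearson): r = 0.31, p = 0.226, 95% CI [-0.36, 0.78]
```

Reading the numbers: every subject is reduced to 532 tract features and
compressed to 179; the age model generalizes to the held-out test set with a
3.2-year MAE; the control group's mean PAD sits near zero while the strongly
lesioned group is ~4 years "older" than its chronological age, a group
difference the ANCOVA detects decisively; and the PCA attribution points at
tracts that were actually lesioned by the generator (PerpF_R, ILF_L,
FS_OFC_R, plus UF_R and IFOF_L further down the table). At the default
Table-1-scale clinical coupling the seizure-frequency correlation is positive
but not individually significant at n = 17; the strong-coupling setting used
in the recovery tests produces confidence intervals that exclude zero.

## Command line

The same pipeline runs as staged shell commands against a run directory,
with a YAML config, per-stage artifacts (long-format connectogram TSVs,
feature/prediction/z-score CSVs, JSON reports) and config-hash guards:

```bash
tractage all --config demo.yaml --out run/        # simulate ... report
tractage simulate --out run/                      # or stage by stage
tractage preprocess --out run/
...
tractage report --out run/ --figures
```

Each artifact records the hash of the config that produced it; rerunning
with the same config and seed reproduces every CSV byte for byte.

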