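import warnings; warnings.filterwarnings("ignore")
import numpy as np
import tractage as ta
from tractage.age_model import add_sex_feature, compute_metrics, cross_validate_10fold
from tractage.analysis import (ancova_pad, bootstrap_correlation,
                               mass_univariate_z, pca_attribution,
                               select_top_features)
from tractage.preprocess import TractFeaturePipeline

# 1. Synthetic study: 300 training / 40 test / 524 normative subjects plus
#    age- and sex-matched study groups (37 controls, 18 + 17 patients).
suite = ta.make_study_suite(seed=1)
train_c, train_t = suite["train"]

# 2. Feature pipeline: smoothing -> frozen normalization -> -log10(p) age
#    weights -> 532 tract features; then 532 -> 179 sparse autoencoder.
pipe = TractFeaturePipeline().fit(train_c, train_t["age"].to_numpy())
F = {g: pipe.transform(c) for g, (c, _) in suite.items()}
enc = ta.SparseAutoencoder(random_state=0).fit(F["train"])
X = {g: add_sex_feature(enc.transform(F[g]), t["sex"].to_numpy())
     for g, (_, t) in suite.items()}
print(f"feature width: {F['train'].shape[1]}, compact width: {enc.transform(F['train']).shape[1]}")
print(f"encoder reconstruction rate: {enc.reconstruction_rate_:.1f}%")

# 3. GPR brain-age model: 10-fold CV and independent test set.
ages = train_t["age"].to_numpy()
model = ta.BrainAgeModel(random_state=0).fit(X["train"], ages)
cv, _ = cross_validate_10fold(X["train"], ages, seed=11)
test = compute_metrics(suite["test"][1]["age"], model.predict(X["test"]))
print(f"10-fold CV:  r={cv.r:.3f}  RMSE={cv.rmse:.2f} y  MAE={cv.mae:.2f} y")
print(f"test set:    r={test.r:.3f}  RMSE={test.rmse:.2f} y  MAE={test.mae:.2f} y")

# 4. PAD per study group and the ANCOVA group test.
pad, meta = {}, {}
for g in ("control", "lmtle", "rmtle"):
    table = suite[g][1]
    pad[g] = model.predict(X[g]) - table["age"].to_numpy()
    meta[g] = table
    print(f"{g:8s} mean PAD = {pad[g].mean():+.2f} y (SD {pad[g].std(ddof=1):.2f})")
pads = np.concatenate([pad[g] for g in ("control", "lmtle", "rmtle")])
groups = np.concatenate([[g] * len(pad[g]) for g in ("control", "lmtle", "rmtle")])
cov = np.concatenate([np.column_stack([m["age"], m["sex"] == "M", m["handedness"]])
                      for m in meta.values()]).astype(float)
fstat, p, df = ancova_pad(pads, groups, cov)
print(f"ANCOVA group effect: F({df[0]},{df[1]}) = {fstat:.2f}, p = {p:.2g}")

# 5. Normative z-scores, top-5% selection, PC1 attribution (rmtle group).
norm_t = suite["normative"][1]
nm = ta.NormativeModel().fit(F["normative"], norm_t["age"].to_numpy(), norm_t["sex"].to_numpy())
t_r = meta["rmtle"]
Z = nm.zscore(F["rmtle"], t_r["age"].to_numpy(), t_r["sex"].to_numpy())
grid = mass_univariate_z(Z)
sel = select_top_features(grid, 0.05)
names = ta.feature_names()
att = pca_attribution(Z[:, [names.index(s) for s in sel]], pad["rmtle"], sel)
print(f"selected features: {len(sel)}; PC1 explains {att.variance_explained_pc1:.1f}% "
      f"of their variance; PAD ~ PC1 R^2 = {att.regression_r2:.2f}")
top = ", ".join(f"{t} {v:.1f}%" for t, v in att.tract_contributions.head(3).items())
print(f"top tract contributions: {top}")

# 6. Confound-adjusted clinical correlation with bootstrap CI.
conf = np.column_stack([t_r["age"], t_r["sex"] == "M", t_r["n_aed_classes"]]).astype(float)
res = bootstrap_correlation(pad["rmtle"], t_r["seizure_frequency"].to_numpy(),
                            conf, n_boot=2000, seed=0, variable="seizure_frequency")
print(f"PAD ~ seizure frequency ({res.method}): r = {res.r:.2f}, p = {res.p:.3g}, "
      f"95% CI [{res.ci_lower:.2f}, {res.ci_upper:.2f}]")
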