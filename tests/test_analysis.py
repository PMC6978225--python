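"""Group statistics against independent oracles: explicit linear-algebra
ANCOVA, closed-form Welch df, eigendecomposition PCA, pingouin partial
correlations, and calibration/power simulations on plain numbers."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import statsmodels.api as sm
from scipy import stats

from tractage.analysis import (
    AnalysisError,
    ancova_pad,
    bootstrap_correlation,
    clinical_correlation,
    mass_univariate_z,
    pca_attribution,
    posthoc_pairwise,
    select_top_features,
)
from tractage.registry import N_FEATURES, feature_names


# ------------------------------------------------------------------- ANCOVA

def test_identical_groups_give_zero_f(rng):
    pads = np.tile(rng.normal(size=10), 3)
    groups = np.repeat(["a", "b", "c"], 10)
    cov = np.tile(rng.normal(size=(10, 2)), (3, 1))
    f, p, df = ancova_pad(pads, groups, cov)
    assert f == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_ancova_matches_statsmodels_oracle(rng):
    n = 30
    groups = rng.choice(["a", "b", "c"], n)
    cov = rng.normal(size=(n, 3))
    pads = rng.normal(size=n) + (groups == "b") * 1.5 + cov[:, 0]
    f, p, df = ancova_pad(pads, groups, cov)

    frame = pd.DataFrame(cov, columns=["age", "sex", "hand"])
    frame["pad"] = pads
    frame["group"] = groups
    full = sm.OLS.from_formula("pad ~ age + sex + hand + C(group)", frame).fit()
    reduced = sm.OLS.from_formula("pad ~ age + sex + hand", frame).fit()
    f_sm, p_sm, df_sm = full.compare_f_test(reduced)
    assert f == pytest.approx(f_sm, abs=1e-10)
    assert p == pytest.approx(p_sm, abs=1e-10)
    assert df == (2, n - 3 - 3)


def test_ancova_power_detects_ten_year_shift():
    """A +10 y PAD shift in one 17-subject group is detected at p < 0.05 in
    nearly every seeded replicate."""
    hits = 0
    reps = 100
    for rep in range(reps):
        rng = np.random.default_rng(3000 + rep)
        n = (37, 18, 17)
        pads = np.concatenate([
            rng.normal(0, 6, n[0]), rng.normal(0, 6, n[1]),
            rng.normal(10, 6, n[2]),
        ])
        groups = np.repeat(["control", "lmtle", "rmtle"], n)
        cov = np.column_stack([
            rng.normal(38, 8, sum(n)), rng.integers(0, 2, sum(n)),
            rng.normal(90, 20, sum(n)),
        ])
        _, p, _ = ancova_pad(pads, groups, cov)
        hits += p < 0.05
    assert hits >= 95


def test_rank_deficient_design_rejected(rng):
    pads = rng.normal(size=20)
    groups = np.repeat(["a", "b"], 10)
    cov = np.column_stack([np.ones(20), np.ones(20)])
    with pytest.raises(AnalysisError, match="rank-deficient"):
        ancova_pad(pads, groups, cov)


# ------------------------------------------------------------------ post hoc

def test_identical_groups_posthoc_is_null(rng):
    x = rng.normal(size=12)
    pads = np.concatenate([x, x, x])
    groups = np.repeat(["a", "b", "c"], 12)
    table = posthoc_pairwise(pads, groups)
    assert np.allclose(table["t"], 0.0)
    assert np.allclose(table["p_bonferroni"], 1.0)


def test_bonferroni_is_multiplication_capped_at_one(rng):
    pads = rng.normal(size=30) + np.repeat([0, 0.5, 3.0], 10)
    groups = np.repeat(["a", "b", "c"], 10)
    table = posthoc_pairwise(pads, groups)
    np.testing.assert_allclose(
        table["p_bonferroni"], np.minimum(1.0, table["p_raw"] * 3), atol=1e-15
    )
    assert 0.02 * 3 == pytest.approx(0.06)


def test_welch_df_matches_closed_form(rng):
    a = rng.normal(0, 1, 5)
    b = rng.normal(1, 4, 5)
    table = posthoc_pairwise(np.concatenate([a, b]), np.repeat(["a", "b"], 5))
    va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
    df_ws = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
    assert table["df"].iloc[0] == pytest.approx(df_ws, abs=1e-10)


# ----------------------------------------------------------- mass univariate

def test_mass_univariate_against_scipy_oracle(rng):
    Z = rng.normal(0.3, 1.0, size=(15, N_FEATURES))
    grid = mass_univariate_z(Z)
    t_ref, p_ref = stats.ttest_1samp(Z, 0.0)
    np.testing.assert_allclose(grid["t"], t_ref, atol=1e-10)
    np.testing.assert_allclose(grid["p"], p_ref, atol=1e-10)
    d_ref = Z.mean(0) / Z.std(0, ddof=1)
    np.testing.assert_allclose(grid["d"], d_ref, atol=1e-12)


def test_degenerate_cells_flagged(rng):
    Z = rng.normal(size=(4, N_FEATURES))
    Z[:, 0] = 2.0            # {2,2,2,2}: zero SD -> undefined d
    Z[:, 1] = 0.0            # all-zero cell: t = 0, not significant
    grid = mass_univariate_z(Z)
    assert grid.loc[0, "degenerate"] and np.isnan(grid.loc[0, "d"])
    assert not grid.loc[0, "significant"]
    assert grid.loc[1, "t"] == 0.0 and not grid.loc[1, "significant"]


def test_bonferroni_option_is_more_conservative(rng):
    Z = rng.normal(0.8, 1.0, size=(20, N_FEATURES))
    bh = mass_univariate_z(Z, method="fdr_bh")
    bonf = mass_univariate_z(Z, method="bonferroni")
    assert bonf["significant"].sum() <= bh["significant"].sum()


# ------------------------------------------------------------------ selection

def test_top_fraction_counts():
    names = feature_names()
    grid = pd.DataFrame({"feature": names, "d": np.linspace(2, 0.1, len(names)),
                         "significant": True})
    assert len(select_top_features(grid, 0.05)) == 27
    small = grid.iloc[:100].reset_index(drop=True)
    assert len(select_top_features(small, 0.05)) == 5
    with pytest.raises(AnalysisError, match="fraction"):
        select_top_features(grid, 0.0)


def test_ties_break_in_canonical_order():
    names = feature_names()[:10]
    grid = pd.DataFrame({"feature": names, "d": 1.0, "significant": True})
    assert select_top_features(grid, 0.3) == names[:3]


def test_selection_ranks_by_absolute_effect_size(rng):
    names = feature_names()[:20]
    d = rng.normal(0, 1, 20)
    grid = pd.DataFrame({"feature": names, "d": d, "significant": True})
    top = select_top_features(grid, 0.1)
    expected = [names[i] for i in np.argsort(-np.abs(d), kind="stable")[:2]]
    assert top == expected


# ---------------------------------------------------------------------- PCA

def test_single_feature_contribution_is_total(rng):
    z = rng.normal(size=(10, 1))
    pads = 2.0 * z[:, 0] + 1.0
    att = pca_attribution(z, pads, ["UF_R:RD"])
    assert att.tract_contributions["UF_R"] == pytest.approx(100.0)
    assert att.index_contributions["RD"] == pytest.approx(100.0)


def test_equal_loadings_split_fifty_fifty(rng):
    s = rng.normal(size=12)
    z = np.column_stack([s, s])
    att = pca_attribution(z, s, ["UF_R:RD", "ILF_L:MD"])
    assert att.tract_contributions["UF_R"] == pytest.approx(50.0, abs=1e-9)
    assert att.tract_contributions["ILF_L"] == pytest.approx(50.0, abs=1e-9)


def test_exact_linear_pad_gives_unit_r2(rng):
    z = rng.normal(size=(12, 4))
    names = feature_names()[:4]
    att0 = pca_attribution(z, rng.normal(size=12), names)
    pads = 3.0 * att0.pc1_scores + 7.0
    att = pca_attribution(z, pads, names)
    assert att.regression_r2 == pytest.approx(1.0, abs=1e-12)
    assert att.regression_p < 1e-10


def test_pca_matches_eigendecomposition_oracle(rng):
    z = rng.normal(size=(6, 4))
    names = feature_names()[:4]
    att = pca_attribution(z, rng.normal(size=6), names)
    cov = np.cov(z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    lead = evecs[:, -1]
    if np.dot(lead, att.pc1_loadings) < 0:
        lead = -lead
    np.testing.assert_allclose(att.pc1_loadings, lead, atol=1e-10)
    np.testing.assert_allclose(att.variance_explained_pc1,
                               100 * evals[-1] / evals.sum(), atol=1e-10)
    assert np.linalg.norm(att.pc1_loadings) == pytest.approx(1.0, abs=1e-12)
    assert att.tract_contributions.sum() == pytest.approx(100.0, abs=0.1)
    assert att.index_contributions.sum() == pytest.approx(100.0, abs=0.1)


def test_pc1_sign_oriented_toward_positive_pad_slope(rng):
    z = rng.normal(size=(15, 3))
    names = feature_names()[:3]
    att0 = pca_attribution(z, rng.normal(size=15), names)
    pads = -2.0 * att0.pc1_scores + rng.normal(0, 0.1, 15)
    att = pca_attribution(z, pads, names)
    slope = np.polyfit(att.pc1_scores, pads, 1)[0]
    assert slope > 0


# ------------------------------------------------------------- correlations

def test_no_confounders_equals_plain_correlation(rng):
    pads = rng.normal(size=40)
    clin = 0.5 * pads + rng.normal(0, 1, 40)
    res = clinical_correlation(pads, clin)
    if res.method == "pearson":
        ref = stats.pearsonr(pads, clin)
    else:
        ref = stats.spearmanr(pads, clin)
    assert res.r == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_partial_correlation_matches_pingouin(rng):
    n = 40
    age = rng.normal(40, 10, n)
    sex = rng.integers(0, 2, n).astype(float)
    pads = 0.3 * age + rng.normal(0, 3, n)
    clin = -0.2 * age + 0.5 * pads + rng.normal(0, 2, n)
    conf = np.column_stack([age, sex])
    res = clinical_correlation(pads, clin, conf)
    frame = pd.DataFrame({"pad": pads, "clin": clin, "age": age, "sex": sex})
    ref = pg.partial_corr(frame, x="pad", y="clin", covar=["age", "sex"],
                          method=res.method)
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)


def test_confounder_driven_variable_has_null_partial_correlation(rng):
    n = 200
    age = rng.normal(40, 10, n)
    pads = rng.normal(0, 4, n) + 0.2 * age
    clin = 2.0 * age + 5.0           # exact function of the confounder
    res = clinical_correlation(pads, clin, age)
    assert abs(res.r) < 0.05


def test_spearman_branch_invariant_under_monotone_transform(rng):
    pads = rng.normal(size=30)
    clin = np.exp(rng.normal(size=30) * 2)       # heavy-tailed -> spearman
    res = clinical_correlation(pads, clin)
    res_t = clinical_correlation(pads, np.log(clin))
    if res.method == "spearman" and res_t.method == "spearman":
        assert res.r == pytest.approx(res_t.r, abs=1e-12)


def test_constant_clinical_variable_rejected(rng):
    with pytest.raises(AnalysisError, match="constant"):
        clinical_correlation(rng.normal(size=10), np.full(10, 2.0))


def test_outlier_rule_excludes_extreme_points(rng):
    pads = rng.normal(size=30)
    clin = rng.normal(size=30)
    clin[0] = 50.0
    res = clinical_correlation(pads, clin, outlier_sd=2.5)
    assert res.n == 29


# ---------------------------------------------------------------- bootstrap

def test_collinear_data_gives_degenerate_ci(rng):
    pads = rng.normal(size=20)
    res = bootstrap_correlation(pads, pads.copy(), n_boot=200, seed=1)
    assert res.ci_lower == pytest.approx(1.0)
    assert res.ci_upper == pytest.approx(1.0)


def test_bootstrap_is_seed_deterministic(rng):
    pads = rng.normal(size=25)
    clin = 0.5 * pads + rng.normal(0, 1, 25)
    a = bootstrap_correlation(pads, clin, n_boot=500, seed=9)
    b = bootstrap_correlation(pads, clin, n_boot=500, seed=9)
    assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)


def test_bootstrap_ci_is_monte_carlo_stable(rng):
    n = 30
    age = rng.normal(40, 8, n)
    pads = rng.normal(0, 3, n) + 0.2 * age
    clin = 0.6 * pads + rng.normal(0, 2, n)
    a = bootstrap_correlation(pads, clin, age, n_boot=10_000, seed=1)
    b = bootstrap_correlation(pads, clin, age, n_boot=10_000, seed=2)
    assert abs(a.ci_lower - b.ci_lower) < 0.02
    assert abs(a.ci_upper - b.ci_upper) < 0.02
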