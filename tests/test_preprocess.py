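"""Feature pipeline: smoothing against a brute-force convolution oracle,
frozen normalization, -log10(p) age weights, and the 532-feature reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tractage.preprocess import (
    PreprocessError,
    TractFeaturePipeline,
    _ols_age_ftest,
    apply_normalization,
    compute_age_weights,
    fit_step_normalization,
    reduce_to_features,
    smooth_profiles,
)
from tractage.registry import N_FEATURES, N_INDICES, N_STEPS, N_TRACTS
from tractage.simulate import default_config, generate_cohort


def _values(rng, n=3):
    return rng.normal(0.5, 0.1, (n, N_TRACTS, N_STEPS, N_INDICES))


# --------------------------------------------------------------------- smooth

def test_sigma_zero_is_identity(rng):
    x = _values(rng)
    assert np.array_equal(smooth_profiles(x, sigma=0.0), x)


def test_constant_profile_preserved():
    x = np.full((1, N_TRACTS, N_STEPS, N_INDICES), 3.7)
    np.testing.assert_allclose(smooth_profiles(x, sigma=2.0), 3.7, rtol=0, atol=1e-12)


def _brute_force_gaussian(profile, sigma, truncate, mode):
    """Direct discrete convolution with an explicit double loop."""
    radius = int(truncate * sigma + 0.5)
    kernel = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    kernel /= kernel.sum()
    pad_mode = {"reflect": "symmetric", "nearest": "edge"}[mode]
    padded = np.pad(profile, radius, mode=pad_mode)
    out = np.zeros_like(profile)
    for i in range(len(profile)):
        for j, w in enumerate(kernel):
            out[i] += w * padded[i + j]
    return out


@pytest.mark.parametrize("mode", ["reflect", "nearest"])
def test_smoothing_matches_brute_force_convolution(mode):
    profile = np.zeros(N_STEPS)
    profile[50] = 1.0                      # unit impulse at step 50
    x = np.zeros((1, N_TRACTS, N_STEPS, N_INDICES))
    x[0, 0, :, 0] = profile
    smoothed = smooth_profiles(x, sigma=2.0, truncate=3.0, boundary_mode=mode)
    expected = _brute_force_gaussian(profile, 2.0, 3.0, mode)
    np.testing.assert_allclose(smoothed[0, 0, :, 0], expected, atol=1e-12)


def test_negative_sigma_rejected(rng):
    with pytest.raises(PreprocessError, match="smooth_sigma"):
        smooth_profiles(_values(rng), sigma=-1.0)


# ---------------------------------------------------------------- normalize

def test_sample_statistics_of_small_cohort():
    x = np.zeros((3, N_TRACTS, N_STEPS, N_INDICES))
    x[0], x[1], x[2] = 1.0, 2.0, 3.0
    norm = fit_step_normalization(x)
    assert np.all(norm.mean == 2.0)
    assert np.all(norm.sd == 1.0)          # sample SD of {1,2,3}
    assert not norm.degenerate.any()


def test_identical_subjects_flag_all_cells_degenerate(rng):
    x = np.repeat(_values(rng, 1), 4, axis=0)
    norm = fit_step_normalization(x)
    assert norm.degenerate.all()
    with pytest.raises(PreprocessError, match="degenerate cell"):
        apply_normalization(x, norm)
    z = apply_normalization(x, norm, epsilon=1.0)    # epsilon substitution
    np.testing.assert_allclose(z, 0.0, atol=1e-12)


def test_training_set_self_normalizes_to_unit_moments(rng):
    x = _values(rng, n=20)
    norm = fit_step_normalization(x)
    z = apply_normalization(x, norm)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_normalization_is_exactly_invertible_across_cohorts(rng):
    stats_a = fit_step_normalization(_values(rng, 10))
    cohort_b = _values(rng, 5)
    z = apply_normalization(cohort_b, stats_a)
    np.testing.assert_allclose(stats_a.inverse(z), cohort_b, atol=1e-12)


# ------------------------------------------------------------------- weights

def test_raw_weights_are_minus_log10_p(rng):
    x = _values(rng, n=30)
    ages = rng.uniform(20, 80, 30)
    w = compute_age_weights(x, ages, normalize_weights=False)
    np.testing.assert_allclose(w.raw, -np.log10(w.p_value), atol=1e-12)
    assert np.all(w.raw >= 0) and np.all(np.isfinite(w.raw))


def test_pvalue_floor_caps_raw_weight(rng):
    x = _values(rng, n=30)
    ages = rng.uniform(20, 80, 30)
    x[:, 0, 0, 0] = 10.0 * ages            # p underflows the floor
    w = compute_age_weights(x, ages, pvalue_floor=1e-300, normalize_weights=False)
    assert w.raw[0, 0, 0] == pytest.approx(300.0)
    # floor arithmetic directly: p = 0.1 -> 1.0, p = 0.01 -> 2.0
    assert -np.log10(max(0.1, 1e-300)) == pytest.approx(1.0)
    assert -np.log10(max(0.01, 1e-300)) == pytest.approx(2.0)


def test_normalized_weights_sum_to_one(rng):
    x = _values(rng, n=25)
    ages = rng.uniform(20, 80, 25)
    w = compute_age_weights(x, ages, normalize_weights=True)
    np.testing.assert_allclose(w.weights.sum(axis=1), 1.0, atol=1e-9)


def test_constant_ages_are_singular(rng):
    with pytest.raises(PreprocessError, match="singular|constant"):
        compute_age_weights(_values(rng, 10), np.full(10, 40.0))


def test_age_informative_step_outweighs_flat_step():
    """A step with a strong age slope earns a larger -log10(p) weight than a
    flat step of the same tract, replicate after replicate."""
    slopes = np.zeros((N_TRACTS, N_STEPS, N_INDICES))
    slopes[0, 10, 0] = 0.02                 # step 10 ages, step 50 does not
    wins = 0
    for rep in range(5):
        cfg = default_config(200, seed=100 + rep, age_slopes=slopes,
                             subject_sd=0.0, step_sd=0.05, latent_sd=0.0)
        connectograms, table = generate_cohort(cfg)
        x = np.stack([c.values for c in connectograms])
        norm = fit_step_normalization(x)
        z = apply_normalization(x, norm)
        w = compute_age_weights(z, table["age"].to_numpy())
        wins += w.raw[0, 10, 0] > w.raw[0, 50, 0]
    assert wins == 5


def test_f_test_p_matches_permutation_p():
    """The parametric F-test p agrees with a permutation p at small n."""
    rng = np.random.default_rng(42)
    n = 20
    ages = rng.uniform(20, 80, n)
    y = 0.004 * ages + rng.normal(0, 0.3, n)   # weak signal, moderate p
    _, f_obs, p_param = _ols_age_ftest(ages, y[:, None])
    n_perm = 5000
    perm_rng = np.random.default_rng(1)
    count = 0
    for _ in range(n_perm):
        _, f_perm, _ = _ols_age_ftest(perm_rng.permutation(ages), y[:, None])
        count += f_perm[0] >= f_obs[0]
    p_perm = (count + 1) / (n_perm + 1)
    mc_se = np.sqrt(p_param[0] * (1 - p_param[0]) / n_perm)
    assert abs(p_perm - p_param[0]) < 4 * mc_se + 0.01


# -------------------------------------------------------------------- reduce

def test_uniform_weights_give_plain_mean(rng):
    from tractage.preprocess import StepWeights
    x = _values(rng, 2)
    w = np.full((N_TRACTS, N_STEPS, N_INDICES), 1.0 / N_STEPS)
    weights = StepWeights(raw=w, weights=w, f_stat=w, p_value=w, coef=None,
                          normalized=True)
    feats = reduce_to_features(x, weights)
    assert feats.shape == (2, N_FEATURES)
    expected = x.mean(axis=2).reshape(2, -1)
    np.testing.assert_allclose(feats, expected, atol=1e-12)


def test_point_mass_weight_selects_single_step(rng):
    from tractage.preprocess import StepWeights
    x = _values(rng, 1)
    w = np.zeros((N_TRACTS, N_STEPS, N_INDICES))
    w[:, 17, :] = 1.0
    weights = StepWeights(raw=w, weights=w, f_stat=w, p_value=w, coef=None,
                          normalized=True)
    feats = reduce_to_features(x, weights)
    np.testing.assert_allclose(feats[0], x[0, :, 17, :].ravel(), atol=1e-12)


def test_all_zero_weight_cell_rejected(rng):
    from tractage.preprocess import StepWeights
    x = _values(rng, 1)
    w = np.full((N_TRACTS, N_STEPS, N_INDICES), 0.01)
    w[3, :, 2] = 0.0
    weights = StepWeights(raw=w, weights=w, f_stat=w, p_value=w, coef=None,
                          normalized=False)
    with pytest.raises(PreprocessError, match="all-zero weight"):
        reduce_to_features(x, weights)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_weighted_average_matches_dot_product_oracle(seed):
    """reduce_to_features equals an explicit per-cell dot product."""
    from tractage.preprocess import StepWeights
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2, N_TRACTS, N_STEPS, N_INDICES))
    w = rng.uniform(0.01, 1.0, (N_TRACTS, N_STEPS, N_INDICES))
    weights = StepWeights(raw=w, weights=w, f_stat=w, p_value=w, coef=None,
                          normalized=False)
    feats = reduce_to_features(x, weights)
    for t, k in [(0, 0), (33, 4), (75, 6)]:
        expected = x[:, t, :, k] @ w[t, :, k] / w[t, :, k].sum()
        np.testing.assert_allclose(feats[:, t * N_INDICES + k], expected,
                                   atol=1e-12)


# ------------------------------------------------------------------ pipeline

def test_pipeline_output_is_order_stable(fitted_pipeline, study_suite):
    connectograms, _ = study_suite["test"]
    feats = fitted_pipeline.transform(connectograms)
    reordered = fitted_pipeline.transform(connectograms[::-1])
    np.testing.assert_allclose(reordered, feats[::-1], atol=0)


def test_transform_is_per_subject(fitted_pipeline, study_suite):
    """Frozen statistics: a subject's features do not depend on who else is
    in the transformed batch."""
    connectograms, _ = study_suite["test"]
    batch = fitted_pipeline.transform(connectograms[:5])
    single = fitted_pipeline.transform([connectograms[2]])
    np.testing.assert_allclose(single[0], batch[2], atol=0)


def test_feature_names_and_width(fitted_pipeline):
    names = fitted_pipeline.get_feature_names_out()
    assert len(names) == 532
    assert names[0] == "AF_L:GFA" and names[-1] == "CF_hippocampal:NGP"
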