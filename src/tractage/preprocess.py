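"""Feature preprocessing: along-tract smoothing, per-step normalization,
age-association weighting, and reduction to 532 tract features.

The pipeline runs, in order:

1.  **Smoothing** — each 100-step profile is convolved with a normalized
    1-D Gaussian kernel (independently per tract and index), damping local
    sampling variation while preserving constants.
2.  **Normalization** — every (tract, step, index) cell is standardized to
    zero mean and unit variance using statistics estimated on the training
    cohort and frozen for all later cohorts.
3.  **Age weighting** — per cell, an ordinary least-squares fit of the
    normalized value on (1, age, age^2); the model-vs-intercept F test's
    p-value, transformed as w = -log10(p), weights each step by how
    strongly it tracks age.
4.  **Reduction** — per tract and index, the 100 steps are collapsed to a
    single weighted average, yielding 76 x 7 = 532 features per subject.

Training statistics and weights are estimated once on the training cohort
and applied frozen to every other cohort (test, normative, patients), so no
patient data can leak into the feature definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import Connectogram, stack_cohort
from .registry import N_FEATURES, N_INDICES, N_STEPS, N_TRACTS, feature_names


class PreprocessError(ValueError):
    """Invalid preprocessing configuration or degenerate input."""


def _as_values(x) -> np.ndarray:
    """Accept a Connectogram, a list of them, or a 3D/4D array; return a
    float64 array of shape (n, 76, 100, 7)."""
    if isinstance(x, Connectogram):
        return x.values[None]
    if isinstance(x, (list, tuple)) and x and isinstance(x[0], Connectogram):
        return stack_cohort(x)
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1:] != (N_TRACTS, N_STEPS, N_INDICES):
        raise PreprocessError(
            f"expected (n, {N_TRACTS}, {N_STEPS}, {N_INDICES}) values, got {arr.shape}"
        )
    return arr


def smooth_profiles(values, sigma: float = 2.0, truncate: float = 3.0,
                    boundary_mode: str = "reflect") -> np.ndarray:
    """Convolve each along-tract profile with a normalized Gaussian kernel.

    ``sigma`` is in step units; ``sigma=0`` returns the input unchanged.
    The kernel is normalized, so constant profiles are preserved exactly.
    """
    if sigma < 0:
        raise PreprocessError("smooth_sigma must be >= 0")
    if boundary_mode not in ("reflect", "nearest"):
        raise PreprocessError("boundary_mode must be 'reflect' or 'nearest'")
    arr = _as_values(values)
    if sigma == 0:
        return arr.copy()
    return gaussian_filter1d(arr, sigma=sigma, axis=2, mode=boundary_mode,
                             truncate=truncate)


@dataclass
class NormalizationStats:
    """Per-cell training mean/SD (sample SD, n-1 denominator).

    ``degenerate`` flags cells whose training SD is zero; normalizing such
    a cell raises unless an epsilon substitution is configured.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray
    n_subjects: int

    def inverse(self, normalized: np.ndarray, epsilon: float | None = None) -> np.ndarray:
        sd = self._effective_sd(epsilon)
        return normalized * sd + self.mean

    def _effective_sd(self, epsilon: float | None) -> np.ndarray:
        if not self.degenerate.any():
            return self.sd
        if epsilon is None:
            t, s, k = np.argwhere(self.degenerate)[0]
            raise PreprocessError(
                f"degenerate cell (tract {t}, step {s}, index {k}) has zero "
                "training SD; set an epsilon substitution to normalize it"
            )
        return np.where(self.degenerate, epsilon, self.sd)


def fit_step_normalization(training) -> NormalizationStats:
    """Estimate per-cell mean and sample SD over the training subjects."""
    arr = _as_values(training)
    if arr.shape[0] < 2:
        raise PreprocessError("normalization needs at least 2 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return NormalizationStats(mean=mean, sd=sd, degenerate=sd == 0,
                              n_subjects=arr.shape[0])


def apply_normalization(values, stats_: NormalizationStats,
                        epsilon: float | None = None) -> np.ndarray:
    """Standardize values with frozen training statistics."""
    arr = _as_values(values)
    sd = stats_._effective_sd(epsilon)
    return (arr - stats_.mean) / sd


@dataclass
class StepWeights:
    """Per (tract, index), a 100-step weight vector w_s = -log10(p_s).

    ``raw`` holds the unnormalized -log10 p weights; ``weights`` the
    vectors renormalized to sum 1 per tract and index when requested.
    ``f_stat``/``p_value`` retain the underlying per-cell model F tests,
    and ``coef`` the (intercept, beta_age, beta_age2) OLS coefficients.
    """

    raw: np.ndarray
    weights: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    coef: np.ndarray
    normalized: bool


def _ols_age_ftest(ages: np.ndarray, y: np.ndarray):
    """Vectorized OLS of each column of ``y`` on (1, age, age^2) plus the
    model-vs-intercept F test with (2, n-3) degrees of freedom.

    ``y`` has shape (n, m); returns (coef (3, m), F (m,), p (m,)).
    """
    n = ages.shape[0]
    if n < 4:
        raise PreprocessError("age weighting needs at least 4 subjects")
    if np.ptp(ages) == 0:
        raise PreprocessError("singular design: ages are constant")
    X = np.column_stack([np.ones(n), ages, ages**2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise PreprocessError("singular design in age GLM")
    resid = y - X @ coef
    rss1 = np.einsum("ij,ij->j", resid, resid)
    centered = y - y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    df1, df2 = 2, n - 3
    denom = np.where(rss1 > 0, rss1, np.finfo(float).tiny)
    f = ((rss0 - rss1) / df1) / (denom / df2)
    f = np.maximum(f, 0.0)
    p = stats.f.sf(f, df1, df2)
    return coef, f, p


def compute_age_weights(normalized_training, ages, pvalue_floor: float = 1e-300,
                        normalize_weights: bool = True) -> StepWeights:
    """Fit the per-step age GLM on the (normalized) training cohort and turn
    the F-test p-values into -log10 step weights."""
    if not 0.0 < pvalue_floor < 1.0:
        raise PreprocessError("pvalue_floor must be in (0, 1)")
    arr = _as_values(normalized_training)
    ages = np.asarray(ages, dtype=np.float64)
    if ages.shape != (arr.shape[0],):
        raise PreprocessError("ages must match the number of subjects")
    flat = arr.reshape(arr.shape[0], -1)
    coef, f, p = _ols_age_ftest(ages, flat)
    shape = (N_TRACTS, N_STEPS, N_INDICES)
    raw = -np.log10(np.maximum(p, pvalue_floor)).reshape(shape)
    if normalize_weights:
        sums = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            weights = np.where(sums > 0, raw / np.where(sums > 0, sums, 1.0), 0.0)
    else:
        weights = raw.copy()
    return StepWeights(
        raw=raw,
        weights=weights,
        f_stat=f.reshape(shape),
        p_value=p.reshape(shape),
        coef=coef.reshape(3, *shape),
        normalized=normalize_weights,
    )


def reduce_to_features(values, weights: StepWeights) -> np.ndarray:
    """Collapse each tract x index profile to its weighted average.

    Returns an (n, 532) array in canonical tract-major, index-minor order.
    """
    arr = _as_values(values)
    w = weights.weights
    sums = w.sum(axis=1)
    if (sums <= 0).any():
        t, k = np.argwhere(sums <= 0)[0]
        raise PreprocessError(
            f"all-zero weight vector for cell (tract {t}, index {k})"
        )
    feats = np.einsum("ntsk,tsk->ntk", arr, w) / sums[None]
    return feats.reshape(arr.shape[0], N_FEATURES)


class TractFeaturePipeline(BaseEstimator, TransformerMixin):
    """Smoothing + frozen normalization + age weighting + reduction.

    Fit on the training cohort (``X`` = connectograms or a 4D array,
    ``y`` = ages in years); ``transform`` maps any cohort to its (n, 532)
    feature matrix using the frozen training statistics and weights.

    Parameters
    ----------
    smooth_sigma : float, default 2.0
        Gaussian kernel SD in step units (0 disables smoothing).
    kernel_truncation : float, default 3.0
        Kernel support in multiples of sigma.
    boundary_mode : {"reflect", "nearest"}
    pvalue_floor : float, default 1e-300
        Smallest admissible p-value; caps raw weights at -log10(floor).
    normalize_weights : bool, default True
        Renormalize each cell's 100 weights to sum 1 (true weighted mean).
    degenerate_epsilon : float or None
        SD substituted for zero-variance training cells; None raises.
    """

    def __init__(self, smooth_sigma: float = 2.0, kernel_truncation: float = 3.0,
                 boundary_mode: str = "reflect", pvalue_floor: float = 1e-300,
                 normalize_weights: bool = True,
                 degenerate_epsilon: float | None = None):
        self.smooth_sigma = smooth_sigma
        self.kernel_truncation = kernel_truncation
        self.boundary_mode = boundary_mode
        self.pvalue_floor = pvalue_floor
        self.normalize_weights = normalize_weights
        self.degenerate_epsilon = degenerate_epsilon

    def fit(self, X, y=None):
        if y is None:
            raise PreprocessError("fit requires ages as y")
        smoothed = smooth_profiles(X, self.smooth_sigma, self.kernel_truncation,
                                   self.boundary_mode)
        self.norm_stats_ = fit_step_normalization(smoothed)
        normalized = apply_normalization(smoothed, self.norm_stats_,
                                         self.degenerate_epsilon)
        self.step_weights_ = compute_age_weights(
            normalized, y, self.pvalue_floor, self.normalize_weights
        )
        self.feature_names_ = feature_names()
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "step_weights_")
        smoothed = smooth_profiles(X, self.smooth_sigma, self.kernel_truncation,
                                   self.boundary_mode)
        normalized = apply_normalization(smoothed, self.norm_stats_,
                                         self.degenerate_epsilon)
        return reduce_to_features(normalized, self.step_weights_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)
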