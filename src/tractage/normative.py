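"""Age- and sex-conditioned normative model and z-score deviation maps.

For every (tract, index) feature and each sex, the normative cohort defines
a population mean curve mu(age) and dispersion curve sigma(age).  A
subject's feature is converted to a z-score

    z = (x - mu_sex(age)) / sigma_sex(age)

against the age- and sex-matched population; larger |z| means larger
deviation.  The mean is a quadratic-in-age regression per sex.  The default
dispersion model fits a quadratic to log absolute residuals (with the
analytic half-normal bias correction, so that for Gaussian residuals the
back-transformed curve is an unbiased estimate of sigma); the alternative
``"window"`` method takes the SD of residuals inside a sliding +/- w-year
window.  Queries outside the fitted age span raise — no silent
extrapolation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .registry import N_FEATURES, N_INDICES, N_TRACTS

# E[log |Z|] = -(euler_gamma + log 2) / 2 for standard normal Z.
_HALF_NORMAL_LOG_BIAS = 0.5 * (np.euler_gamma + np.log(2.0))

_SEXES = ("F", "M")


class NormativeError(ValueError):
    """Invalid normative-model input."""


class ExtrapolationError(NormativeError):
    """Query age outside the fitted span."""


def _design(ages: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(ages), ages, ages**2])


class NormativeModel(BaseEstimator):
    """Per-sex, per-feature normative mean/SD curves over age.

    Parameters
    ----------
    method : {"loglinear", "window"}
        Dispersion model: quadratic fit to log absolute residuals
        (default) or sliding-window residual SD.
    window_years : float, default 10.0
        Half-width of the sliding window for ``method="window"``.

    Attributes
    ----------
    mu_coef_ : dict sex -> (3, 532) quadratic mean coefficients
    sigma_coef_ : dict sex -> (3, 532) quadratic log-dispersion coefficients
    age_span_ : dict sex -> (min, max) fitted ages
    """

    def __init__(self, method: str = "loglinear", window_years: float = 10.0):
        self.method = method
        self.window_years = window_years

    def fit(self, X, ages, sexes):
        X = np.asarray(X, dtype=np.float64)
        ages = np.asarray(ages, dtype=np.float64)
        sexes = np.asarray(sexes)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise NormativeError(f"expected (n, {N_FEATURES}) features, got {X.shape}")
        if self.method not in ("loglinear", "window"):
            raise NormativeError("method must be 'loglinear' or 'window'")
        present = set(np.unique(sexes))
        if not {"F", "M"} <= present:
            raise NormativeError(
                f"normative cohort must contain both sexes, found {sorted(present)}"
            )
        self.mu_coef_ = {}
        self.sigma_coef_ = {}
        self._window_grid_ = {}
        self.age_span_ = {}
        self.n_subjects_ = {}
        for sex in _SEXES:
            mask = sexes == sex
            a, F = ages[mask], X[mask]
            if a.shape[0] < 8:
                raise NormativeError(f"too few {sex} subjects ({a.shape[0]}) to fit")
            D = _design(a)
            coef, _, rank, _ = np.linalg.lstsq(D, F, rcond=None)
            if rank < 3:
                raise NormativeError(f"singular age design for sex {sex}")
            resid = F - D @ coef
            self.mu_coef_[sex] = coef
            self.age_span_[sex] = (float(a.min()), float(a.max()))
            self.n_subjects_[sex] = int(a.shape[0])
            # small-sample inflation for the 3 fitted mean parameters
            inflation = np.sqrt(a.shape[0] / (a.shape[0] - 3))
            if self.method == "loglinear":
                logabs = np.log(np.abs(resid) + 1e-300)
                scoef, _, _, _ = np.linalg.lstsq(D, logabs, rcond=None)
                # absorb bias correction and inflation into the intercept
                scoef = scoef.copy()
                scoef[0] += _HALF_NORMAL_LOG_BIAS + np.log(inflation)
                self.sigma_coef_[sex] = scoef
            else:
                grid = np.arange(np.floor(a.min()), np.ceil(a.max()) + 1.0)
                sig = np.empty((grid.size, N_FEATURES))
                for i, g in enumerate(grid):
                    w = np.abs(a - g) <= self.window_years
                    if w.sum() < 4:
                        # widen until enough neighbours
                        order = np.argsort(np.abs(a - g))
                        w = np.zeros_like(w)
                        w[order[:4]] = True
                    sig[i] = resid[w].std(axis=0, ddof=1)
                sig = np.maximum(sig, 1e-12) * inflation
                self._window_grid_[sex] = (grid, sig)
        return self

    def _check_age(self, age: float, sex: str) -> None:
        lo, hi = self.age_span_[sex]
        if age < lo or age > hi:
            raise ExtrapolationError(
                f"age {age:.1f} outside fitted span [{lo:.1f}, {hi:.1f}] for sex {sex}"
            )

    def mu(self, age: float, sex: str) -> np.ndarray:
        """Population mean of all 532 features at (age, sex)."""
        check_is_fitted(self, "mu_coef_")
        if sex not in _SEXES:
            raise NormativeError(f"unknown sex {sex!r}")
        self._check_age(age, sex)
        d = np.array([1.0, age, age**2])
        return d @ self.mu_coef_[sex]

    def sigma(self, age: float, sex: str) -> np.ndarray:
        """Population SD of all 532 features at (age, sex); strictly > 0."""
        check_is_fitted(self, "mu_coef_")
        if sex not in _SEXES:
            raise NormativeError(f"unknown sex {sex!r}")
        self._check_age(age, sex)
        if self.method == "loglinear":
            d = np.array([1.0, age, age**2])
            return np.exp(d @ self.sigma_coef_[sex])
        grid, sig = self._window_grid_[sex]
        out = np.empty(N_FEATURES)
        for j in range(N_FEATURES):
            out[j] = np.interp(age, grid, sig[:, j])
        return out

    def zscore_subject(self, features, age: float, sex: str) -> np.ndarray:
        """One subject's 76 x 7 z-score grid."""
        x = np.asarray(features, dtype=np.float64).reshape(N_FEATURES)
        z = (x - self.mu(age, sex)) / self.sigma(age, sex)
        return z.reshape(N_TRACTS, N_INDICES)

    def zscore(self, X, ages, sexes) -> np.ndarray:
        """Cohort z-scores, shape (n, 532)."""
        X = np.asarray(X, dtype=np.float64)
        ages = np.asarray(ages, dtype=np.float64)
        sexes = np.asarray(sexes)
        out = np.empty((X.shape[0], N_FEATURES))
        for i in range(X.shape[0]):
            out[i] = (X[i] - self.mu(ages[i], sexes[i])) / self.sigma(
                ages[i], sexes[i]
            )
        return out

    def inverse_zscore(self, Z, ages, sexes) -> np.ndarray:
        """Invert :meth:`zscore` exactly (affine transform)."""
        Z = np.asarray(Z, dtype=np.float64)
        out = np.empty_like(Z)
        for i in range(Z.shape[0]):
            out[i] = Z[i] * self.sigma(ages[i], sexes[i]) + self.mu(
                ages[i], sexes[i]
            )
        return out
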