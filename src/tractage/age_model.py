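"""Gaussian-process brain-age regression, evaluation, and PAD.

Age is regressed on the compact features plus a binary sex column with
Gaussian-process regression (squared-exponential or rational-quadratic
kernel plus white noise), hyperparameters fitted by seeded marginal-
likelihood maximization.  The predicted age difference (PAD) of a subject
is predicted age minus chronological age: positive PAD means an apparently
older brain.

Model quality is summarized by the Pearson correlation r, RMSE and MAE
between chronological and predicted age, either on pooled out-of-fold
predictions from a seeded 10-fold cross-validation of the training set or
on an independent test set predicted by a model trained on the entire
training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, RationalQuadratic, WhiteKernel
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted


class AgeModelError(ValueError):
    """Invalid age-model input."""


@dataclass
class ModelMetrics:
    """Agreement between chronological and predicted age."""

    r: float
    rmse: float
    mae: float


def add_sex_feature(features: np.ndarray, sexes) -> np.ndarray:
    """Append a binary sex column (M=1, F=0) to a compact feature matrix."""
    sexes = np.asarray(sexes)
    col = np.where(sexes == "M", 1.0, 0.0) if sexes.dtype.kind in "OUS" else sexes.astype(float)
    return np.column_stack([np.asarray(features, dtype=np.float64), col])


class BrainAgeModel(RegressorMixin, BaseEstimator):
    """GPR of age on compact features (+ sex).

    Parameters
    ----------
    kernel : {"squared_exponential", "rational_quadratic"}
        Stationary kernel; a white-noise component is always added.
    n_restarts : int, default 3
        Restarts of the marginal-likelihood optimizer (seeded).
    random_state : int, default 0
    """

    def __init__(self, kernel: str = "squared_exponential", n_restarts: int = 3,
                 random_state: int = 0):
        self.kernel = kernel
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _make_kernel(self):
        if self.kernel == "squared_exponential":
            core = RBF(length_scale=10.0, length_scale_bounds=(1e-2, 1e4))
        elif self.kernel == "rational_quadratic":
            core = RationalQuadratic(length_scale=10.0, alpha=1.0,
                                     length_scale_bounds=(1e-2, 1e4))
        else:
            raise AgeModelError(f"unknown kernel {self.kernel!r}")
        return (
            ConstantKernel(1.0, (1e-3, 1e3)) * core
            + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-10, 1e2))
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise AgeModelError("X must be 2D with one age per row")
        if X.shape[0] < 20:
            raise AgeModelError("age model needs at least 20 subjects")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise AgeModelError("non-finite features or ages")
        if np.ptp(y) == 0:
            raise AgeModelError("degenerate target: ages are constant")
        if self.n_restarts < 1:
            raise AgeModelError("n_restarts must be >= 1")
        self.gp_ = GaussianProcessRegressor(
            kernel=self._make_kernel(),
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts - 1,
            random_state=self.random_state,
        )
        self.gp_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean predicted ages (years)."""
        check_is_fitted(self, "gp_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise AgeModelError(
                f"expected (n, {self.n_features_in_}) features, got {X.shape}"
            )
        return self.gp_.predict(X)

    def predict_pad(self, X, chronological_age, subject_ids=None) -> pd.DataFrame:
        """Prediction table with exact PAD = predicted - chronological."""
        predicted = self.predict(X)
        chronological = np.asarray(chronological_age, dtype=np.float64)
        frame = pd.DataFrame(
            {
                "predicted_age": predicted,
                "chronological_age": chronological,
                "pad": predicted - chronological,
            }
        )
        if subject_ids is not None:
            frame.insert(0, "subject_id", list(subject_ids))
        return frame


def compute_metrics(chronological, predicted) -> ModelMetrics:
    """Pearson r, RMSE and MAE between chronological and predicted age."""
    y = np.asarray(chronological, dtype=np.float64)
    yhat = np.asarray(predicted, dtype=np.float64)
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        r = np.nan if np.ptp(y) == 0 else 1.0 if rmse == 0 else np.nan
    else:
        r = float(stats.pearsonr(y, yhat).statistic)
    if rmse == 0:
        r = 1.0
    return ModelMetrics(r=r, rmse=rmse, mae=mae)


def cross_validate_10fold(X, ages, model: BrainAgeModel | None = None,
                          seed: int = 0, n_folds: int = 10):
    """Seeded 10-fold CV; metrics on pooled out-of-fold predictions.

    Every subject appears in exactly one held-out fold.  Returns
    ``(metrics, out_of_fold_predictions)``.
    """
    X = np.asarray(X, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    n = X.shape[0]
    if n < n_folds:
        raise AgeModelError(f"cross-validation needs at least {n_folds} subjects")
    if model is None:
        model = BrainAgeModel()
    oof = np.empty(n)
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X):
        fold_model = clone(model)
        fold_model.fit(X[train_idx], ages[train_idx])
        oof[test_idx] = fold_model.predict(X[test_idx])
    return compute_metrics(ages, oof), oof


def residual_age_correlation(pads, ages) -> float:
    """Pearson r between PAD and chronological age (regression-to-the-mean
    diagnostic of the trained model)."""
    pads = np.asarray(pads, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    if pads.shape[0] < 3:
        raise AgeModelError("correlation needs at least 3 subjects")
    if np.ptp(pads) == 0 or np.ptp(ages) == 0:
        raise AgeModelError("undefined correlation: constant input")
    return float(stats.pearsonr(pads, ages).statistic)
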