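"""Group statistics: PAD comparisons, mass-univariate deviation testing,
effect-size feature selection, PCA attribution, and confound-adjusted
clinical correlations with bootstrap confidence intervals.

The analyses mirror the downstream characterization of a brain-age study:

* ANCOVA of PAD across the three study groups controlling for age, sex and
  handedness, with Bonferroni-corrected pairwise Welch t tests post hoc;
* one-sample t tests of each (tract, index) z-score cell against zero with
  Benjamini-Hochberg (default) or Bonferroni adjustment across all 532
  cells, plus the one-sample effect size d = mean(z)/SD(z);
* selection of the top 5% of cells by |d| (ceil(0.05 * 532) = 27) and PCA
  of the patients-by-selected-cells z matrix; the first component is
  regressed against PAD and its squared loadings are decomposed into tract
  and index contribution percentages;
* partial (confound-residualized) Pearson/Spearman correlations of PAD
  with clinical variables, with percentile bootstrap CIs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .registry import INDEX_NAMES, N_FEATURES, N_INDICES, TRACT_NAMES, feature_names


class AnalysisError(ValueError):
    """Invalid analysis input."""


# --------------------------------------------------------------------------
# PAD group statistics
# --------------------------------------------------------------------------

def ancova_pad(pads, groups, covariates: pd.DataFrame):
    """ANCOVA F test for the group factor, adjusting for covariates.

    Compares the full linear model (covariates + group dummies) against the
    reduced model (covariates only) via extra-sum-of-squares, with
    df = (n_groups - 1, n - n_groups - n_covariates).
    Returns ``(F, p, (df1, df2))``.
    """
    pads = np.asarray(pads, dtype=np.float64)
    groups = np.asarray(groups)
    cov = np.asarray(covariates, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[:, None]
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise AnalysisError("ANCOVA needs at least 2 groups")
    if np.isnan(cov).any() or np.isnan(pads).any():
        raise AnalysisError("covariates and PADs must be complete")
    n = pads.shape[0]
    dummies = np.column_stack([(groups == g).astype(float) for g in levels[1:]])
    X_red = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([X_red, dummies])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise AnalysisError("rank-deficient ANCOVA design")

    def rss(X):
        beta, _, _, _ = np.linalg.lstsq(X, pads, rcond=None)
        r = pads - X @ beta
        return float(r @ r)

    rss_red, rss_full = rss(X_red), rss(X_full)
    df1 = len(levels) - 1
    df2 = n - len(levels) - cov.shape[1]
    if df2 <= 0:
        raise AnalysisError("not enough residual degrees of freedom")
    if rss_full == 0:
        return 0.0 if rss_red == rss_full else np.inf, 1.0, (df1, df2)
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p, (df1, df2)


def posthoc_pairwise(pads, groups, pooled: bool = False) -> pd.DataFrame:
    """Pairwise two-sample t tests with Bonferroni correction.

    Welch t by default (``pooled=True`` for the equal-variance test);
    raw p is multiplied by the number of pairs and capped at 1.
    """
    pads = np.asarray(pads, dtype=np.float64)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    rows = []
    for a, b in pairs:
        xa, xb = pads[groups == a], pads[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            raise AnalysisError(f"group {a if len(xa) < 2 else b!r} has n < 2")
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, df, p = 0.0, float(len(xa) + len(xb) - 2), 1.0
        else:
            res = stats.ttest_ind(xa, xb, equal_var=pooled)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append(
            {"group_a": a, "group_b": b, "t": t, "df": df, "p_raw": p,
             "p_bonferroni": min(1.0, p * len(pairs))}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Mass-univariate z testing and feature selection
# --------------------------------------------------------------------------

def mass_univariate_z(zgrids, method: str = "fdr_bh", alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t of each (tract, index) z cell against 0 across patients.

    ``zgrids`` is (n_patients, 532) or (n_patients, 76, 7).  Adjustment is
    Benjamini-Hochberg by default (``method="bonferroni"`` optional) across
    all 532 cells.  Returns one row per cell with t, p, adjusted p, the
    one-sample effect size d = mean(z)/SD(z) (NaN where SD is 0, flagged
    ``degenerate``), and a significance flag.
    """
    Z = np.asarray(zgrids, dtype=np.float64).reshape(-1, N_FEATURES)
    n = Z.shape[0]
    if n < 2:
        raise AnalysisError("mass-univariate test needs at least 2 patients")
    if method not in ("fdr_bh", "bonferroni"):
        raise AnalysisError("method must be 'fdr_bh' or 'bonferroni'")
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, mean / (sd / np.sqrt(n)))
        d = np.where(degenerate, np.nan, mean / sd)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    names = feature_names()
    return pd.DataFrame(
        {
            "feature": names,
            "tract": [f.split(":")[0] for f in names],
            "index": [f.split(":")[1] for f in names],
            "mean_z": mean,
            "t": t,
            "p": p,
            "p_adjusted": np.minimum(p_adj, 1.0),
            "d": d,
            "significant": reject & ~degenerate,
            "degenerate": degenerate,
        }
    )


def select_top_features(grid: pd.DataFrame, fraction: float = 0.05,
                        significant_only: bool = False) -> list[str]:
    """Select the top ``ceil(fraction * n_cells)`` cells by |effect size|.

    Ties are broken by canonical feature order; cells with undefined d rank
    last.  ``significant_only`` restricts the ranking to cells whose
    adjusted p passed the significance threshold.
    """
    if not 0.0 < fraction <= 1.0:
        raise AnalysisError("fraction must be in (0, 1]")
    frame = grid
    if significant_only:
        frame = frame[frame["significant"]]
    k = math.ceil(fraction * len(grid))
    mag = frame["d"].abs().fillna(-np.inf).to_numpy()
    order = np.lexsort((np.arange(len(frame)), -mag))
    return list(frame["feature"].to_numpy()[order[:k]])


# --------------------------------------------------------------------------
# PCA attribution
# --------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """First-principal-component attribution of PAD to deviation features."""

    selected_features: list[str]
    pc1_scores: np.ndarray
    pc1_loadings: np.ndarray
    variance_explained_pc1: float       # percent
    tract_contributions: pd.Series      # percent per tract, sums to 100
    index_contributions: pd.Series      # percent per index, sums to 100
    regression_f: float
    regression_p: float
    regression_r2: float
    contribution_mode: str = "squared"


def pca_attribution(z_selected, pads, selected_features,
                    contribution_mode: str = "squared") -> AttributionResult:
    """PCA of the patients x selected-features z matrix + PAD regression.

    The column-centered matrix is decomposed by SVD; the first right
    singular vector (unit norm) gives the loadings, oriented so that the
    simple regression of PAD on the PC1 scores has a positive slope.
    Feature contributions are squared loadings normalized to 100%
    (``contribution_mode="absolute"`` uses |loading| instead); tract and
    index contributions are sums over each tract's / index's selected
    features.
    """
    Z = np.asarray(z_selected, dtype=np.float64)
    pads = np.asarray(pads, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != len(selected_features):
        raise AnalysisError("z matrix must be patients x selected features")
    n, k = Z.shape
    if n < 3:
        raise AnalysisError("PCA attribution needs at least 3 patients")
    if k < 1:
        raise AnalysisError("needs at least one selected feature")
    if contribution_mode not in ("squared", "absolute"):
        raise AnalysisError("contribution_mode must be 'squared' or 'absolute'")

    centered = Z - Z.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[0]
    scores = centered @ loadings
    var_explained = float(100.0 * s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0

    # Simple regression of PAD on PC1 scores.
    x = scores - scores.mean()
    sxx = float(x @ x)
    if sxx == 0:
        raise AnalysisError("degenerate PC1 scores")
    slope = float(x @ (pads - pads.mean())) / sxx
    if slope < 0:
        loadings = -loadings
        scores = -scores
        slope = -slope
    fitted = pads.mean() + slope * (scores - scores.mean())
    ss_res = float(np.sum((pads - fitted) ** 2))
    ss_tot = float(np.sum((pads - pads.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df2 = n - 2
    if ss_res == 0:
        f, p = np.inf, 0.0
    else:
        f = (ss_tot - ss_res) / (ss_res / df2)
        p = float(stats.f.sf(f, 1, df2))

    weight = loadings**2 if contribution_mode == "squared" else np.abs(loadings)
    contrib = 100.0 * weight / weight.sum()
    tracts = [f.split(":")[0] for f in selected_features]
    indices = [f.split(":")[1] for f in selected_features]
    tract_contrib = pd.Series(contrib).groupby(tracts).sum().sort_values(ascending=False)
    index_contrib = pd.Series(contrib).groupby(indices).sum().sort_values(ascending=False)
    return AttributionResult(
        selected_features=list(selected_features),
        pc1_scores=scores,
        pc1_loadings=loadings,
        variance_explained_pc1=var_explained,
        tract_contributions=tract_contrib,
        index_contributions=index_contrib,
        regression_f=float(f),
        regression_p=p,
        regression_r2=float(r2),
        contribution_mode=contribution_mode,
    )


# --------------------------------------------------------------------------
# Confound-adjusted clinical correlations
# --------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Confound-adjusted correlation of PAD with one clinical variable."""

    variable: str
    method: str                       # "pearson" or "spearman"
    r: float
    p: float
    n: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int | None = None
    seed: int | None = None
    n_skipped: int = 0
    warnings: list[str] = field(default_factory=list)


def _residualize(y: np.ndarray, confounders: np.ndarray | None) -> np.ndarray:
    n = y.shape[0]
    X = np.ones((n, 1))
    if confounders is not None and confounders.size:
        X = np.column_stack([X, confounders])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _adjusted_correlation(pads, clinical, confounders, method: str):
    r_pad = _residualize(pads, confounders)
    r_cli = _residualize(clinical, confounders)
    if np.ptp(r_pad) == 0 or np.ptp(r_cli) == 0:
        return None
    if method == "pearson":
        res = stats.pearsonr(r_pad, r_cli)
    else:
        res = stats.spearmanr(r_pad, r_cli)
    return float(res.statistic), float(res.pvalue)


def clinical_correlation(pads, clinical, confounders=None,
                         normality_alpha: float = 0.05,
                         variable: str = "clinical",
                         outlier_sd: float | None = None) -> CorrelationResult:
    """Confound-adjusted correlation of PAD with one clinical variable.

    PAD and the variable are residualized on the confounders by OLS;
    Pearson correlation is used when both residual sets pass Shapiro-Wilk
    normality at ``normality_alpha``, Spearman otherwise.  ``outlier_sd``
    optionally excludes subjects whose standardized clinical value exceeds
    that many SDs before the analysis.
    """
    pads = np.asarray(pads, dtype=np.float64)
    clinical = np.asarray(clinical, dtype=np.float64)
    conf = None if confounders is None else np.asarray(confounders, dtype=np.float64)
    if conf is not None and conf.ndim == 1:
        conf = conf[:, None]
    if pads.shape[0] < 5:
        raise AnalysisError("correlation needs at least 5 subjects")
    if np.ptp(clinical) == 0:
        raise AnalysisError(f"undefined correlation: {variable} is constant")

    if outlier_sd is not None:
        z = (clinical - clinical.mean()) / clinical.std(ddof=1)
        keep = np.abs(z) <= outlier_sd
        pads, clinical = pads[keep], clinical[keep]
        conf = None if conf is None else conf[keep]
        if pads.shape[0] < 5:
            raise AnalysisError("too few subjects after outlier exclusion")

    r_pad = _residualize(pads, conf)
    r_cli = _residualize(clinical, conf)
    if np.ptp(r_pad) == 0 or np.ptp(r_cli) == 0:
        raise AnalysisError("undefined correlation: constant residuals")
    normal = (
        stats.shapiro(r_pad).pvalue > normality_alpha
        and stats.shapiro(r_cli).pvalue > normality_alpha
    )
    method = "pearson" if normal else "spearman"
    r, p = _adjusted_correlation(pads, clinical, conf, method)
    return CorrelationResult(variable=variable, method=method, r=r, p=p,
                             n=int(pads.shape[0]))


def bootstrap_correlation(pads, clinical, confounders=None, n_boot: int = 2000,
                          seed: int = 0, method: str | None = None,
                          normality_alpha: float = 0.05,
                          variable: str = "clinical") -> CorrelationResult:
    """Percentile bootstrap CI for the confound-adjusted correlation.

    Subjects are resampled with replacement; the adjusted correlation is
    recomputed per replicate with the method fixed to the full-sample
    choice.  Replicates with zero residual variance are skipped and
    counted; a warning is recorded if more than 10% are skipped.
    """
    if n_boot < 100:
        raise AnalysisError("n_boot must be >= 100")
    base = clinical_correlation(pads, clinical, confounders,
                                normality_alpha=normality_alpha,
                                variable=variable)
    if method is None:
        method = base.method
    pads = np.asarray(pads, dtype=np.float64)
    clinical = np.asarray(clinical, dtype=np.float64)
    conf = None if confounders is None else np.asarray(confounders, dtype=np.float64)
    if conf is not None and conf.ndim == 1:
        conf = conf[:, None]
    n = pads.shape[0]
    rng = np.random.default_rng(seed)
    rs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out = _adjusted_correlation(
            pads[idx], clinical[idx], None if conf is None else conf[idx], method
        )
        if out is None or not np.isfinite(out[0]):
            skipped += 1
            continue
        rs.append(out[0])
    msgs = []
    if skipped > 0.1 * n_boot:
        msgs.append(f"{skipped}/{n_boot} bootstrap replicates skipped")
        warnings.warn(msgs[-1])
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return CorrelationResult(
        variable=variable, method=method, r=base.r, p=base.p, n=base.n,
        ci_lower=float(lo), ci_upper=float(hi), n_boot=n_boot, seed=seed,
        n_skipped=skipped, warnings=msgs,
    )
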