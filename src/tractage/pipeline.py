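"""Staged pipeline orchestration: simulate -> preprocess -> train ->
predict -> normative -> analyze -> report.

Every stage reads its inputs from, and writes versioned artifacts to, a run
directory.  Each stage records a manifest with the hash of the config that
produced it; downstream stages refuse mismatched upstream artifacts unless
forced.  All stochastic stages derive their seeds deterministically from the
single global seed (via ``derive_seed``), so a rerun with the same config
reproduces every CSV byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from .age_model import (
    BrainAgeModel,
    add_sex_feature,
    compute_metrics,
    cross_validate_10fold,
    residual_age_correlation,
)
from .encoder import PassthroughEncoder, SparseAutoencoder
from .io import (
    PATIENT_GROUPS,
    read_cohort,
    read_connectogram,
    write_cohort,
    write_connectogram,
)
from .normative import NormativeModel
from .preprocess import TractFeaturePipeline
from .registry import feature_names
from .simulate import STUDY_SIZES, default_lesion_spec, make_study_suite

STAGES = ("simulate", "preprocess", "train", "predict", "normative", "analyze", "report")
STUDY_GROUPS = ("control", "lmtle", "rmtle")
CLINICAL_VARS = ("age_of_onset", "duration_of_illness", "seizure_frequency")


class PipelineError(RuntimeError):
    """Missing or inconsistent upstream artifacts."""


def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage seed: mixes the global seed with a CRC32 of
    the stage label through a SeedSequence; always < 2**31."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Full run configuration; round-trips through YAML."""

    seed: int = 42
    cohort_sizes: dict = field(default_factory=lambda: dict(STUDY_SIZES))
    noise: dict = field(default_factory=lambda: {
        "subject_sd": 0.04, "step_sd": 0.04, "latent_sd": 0.018})
    lesion: dict = field(default_factory=lambda: {
        "rmtle_strength": 1.0, "lmtle_strength": 0.25})
    preprocess: dict = field(default_factory=lambda: {
        "smooth_sigma": 2.0, "kernel_truncation": 3.0, "boundary_mode": "reflect",
        "pvalue_floor": 1e-300, "normalize_weights": True})
    encoder: dict = field(default_factory=lambda: {
        "passthrough": False, "hidden_units": 179, "epochs": 1600,
        "sparsity_target": 0.05, "sparsity_weight": 1.0, "l2_weight": 1e-4,
        "activation": "sigmoid"})
    age_model: dict = field(default_factory=lambda: {
        "kernel": "squared_exponential", "n_restarts": 3})
    normative: dict = field(default_factory=lambda: {
        "method": "loglinear", "window_years": 10.0})
    analysis: dict = field(default_factory=lambda: {
        "mc_method": "fdr_bh", "top_fraction": 0.05, "contribution_mode": "squared",
        "n_boot": 2000, "outlier_sd": None, "display_indices":
        ["GFA", "AD", "RD", "MD", "NGP"]})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise PipelineError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg


# --------------------------------------------------------------------------
# manifests
# --------------------------------------------------------------------------

def _manifest_path(outdir: Path, stage: str) -> Path:
    return Path(outdir) / "stages" / f"{stage}.json"


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig, **extra) -> None:
    path = _manifest_path(outdir, stage)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "config_hash": cfg.config_hash(),
               "seed": derive_seed(cfg.seed, stage), **extra}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _require_stage(outdir: Path, stage: str, cfg: RunConfig, force: bool = False) -> None:
    path = _manifest_path(outdir, stage)
    if not path.exists():
        raise PipelineError(
            f"missing artifacts from the '{stage}' stage: run `tractage {stage}` first"
        )
    manifest = json.loads(path.read_text())
    if manifest.get("config_hash") != cfg.config_hash() and not force:
        raise PipelineError(
            f"artifacts from '{stage}' were produced with a different config "
            f"(hash {manifest.get('config_hash')} != {cfg.config_hash()}); "
            "rerun the stage or pass --force"
        )


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, outdir) -> None:
    """Generate the study suite and write cohort CSV + connectogram TSVs."""
    outdir = Path(outdir)
    seed = derive_seed(cfg.seed, "simulate")
    lesions = {
        "rmtle": default_lesion_spec(cfg.lesion["rmtle_strength"]),
        "lmtle": default_lesion_spec(cfg.lesion["lmtle_strength"]),
    }
    suite = make_study_suite(seed, sizes=cfg.cohort_sizes, lesion_specs=lesions,
                             **cfg.noise)
    tables = []
    for name, (connectograms, table) in suite.items():
        cohort_dir = outdir / "profiles" / name
        cohort_dir.mkdir(parents=True, exist_ok=True)
        for c in connectograms:
            write_connectogram(c, cohort_dir / f"{c.subject_id}.tsv")
        tables.append(table)
    write_cohort(pd.concat(tables, ignore_index=True), outdir / "cohorts.csv")
    _write_manifest(outdir, "simulate", cfg,
                    sizes={k: len(v[0]) for k, v in suite.items()})


def _load_cohort_values(outdir: Path, table: pd.DataFrame, group: str):
    sub = table[table["group"] == group]
    connectograms = [
        read_connectogram(Path(outdir) / "profiles" / group / f"{sid}.tsv")
        for sid in sub["subject_id"]
    ]
    return connectograms, sub.reset_index(drop=True)


def _features_path(outdir: Path, group: str) -> Path:
    return Path(outdir) / f"features_{group}.csv"


def _read_features(outdir: Path, group: str):
    frame = pd.read_csv(_features_path(outdir, group), float_precision="round_trip")
    return frame["subject_id"].to_numpy(), frame.drop(columns="subject_id").to_numpy()


def stage_preprocess(cfg: RunConfig, outdir, force: bool = False) -> None:
    """Fit the feature pipeline on the training cohort; emit features for
    every cohort plus the fitted statistics artifact."""
    outdir = Path(outdir)
    _require_stage(outdir, "simulate", cfg, force)
    table = read_cohort(outdir / "cohorts.csv")
    groups = [g for g in STUDY_SIZES if (table["group"] == g).any()]

    train_c, train_t = _load_cohort_values(outdir, table, "train")
    pipe = TractFeaturePipeline(**cfg.preprocess)
    pipe.fit(train_c, train_t["age"].to_numpy())
    names = feature_names()
    for group in groups:
        connectograms, sub = _load_cohort_values(outdir, table, group)
        feats = pipe.transform(connectograms)
        frame = pd.DataFrame(feats, columns=names)
        frame.insert(0, "subject_id", sub["subject_id"].to_numpy())
        frame.to_csv(_features_path(outdir, group), index=False)

    model = {
        "params": cfg.preprocess,
        "n_train": len(train_c),
        "mean": pipe.norm_stats_.mean.tolist(),
        "sd": pipe.norm_stats_.sd.tolist(),
        "weights": pipe.step_weights_.weights.tolist(),
        "raw_weights": pipe.step_weights_.raw.tolist(),
    }
    (outdir / "preprocess_model.json").write_text(json.dumps(model))
    _write_manifest(outdir, "preprocess", cfg, groups=groups)


def _fit_encoder(cfg: RunConfig, features: np.ndarray):
    enc_cfg = dict(cfg.encoder)
    if enc_cfg.pop("passthrough", False):
        return PassthroughEncoder().fit(features)
    return SparseAutoencoder(random_state=derive_seed(cfg.seed, "encoder"),
                             **enc_cfg).fit(features)


def stage_train(cfg: RunConfig, outdir, force: bool = False) -> None:
    """Train the encoder and the GPR age model; run 10-fold CV."""
    outdir = Path(outdir)
    _require_stage(outdir, "preprocess", cfg, force)
    table = read_cohort(outdir / "cohorts.csv")
    ids, F_train = _read_features(outdir, "train")
    train_t = table.set_index("subject_id").loc[ids]

    encoder = _fit_encoder(cfg, F_train)
    X = add_sex_feature(encoder.transform(F_train), train_t["sex"].to_numpy())
    ages = train_t["age"].to_numpy()

    model = BrainAgeModel(random_state=derive_seed(cfg.seed, "age_model"),
                          **cfg.age_model)
    model.fit(X, ages)
    cv_metrics, oof = cross_validate_10fold(
        X, ages, model=BrainAgeModel(random_state=derive_seed(cfg.seed, "age_model"),
                                     **cfg.age_model),
        seed=derive_seed(cfg.seed, "cv"),
    )
    joblib.dump({"encoder": encoder, "age_model": model}, outdir / "models.joblib")
    report = {
        "encoded_dim": int(X.shape[1] - 1),
        "encoder": {
            "reconstruction_rate": float(encoder.reconstruction_rate_),
            "final_loss": float(encoder.final_loss_),
            "converged": bool(encoder.converged_),
        },
        "cv": {"r": cv_metrics.r, "rmse": cv_metrics.rmse, "mae": cv_metrics.mae,
               "residual_age_r": residual_age_correlation(oof - ages, ages)},
    }
    (outdir / "train_report.json").write_text(json.dumps(report, indent=2))
    _write_manifest(outdir, "train", cfg, encoded_dim=report["encoded_dim"])


def stage_predict(cfg: RunConfig, outdir, force: bool = False) -> None:
    """Predict age and PAD for every cohort with the trained model."""
    outdir = Path(outdir)
    _require_stage(outdir, "train", cfg, force)
    table = read_cohort(outdir / "cohorts.csv")
    bundle = joblib.load(outdir / "models.joblib")
    encoder, model = bundle["encoder"], bundle["age_model"]

    frames = []
    indexed = table.set_index("subject_id")
    for group in [g for g in STUDY_SIZES if (table["group"] == g).any()]:
        ids, F = _read_features(outdir, group)
        sub = indexed.loc[ids]
        X = add_sex_feature(encoder.transform(F), sub["sex"].to_numpy())
        frame = model.predict_pad(X, sub["age"].to_numpy(), subject_ids=ids)
        frame.insert(1, "group", group)
        frames.append(frame)
    predictions = pd.concat(frames, ignore_index=True)
    predictions.to_csv(outdir / "predictions.csv", index=False)

    test = predictions[predictions["group"] == "test"]
    metrics = {}
    if len(test):
        m = compute_metrics(test["chronological_age"], test["predicted_age"])
        metrics["test"] = {"r": m.r, "rmse": m.rmse, "mae": m.mae}
    (outdir / "predict_report.json").write_text(json.dumps(metrics, indent=2))
    _write_manifest(outdir, "predict", cfg)


def stage_normative(cfg: RunConfig, outdir, force: bool = False) -> None:
    """Fit the normative model on the normative cohort; z-score the study
    groups."""
    outdir = Path(outdir)
    _require_stage(outdir, "preprocess", cfg, force)
    table = read_cohort(outdir / "cohorts.csv").set_index("subject_id")
    ids, F = _read_features(outdir, "normative")
    sub = table.loc[ids]
    nm = NormativeModel(**cfg.normative)
    nm.fit(F, sub["age"].to_numpy(), sub["sex"].to_numpy())

    artifact = {
        "method": cfg.normative["method"],
        "mu_coef": {s: c.tolist() for s, c in nm.mu_coef_.items()},
        "age_span": nm.age_span_,
        "n_subjects": nm.n_subjects_,
    }
    if cfg.normative["method"] == "loglinear":
        artifact["sigma_coef"] = {s: c.tolist() for s, c in nm.sigma_coef_.items()}
    (outdir / "normative_model.json").write_text(json.dumps(artifact))
    joblib.dump(nm, outdir / "normative_model.joblib")

    names = feature_names()
    rows = []
    for group in STUDY_GROUPS:
        path = _features_path(outdir, group)
        if not path.exists():
            continue
        gids, Fg = _read_features(outdir, group)
        gsub = table.loc[gids]
        Z = nm.zscore(Fg, gsub["age"].to_numpy(), gsub["sex"].to_numpy())
        frame = pd.DataFrame(Z, columns=names)
        frame.insert(0, "subject_id", gids)
        frame.insert(1, "group", group)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "zscores.csv", index=False)
    _write_manifest(outdir, "normative", cfg)


def stage_analyze(cfg: RunConfig, outdir, force: bool = False) -> dict:
    """Group PAD statistics, deviation testing, attribution, and clinical
    correlations; returns the summary dict written to ``analysis.json``."""
    outdir = Path(outdir)
    _require_stage(outdir, "predict", cfg, force)
    _require_stage(outdir, "normative", cfg, force)
    table = read_cohort(outdir / "cohorts.csv").set_index("subject_id")
    predictions = pd.read_csv(outdir / "predictions.csv",
                              float_precision="round_trip")
    study = predictions[predictions["group"].isin(STUDY_GROUPS)].copy()
    meta = table.loc[study["subject_id"]]
    study["age"] = meta["age"].to_numpy()
    study["sex01"] = (meta["sex"] == "M").astype(float).to_numpy()
    study["handedness"] = meta["handedness"].to_numpy()

    f, p, df = an.ancova_pad(
        study["pad"].to_numpy(), study["group"].to_numpy(),
        study[["age", "sex01", "handedness"]],
    )
    posthoc = an.posthoc_pairwise(study["pad"].to_numpy(), study["group"].to_numpy())
    posthoc.to_csv(outdir / "posthoc.csv", index=False)

    zscores = pd.read_csv(outdir / "zscores.csv", float_precision="round_trip")
    names = feature_names()
    summary = {
        "ancova": {"F": f, "p": p, "df": list(df)},
        "group_pad_mean": study.groupby("group")["pad"].mean().to_dict(),
        "groups": {},
    }
    seed0 = derive_seed(cfg.seed, "bootstrap")
    for gi, group in enumerate(PATIENT_GROUPS):
        gz = zscores[zscores["group"] == group]
        if len(gz) < 3:
            continue
        Z = gz[names].to_numpy()
        grid = an.mass_univariate_z(Z, method=cfg.analysis["mc_method"])
        grid.to_csv(outdir / f"effect_sizes_{group}.csv", index=False)
        selected = an.select_top_features(grid, cfg.analysis["top_fraction"])
        pads = study.set_index("subject_id").loc[gz["subject_id"], "pad"].to_numpy()
        cols = [names.index(s) for s in selected]
        att = an.pca_attribution(Z[:, cols], pads, selected,
                                 cfg.analysis["contribution_mode"])
        att.tract_contributions.rename("contribution_pct").to_csv(
            outdir / f"tract_contributions_{group}.csv")
        att.index_contributions.rename("contribution_pct").to_csv(
            outdir / f"index_contributions_{group}.csv")

        gmeta = table.loc[gz["subject_id"]]
        conf = np.column_stack([
            gmeta["age"].to_numpy(),
            (gmeta["sex"] == "M").astype(float).to_numpy(),
            gmeta["n_aed_classes"].to_numpy(),
        ])
        correlations = []
        for vi, var in enumerate(CLINICAL_VARS):
            res = an.bootstrap_correlation(
                pads, gmeta[var].to_numpy(), conf,
                n_boot=cfg.analysis["n_boot"],
                seed=seed0 + 100 * gi + vi, variable=var,
            )
            correlations.append({
                "variable": var, "method": res.method, "r": res.r, "p": res.p,
                "n": res.n, "ci_lower": res.ci_lower, "ci_upper": res.ci_upper,
                "n_boot": res.n_boot,
            })
        pd.DataFrame(correlations).to_csv(outdir / f"clinical_{group}.csv",
                                          index=False)
        summary["groups"][group] = {
            "n_significant_cells": int(grid["significant"].sum()),
            "n_significant_tracts": int(
                grid[grid["significant"]]["tract"].nunique()),
            "n_selected": len(selected),
            "pc1_variance_pct": att.variance_explained_pc1,
            "pad_regression": {"F": att.regression_f, "p": att.regression_p,
                               "r2": att.regression_r2},
            "top_tracts": att.tract_contributions.head(5).to_dict(),
            "index_contributions": att.index_contributions.to_dict(),
            "clinical": correlations,
        }
    (outdir / "analysis.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    _write_manifest(outdir, "analyze", cfg)
    return summary


def stage_report(cfg: RunConfig, outdir, force: bool = False,
                 figures: bool = False) -> str:
    """Assemble the plain-text analysis report (optionally with figures)."""
    outdir = Path(outdir)
    _require_stage(outdir, "analyze", cfg, force)
    train_report = json.loads((outdir / "train_report.json").read_text())
    predict_report = json.loads((outdir / "predict_report.json").read_text())
    summary = json.loads((outdir / "analysis.json").read_text())

    lines = ["White-matter brain age analysis report",
             "=" * 40,
             f"config hash: {cfg.config_hash()}  seed: {cfg.seed}",
             "",
             f"encoded feature dimension: {train_report['encoded_dim']}",
             "encoder reconstruction rate: "
             f"{train_report['encoder']['reconstruction_rate']:.2f}%",
             "training 10-fold CV: r={r:.3f} RMSE={rmse:.2f}y MAE={mae:.2f}y".format(
                 **{k: train_report["cv"][k] for k in ("r", "rmse", "mae")}),
             f"CV residual-age correlation: {train_report['cv']['residual_age_r']:.3f}"]
    if "test" in predict_report:
        lines.append(
            "independent test set: r={r:.3f} RMSE={rmse:.2f}y MAE={mae:.2f}y".format(
                **predict_report["test"]))
    a = summary["ancova"]
    lines += ["",
              f"ANCOVA group effect on PAD: F({a['df'][0]},{a['df'][1]}) = "
              f"{a['F']:.3f}, p = {a['p']:.3g}",
              "group mean PAD (years): " + ", ".join(
                  f"{g}={v:.2f}" for g, v in sorted(
                      summary["group_pad_mean"].items()))]
    for group, g in summary.get("groups", {}).items():
        lines += ["",
                  f"[{group}] significant cells: {g['n_significant_cells']} "
                  f"(tracts with any significant index: {g['n_significant_tracts']})",
                  f"[{group}] PC1 of top-{g['n_selected']} deviations explains "
                  f"{g['pc1_variance_pct']:.1f}% variance; PAD regression "
                  f"R^2={g['pad_regression']['r2']:.3f} "
                  f"(p={g['pad_regression']['p']:.3g})",
                  f"[{group}] top tracts: " + ", ".join(
                      f"{t}={v:.1f}%" for t, v in g["top_tracts"].items())]
        for c in g["clinical"]:
            lines.append(
                f"[{group}] PAD ~ {c['variable']}: {c['method']} r={c['r']:.3f} "
                f"p={c['p']:.3g} CI95=[{c['ci_lower']:.3f}, {c['ci_upper']:.3f}]")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    if figures:
        _make_figures(outdir)
    _write_manifest(outdir, "report", cfg)
    return text


def _make_figures(outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    predictions = pd.read_csv(outdir / "predictions.csv")
    study = predictions[predictions["group"].isin(STUDY_GROUPS)]
    fig, ax = plt.subplots(figsize=(5, 4))
    data = [study.loc[study["group"] == g, "pad"] for g in STUDY_GROUPS]
    ax.boxplot(data, tick_labels=list(STUDY_GROUPS))
    ax.set_ylabel("PAD (years)")
    fig.tight_layout()
    fig.savefig(outdir / "pad_boxplot.png", dpi=120)
    plt.close(fig)

    zscores = pd.read_csv(outdir / "zscores.csv")
    names = feature_names()
    for group in PATIENT_GROUPS:
        gz = zscores[zscores["group"] == group]
        if not len(gz):
            continue
        Z = gz[names].to_numpy().mean(axis=0).reshape(76, 7)
        fig, ax = plt.subplots(figsize=(4, 9))
        im = ax.imshow(Z, aspect="auto", cmap="coolwarm", vmin=-3, vmax=3)
        ax.set_xticks(range(7), [n.split(":")[1] for n in names[:7]])
        ax.set_ylabel("tract")
        fig.colorbar(im, ax=ax, label="mean z")
        fig.tight_layout()
        fig.savefig(outdir / f"zscore_heatmap_{group}.png", dpi=120)
        plt.close(fig)


def run_end_to_end(cfg: RunConfig, outdir, figures: bool = False) -> dict:
    """Execute every stage in order and return the headline summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_simulate(cfg, outdir)
    stage_preprocess(cfg, outdir)
    stage_train(cfg, outdir)
    stage_predict(cfg, outdir)
    stage_normative(cfg, outdir)
    summary = stage_analyze(cfg, outdir)
    stage_report(cfg, outdir, figures=figures)
    train_report = json.loads((outdir / "train_report.json").read_text())
    predict_report = json.loads((outdir / "predict_report.json").read_text())
    return {
        "encoded_dim": train_report["encoded_dim"],
        "cv": train_report["cv"],
        "test": predict_report.get("test"),
        "group_pad_mean": summary["group_pad_mean"],
        "ancova": summary["ancova"],
        "groups": summary["groups"],
    }
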