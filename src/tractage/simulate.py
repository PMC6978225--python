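"""Synthetic connectogram cohorts with the statistical structure the
analysis assumes.

No public along-tract dataset accompanies the study design this package
implements, so every downstream stage is exercised on cohorts drawn from an
explicit generative model:

    value(t, s, k) = baseline(t, s, k)
                   + slope(t, s, k) * age + curvature(t, s, k) * age**2
                   + sex_offset(t, k) * [sex == M]
                   + latent_sd * sum_l score_l * loading_l(t, k)   (shared factors)
                   + subject_effect(t, k)          ~ N(0, subject_sd**2)
                   + step_noise(t, s, k)           ~ N(0, step_sd**2)

The latent factors (scores ~ N(0,1) per subject, fixed N(0,1) loadings per
tract and index) emulate the strong low-rank between-subject covariation of
real tract features — global physiology and acquisition effects that move
many tracts together — and are what makes feature compression meaningful.

Baselines are low-order cosine series over the 100 steps (smooth, like real
tract profiles).  Age slopes carry the field's canonical aging directions
(diffusivities rise with age; anisotropy and non-Gaussianity fall), differ
across tracts and indices (about a third of cells are flat so that
age-association weights are informative), and are modulated along the tract
so that age information concentrates mid-bundle.  All of these choices are
stand-ins for an unknown real-world generative process; see
``docs/methods.md`` for what they do and do not emulate.

Disease effects are injected separately (:func:`inject_lesion`): selected
tracts are shifted, per diffusion index, by a signed delta expressed in
healthy-population standard deviations and scaled by a severity that is a
deterministic function of the subject's clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Connectogram, PATIENT_GROUPS
from .registry import (
    INDEX_NAMES,
    INDEX_TO_IDX,
    N_INDICES,
    N_STEPS,
    N_TRACTS,
    TRACT_TO_IDX,
)

# Seed of the frozen population structure (baselines, slopes, offsets).
# All cohorts of a study share one structure; per-cohort seeds control only
# subject-level randomness.
_STRUCTURE_SEED = 76100

# Typical index magnitudes (diffusivities in 1e-3 mm^2/s units) and aging
# direction: +1 = rises with age, -1 = falls.
_INDEX_LEVEL = {"GFA": 0.45, "AD": 1.25, "RD": 0.55, "MD": 0.80,
                "NG": 0.45, "NGO": 0.30, "NGP": 0.40}
_AGING_DIRECTION = {"GFA": -1, "AD": 1, "RD": 1, "MD": 1,
                    "NG": -1, "NGO": -1, "NGP": -1}

#: Default noise scales (index units): between-subject random effect,
#: within-profile step noise, and the shared latent-factor scale.
DEFAULT_SUBJECT_SD = 0.04
DEFAULT_STEP_SD = 0.04
DEFAULT_LATENT_SD = 0.018
N_LATENT = 12

#: Healthy-population per-step SD implied by the default noise scales.
DEFAULT_POPULATION_SD = float(
    np.sqrt(DEFAULT_SUBJECT_SD**2 + N_LATENT * DEFAULT_LATENT_SD**2 + DEFAULT_STEP_SD**2)
)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


class LesionError(ValueError):
    """Invalid lesion specification or subject."""


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort draw.

    ``age_slopes``/``age_curvatures`` may be (76, 7) — one coefficient per
    tract and index, constant along the tract — or (76, 100, 7) for
    step-resolved age effects.  ``ages``/``sexes`` may be given explicitly
    (e.g. for matched groups); otherwise ages are uniform on ``age_range``
    and sex is Bernoulli(``sex_ratio``) male.
    """

    n_subjects: int
    age_range: tuple[float, float]
    sex_ratio: float
    baseline: np.ndarray
    age_slopes: np.ndarray
    age_curvatures: np.ndarray
    sex_offsets: np.ndarray
    latent_loadings: np.ndarray | None = None
    subject_sd: float = DEFAULT_SUBJECT_SD
    step_sd: float = DEFAULT_STEP_SD
    latent_sd: float = DEFAULT_LATENT_SD
    seed: int = 0
    group: str = "train"
    subject_prefix: str = "sub"
    ages: np.ndarray | None = None
    sexes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise GeneratorConfigError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise GeneratorConfigError("age_range min must be < max")
        if self.subject_sd < 0 or self.step_sd < 0 or self.latent_sd < 0:
            raise GeneratorConfigError("noise SDs must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise GeneratorConfigError("sex_ratio must be in [0, 1]")
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        if self.baseline.shape != (N_TRACTS, N_STEPS, N_INDICES):
            raise GeneratorConfigError(
                f"baseline must have shape {(N_TRACTS, N_STEPS, N_INDICES)}"
            )
        for name in ("age_slopes", "age_curvatures"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape == (N_TRACTS, N_INDICES):
                arr = np.broadcast_to(arr[:, None, :], self.baseline.shape).copy()
            elif arr.shape != (N_TRACTS, N_STEPS, N_INDICES):
                raise GeneratorConfigError(
                    f"{name} must have shape (76, 7) or (76, 100, 7)"
                )
            setattr(self, name, arr)
        self.sex_offsets = np.asarray(self.sex_offsets, dtype=np.float64)
        if self.sex_offsets.shape != (N_TRACTS, N_INDICES):
            raise GeneratorConfigError("sex_offsets must have shape (76, 7)")
        if self.latent_loadings is not None:
            self.latent_loadings = np.asarray(self.latent_loadings, dtype=np.float64)
            if (
                self.latent_loadings.ndim != 3
                or self.latent_loadings.shape[1:] != (N_TRACTS, N_INDICES)
            ):
                raise GeneratorConfigError(
                    "latent_loadings must have shape (n_factors, 76, 7)"
                )
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=np.float64)
            if self.ages.shape != (self.n_subjects,):
                raise GeneratorConfigError("explicit ages must match n_subjects")
        if self.sexes is not None:
            self.sexes = np.asarray(self.sexes)
            if self.sexes.shape != (self.n_subjects,):
                raise GeneratorConfigError("explicit sexes must match n_subjects")


@dataclass
class LesionSpec:
    """Tract-specific disease alteration, in healthy-population SD units.

    ``index_deltas`` maps diffusion-index name to a signed delta; the shift
    applied to every step of each target tract is
    ``delta * severity(subject) * population_sd``.  Severity is the
    deterministic, non-negative linear function of the clinical covariates

        max(0, intercept
               + onset_coef * (onset_ref - age_of_onset)
               + duration_coef * (duration - duration_ref)
               + frequency_coef * seizure_frequency)

    so earlier onset, longer illness and more frequent seizures all increase
    severity under the default (positive) coefficients.
    """

    target_tracts: tuple[str, ...]
    index_deltas: dict[str, float]
    intercept: float = 2.0
    onset_coef: float = 0.05
    onset_ref: float = 14.0
    duration_coef: float = 0.03
    duration_ref: float = 20.0
    frequency_coef: float = 0.8
    population_sd: float = DEFAULT_POPULATION_SD

    def __post_init__(self) -> None:
        for t in self.target_tracts:
            if t not in TRACT_TO_IDX:
                raise LesionError(f"unknown tract name {t!r}")
        for k in self.index_deltas:
            if k not in INDEX_TO_IDX:
                raise LesionError(f"unknown diffusion index {k!r}")

    def severity(self, subject) -> float:
        """Deterministic severity for one subject record (row or mapping)."""
        for fieldname in ("age_of_onset", "duration_of_illness", "seizure_frequency"):
            v = subject[fieldname]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise LesionError(f"subject lacks clinical field {fieldname!r}")
        raw = (
            self.intercept
            + self.onset_coef * (self.onset_ref - float(subject["age_of_onset"]))
            + self.duration_coef
            * (float(subject["duration_of_illness"]) - self.duration_ref)
            + self.frequency_coef * float(subject["seizure_frequency"])
        )
        return max(0.0, raw)

    def scaled(self, factor: float) -> "LesionSpec":
        """Same lesion topography with severity scaled by ``factor``."""
        return replace(
            self,
            intercept=self.intercept * factor,
            onset_coef=self.onset_coef * factor,
            duration_coef=self.duration_coef * factor,
            frequency_coef=self.frequency_coef * factor,
        )


def population_structure(structure_seed: int = _STRUCTURE_SEED):
    """Frozen population parameters shared by all cohorts of a study.

    Returns (baseline, age_slopes, age_curvatures, sex_offsets,
    latent_loadings) with shapes (76, 100, 7), (76, 100, 7), (76, 100, 7),
    (76, 7), (12, 76, 7).
    """
    rng = np.random.default_rng(structure_seed)
    s = np.arange(N_STEPS)
    levels = np.array([_INDEX_LEVEL[k] for k in INDEX_NAMES])
    directions = np.array([_AGING_DIRECTION[k] for k in INDEX_NAMES], dtype=float)

    # Smooth baselines: level * (1 + sum_h a_h cos(pi h s / 99 + phi_h)).
    baseline = np.ones((N_TRACTS, N_STEPS, N_INDICES))
    for h in (1, 2, 3):
        amp = rng.uniform(-0.06, 0.06, size=(N_TRACTS, 1, N_INDICES)) / h
        phase = rng.uniform(0, 2 * np.pi, size=(N_TRACTS, 1, N_INDICES))
        baseline += amp * np.cos(np.pi * h * s[None, :, None] / (N_STEPS - 1) + phase)
    baseline *= levels[None, None, :]

    # Linear age effects: ~1/3 of cells flat, the rest with the canonical
    # aging sign and magnitude 0.002-0.006 index units per year, modulated
    # along the tract so mid-bundle steps carry most age information.
    informative = rng.random((N_TRACTS, N_INDICES)) >= (1.0 / 3.0)
    magnitude = rng.uniform(0.002, 0.006, size=(N_TRACTS, N_INDICES))
    cell_slope = informative * magnitude * directions[None, :]
    modulation = 0.25 + 0.75 * np.sin(np.pi * s / (N_STEPS - 1)) ** 2
    slopes = cell_slope[:, None, :] * modulation[None, :, None]

    curvatures = rng.uniform(-1.5e-5, 1.5e-5, size=(N_TRACTS, N_INDICES))
    curvatures = np.broadcast_to(curvatures[:, None, :], slopes.shape).copy()

    sex_offsets = rng.normal(0.0, 0.02, size=(N_TRACTS, N_INDICES))
    latent_loadings = rng.normal(0.0, 1.0, size=(N_LATENT, N_TRACTS, N_INDICES))
    return baseline, slopes, curvatures, sex_offsets, latent_loadings


def default_config(
    n_subjects: int,
    seed: int,
    age_range: tuple[float, float] = (18.0, 92.0),
    sex_ratio: float = 0.5,
    **overrides,
) -> GeneratorConfig:
    """A cohort config over the frozen default population structure."""
    baseline, slopes, curvatures, sex_offsets, latent = population_structure()
    params = dict(
        n_subjects=n_subjects,
        age_range=age_range,
        sex_ratio=sex_ratio,
        baseline=baseline,
        age_slopes=slopes,
        age_curvatures=curvatures,
        sex_offsets=sex_offsets,
        latent_loadings=latent,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def generate_cohort(config: GeneratorConfig):
    """Draw one cohort.

    Returns ``(connectograms, cohort_table)`` where connectograms is a list
    of :class:`~tractage.io.Connectogram` and the table is a cohort
    DataFrame.  Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    if config.ages is not None:
        ages = config.ages.copy()
    else:
        ages = rng.uniform(*config.age_range, size=n)
    if config.sexes is not None:
        sexes = np.asarray(config.sexes, dtype=object)
    else:
        sexes = np.where(rng.random(n) < config.sex_ratio, "M", "F").astype(object)
    handedness = np.clip(rng.normal(90.0, 22.0, size=n), -100.0, 100.0)

    male = (sexes == "M").astype(float)
    values = (
        config.baseline[None]
        + config.age_slopes[None] * ages[:, None, None, None]
        + config.age_curvatures[None] * (ages**2)[:, None, None, None]
        + config.sex_offsets[None, :, None, :] * male[:, None, None, None]
    )
    if config.latent_loadings is not None and config.latent_sd > 0:
        scores = rng.normal(0.0, 1.0, size=(n, config.latent_loadings.shape[0]))
        shared = config.latent_sd * np.einsum(
            "nl,ltk->ntk", scores, config.latent_loadings
        )
        values = values + shared[:, :, None, :]
    if config.subject_sd > 0:
        values = values + (
            rng.normal(0.0, config.subject_sd, size=(n, N_TRACTS, N_INDICES))[
                :, :, None, :
            ]
        )
    if config.step_sd > 0:
        values = values + rng.normal(0.0, config.step_sd, size=values.shape)

    ids = [f"{config.subject_prefix}{i:04d}" for i in range(n)]
    connectograms = [Connectogram(sid, values[i]) for i, sid in enumerate(ids)]
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "age": ages,
            "sex": sexes,
            "handedness": handedness,
            "group": config.group,
            "age_of_onset": np.nan,
            "duration_of_illness": np.nan,
            "seizure_frequency": np.nan,
            "n_aed_classes": np.nan,
        }
    )
    return connectograms, table


def inject_lesion(
    connectogram: Connectogram, subject, spec: LesionSpec
) -> Connectogram:
    """Apply a tract-specific lesion to one subject's connectogram.

    Target tracts are shifted per index by ``delta * severity *
    population_sd`` uniformly along the tract; all other cells are
    bit-identical to the input.
    """
    severity = spec.severity(subject)
    values = connectogram.values.copy()
    for tract in spec.target_tracts:
        t = TRACT_TO_IDX[tract]
        for index, delta in spec.index_deltas.items():
            k = INDEX_TO_IDX[index]
            values[t, :, k] += delta * severity * spec.population_sd
    return Connectogram(connectogram.subject_id, values)


def default_lesion_spec(strength: float = 1.0) -> LesionSpec:
    """The default disease topography for the strongly-affected group.

    Five target tracts (temporal-lobe association fibers and orbitofrontal
    frontostriatal projections) with diffusivities raised and anisotropy /
    parallel non-Gaussianity lowered — the canonical degeneration pattern.
    ``strength`` scales all severity coefficients (1.0 = strong effect,
    used for the right-lateralized patient group; the contralateral group
    uses a quarter-strength copy).
    """
    spec = LesionSpec(
        target_tracts=("UF_R", "FS_OFC_R", "IFOF_L", "ILF_L", "PerpF_R"),
        index_deltas={"GFA": -0.8, "AD": 0.4, "RD": 1.0, "MD": 0.9, "NGP": -0.5},
    )
    return spec.scaled(strength) if strength != 1.0 else spec


def strong_lesion_spec() -> LesionSpec:
    """The strong-effect lesion setting used for recovery analyses.

    Same topography as :func:`default_lesion_spec` but with the seizure-
    frequency coupling raised to 3.0 severity units per seizure/month, so
    clinical severity dominates prediction noise.
    """
    return replace(default_lesion_spec(), frequency_coef=3.0)


# Clinical covariate moments typical of unilateral-MTLE case series:
# (onset mean, sd), (duration mean, sd), (frequency mean, sd), (AED mean, sd)
_CLINICAL_MOMENTS = {
    "lmtle": ((14.5, 5.6), (22.9, 7.7), (1.56, 1.73), (2.39, 1.33)),
    "rmtle": ((12.5, 6.7), (25.5, 9.3), (1.09, 1.31), (2.71, 0.69)),
}

#: Study cohort sizes: training/testing for the age model, the normative
#: cohort, and the age- and sex-matched study groups.
STUDY_SIZES = {
    "train": 300,
    "test": 40,
    "normative": 524,
    "control": 37,
    "lmtle": 18,
    "rmtle": 17,
}

# Exact male counts for the matched study groups (controls 17/37 etc.).
_STUDY_MALES = {"control": 17, "lmtle": 10, "rmtle": 9}

# Lifespan age bands for the model cohorts: under 40 / 40-60 / over 60,
# with weights matching the training-set composition (49.0/20.7/30.3%).
_AGE_BANDS = ((18.0, 40.0), (40.0, 60.0), (60.0, 92.0))
_BAND_WEIGHTS = (0.490, 0.207, 0.303)


def _lifespan_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    bands = rng.choice(len(_AGE_BANDS), size=n, p=_BAND_WEIGHTS)
    lo = np.array([_AGE_BANDS[b][0] for b in bands])
    hi = np.array([_AGE_BANDS[b][1] for b in bands])
    return rng.uniform(lo, hi)


def _matched_group_ages(rng: np.random.Generator, sizes: dict) -> dict:
    """Draw study-group ages matched by stratified (sorted-interleaved)
    assignment, so group means agree closely by construction."""
    names = ("control", "lmtle", "rmtle")
    total = sum(sizes[g] for g in names)
    pooled = np.sort(np.clip(rng.normal(38.0, 8.3, size=total), 20.0, 58.0))
    # Proportional systematic assignment over the sorted pool.
    quota = {g: sizes[g] for g in names}
    frac = {g: 0.0 for g in names}
    out = {g: [] for g in names}
    for a in pooled:
        for g in names:
            frac[g] += quota[g] / total
        g = max(names, key=lambda x: frac[x] if len(out[x]) < quota[x] else -np.inf)
        frac[g] -= 1.0
        out[g].append(a)
    return {g: rng.permutation(np.array(out[g])) for g in names}


def _group_sexes(rng: np.random.Generator, n: int, n_male: int) -> np.ndarray:
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)
    return rng.permutation(sexes)


def _clinical_covariates(rng: np.random.Generator, group: str, n: int) -> dict:
    (om, osd), (dm, dsd), (fm, fsd), (am, asd) = _CLINICAL_MOMENTS[group]
    onset = np.clip(rng.normal(om, osd, size=n), 3.0, 35.0)
    duration = np.clip(rng.normal(dm, dsd, size=n), 2.0, 45.0)
    frequency = np.clip(rng.normal(fm, fsd, size=n), 0.05, None)
    aed = np.clip(np.round(rng.normal(am, asd, size=n)), 1, 6)
    return {
        "age_of_onset": onset,
        "duration_of_illness": duration,
        "seizure_frequency": frequency,
        "n_aed_classes": aed,
    }


def make_study_suite(
    seed: int,
    sizes: dict | None = None,
    lesion_specs: dict | None = None,
    subject_sd: float = DEFAULT_SUBJECT_SD,
    step_sd: float = DEFAULT_STEP_SD,
    latent_sd: float = DEFAULT_LATENT_SD,
):
    """Generate the full study: training, testing, normative, control and
    two patient cohorts, with lesions injected into the patient groups.

    Returns a dict mapping cohort name to ``(connectograms, cohort_table)``.
    ``sizes`` may override :data:`STUDY_SIZES` (e.g. for fast tests);
    ``lesion_specs`` maps patient group to a :class:`LesionSpec` or ``None``
    for unlesioned patients.  Defaults: strong lesion in ``rmtle``,
    quarter-strength in ``lmtle``.
    """
    sizes = {**STUDY_SIZES, **(sizes or {})}
    if lesion_specs is None:
        lesion_specs = {
            "rmtle": default_lesion_spec(1.0),
            "lmtle": default_lesion_spec(0.25),
        }
    root = np.random.SeedSequence([int(seed), 20191023])
    cohort_seeds = {
        name: int(ss.generate_state(1)[0] % 2**31)
        for name, ss in zip(STUDY_SIZES, root.spawn(len(STUDY_SIZES)))
    }
    plan_rng = np.random.default_rng(
        int(root.spawn(10)[9].generate_state(1)[0] % 2**31)
    )
    group_ages = _matched_group_ages(
        plan_rng, {g: sizes[g] for g in ("control", "lmtle", "rmtle")}
    )

    suite = {}
    noise = dict(subject_sd=subject_sd, step_sd=step_sd, latent_sd=latent_sd)
    for name, prefix, age_mode in (
        ("train", "trn", "lifespan"),
        ("test", "tst", "lifespan"),
        ("normative", "nrm", "uniform"),
        ("control", "ctl", "matched"),
        ("lmtle", "lmt", "matched"),
        ("rmtle", "rmt", "matched"),
    ):
        n = sizes[name]
        kw = dict(group=name, subject_prefix=prefix, **noise)
        if age_mode == "lifespan":
            ages_rng = np.random.default_rng(cohort_seeds[name] ^ 0x5A5A5A)
            kw["ages"] = _lifespan_ages(ages_rng, n)
            cfg = default_config(n, cohort_seeds[name], age_range=(18.0, 92.0), **kw)
        elif age_mode == "uniform":
            cfg = default_config(n, cohort_seeds[name], age_range=(7.0, 92.0), **kw)
        else:
            kw["ages"] = group_ages[name][:n]
            n_male = int(round(n * _STUDY_MALES[name] / STUDY_SIZES[name]))
            kw["sexes"] = _group_sexes(plan_rng, n, min(max(n_male, 1), n - 1) if n >= 2 else n_male)
            cfg = default_config(n, cohort_seeds[name], age_range=(18.0, 60.0), **kw)
        connectograms, table = generate_cohort(cfg)
        if name in PATIENT_GROUPS:
            clin_rng = np.random.default_rng(cohort_seeds[name] ^ 0xC11)
            covars = _clinical_covariates(clin_rng, name, n)
            for col, arr in covars.items():
                table[col] = arr
            spec = lesion_specs.get(name)
            if spec is not None:
                connectograms = [
                    inject_lesion(c, table.iloc[i], spec)
                    for i, c in enumerate(connectograms)
                ]
        suite[name] = (connectograms, table)
    return suite
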