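"""Text serialization of connectograms and cohort metadata.

A connectogram is stored as long-format tab-separated text with columns
``subject, tract, step, index, value`` — one row per (tract, step, index)
cell, 53,200 rows per subject.  The format is diff-able, language neutral
and lossless: floats are written with shortest round-trip ``repr`` and read
back with round-trip precision, so ``read(write(c)) == c`` bit for bit.

Cohort metadata travels as a CSV with one row per subject (see
:data:`COHORT_COLUMNS` for the column dictionary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import (
    INDEX_NAMES,
    INDEX_TO_IDX,
    N_INDICES,
    N_STEPS,
    N_TRACTS,
    TRACT_NAMES,
    TRACT_TO_IDX,
)

GROUPS = ("train", "test", "normative", "control", "lmtle", "rmtle")
PATIENT_GROUPS = ("lmtle", "rmtle")
CLINICAL_FIELDS = (
    "age_of_onset",
    "duration_of_illness",
    "seizure_frequency",
    "n_aed_classes",
)

#: Column dictionary for the cohort CSV.
COHORT_COLUMNS = (
    "subject_id",            # unique string identifier
    "age",                   # years
    "sex",                   # "M" or "F"
    "handedness",            # Edinburgh inventory percent, -100..100
    "group",                 # one of GROUPS
    "age_of_onset",          # years; patients only
    "duration_of_illness",   # years; patients only
    "seizure_frequency",     # per month; patients only
    "n_aed_classes",         # count of anti-epileptic drug classes; patients only
)


class ConnectogramError(ValueError):
    """Malformed connectogram data or file."""


class CohortError(ValueError):
    """Malformed cohort table."""


@dataclass
class Connectogram:
    """One subject's along-tract diffusion profiles.

    ``values[t, s, k]`` is the value of diffusion index ``k`` at normalized
    step ``s`` (0-99) along tract ``t``, in the canonical registry order.
    """

    subject_id: str
    values: np.ndarray
    tract_names: tuple[str, ...] = field(default=TRACT_NAMES)
    index_names: tuple[str, ...] = field(default=INDEX_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_TRACTS, N_STEPS, N_INDICES):
            raise ConnectogramError(
                f"connectogram for {self.subject_id!r} has shape "
                f"{self.values.shape}, expected {(N_TRACTS, N_STEPS, N_INDICES)}"
            )
        if tuple(self.tract_names) != TRACT_NAMES:
            raise ConnectogramError("tract ordering differs from the canonical registry")
        if tuple(self.index_names) != INDEX_NAMES:
            raise ConnectogramError("index ordering differs from the canonical registry")
        if not np.all(np.isfinite(self.values)):
            raise ConnectogramError(
                f"connectogram for {self.subject_id!r} contains non-finite values"
            )


def stack_cohort(connectograms) -> np.ndarray:
    """Stack connectograms into an (n, 76, 100, 7) array in subject order."""
    return np.stack([c.values for c in connectograms], axis=0)


def write_connectogram(c: Connectogram, path) -> None:
    """Write one connectogram as long-format TSV (full float precision)."""
    n = N_TRACTS * N_STEPS * N_INDICES
    frame = pd.DataFrame(
        {
            "subject": np.repeat(c.subject_id, n),
            "tract": np.repeat(TRACT_NAMES, N_STEPS * N_INDICES),
            "step": np.tile(np.repeat(np.arange(N_STEPS), N_INDICES), N_TRACTS),
            "index": np.tile(INDEX_NAMES, N_TRACTS * N_STEPS),
            "value": c.values.ravel(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_connectogram(path) -> Connectogram:
    """Read a long-format connectogram TSV, validating the full grid.

    Rows may appear in any order; the result is always in canonical
    registry order.  Errors name the first offending row (1-based data row
    numbers, excluding the header).
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    expected = ["subject", "tract", "step", "index", "value"]
    if list(frame.columns) != expected:
        raise ConnectogramError(
            f"{path}: expected columns {expected}, found {list(frame.columns)}"
        )
    subjects = frame["subject"].unique()
    if len(subjects) != 1:
        raise ConnectogramError(f"{path}: expected one subject, found {len(subjects)}")

    tract_idx = frame["tract"].map(TRACT_TO_IDX)
    if tract_idx.isna().any():
        row = int(tract_idx.index[tract_idx.isna()][0]) + 1
        raise ConnectogramError(
            f"{path}: unknown tract name {frame['tract'][row - 1]!r} at row {row}"
        )
    index_idx = frame["index"].map(INDEX_TO_IDX)
    if index_idx.isna().any():
        row = int(index_idx.index[index_idx.isna()][0]) + 1
        raise ConnectogramError(
            f"{path}: unknown index name {frame['index'][row - 1]!r} at row {row}"
        )
    steps = frame["step"].to_numpy()
    if steps.min() < 0 or steps.max() >= N_STEPS:
        row = int(np.flatnonzero((steps < 0) | (steps >= N_STEPS))[0]) + 1
        raise ConnectogramError(f"{path}: step out of range 0-99 at row {row}")

    flat = (
        tract_idx.to_numpy() * (N_STEPS * N_INDICES)
        + steps * N_INDICES
        + index_idx.to_numpy()
    ).astype(np.int64)
    counts = np.bincount(flat, minlength=N_TRACTS * N_STEPS * N_INDICES)
    if (counts > 1).any():
        dup_flat = int(np.flatnonzero(counts > 1)[0])
        row = int(np.flatnonzero(flat == dup_flat)[1]) + 1
        raise ConnectogramError(
            f"{path}: duplicate (tract, step, index) key at row {row}"
        )
    if (counts == 0).any():
        missing_tracts = N_TRACTS - len(np.unique(tract_idx))
        if missing_tracts:
            raise ConnectogramError(
                f"{path}: incomplete tract set ({missing_tracts} of "
                f"{N_TRACTS} tracts missing)"
            )
        miss = int(np.flatnonzero(counts == 0)[0])
        t, rem = divmod(miss, N_STEPS * N_INDICES)
        s, k = divmod(rem, N_INDICES)
        raise ConnectogramError(
            f"{path}: missing cell (tract={TRACT_NAMES[t]}, step={s}, "
            f"index={INDEX_NAMES[k]})"
        )

    values = np.empty(N_TRACTS * N_STEPS * N_INDICES, dtype=np.float64)
    values[flat] = frame["value"].to_numpy(dtype=np.float64)
    return Connectogram(
        subject_id=str(subjects[0]),
        values=values.reshape(N_TRACTS, N_STEPS, N_INDICES),
    )


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with the canonical column set."""
    table.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Clinical fields may be empty only for non-patient groups; patient rows
    (``lmtle``/``rmtle``) must carry all four clinical variables.
    """
    table = pd.read_csv(path, float_precision="round_trip", dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"{path}: missing columns {missing}")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortError(f"{path}: duplicate subject_id {dup!r}")
    bad_group = ~table["group"].isin(GROUPS)
    if bad_group.any():
        raise CohortError(
            f"{path}: unknown group {table.loc[bad_group, 'group'].iloc[0]!r}"
        )
    bad_sex = ~table["sex"].isin(("M", "F"))
    if bad_sex.any():
        raise CohortError(f"{path}: sex must be 'M' or 'F'")
    patients = table["group"].isin(PATIENT_GROUPS)
    for col in CLINICAL_FIELDS:
        incomplete = patients & table[col].isna()
        if incomplete.any():
            sid = table.loc[incomplete, "subject_id"].iloc[0]
            raise CohortError(
                f"{path}: patient {sid!r} is missing clinical field {col!r}"
            )
    return table


def validate_cohort_against_connectograms(table: pd.DataFrame, connectograms) -> None:
    """Check that every connectogram subject appears exactly once in the table."""
    ids = set(table["subject_id"])
    for c in connectograms:
        if c.subject_id not in ids:
            raise CohortError(f"connectogram subject {c.subject_id!r} not in cohort table")
    seen = [c.subject_id for c in connectograms]
    if len(seen) != len(set(seen)):
        raise CohortError("duplicate connectogram subject ids")
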