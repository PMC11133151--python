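"""Trial-level reaction-time data: types, validation, CSV reading/writing.

The on-disk format is a long-format, comma-separated, UTF-8 CSV with a
mandatory header and one row per task trial:

    participant_id, trial_index, phase, condition, colour, correct, rt_ms, block_id

``phase`` is ``practice`` or ``critical``; ``condition`` is ``alcohol`` or
``neutral`` and must be present on every critical trial (practice trials may
leave it empty); ``correct`` is encoded 0/1; ``rt_ms`` is a positive real
number of milliseconds, left empty when no response was registered before the
3000-ms timeout (timed-out trials are stored with ``correct=0`` and an empty
``rt_ms``, never ``rt_ms=3000``); ``colour`` and ``block_id`` are optional
labels. Participant covariates travel in a second CSV keyed by
``participant_id`` with optional ``craving`` (0-100) and ``distracted`` (0/1)
columns.

Validation is total: every malformed row raises with its row index; nothing is
silently coerced or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Response window in milliseconds; slower trials time out and are coded
#: incorrect with no recorded RT.
TIMEOUT_MS = 3000.0

#: Critical-trial counts implied by each known task layout.
LAYOUT_CRITICAL_TRIALS = {
    "mobile_blocked_66": 66,
    "web_random_168": 168,
}
#: Practice-trial counts implied by each known task layout.
LAYOUT_PRACTICE_TRIALS = {
    "mobile_blocked_66": 0,
    "web_random_168": 24,
}

LAYOUTS = ("mobile_blocked_66", "web_random_168", "custom")
PHASES = ("practice", "critical")
CONDITIONS = ("alcohol", "neutral")

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "phase",
    "condition",
    "colour",
    "correct",
    "rt_ms",
    "block_id",
]
REQUIRED_TRIAL_COLUMNS = ["participant_id", "trial_index", "phase", "condition",
                          "correct", "rt_ms"]

COVARIATE_COLUMNS = ["participant_id", "craving", "distracted"]


@dataclass
class Dataset:
    """A validated trial table plus optional participant covariates.

    ``trials`` holds one row per trial with the columns documented above;
    ``covariates`` (may be ``None``) holds one row per participant. ``layout``
    names the task design; when it is not ``custom`` the per-participant
    critical-trial count must match the design.
    """

    trials: pd.DataFrame
    covariates: pd.DataFrame | None = None
    layout: str = "custom"

    def __post_init__(self) -> None:
        self.trials = _normalize_trials(self.trials)
        if self.covariates is not None:
            self.covariates = _normalize_covariates(self.covariates)
        validate_dataset(self)

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant_id"].unique().tolist())

    @property
    def critical_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["phase"] == "critical"]

    def __eq__(self, other) -> bool:  # field-for-field, NaN-tolerant
        if not isinstance(other, Dataset):
            return NotImplemented
        if self.layout != other.layout:
            return False
        if not _frames_equal(self.trials, other.trials):
            return False
        if (self.covariates is None) != (other.covariates is None):
            return False
        if self.covariates is not None and not _frames_equal(
            self.covariates, other.covariates
        ):
            return False
        return True


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True), check_dtype=False
        )
        return True
    except AssertionError:
        return False


def _normalize_trials(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            if col in REQUIRED_TRIAL_COLUMNS:
                raise SchemaError(f"missing required column: {col!r}")
            df[col] = None
    df = df[TRIAL_COLUMNS]
    df["participant_id"] = df["participant_id"].astype(str)
    df["trial_index"] = pd.to_numeric(df["trial_index"], errors="raise").astype(int)
    df["phase"] = df["phase"].astype(str)
    df["condition"] = df["condition"].astype(object).where(df["condition"].notna(), None)
    df["colour"] = df["colour"].astype(object).where(df["colour"].notna(), None)
    df["correct"] = _parse_correct(df["correct"])
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="raise").astype(float)
    df["block_id"] = df["block_id"].astype(object).where(df["block_id"].notna(), None)
    return df.reset_index(drop=True)


def _parse_correct(s: pd.Series) -> pd.Series:
    mapped = s.map(
        {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
         1.0: True, 0.0: False, "True": True, "False": False}
    )
    if mapped.isna().any():
        bad = int(mapped.index[mapped.isna()][0])
        raise ValidationError(f"row {bad}: 'correct' must be 0/1, got {s.iloc[bad]!r}")
    return mapped.astype(bool)


def _normalize_covariates(df: pd.DataFrame) -> pd.DataFrame:
    if "participant_id" not in df.columns:
        raise SchemaError("covariates: missing required column: 'participant_id'")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    if "craving" in df.columns:
        df["craving"] = pd.to_numeric(df["craving"], errors="raise").astype(float)
    if "distracted" in df.columns:
        df["distracted"] = df["distracted"].map(
            {True: True, False: False, 1: True, 0: False, "1": True, "0": False,
             1.0: True, 0.0: False}
        )
    return df.reset_index(drop=True)


def validate_dataset(ds: Dataset) -> None:
    """Raise on any violated invariant; silent on a valid dataset."""
    trials = ds.trials
    if ds.layout not in LAYOUTS:
        raise ValidationError(f"unknown layout {ds.layout!r}; expected one of {LAYOUTS}")

    bad_phase = ~trials["phase"].isin(PHASES)
    if bad_phase.any():
        i = int(trials.index[bad_phase][0])
        raise ValidationError(f"row {i}: phase must be practice/critical, got "
                              f"{trials.loc[i, 'phase']!r}")

    crit = trials["phase"] == "critical"
    cond_missing = crit & ~trials["condition"].isin(CONDITIONS)
    if cond_missing.any():
        i = int(trials.index[cond_missing][0])
        raise ValidationError(
            f"row {i}: critical trial lacks a valid condition "
            f"(got {trials.loc[i, 'condition']!r})"
        )

    rt = trials["rt_ms"]
    has_rt = rt.notna()
    nonpos = has_rt & (rt <= 0)
    if nonpos.any():
        i = int(trials.index[nonpos][0])
        raise ValidationError(f"row {i}: rt_ms must be > 0, got {rt.iloc[i]!r}")
    over = has_rt & (rt > TIMEOUT_MS)
    if over.any():
        i = int(trials.index[over][0])
        raise ValidationError(
            f"row {i}: rt_ms exceeds the {TIMEOUT_MS:.0f} ms timeout: {rt.iloc[i]!r}"
        )
    timeout_correct = ~has_rt & trials["correct"]
    if timeout_correct.any():
        i = int(trials.index[timeout_correct][0])
        raise ValidationError(
            f"row {i}: trial without a recorded RT (timeout) must have correct=0"
        )

    if ds.covariates is not None:
        cov = ds.covariates
        known = set(trials["participant_id"].unique())
        orphan = ~cov["participant_id"].isin(known)
        if orphan.any():
            pid = cov.loc[cov.index[orphan][0], "participant_id"]
            raise ValidationError(
                f"covariates reference unknown participant {pid!r}"
            )
        if "craving" in cov.columns:
            c = cov["craving"]
            bad = c.notna() & ((c < 0) | (c > 100))
            if bad.any():
                i = int(cov.index[bad][0])
                raise ValidationError(
                    f"covariates row {i}: craving must lie in [0, 100], got {c.iloc[i]!r}"
                )

    if ds.layout != "custom":
        expected = LAYOUT_CRITICAL_TRIALS[ds.layout]
        counts = trials[crit].groupby("participant_id").size()
        mismatched = counts[counts != expected]
        if len(mismatched):
            pid = mismatched.index[0]
            raise ValidationError(
                f"participant {pid!r} has {int(mismatched.iloc[0])} critical trials; "
                f"layout {ds.layout!r} requires {expected}"
            )


def read_dataset(
    path: str | Path,
    layout: str = "custom",
    covariates_path: str | Path | None = None,
) -> Dataset:
    """Read a trial CSV (and optionally a covariate CSV) into a validated Dataset.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`ValidationError` (naming the row) when a value is malformed; rows
    are never silently dropped or repaired.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    trials = pd.read_csv(path, dtype={"participant_id": str}, encoding="utf-8")
    try:
        trials = _normalize_trials(trials)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    covariates = None
    if covariates_path is not None:
        covariates = pd.read_csv(
            covariates_path, dtype={"participant_id": str}, encoding="utf-8"
        )
    return Dataset(trials=trials, covariates=covariates, layout=layout)


def write_dataset(
    ds: Dataset, path: str | Path, covariates_path: str | Path | None = None
) -> None:
    """Write a Dataset back to CSV; ``read_dataset`` of the output reproduces it.

    ``correct`` is written 0/1; a timed-out trial has an empty ``rt_ms`` cell.
    """
    out = ds.trials.copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False, encoding="utf-8")
    if covariates_path is not None and ds.covariates is not None:
        cov = ds.covariates.copy()
        if "distracted" in cov.columns:
            cov["distracted"] = cov["distracted"].map(
                lambda v: "" if pd.isna(v) else int(bool(v))
            )
        cov.to_csv(covariates_path, index=False, encoding="utf-8")
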