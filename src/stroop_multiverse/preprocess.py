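"""Base cleaning applied once, before any outlier-handling specification.

Two rules, applied to every dataset exactly once:

1. practice trials are removed;
2. RTs from incorrect trials never enter any RT computation (mean, SD,
   median, MAD, cutoff) — incorrect trials are kept only as error counts.

Error-rate denominators use *all* critical trials (correct, incorrect, and
timed out). A timed-out trial has no recorded RT: it counts as an error and
contributes no RT anywhere, including the fast-guess (< 200 ms) participant
screen, which operates on critical trials with a recorded RT regardless of
correctness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .trial_data import Dataset


@dataclass
class BaseDataset:
    """The cleaned dataset every specification starts from.

    ``valid_rts``: one row per correct critical trial with a recorded RT
    (columns ``participant_id``, ``condition``, ``rt_ms``).
    ``recorded_rts``: one row per critical trial with a recorded RT regardless
    of correctness (same columns) — used only by the fast-RT participant screen.
    ``error_counts``: per participant, ``n_errors`` (incorrect + timed out) and
    ``n_critical`` (all critical trials).
    ``flagged``: participants with zero correct RTs in one or both conditions;
    they are retained here and dropped pairwise (and logged) downstream.
    """

    valid_rts: pd.DataFrame
    recorded_rts: pd.DataFrame
    error_counts: pd.DataFrame
    covariates: pd.DataFrame | None = None
    flagged: frozenset = field(default_factory=frozenset)

    @property
    def participants(self) -> list:
        return sorted(self.error_counts["participant_id"].tolist())


def clean_base(ds: Dataset) -> BaseDataset:
    """Build the cleaned base dataset (practice removed, incorrect RTs excluded).

    Idempotent in effect: a dataset already containing only correct critical
    trials passes through unchanged. Raises :class:`ValidationError` when the
    dataset has no critical trials.

    Participants with no correct RT in one or both conditions are retained but
    flagged; trial-count conservation (``n_errors + correct = n_critical``)
    holds per participant by construction.
    """
    crit = ds.critical_trials
    if len(crit) == 0:
        raise ValidationError("dataset contains no critical trials")

    correct = crit[crit["correct"] & crit["rt_ms"].notna()]
    valid_rts = correct[["participant_id", "condition", "rt_ms"]].reset_index(drop=True)
    recorded = crit[crit["rt_ms"].notna()]
    recorded_rts = recorded[["participant_id", "condition", "rt_ms"]].reset_index(
        drop=True
    )

    per = crit.groupby("participant_id", sort=True)
    error_counts = pd.DataFrame(
        {
            "participant_id": list(per.groups),
            "n_errors": per.apply(
                lambda g: int((~g["correct"]).sum()), include_groups=False
            ).values,
            "n_critical": per.size().values,
        }
    ).reset_index(drop=True)

    cell_counts = valid_rts.groupby(["participant_id", "condition"]).size().unstack(
        fill_value=0
    )
    flagged = set()
    for pid in error_counts["participant_id"]:
        n_alc = int(cell_counts["alcohol"].get(pid, 0)) if "alcohol" in cell_counts else 0
        n_neu = int(cell_counts["neutral"].get(pid, 0)) if "neutral" in cell_counts else 0
        if n_alc == 0 or n_neu == 0:
            flagged.add(pid)

    return BaseDataset(
        valid_rts=valid_rts,
        recorded_rts=recorded_rts,
        error_counts=error_counts,
        covariates=ds.covariates,
        flagged=frozenset(flagged),
    )
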