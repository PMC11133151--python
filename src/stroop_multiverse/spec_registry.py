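"""The registry of 27 outlier-handling specifications and their operators.

Each specification is one complete, *isolated* data-handling pipeline: it is
applied to the same cleaned base dataset, never chained after another
specification. Six decision categories partition the registry:

====================  ==  ========================================================
category               n  decision
====================  ==  ========================================================
no_exclusion           2  keep everything; interference from per-participant
                          medians, or means
sd_based               6  remove/replace trial RTs relative to the participant's
                          mean +/- k * SD (pooled across conditions)
raw_rt_cutoff          8  remove trial RTs beyond a fixed millisecond bound
participant_removal    7  drop whole participants by sample-level screens
mad_based              2  remove trial RTs relative to the participant's
                          median +/- 2.5 * MAD
trimmed_mean           2  drop the most extreme participants by interference
                          score (10% or 20% total, split across tails)
====================  ==  ========================================================

Conventions, applied uniformly:

* removal comparisons are strict (``>`` / ``<``), matching the printed rules;
* per-participant statistics pool alcohol and neutral RTs into one
  distribution — a single pass, no iteration to convergence;
* the sample SD uses the n-1 denominator; MAD uses the normal-consistency
  constant b = 1.4826;
* degenerate dispersion (participant SD or MAD of 0, or a sample-level SD of
  0) removes nothing: the bounds collapse onto the centre and the rule is
  vacuous rather than all-destroying;
* a participant with fewer than 2 pooled RTs passes through a trial-level
  filter unfiltered (and is logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import BaseDataset

#: Normal-consistency scale factor for the median absolute deviation.
MAD_CONSISTENCY = 1.4826

CATEGORIES = (
    "no_exclusion",
    "sd_based",
    "raw_rt_cutoff",
    "participant_removal",
    "mad_based",
    "trimmed_mean",
)


@dataclass(frozen=True)
class Specification:
    """One named pipeline: a decision category, an operator, and parameters."""

    spec_id: str
    category: str
    operator: str
    params: Mapping = field(default_factory=dict)
    label: str = ""

    #: centre statistic used when collapsing each participant x condition cell
    center: str = "mean"


@dataclass
class RemovalLog:
    """Bookkeeping for one specification run."""

    n_trials_removed: int = 0
    n_trials_replaced: int = 0
    n_participants_removed: int = 0
    participants_removed: dict = field(default_factory=dict)  # pid -> reason
    trials_removed_by_participant: dict = field(default_factory=dict)
    unfiltered_participants: list = field(default_factory=list)


@dataclass
class AnalysisDataset:
    """A base dataset after one specification's filter/replacement.

    ``rts`` has one row per retained (or replaced) correct critical trial with
    columns ``participant_id``, ``condition``, ``rt_ms``; for replacement
    operators the row count equals the base's. ``retained_participants`` is
    the set entering estimation; ``removal_log`` records what was removed,
    replaced, or skipped and why.
    """

    rts: pd.DataFrame
    retained_participants: frozenset
    removal_log: RemovalLog
    spec: Specification
    base_flagged: frozenset = field(default_factory=frozenset)


def build_registry() -> list[Specification]:
    """The canonical ordered registry of 27 specifications."""
    specs: list[Specification] = []

    specs.append(Specification(
        "noexcl_median", "no_exclusion", "identity", {}, "No exclusions (median RTs)",
        center="median"))
    specs.append(Specification(
        "noexcl_mean", "no_exclusion", "identity", {}, "No exclusions (mean RTs)"))

    specs.append(Specification(
        "sd_remove_2s_3", "sd_based", "sd_filter",
        {"k_upper": 3.0, "k_lower": 3.0, "mode": "remove"},
        "Remove RTs > 3 SD or < 3 SD from individual mean"))
    specs.append(Specification(
        "sd_remove_2s_2", "sd_based", "sd_filter",
        {"k_upper": 2.0, "k_lower": 2.0, "mode": "remove"},
        "Remove RTs > 2 SD or < 2 SD from individual mean"))
    specs.append(Specification(
        "sd_remove_up_2", "sd_based", "sd_filter",
        {"k_upper": 2.0, "k_lower": None, "mode": "remove"},
        "Remove RTs > 2 SD from individual mean"))
    specs.append(Specification(
        "sd_remove_up_3", "sd_based", "sd_filter",
        {"k_upper": 3.0, "k_lower": None, "mode": "remove"},
        "Remove RTs > 3 SD from individual mean"))
    specs.append(Specification(
        "sd_replace_mean_3", "sd_based", "sd_filter",
        {"k_upper": 3.0, "k_lower": None, "mode": "replace_with_mean"},
        "Replace RTs > 3 SD from the mean with the mean"))
    specs.append(Specification(
        "sd_replace_bound_3", "sd_based", "sd_filter",
        {"k_upper": 3.0, "k_lower": None, "mode": "replace_with_boundary"},
        "Replace RTs > 3 SD from the mean with the mean + 3 SD"))

    for ms in (2000, 1500, 1000):
        specs.append(Specification(
            f"cut_gt_{ms}", "raw_rt_cutoff", "absolute_cutoff",
            {"lower": None, "upper": float(ms)}, f"Remove all RTs > {ms} ms"))
    for ms in (400, 300, 200, 150, 100):
        specs.append(Specification(
            f"cut_lt_{ms}", "raw_rt_cutoff", "absolute_cutoff",
            {"lower": float(ms), "upper": None}, f"Remove all RTs < {ms} ms"))

    specs.append(Specification(
        "part_meanrt_4sd", "participant_removal", "participant_rule",
        {"rule": "mean_rt_sd", "k": 4.0},
        "Remove participant if mean RT > 4 SD above sample mean"))
    specs.append(Specification(
        "part_meanrt_2sd", "participant_removal", "participant_rule",
        {"rule": "mean_rt_sd", "k": 2.0},
        "Remove participant if mean RT > 2 SD above sample mean"))
    specs.append(Specification(
        "part_errct_3sd", "participant_removal", "participant_rule",
        {"rule": "error_count_sd", "k": 3.0},
        "Remove participant if error count > 3 SD above sample mean"))
    specs.append(Specification(
        "part_err_33", "participant_removal", "participant_rule",
        {"rule": "error_rate", "threshold": 1 / 3},
        "Remove participant if > 33% errors"))
    specs.append(Specification(
        "part_err_25", "participant_removal", "participant_rule",
        {"rule": "error_rate", "threshold": 0.25},
        "Remove participant if > 25% errors"))
    specs.append(Specification(
        "part_interf_4sd", "participant_removal", "participant_rule",
        {"rule": "interference_sd", "k": 4.0},
        "Remove participant if interference beyond +/- 4 SD of sample"))
    specs.append(Specification(
        "part_fast_25", "participant_removal", "participant_rule",
        {"rule": "fast_rt_share", "rt_threshold": 200.0, "share": 0.25},
        "Remove participant if > 25% of RTs < 200 ms"))

    specs.append(Specification(
        "mad_upper", "mad_based", "mad_filter",
        {"multiplier": 2.5, "two_sided": False},
        "Remove RTs > median + 2.5 MAD"))
    specs.append(Specification(
        "mad_twosided", "mad_based", "mad_filter",
        {"multiplier": 2.5, "two_sided": True},
        "Remove RTs beyond median +/- 2.5 MAD"))

    specs.append(Specification(
        "trim_10", "trimmed_mean", "trim",
        {"total_proportion": 0.10}, "Trim 10% of participants by interference"))
    specs.append(Specification(
        "trim_20", "trimmed_mean", "trim",
        {"total_proportion": 0.20}, "Trim 20% of participants by interference"))

    assert len(specs) == 27
    assert len({s.spec_id for s in specs}) == 27
    return specs


def registry_table(registry: Iterable[Specification] | None = None) -> pd.DataFrame:
    """Machine-readable registry export (single source of truth for docs/CLI)."""
    registry = build_registry() if registry is None else list(registry)
    return pd.DataFrame(
        [
            {
                "spec_id": s.spec_id,
                "category": s.category,
                "operator": s.operator,
                "center": s.center,
                "label": s.label,
                "params": ";".join(f"{k}={v}" for k, v in sorted(s.params.items())),
            }
            for s in registry
        ]
    )


# ---------------------------------------------------------------------------
# trial-level operators


def filter_rt_absolute(
    rts, lower: float | None = None, upper: float | None = None
) -> np.ndarray:
    """Keep RTs within the closed interval; removal is strict (> upper, < lower)."""
    if lower is None and upper is None:
        raise ParameterError("absolute cutoff needs at least one bound")
    if lower is not None and upper is not None and lower > upper:
        raise ParameterError(f"lower bound {lower} exceeds upper bound {upper}")
    arr = np.asarray(rts, dtype=float)
    keep = np.ones(arr.shape, dtype=bool)
    if lower is not None:
        keep &= arr >= lower
    if upper is not None:
        keep &= arr <= upper
    return arr[keep]


def filter_rt_sd(
    rts: pd.DataFrame,
    k_upper: float | None = None,
    k_lower: float | None = None,
    mode: str = "remove",
    log: RemovalLog | None = None,
) -> pd.DataFrame:
    """Per-participant SD filter on RTs pooled across conditions.

    ``rts`` needs ``participant_id`` and ``rt_ms`` columns; other columns are
    carried through. The participant mean and sample SD (n-1) are computed
    once on the pooled RTs, then trials beyond mean + k_upper*SD (and below
    mean - k_lower*SD when given) are removed, replaced with the participant
    mean, or replaced with the boundary value, per ``mode``. A participant
    with < 2 RTs, or with SD 0, passes through unchanged.
    """
    if k_upper is None and k_lower is None:
        raise ParameterError("SD filter needs k_upper and/or k_lower")
    if mode not in ("remove", "replace_with_mean", "replace_with_boundary"):
        raise ParameterError(f"unknown SD-filter mode {mode!r}")
    if mode != "remove" and k_upper is None:
        raise ParameterError("replacement modes act on the upper bound only")

    g = rts.groupby("participant_id")["rt_ms"]
    mean = g.transform("mean")
    sd = g.transform("std")  # ddof=1; NaN for singleton participants
    n = g.transform("size")
    usable = (n >= 2) & sd.notna() & (sd > 0)

    if log is not None:
        skipped = rts.loc[~usable, "participant_id"].unique().tolist()
        log.unfiltered_participants.extend(sorted(skipped))

    hi = mean + (np.inf if k_upper is None else k_upper) * sd
    lo = mean - (np.inf if k_lower is None else k_lower) * sd
    above = usable & (rts["rt_ms"] > hi)
    below = usable & (rts["rt_ms"] < lo)

    if mode == "remove":
        out = rts[~(above | below)].copy()
        if log is not None:
            removed = rts.loc[above | below, "participant_id"]
            log.n_trials_removed += int(len(removed))
            for pid, cnt in removed.value_counts().items():
                log.trials_removed_by_participant[pid] = (
                    log.trials_removed_by_participant.get(pid, 0) + int(cnt)
                )
        return out.reset_index(drop=True)

    out = rts.copy()
    if mode == "replace_with_mean":
        out.loc[above, "rt_ms"] = mean[above]
    else:  # replace_with_boundary
        out.loc[above, "rt_ms"] = hi[above]
    if log is not None:
        log.n_trials_replaced += int(above.sum())
    return out.reset_index(drop=True)


def filter_rt_mad(
    rts: pd.DataFrame,
    multiplier: float = 2.5,
    two_sided: bool = False,
    log: RemovalLog | None = None,
) -> pd.DataFrame:
    """Per-participant MAD filter on RTs pooled across conditions.

    MAD = 1.4826 * median(|r - median(r)|). Removes r > median + m*MAD (and
    r < median - m*MAD when two-sided), strictly. MAD of 0 removes nothing.
    """
    if multiplier <= 0:
        raise ParameterError("MAD multiplier must be positive")

    g = rts.groupby("participant_id")["rt_ms"]
    med = g.transform("median")
    mad = MAD_CONSISTENCY * (rts["rt_ms"] - med).abs().groupby(
        rts["participant_id"]
    ).transform("median")
    n = g.transform("size")
    usable = (n >= 2) & (mad > 0)

    if log is not None:
        skipped = rts.loc[~usable, "participant_id"].unique().tolist()
        log.unfiltered_participants.extend(sorted(skipped))

    above = usable & (rts["rt_ms"] > med + multiplier * mad)
    below = usable & two_sided & (rts["rt_ms"] < med - multiplier * mad)
    out = rts[~(above | below)].copy()
    if log is not None:
        removed = rts.loc[above | below, "participant_id"]
        log.n_trials_removed += int(len(removed))
        for pid, cnt in removed.value_counts().items():
            log.trials_removed_by_participant[pid] = (
                log.trials_removed_by_participant.get(pid, 0) + int(cnt)
            )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# participant-level operators


def _participant_mean_interference(base: BaseDataset) -> pd.Series:
    """Mean-centre interference per participant (alcohol - neutral), NaN when
    a condition has no valid RT."""
    cell = base.valid_rts.groupby(["participant_id", "condition"])["rt_ms"].mean()
    wide = cell.unstack()
    for cond in ("alcohol", "neutral"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    return wide["alcohol"] - wide["neutral"]


def remove_participants(
    base: BaseDataset, rule: str, params: Mapping, log: RemovalLog | None = None
) -> frozenset:
    """Apply one sample-level participant screen; return the retained set.

    Rules with ``>`` are upper-tail only except the interference rule, which
    is two-sided. A sample SD of 0 removes no one.
    """
    all_pids = set(base.error_counts["participant_id"])
    removed: dict = {}

    if rule == "mean_rt_sd":
        k = params["k"]
        means = base.valid_rts.groupby("participant_id")["rt_ms"].mean()
        mu, sd = means.mean(), means.std(ddof=1)
        if len(means) >= 2 and sd > 0:
            for pid, m in means.items():
                if m > mu + k * sd:
                    removed[pid] = f"mean RT {m:.1f} > sample mean + {k:g} SD"
    elif rule == "error_count_sd":
        k = params["k"]
        errs = base.error_counts.set_index("participant_id")["n_errors"].astype(float)
        mu, sd = errs.mean(), errs.std(ddof=1)
        if len(errs) >= 2 and sd > 0:
            for pid, e in errs.items():
                if e > mu + k * sd:
                    removed[pid] = f"error count {e:.0f} > sample mean + {k:g} SD"
    elif rule == "error_rate":
        thr = params["threshold"]
        ec = base.error_counts
        rates = ec["n_errors"] / ec["n_critical"]
        for pid, r in zip(ec["participant_id"], rates):
            if r > thr:
                removed[pid] = f"error rate {r:.3f} > {thr:.3f}"
    elif rule == "interference_sd":
        k = params["k"]
        scores = _participant_mean_interference(base).dropna()
        mu, sd = scores.mean(), scores.std(ddof=1)
        if len(scores) >= 2 and sd > 0:
            for pid, s in scores.items():
                if abs(s - mu) > k * sd:
                    removed[pid] = f"interference {s:.1f} beyond +/- {k:g} SD of sample"
    elif rule == "fast_rt_share":
        thr_ms = params["rt_threshold"]
        share = params["share"]
        rec = base.recorded_rts
        fast = rec.assign(is_fast=rec["rt_ms"] < thr_ms).groupby("participant_id")[
            "is_fast"
        ].mean()
        for pid, f in fast.items():
            if f > share:
                removed[pid] = f"{f:.0%} of recorded RTs < {thr_ms:.0f} ms"
    else:
        raise ParameterError(f"unknown participant rule {rule!r}")

    if log is not None:
        log.participants_removed.update(removed)
        log.n_participants_removed += len(removed)
    return frozenset(all_pids - set(removed))


def trim_participants(scores: pd.Series, total_proportion: float) -> frozenset:
    """Symmetric trim of participants by interference score.

    Removes floor(n * total_proportion / 2) participants from each tail of the
    sorted scores (so the total trimmed fraction is at most
    ``total_proportion``, split equally). Ties are broken by participant id
    for determinism.
    """
    if not (0 < total_proportion < 1):
        raise ParameterError("total_proportion must lie in (0, 1)")
    scores = scores.dropna()
    n = len(scores)
    if n < 3:
        raise ParameterError("trimming needs at least 3 scored participants")
    per_tail = int(np.floor(n * total_proportion / 2))
    order = scores.reset_index()
    order.columns = ["participant_id", "score"]
    order = order.sort_values(["score", "participant_id"], kind="mergesort")
    keep = order.iloc[per_tail : n - per_tail if per_tail else n]
    return frozenset(keep["participant_id"])


# ---------------------------------------------------------------------------
# dispatch


def apply_specification(base: BaseDataset, spec: Specification) -> AnalysisDataset:
    """Apply one specification, in isolation, to the cleaned base dataset.

    Pure in (base, spec): the same inputs always give the same
    :class:`AnalysisDataset`, regardless of what ran before.
    """
    log = RemovalLog()
    rts = base.valid_rts.copy()
    retained = frozenset(base.error_counts["participant_id"])

    if spec.operator == "identity":
        pass
    elif spec.operator == "absolute_cutoff":
        lower, upper = spec.params.get("lower"), spec.params.get("upper")
        arr = rts["rt_ms"].to_numpy()
        keep = np.ones(len(arr), dtype=bool)
        if lower is not None:
            keep &= arr >= lower
        if upper is not None:
            keep &= arr <= upper
        if lower is None and upper is None:
            raise ParameterError("absolute cutoff needs at least one bound")
        removed = rts.loc[~keep, "participant_id"]
        log.n_trials_removed = int((~keep).sum())
        for pid, cnt in removed.value_counts().items():
            log.trials_removed_by_participant[pid] = int(cnt)
        rts = rts[keep].reset_index(drop=True)
    elif spec.operator == "sd_filter":
        rts = filter_rt_sd(
            rts,
            k_upper=spec.params.get("k_upper"),
            k_lower=spec.params.get("k_lower"),
            mode=spec.params.get("mode", "remove"),
            log=log,
        )
    elif spec.operator == "mad_filter":
        rts = filter_rt_mad(
            rts,
            multiplier=spec.params.get("multiplier", 2.5),
            two_sided=spec.params.get("two_sided", False),
            log=log,
        )
    elif spec.operator == "participant_rule":
        retained = remove_participants(
            base, spec.params["rule"],
            {k: v for k, v in spec.params.items() if k != "rule"}, log=log,
        )
        rts = rts[rts["participant_id"].isin(retained)].reset_index(drop=True)
    elif spec.operator == "trim":
        scores = _participant_mean_interference(base)
        retained = trim_participants(scores, spec.params["total_proportion"])
        trimmed = set(base.error_counts["participant_id"]) - set(retained)
        for pid in sorted(trimmed):
            log.participants_removed.setdefault(pid, "trimmed by extreme interference")
        log.n_participants_removed = len(trimmed)
        rts = rts[rts["participant_id"].isin(retained)].reset_index(drop=True)
    else:
        raise ParameterError(f"unknown operator {spec.operator!r}")

    return AnalysisDataset(
        rts=rts,
        retained_participants=retained,
        removal_log=log,
        spec=spec,
        base_flagged=base.flagged,
    )
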