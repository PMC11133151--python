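"""Interference scores, the group-level estimate per specification, and the
paired-test sample-size solver.

The Stroop interference effect is, per participant, the centre (mean, or
median for the no-exclusion/median pipeline) of alcohol-trial RTs minus the
centre of neutral-trial RTs. The group estimate is the arithmetic mean of
these scores; its 95% CI and two-sided p come from the one-sample t test
against zero (equivalent to a paired t on the condition means).

Degenerate conventions, logged with a warning when hit: scores all exactly 0
report p = 1; scores all equal to a nonzero constant report p = 0; both give
a zero-width CI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .spec_registry import AnalysisDataset, RemovalLog


@dataclass
class SpecResult:
    """One specification's interference estimate with inference and bookkeeping."""

    spec_id: str
    category: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_participants: int
    n_trials_removed: int = 0
    n_trials_replaced: int = 0
    n_participants_removed: int = 0
    n_dropped_pairwise: int = 0


def participant_interference(
    ad: AnalysisDataset, center: str | None = None
) -> pd.DataFrame:
    """Per-participant interference scores under one analysis dataset.

    ``center`` defaults to the specification's own centre statistic. A
    participant without at least one retained RT in each condition is excluded
    pairwise (column-complete participants only) and counted in the result's
    attrs under ``n_dropped_pairwise``.
    """
    if len(ad.rts) == 0:
        raise ValidationError("analysis dataset has no retained RTs")
    center = ad.spec.center if center is None else center
    if center not in ("mean", "median"):
        raise ParameterError(f"unknown centre statistic {center!r}")

    agg = ad.rts.groupby(["participant_id", "condition"])["rt_ms"].agg(center)
    wide = agg.unstack()
    for cond in ("alcohol", "neutral"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    wide = wide.loc[wide.index.isin(ad.retained_participants)]
    complete = wide.dropna(subset=["alcohol", "neutral"])
    n_dropped = len(ad.retained_participants) - len(complete)

    out = pd.DataFrame(
        {
            "participant_id": complete.index,
            "rt_alcohol": complete["alcohol"].to_numpy(),
            "rt_neutral": complete["neutral"].to_numpy(),
        }
    )
    out["interference"] = out["rt_alcohol"] - out["rt_neutral"]
    out = out.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    out.attrs["n_dropped_pairwise"] = int(n_dropped)
    out.attrs["center"] = center
    return out


def group_estimate(
    scores: pd.DataFrame,
    spec_id: str = "",
    category: str = "",
    removal_log: RemovalLog | None = None,
) -> SpecResult:
    """Group mean of interference scores with 95% t CI and two-sided p vs 0."""
    x = np.asarray(scores["interference"], dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("group estimate needs at least 2 interference scores")

    est = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "zero-variance interference scores: degenerate CI and p-value",
            stacklevel=2,
        )
        ci_low = ci_high = est
        p = 1.0 if est == 0.0 else 0.0
    else:
        tcrit = float(stats.t.ppf(0.975, n - 1))
        half = tcrit * sd / math.sqrt(n)
        ci_low, ci_high = est - half, est + half
        p = float(stats.ttest_1samp(x, 0.0).pvalue)

    log = removal_log or RemovalLog()
    return SpecResult(
        spec_id=spec_id,
        category=category,
        estimate=est,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        n_participants=n,
        n_trials_removed=log.n_trials_removed,
        n_trials_replaced=log.n_trials_replaced,
        n_participants_removed=log.n_participants_removed,
        n_dropped_pairwise=int(scores.attrs.get("n_dropped_pairwise", 0)),
    )


def estimate_spec(ad: AnalysisDataset) -> SpecResult:
    """Convenience: scores then group estimate for one analysis dataset."""
    scores = participant_interference(ad)
    return group_estimate(
        scores, spec_id=ad.spec.spec_id, category=ad.spec.category,
        removal_log=ad.removal_log,
    )


def power_paired_t(n: int, dz: float, alpha: float, tails: str) -> float:
    """Power of a paired/one-sample t test at sample size n, via noncentral t."""
    df = n - 1
    ncp = dz * math.sqrt(n)
    if tails == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float((1 - stats.nct.cdf(tcrit, df, ncp)) + stats.nct.cdf(-tcrit, df, ncp))


def required_sample_size(
    dz: float, alpha: float = 0.05, power: float = 0.80, tails: str = "two",
    n_max: int = 1_000_000,
) -> int:
    """Smallest n at which a paired t test on within-participant differences
    with standardized effect dz reaches the target power.

    ``tails`` is explicit ("one" or "two"); there is no hidden default beyond
    the conventional two-sided test. The floor is n = 2 (df >= 1).
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    if not (0 < power < 1):
        raise ParameterError("power must lie in (0, 1)")
    if dz <= 0:
        raise ParameterError("dz must be positive")
    if tails not in ("one", "two"):
        raise ParameterError("tails must be 'one' or 'two'")

    # exponential search for an upper bracket, then bisect on the integer n
    lo, hi = 2, 2
    while power_paired_t(hi, dz, alpha, tails) < power:
        hi *= 2
        if hi > n_max:
            raise ParameterError(
                f"power {power} unattainable below n = {n_max} for dz = {dz}"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if power_paired_t(mid, dz, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
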