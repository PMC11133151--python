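"""Person-level stability of the interference score across pipelines.

Two questions: (1) how strongly does each pipeline's per-participant
interference score correlate with the no-exclusion (median) reference —
a narrow distribution of strong positive Pearson r values means the pipelines
agree about *who* shows the effect; (2) does the choice of pipeline change
the correlation between interference and an external outcome (craving)?

Deletion is pairwise-complete per comparison, one pipeline at a time, never
listwise across all 26.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .preprocess import BaseDataset
from .estimation import participant_interference
from .spec_registry import Specification, apply_specification, build_registry

#: Fewer complete pairs than this flags the correlation as unstable.
MIN_PAIRS = 3

REFERENCE_SPEC = "noexcl_median"


@dataclass
class CorrelationResult:
    """Pearson correlation of one pipeline's scores against the reference."""

    spec_id: str
    r: float | None  # None when < MIN_PAIRS complete pairs
    n_pairs: int
    unstable: bool = False


def _scores_by_spec(
    base: BaseDataset, registry: Sequence[Specification]
) -> dict[str, pd.Series]:
    out = {}
    for spec in registry:
        scores = participant_interference(apply_specification(base, spec))
        out[spec.spec_id] = scores.set_index("participant_id")["interference"]
    return out


def _pearson(a: pd.Series, b: pd.Series) -> CorrelationResult:
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < MIN_PAIRS:
        return CorrelationResult("", None, n, unstable=True)
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult("", None, n, unstable=True)  # r undefined
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult("", r, n)


def spec_correlations(
    base: BaseDataset,
    registry: Sequence[Specification] | None = None,
    reference: str = REFERENCE_SPEC,
) -> list[CorrelationResult]:
    """Per non-reference specification, Pearson r of per-participant scores
    against the reference pipeline's, pairwise-complete."""
    registry = build_registry() if registry is None else list(registry)
    ids = [s.spec_id for s in registry]
    if reference not in ids:
        raise ValidationError(f"reference spec {reference!r} not in registry")
    scores = _scores_by_spec(base, registry)
    ref = scores[reference]
    out = []
    for spec in registry:
        if spec.spec_id == reference:
            continue
        res = _pearson(scores[spec.spec_id], ref)
        res.spec_id = spec.spec_id
        out.append(res)
    return out


def summarize_correlations(
    results: Sequence[CorrelationResult], bins: int = 10
) -> dict:
    """Mean and sample SD of available r values plus a binned histogram table."""
    rs = np.array([r.r for r in results if r.r is not None], dtype=float)
    n_absent = sum(1 for r in results if r.r is None)
    if len(rs) < 2:
        raise ValidationError("need at least 2 defined correlations to summarize")
    counts, edges = np.histogram(rs, bins=bins, range=(-1.0, 1.0))
    hist = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    return {
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "n": int(len(rs)),
        "n_absent": int(n_absent),
        "histogram": hist,
    }


def outcome_correlations(
    base: BaseDataset,
    registry: Sequence[Specification] | None = None,
    outcome: str = "craving",
) -> list[CorrelationResult]:
    """Per specification, Pearson r between interference and a participant
    covariate (e.g. craving), pairwise-complete."""
    registry = build_registry() if registry is None else list(registry)
    if base.covariates is None or outcome not in base.covariates.columns:
        raise ValidationError(f"outcome column {outcome!r} absent from covariates")
    cov = base.covariates.set_index("participant_id")[outcome].astype(float)
    scores = _scores_by_spec(base, registry)
    out = []
    for spec in registry:
        res = _pearson(scores[spec.spec_id], cov)
        res.spec_id = spec.spec_id
        out.append(res)
    return out


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"spec_id": r.spec_id, "r": r.r, "n_pairs": r.n_pairs,
             "unstable": r.unstable}
            for r in results
        ]
    )


def plot_correlation_histogram(
    results: Sequence[CorrelationResult], path, bins: int = 20
) -> None:
    """Histogram of the r distribution across pipelines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rs = [r.r for r in results if r.r is not None]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(rs, bins=bins, range=(0.0, 1.0), color="tab:blue", edgecolor="white")
    ax.set_xlabel("Pearson r vs no-exclusion (median) reference")
    ax.set_ylabel("specifications")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
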