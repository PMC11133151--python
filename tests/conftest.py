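import numpy as np
import pandas as pd
import pytest

from stroop_multiverse import Dataset, clean_base, generate_dataset, preset


def make_trials(rows):
    """Build a trial frame from compact tuples:
    (pid, idx, phase, condition, correct, rt_ms[, colour[, block_id]]).
    """
    records = []
    for row in rows:
        pid, idx, phase, cond, correct, rt = row[:6]
        colour = row[6] if len(row) > 6 else "red"
        block = row[7] if len(row) > 7 else None
        records.append(
            dict(participant_id=pid, trial_index=idx, phase=phase, condition=cond,
                 colour=colour, correct=correct, rt_ms=rt, block_id=block)
        )
    return pd.DataFrame(records)


def make_dataset(rows, covariates=None, layout="custom"):
    cov = pd.DataFrame(covariates) if covariates is not None else None
    return Dataset(trials=make_trials(rows), covariates=cov, layout=layout)


def dataset_from_rts(rts_by_pid_cond, covariates=None):
    """Dataset of all-correct critical trials from {pid: {cond: [rts]}}."""
    rows = []
    for pid, conds in rts_by_pid_cond.items():
        i = 0
        for cond, rts in conds.items():
            for rt in rts:
                rows.append((pid, i, "critical", cond, True, float(rt)))
                i += 1
    return make_dataset(rows, covariates=covariates)


@pytest.fixture
def tiny_base():
    """2 participants x 2 conditions with a handful of clean RTs."""
    return clean_base(dataset_from_rts({
        "p1": {"alcohol": [500, 700], "neutral": [450, 550]},
        "p2": {"alcohol": [600, 620, 640], "neutral": [580, 600, 620]},
    }))


@pytest.fixture(scope="session")
def novel_base():
    """One paper-like web-layout dataset, cleaned; shared across tests."""
    return clean_base(generate_dataset(preset("paper_like_novel", seed=11)))
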