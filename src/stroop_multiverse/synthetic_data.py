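"""Synthetic trial-level alcohol-Stroop datasets with known ground truth.

Generative model
----------------
Per participant i: a baseline ex-Gaussian location mu_i ~ Normal(mu_base,
sigma_mu) and a true interference shift delta_i ~ Normal(delta, sigma_delta).
Per critical trial: RT = Normal(mu_i + [alcohol] * delta_i, sigma) +
Exponential(tau) — the standard right-skewed reaction-time family. With
probability p_fast the draw is replaced by a fast guess (Uniform 100-250 ms);
with probability p_lapse by a lapse (Uniform 1500-3000 ms). Lapses may be
condition-asymmetric: ``lapse_bias`` is the share of the lapse probability
carried by alcohol trials (0.5 = symmetric; above 0.5 concentrates lapses in
the slower condition, mimicking attention captured by the alcohol words).
Responses are incorrect with probability epsilon, independent of RT. Any RT above the
3000-ms response window becomes a timeout: coded incorrect with no recorded
RT, exactly as the tasks code it.

Two task layouts are emulated: a mobile blocked design (66 critical trials,
33 per condition in two single-condition blocks, randomized block order,
three colours, no practice recorded) and a web randomized design (24 practice
trials with no condition, then 168 critical trials, 84 per condition in fully
random order, four colours).

Craving (0-100) is built from the standardized delta_i by a Gaussian
copula-style mix — z = r * z_delta + sqrt(1 - r^2) * noise, rescaled as
50 + 20 z and clipped to [0, 100] — so its population correlation with the
participant's true interference is r_craving.

Identical configurations (including the seed) give byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .trial_data import Dataset, TIMEOUT_MS

MOBILE_COLOURS = ("red", "green", "blue")
WEB_COLOURS = ("red", "green", "blue", "yellow")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic dataset.

    Milliseconds throughout; probabilities in [0, 1].
    """

    n_participants: int = 50
    layout: str = "web_random_168"
    mu_base: float = 650.0     # population mean of participant locations mu_i
    sigma_mu: float = 80.0     # between-participant SD of mu_i
    sigma: float = 100.0       # within-participant Gaussian SD
    tau: float = 200.0         # exponential tail mean
    delta: float = 25.0        # population mean interference (alcohol - neutral)
    sigma_delta: float = 30.0  # between-participant SD of delta_i
    p_fast: float = 0.02       # fast-guess contaminant probability
    p_lapse: float = 0.02      # lapse contaminant probability (trial-average)
    lapse_bias: float = 0.5    # share of lapse probability on alcohol trials
    epsilon: float = 0.05      # trial error probability
    r_craving: float = 0.3     # target corr(delta_i, craving)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if self.layout not in ("mobile_blocked_66", "web_random_168"):
            raise ParameterError(f"unknown layout {self.layout!r}")
        for name in ("p_fast", "p_lapse", "epsilon"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if not (0 <= self.lapse_bias <= 1):
            raise ParameterError("lapse_bias must lie in [0, 1]")
        if self.p_fast + 2 * max(self.lapse_bias, 1 - self.lapse_bias) * self.p_lapse > 1:
            raise ParameterError("p_fast + per-condition lapse probability exceeds 1")
        for name in ("mu_base", "sigma_mu", "sigma", "tau", "sigma_delta"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (-1 <= self.r_craving <= 1):
            raise ParameterError("r_craving must lie in [-1, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


#: Frozen study-condition presets. ``paper_like_novel`` mirrors the web task
#: (156 analysable participants = 166 recruited minus 10 failing practice;
#: 25 ms true shift). ``paper_like_published`` mirrors the mobile blocked
#: task at a plausible mobile-study sample with a 35 ms shift. ``null`` has
#: no true effect and no contaminants; ``heavy_contamination`` stresses the
#: outlier filters.
_PRESETS = {
    "paper_like_published": dict(
        n_participants=60, layout="mobile_blocked_66", delta=35.0),
    "paper_like_novel": dict(
        n_participants=156, layout="web_random_168", delta=25.0),
    "null": dict(
        n_participants=50, layout="web_random_168", delta=0.0, sigma_delta=0.0,
        p_fast=0.0, p_lapse=0.0),
    "heavy_contamination": dict(
        n_participants=50, layout="web_random_168", delta=25.0,
        p_fast=0.05, p_lapse=0.10, epsilon=0.08),
}


def preset(name: str, seed: int = 0) -> SimConfig:
    """A documented, frozen parameterization by name."""
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return SimConfig(seed=seed, **_PRESETS[name])


def config_from_file(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML or JSON file mirroring its fields."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return SimConfig(**data)


def generate_dataset(cfg: SimConfig) -> Dataset:
    """Draw one trial-level dataset (with covariates) under ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    pids = [f"p{i:03d}" for i in range(1, n + 1)]

    mu_i = rng.normal(cfg.mu_base, cfg.sigma_mu, size=n)
    delta_i = rng.normal(cfg.delta, cfg.sigma_delta, size=n)

    frames = []
    for idx, pid in enumerate(pids):
        frames.append(
            _participant_trials(cfg, rng, pid, mu_i[idx], delta_i[idx])
        )
    trials = pd.concat(frames, ignore_index=True)

    covariates = pd.DataFrame(
        {
            "participant_id": pids,
            "craving": _craving(rng, delta_i, cfg.r_craving, cfg.sigma_delta),
            "distracted": rng.random(n) < 0.1,
        }
    )
    return Dataset(trials=trials, covariates=covariates, layout=cfg.layout)


def _participant_trials(
    cfg: SimConfig, rng: np.random.Generator, pid: str, mu: float, delta: float
) -> pd.DataFrame:
    if cfg.layout == "mobile_blocked_66":
        n_practice = 0
        colours = MOBILE_COLOURS
        first_alcohol = bool(rng.integers(0, 2))
        block1 = ["alcohol" if first_alcohol else "neutral"] * 33
        block2 = ["neutral" if first_alcohol else "alcohol"] * 33
        conditions = block1 + block2
        block_ids = ["block1"] * 33 + ["block2"] * 33
    else:  # web_random_168
        n_practice = 24
        colours = WEB_COLOURS
        conditions = ["alcohol"] * 84 + ["neutral"] * 84
        rng.shuffle(conditions)
        block_ids = [None] * 168

    n_crit = len(conditions)
    n_total = n_practice + n_crit
    is_alc = np.zeros(n_total, dtype=bool)
    is_alc[n_practice:] = np.array(conditions) == "alcohol"

    rt = rng.normal(mu + np.where(is_alc, delta, 0.0), cfg.sigma, size=n_total)
    rt += rng.exponential(cfg.tau, size=n_total)
    # lapse probability may be condition-asymmetric (attention captured by
    # alcohol words produces long RTs preferentially on alcohol trials);
    # with a 50/50 condition split the trial-average rate stays p_lapse
    p_lapse_trial = cfg.p_lapse * np.where(
        is_alc, 2 * cfg.lapse_bias, 2 * (1 - cfg.lapse_bias)
    )
    u = rng.random(n_total)
    fast = u < cfg.p_fast
    lapse = (u >= cfg.p_fast) & (u < cfg.p_fast + p_lapse_trial)
    rt[fast] = rng.uniform(100.0, 250.0, size=int(fast.sum()))
    rt[lapse] = rng.uniform(1500.0, 3000.0, size=int(lapse.sum()))
    rt = np.maximum(rt, 1.0)  # the response window floor; negligible mass

    correct = rng.random(n_total) >= cfg.epsilon
    timeout = rt > TIMEOUT_MS
    correct[timeout] = False
    rt = np.where(timeout, np.nan, rt)

    colour = rng.choice(colours, size=n_total)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial_index": np.arange(n_total),
            "phase": ["practice"] * n_practice + ["critical"] * n_crit,
            "condition": [None] * n_practice + conditions,
            "colour": colour,
            "correct": correct,
            "rt_ms": rt,
            "block_id": [None] * n_practice + block_ids,
        }
    )


def _craving(
    rng: np.random.Generator, delta_i: np.ndarray, r: float, sigma_delta: float
) -> np.ndarray:
    n = len(delta_i)
    if sigma_delta > 0:
        z_delta = (delta_i - delta_i.mean()) / delta_i.std(ddof=0)
    else:
        z_delta = np.zeros(n)
    z = r * z_delta + np.sqrt(max(0.0, 1 - r**2)) * rng.standard_normal(n)
    return np.clip(50.0 + 20.0 * z, 0.0, 100.0)
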