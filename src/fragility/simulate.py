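"""Seeded synthetic data emulating the three input schemas.

Events are binomial per arm under a logit model.  For two-arm designs the
control arm has a fixed baseline event probability and the active arm's
log odds ratio is drawn per study from N(theta, tau2) — the same two-level
normal model the meta-analysis engine assumes — so generated datasets have
known ground truth for parameter-recovery checks.  Defaults mirror the
kinds of trials the bundled examples come from: moderate arm sizes
(50-300), a baseline event risk of 0.15 (e.g. all-cause dropout or
mortality), a modest protective effect (OR 0.8), and mild heterogeneity
(tau2 = 0.1).

All randomness flows through one ``numpy.random.Generator`` derived from
the ``seed`` argument; the same seed always reproduces the same dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import MADataset
from .nma import ArmRecord, NMADataset
from .tables import TwoByTwoTable

__all__ = ["SynthConfig", "gen_trials", "gen_ma", "gen_nma"]


@dataclass(frozen=True)
class SynthConfig:
    """Shared knobs of the generators (see module docstring for defaults)."""

    seed: int
    baseline: float = 0.15
    odds_ratio: float = 0.8
    tau2: float = 0.1
    n_min: int = 50
    n_max: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.baseline < 1):
            raise ValueError("baseline probability must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not (1 <= self.n_min <= self.n_max):
            raise ValueError("need 1 <= n_min <= n_max")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_two_arm(rng: np.random.Generator, cfg: SynthConfig, k: int):
    """k studies: (tables, per-study true log ORs)."""
    theta = np.log(cfg.odds_ratio) + np.sqrt(cfg.tau2) * rng.standard_normal(k)
    logit0 = np.log(cfg.baseline / (1 - cfg.baseline))
    n0 = rng.integers(cfg.n_min, cfg.n_max + 1, size=k)
    n1 = rng.integers(cfg.n_min, cfg.n_max + 1, size=k)
    e0 = rng.binomial(n0, cfg.baseline)
    e1 = rng.binomial(n1, _expit(logit0 + theta))
    tables = [TwoByTwoTable(int(a), int(b), int(c), int(d))
              for a, b, c, d in zip(e0, n0, e1, n1)]
    return tables, theta


def gen_trials(
    n_trials: int, seed: int, **cfg_kw
) -> tuple[list[TwoByTwoTable], pd.DataFrame]:
    """Independent two-arm trials plus a truth record of per-trial log ORs."""
    cfg = SynthConfig(seed=seed, **cfg_kw)
    rng = np.random.default_rng(cfg.seed)
    tables, theta = _draw_two_arm(rng, cfg, n_trials)
    truth = pd.DataFrame({"trial": np.arange(1, n_trials + 1), "log_or": theta})
    return tables, truth


def gen_ma(
    n_studies: int, seed: int, **cfg_kw
) -> tuple[MADataset, pd.DataFrame]:
    """One meta-analysis of ``n_studies`` two-arm studies with known truth."""
    cfg = SynthConfig(seed=seed, **cfg_kw)
    rng = np.random.default_rng(cfg.seed)
    tables, theta = _draw_two_arm(rng, cfg, n_studies)
    truth = pd.DataFrame({"study": np.arange(1, n_studies + 1), "log_or": theta})
    return MADataset(studies=tuple(tables)), truth


def gen_nma(
    k_treatments: int,
    n_studies: int,
    seed: int,
    theta: np.ndarray | None = None,
    **cfg_kw,
) -> tuple[NMADataset, pd.DataFrame]:
    """A connected two-arm-study network comparing ``k_treatments`` treatments.

    ``theta`` gives each treatment's true log odds ratio versus treatment 1
    (length K, first entry 0); by default treatment t has log OR
    ``(t - 1) * log(odds_ratio)``.  The first K-1 studies compare treatment
    1 with each other treatment, guaranteeing connectivity; further studies
    compare random pairs.  Within a study each arm's log odds gets an
    independent N(0, tau2/2) perturbation, so every contrast has
    heterogeneity variance tau2.
    """
    if k_treatments < 2:
        raise ValueError("need at least two treatments")
    if n_studies < k_treatments - 1:
        raise ValueError("need at least K-1 studies for a connected network")
    cfg = SynthConfig(seed=seed, **cfg_kw)
    rng = np.random.default_rng(cfg.seed)
    if theta is None:
        theta = np.arange(k_treatments) * np.log(cfg.odds_ratio)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (k_treatments,):
        raise ValueError("theta must have one entry per treatment")
    logit0 = np.log(cfg.baseline / (1 - cfg.baseline))

    designs = [(1, t) for t in range(2, k_treatments + 1)]
    while len(designs) < n_studies:
        a, b = sorted(rng.choice(np.arange(1, k_treatments + 1), size=2, replace=False))
        designs.append((int(a), int(b)))

    arms: list[ArmRecord] = []
    rows = []
    for sid, (ta, tb) in enumerate(designs, start=1):
        for tid in (ta, tb):
            u = np.sqrt(cfg.tau2 / 2) * rng.standard_normal()
            p = _expit(logit0 + theta[tid - 1] + u)
            n = int(rng.integers(cfg.n_min, cfg.n_max + 1))
            e = int(rng.binomial(n, p))
            arms.append(ArmRecord(sid=sid, tid=tid, e=e, n=n))
            rows.append({"sid": sid, "tid": tid, "true_logit": logit0 + theta[tid - 1] + u})
    truth = pd.DataFrame(rows)
    return NMADataset(tuple(arms)), truth
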