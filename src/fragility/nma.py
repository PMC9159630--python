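"""Frequentist contrast-based network meta-analysis.

Arm-level data (study id, treatment id, events, sample size) are turned
into all within-study pairwise contrasts; for studies with more than two
arms the contrast variances are re-weighted so that the redundant contrasts
carry exactly the information of the joint model (the graph-theoretical
variance-decomposition scheme: the study's variance matrix is mapped to a
Laplacian via the centred pseudoinverse, and the edge weights of that
Laplacian become the adjusted inverse variances).  The network estimates
for all K(K-1)/2 comparisons are then the weighted-least-squares solution
on the treatment graph, obtained through the Moore-Penrose inverse of the
weighted graph Laplacian.  Under the random-effects setting a single
between-study variance tau^2, estimated by a generalized method-of-moments
(DerSimonian-Laird-type) Q statistic, is added to every contrast variance
before re-solving.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .tables import TwoByTwoTable, effect_estimate

__all__ = [
    "ArmRecord",
    "NMADataset",
    "Contrast",
    "NMAFit",
    "arms_to_contrasts",
    "nma_fit",
]


@dataclass(frozen=True)
class ArmRecord:
    """One treatment arm of one study."""

    sid: int
    tid: int
    e: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"arm size must be positive (study {self.sid}, treatment {self.tid})")
        if not (0 <= self.e <= self.n):
            raise ValueError(f"need 0 <= e <= n (study {self.sid}, treatment {self.tid})")


@dataclass(frozen=True)
class NMADataset:
    """Arm-level long-format NMA data, grouped by study."""

    arms: tuple[ArmRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        for sid, tids in self.study_arms().items():
            if len(tids) < 2:
                raise ValueError(f"study {sid} has fewer than two arms")
            ts = [a.tid for a in tids]
            if len(set(ts)) != len(ts):
                raise ValueError(f"study {sid} repeats a treatment id")

    def study_arms(self) -> dict[int, list[ArmRecord]]:
        """Arms grouped by study, studies in order of first appearance."""
        out: dict[int, list[ArmRecord]] = {}
        for a in self.arms:
            out.setdefault(a.sid, []).append(a)
        return out

    @property
    def treatments(self) -> tuple[int, ...]:
        return tuple(sorted({a.tid for a in self.arms}))

    @property
    def n_total(self) -> int:
        return sum(a.n for a in self.arms)

    def n_in_treatments(self, tids) -> int:
        """Total sample size in arms of the given treatments, across studies."""
        tids = set(tids)
        return sum(a.n for a in self.arms if a.tid in tids)

    def with_event_change(self, sid: int, tid: int, delta: int) -> "NMADataset":
        arms = []
        found = False
        for a in self.arms:
            if a.sid == sid and a.tid == tid:
                arms.append(ArmRecord(a.sid, a.tid, a.e + delta, a.n))
                found = True
            else:
                arms.append(a)
        if not found:
            raise KeyError(f"no arm for study {sid}, treatment {tid}")
        return NMADataset(tuple(arms))

    def check_connected(self) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        for arms in self.study_arms().values():
            ts = [a.tid for a in arms]
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    g.add_edge(ts[i], ts[j])
        if not nx.is_connected(g):
            comps = [sorted(c) for c in nx.connected_components(g)]
            raise ValueError(f"treatment network is disconnected: components {comps}")


@dataclass(frozen=True)
class Contrast:
    """Within-study comparison of treatment ``t2`` vs ``t1`` (t1 < t2)."""

    sid: int
    t1: int
    t2: int
    y: float
    var: float       # raw contrast variance
    var_adj: float   # after multi-arm adjustment (equal to var for 2 arms)


def _contrast_effect(
    arm1: ArmRecord, arm2: ArmRecord, measure: str, correct: bool, incr: float
) -> tuple[float, float]:
    """Effect of arm2 vs arm1 with optional forced continuity correction."""
    table = TwoByTwoTable(arm1.e, arm1.n, arm2.e, arm2.n)
    if correct and not table.has_zero_cell():
        # forced correction (allincr/addincr): shift all four cells by incr
        a, b, c, d = (x + incr for x in table.cells)
        import math

        m0, m1 = a + b, c + d
        if measure == "OR":
            y = math.log((c / d) / (a / b))
            var = 1 / a + 1 / b + 1 / c + 1 / d
        elif measure == "RR":
            y = math.log((c / m1) / (a / m0))
            var = 1 / a + 1 / c - 1 / m0 - 1 / m1
        else:
            y = c / m1 - a / m0
            var = a * b / m0**3 + c * d / m1**3
        return y, var
    est = effect_estimate(table, measure, incr=incr)
    return est.y, est.se**2


def arms_to_contrasts(
    dataset: NMADataset,
    measure: str = "OR",
    incr: float = 0.5,
    allincr: bool = False,
    addincr: bool = False,
    allstudies: bool = False,
) -> list[Contrast]:
    """All within-study pairwise contrasts with adjusted variances.

    Zero-cell handling mirrors the usual arm-to-contrast conventions:
    by default ``incr`` is added to all four cells of a contrast that
    contains a zero cell; ``allincr`` extends the correction to every
    contrast once any study has a zero cell; ``addincr`` always corrects.
    Two-arm studies where both arms have zero events (or all events) carry
    no information about OR/RR and are dropped unless ``allstudies``.
    """
    dataset.check_connected()
    any_zero = any(
        TwoByTwoTable(a1.e, a1.n, a2.e, a2.n).has_zero_cell()
        for arms in dataset.study_arms().values()
        for i, a1 in enumerate(arms)
        for a2 in arms[i + 1:]
    )
    out: list[Contrast] = []
    for sid, arms in dataset.study_arms().items():
        arms = sorted(arms, key=lambda a: a.tid)
        pairs = [(i, j) for i in range(len(arms)) for j in range(i + 1, len(arms))]
        raw: list[tuple[int, int, float, float]] = []
        for i, j in pairs:
            a1, a2 = arms[i], arms[j]
            if (
                len(arms) == 2
                and measure in ("OR", "RR")
                and not allstudies
                and not addincr
                and ((a1.e == 0 and a2.e == 0) or (a1.e == a1.n and a2.e == a2.n))
            ):
                continue  # double-zero two-arm study: uninformative
            force = addincr or (allincr and any_zero)
            y, var = _contrast_effect(a1, a2, measure, force, incr)
            raw.append((i, j, y, var))
        if not raw:
            continue
        if len(arms) == 2:
            i, j, y, var = raw[0]
            out.append(Contrast(sid, arms[i].tid, arms[j].tid, y, var, var))
        else:
            adj = _multiarm_adjust(len(arms), raw)
            for (i, j, y, var), va in zip(raw, adj):
                out.append(Contrast(sid, arms[i].tid, arms[j].tid, y, var, va))
    if not out:
        raise ValueError("no informative contrasts in the dataset")
    return out


def _multiarm_adjust(
    p: int, raw: list[tuple[int, int, float, float]]
) -> list[float]:
    """Adjusted variances for the p(p-1)/2 contrasts of a p-arm study.

    The variance matrix V of pairwise contrasts is mapped to the study's
    Laplacian L = pinv(-C V C / 2) (C the centring matrix); the off-diagonal
    Laplacian entries are the adjusted edge weights, whose reciprocals are
    the adjusted variances.  For consistent variances v_ij = s_i^2 + s_j^2
    this reproduces the information of the joint arm-based model.
    """
    V = np.zeros((p, p))
    for i, j, _, var in raw:
        V[i, j] = V[j, i] = var
    C = np.eye(p) - np.ones((p, p)) / p
    L = np.linalg.pinv(-0.5 * C @ V @ C)
    adj = []
    for i, j, _, _ in raw:
        w = -L[i, j]
        if w <= 0:
            raise ValueError(
                "multi-arm variance adjustment produced a non-positive weight; "
                "contrast variances are too inconsistent"
            )
        adj.append(1.0 / w)
    return adj


@dataclass(frozen=True)
class NMAFit:
    """Network estimates for every treatment pair.

    ``theta[i, j]`` is the estimated effect of ``treatments[j]`` versus
    ``treatments[i]`` on the analysis scale (log for OR/RR), so the matrix
    is antisymmetric; ``se`` is symmetric.
    """

    measure: str
    treatments: tuple[int, ...]
    theta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    tau2: float
    random: bool
    alpha: float
    n_total: int
    null_on_scale: float

    def _idx(self, tid: int) -> int:
        try:
            return self.treatments.index(tid)
        except ValueError:
            raise KeyError(f"treatment {tid} not in the network") from None

    def comparison(self, tid1: int, tid2: int) -> tuple[float, float, float, float]:
        """(theta, se, ci_low, ci_high) for the comparison tid1 vs tid2."""
        i, j = self._idx(tid2), self._idx(tid1)
        return (
            float(self.theta[i, j]),
            float(self.se[i, j]),
            float(self.ci_low[i, j]),
            float(self.ci_high[i, j]),
        )

    def significant(self, tid1: int, tid2: int) -> bool:
        _, _, lo, hi = self.comparison(tid1, tid2)
        return lo > self.null_on_scale or hi < self.null_on_scale


def _solve(
    contrasts: list[Contrast],
    treatments: tuple[int, ...],
    variances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """WLS on the network; returns (theta matrix, var matrix, Lplus, Q)."""
    k = len(treatments)
    t_index = {t: i for i, t in enumerate(treatments)}
    m = len(contrasts)
    X = np.zeros((m, k))
    y = np.empty(m)
    for r, c in enumerate(contrasts):
        X[r, t_index[c.t2]] = 1.0
        X[r, t_index[c.t1]] = -1.0
        y[r] = c.y
    w = 1.0 / variances
    L = X.T @ (w[:, None] * X)
    Lplus = np.linalg.pinv(L)
    nu = Lplus @ X.T @ (w * y)
    resid = y - X @ nu
    q = float((w * resid**2).sum())
    theta = nu[None, :] - nu[:, None]  # theta[i, j] = effect of j vs i
    d = np.diag(Lplus)
    var = d[:, None] + d[None, :] - 2 * Lplus
    return theta, var, Lplus, q


def _tau2_gmm(
    contrasts: list[Contrast], treatments: tuple[int, ...], k: int
) -> float:
    """Generalized DerSimonian-Laird tau^2 from the fixed-effect residual Q.

    E[Q] = df + tau^2 * tr(PG) with P the weighted residual-forming matrix
    and G the within-study heterogeneity structure (unit variance per
    contrast, covariance 1/2 for contrasts sharing an arm).  On a network of
    two-arm studies of a single comparison this reduces exactly to the
    pairwise DerSimonian-Laird estimator.
    """
    m = len(contrasts)
    variances = np.array([c.var_adj for c in contrasts])
    _, _, Lplus, q = _solve(contrasts, treatments, variances)
    arms_per_study: dict[int, set[int]] = {}
    for c in contrasts:
        arms_per_study.setdefault(c.sid, set()).update((c.t1, c.t2))
    df = sum(len(ts) - 1 for ts in arms_per_study.values()) - (k - 1)
    if df < 0:
        return 0.0
    G = np.zeros((m, m))
    for a in range(m):
        ca = contrasts[a]
        for b in range(m):
            cb = contrasts[b]
            if ca.sid != cb.sid:
                continue
            G[a, b] = 0.5 * (
                int(ca.t2 == cb.t2) + int(ca.t1 == cb.t1)
                - int(ca.t2 == cb.t1) - int(ca.t1 == cb.t2)
            )
    t_index = {t: i for i, t in enumerate(treatments)}
    X = np.zeros((m, len(treatments)))
    for r, c in enumerate(contrasts):
        X[r, t_index[c.t2]] = 1.0
        X[r, t_index[c.t1]] = -1.0
    w = 1.0 / variances
    P = np.diag(w) - (w[:, None] * X) @ Lplus @ (X.T * w[None, :])
    trace = float(np.trace(P @ G))
    if trace <= 0:
        return 0.0
    return max(0.0, (q - df) / trace)


def nma_fit(
    dataset: NMADataset,
    measure: str = "OR",
    random: bool = True,
    alpha: float = 0.05,
    incr: float = 0.5,
    allincr: bool = False,
    addincr: bool = False,
    allstudies: bool = False,
    null_value: float | None = None,
) -> NMAFit:
    """Fit the network and estimate all K(K-1)/2 pairwise comparisons."""
    contrasts = arms_to_contrasts(
        dataset, measure, incr=incr, allincr=allincr, addincr=addincr,
        allstudies=allstudies,
    )
    treatments = dataset.treatments
    k = len(treatments)
    if k < 2:
        raise ValueError("a network needs at least two treatments")

    tau2 = 0.0
    if random:
        tau2 = _tau2_gmm(contrasts, treatments, k)
        if tau2 > 0:
            # add tau^2 to every raw contrast variance, re-adjust multi-arm
            by_study: dict[int, list[Contrast]] = {}
            for c in contrasts:
                by_study.setdefault(c.sid, []).append(c)
            new: list[Contrast] = []
            for sid, cs in by_study.items():
                arms = sorted({t for c in cs for t in (c.t1, c.t2)})
                if len(cs) == 1:
                    c = cs[0]
                    v = c.var + tau2
                    new.append(Contrast(c.sid, c.t1, c.t2, c.y, c.var, v))
                else:
                    a_index = {t: i for i, t in enumerate(arms)}
                    raw = [
                        (a_index[c.t1], a_index[c.t2], c.y, c.var + tau2) for c in cs
                    ]
                    adj = _multiarm_adjust(len(arms), raw)
                    for c, va in zip(cs, adj):
                        new.append(Contrast(c.sid, c.t1, c.t2, c.y, c.var, va))
            contrasts = new

    variances = np.array([c.var_adj for c in contrasts])
    theta, var, _, _ = _solve(contrasts, treatments, variances)
    se = np.sqrt(np.maximum(var, 0.0))
    np.fill_diagonal(se, 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    if null_value is None:
        null_value = 0.0 if measure == "RD" else 1.0
    null_on_scale = float(np.log(null_value)) if measure in ("OR", "RR") else float(null_value)
    return NMAFit(
        measure=measure, treatments=treatments, theta=theta, se=se,
        ci_low=theta - z * se, ci_high=theta + z * se, tau2=float(tau2),
        random=random, alpha=alpha, n_total=dataset.n_total,
        null_on_scale=null_on_scale,
    )
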