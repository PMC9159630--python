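"""Per-comparison fragility of a network meta-analysis.

For each requested comparison tid1 vs tid2 the greedy single-event
algorithm of the pairwise case is run, but candidate modifications are
restricted to arms of the two compared treatments (in any study containing
them): changes there act most directly on the comparison of interest and
keep the search tractable.  After every candidate change the FULL network
is refit.  An FI of NA therefore means only that no flip is achievable by
modifying those two treatments' arms — modifications elsewhere in the
network might still flip the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nma import NMADataset, NMAFit, nma_fit
from .study import AlphaGrid

__all__ = [
    "NMATrajectoryStep",
    "PairFragility",
    "NMAFragilityResult",
    "fq_nma",
    "fi_nma",
    "fi_nma_alpha_sweep",
]


@dataclass(frozen=True)
class NMATrajectoryStep:
    iteration: int
    sid: int
    tid: int
    delta: int
    theta_hat: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairFragility:
    """Fragility of one comparison tid1 vs tid2 within the network."""

    tid1: int
    tid2: int
    fi: int | None
    direction: str
    fq_pair: float | None
    fq_network: float | None
    n_pair: int
    trajectory: tuple[NMATrajectoryStep, ...]
    final_dataset: NMADataset
    fits_performed: int
    fits_total: int
    na_reason: str | None = None

    def replay(self, dataset: NMADataset) -> NMADataset:
        out = dataset
        for st in self.trajectory:
            out = out.with_event_change(st.sid, st.tid, st.delta)
        return out


@dataclass(frozen=True)
class NMAFragilityResult:
    dataset: NMADataset
    fit0: NMAFit
    alpha: float
    pairs: tuple[PairFragility, ...]

    def pair(self, tid1: int, tid2: int) -> PairFragility:
        for p in self.pairs:
            if {p.tid1, p.tid2} == {tid1, tid2}:
                return p
        raise KeyError(f"comparison {tid1} vs {tid2} was not assessed")

    def fi_matrix(self) -> np.ndarray:
        """Symmetric K x K matrix of FIs (NaN where NA or on the diagonal)."""
        t = self.fit0.treatments
        m = np.full((len(t), len(t)), np.nan)
        for p in self.pairs:
            i, j = t.index(p.tid1), t.index(p.tid2)
            v = np.nan if p.fi is None else float(p.fi)
            m[i, j] = m[j, i] = v
        return m

    def fq_matrix(self, denominator: str = "pair") -> np.ndarray:
        t = self.fit0.treatments
        m = np.full((len(t), len(t)), np.nan)
        for p in self.pairs:
            i, j = t.index(p.tid1), t.index(p.tid2)
            v = p.fq_pair if denominator == "pair" else p.fq_network
            m[i, j] = m[j, i] = np.nan if v is None else float(v)
        return m


def fq_nma(fi: int | None, n_pair: int, n_network: int) -> tuple[float | None, float | None]:
    """(FQ with the pair's sample size, FQ with the whole network's).

    The pair-based quotient ranges over (0, 100] and is comparable across
    treatment pairs; the network-based one is bounded by n_pair/n_network.
    """
    if not (0 < n_pair <= n_network):
        raise ValueError("need 0 < n_pair <= n_network")
    if fi is None:
        return None, None
    if fi < 1:
        raise ValueError("FI must be a positive integer")
    return 100.0 * fi / n_pair, 100.0 * fi / n_network


def _candidates_pair(
    state: NMADataset, tid_down: int, tid_up: int
) -> list[tuple[int, int, int]]:
    """Single-event changes decreasing events in ``tid_down`` arms or
    increasing them in ``tid_up`` arms; ordered by study id, with the
    comparison's first-named treatment's arm first within a study."""
    by_sid: dict[int, list[tuple[int, int, int]]] = {}
    for a in state.arms:
        if a.tid == tid_down and a.e > 0:
            by_sid.setdefault(a.sid, []).append((a.sid, a.tid, -1))
        elif a.tid == tid_up and a.e < a.n:
            by_sid.setdefault(a.sid, []).append((a.sid, a.tid, +1))
    out: list[tuple[int, int, int]] = []
    for sid in sorted(by_sid):
        out.extend(sorted(by_sid[sid], key=lambda c: c[1] != tid_down))
    return out


def _run_pair_direction(
    dataset: NMADataset,
    tid1: int,
    tid2: int,
    target: str,
    watch: str,
    stop,
    max_iter: int,
    fit_kw: dict,
) -> tuple[int | None, tuple[NMATrajectoryStep, ...], NMADataset, int, str | None]:
    # moving the estimate of tid1 vs tid2 left means fewer events under tid1
    # (or more under tid2); right is the mirror image
    tid_down, tid_up = (tid1, tid2) if target == "left" else (tid2, tid1)
    state = dataset
    steps: list[NMATrajectoryStep] = []
    fits = 0
    it = 0
    while True:
        if it >= max_iter:
            return None, tuple(steps), state, fits, "iteration cap reached"
        it += 1
        cands = _candidates_pair(state, tid_down, tid_up)
        if not cands:
            return None, tuple(steps), state, fits, "no admissible modification left"
        best = best_val = best_state = best_fit = None
        for cand in cands:
            sid, tid, delta = cand
            new_state = state.with_event_change(sid, tid, delta)
            fit = nma_fit(new_state, **fit_kw)
            fits += 1
            _, _, lo, hi = fit.comparison(tid1, tid2)
            val = lo if watch == "lower" else hi
            if target == "right":
                val = -val
            if best_val is None or val < best_val:
                best, best_val, best_state, best_fit = cand, val, new_state, fit
        sid, tid, delta = best
        th, _, lo, hi = best_fit.comparison(tid1, tid2)
        steps.append(NMATrajectoryStep(
            iteration=it, sid=sid, tid=tid, delta=delta,
            theta_hat=th, ci_low=lo, ci_high=hi,
        ))
        state = best_state
        if stop(best_fit):
            return it, tuple(steps), state, fits, None


def fi_nma(
    dataset: NMADataset,
    measure: str = "OR",
    alpha: float = 0.05,
    random: bool = True,
    mod_dir: str = "both",
    pairs: list[tuple[int, int]] | None = None,
    incr: float = 0.5,
    allincr: bool = False,
    addincr: bool = False,
    allstudies: bool = False,
    null_value: float | None = None,
    max_iter: int | None = None,
) -> NMAFragilityResult:
    """Greedy fragility index for every (or each requested) comparison.

    ``pairs`` is a list of (tid1, tid2) comparisons; by default all
    K(K-1)/2 comparisons are assessed (as larger vs smaller treatment id).
    Comparisons are assessed independently, each restarting from the
    original data; results do not depend on the order of assessment.
    """
    fit_kw = dict(measure=measure, random=random, alpha=alpha, incr=incr,
                  allincr=allincr, addincr=addincr, allstudies=allstudies,
                  null_value=null_value)
    fit0 = nma_fit(dataset, **fit_kw)
    null = fit0.null_on_scale
    treatments = fit0.treatments
    if pairs is None:
        pairs = [
            (treatments[j], treatments[i])
            for i in range(len(treatments))
            for j in range(i + 1, len(treatments))
        ]
    for t1, t2 in pairs:
        if t1 not in treatments or t2 not in treatments:
            raise KeyError(f"comparison {t1} vs {t2}: treatment not in the network")
        if t1 == t2:
            raise ValueError("a comparison needs two distinct treatments")
    cap_default = dataset.n_total
    cap = cap_default if max_iter is None else max_iter

    out: list[PairFragility] = []
    for tid1, tid2 in pairs:
        th, _, lo, hi = fit0.comparison(tid1, tid2)
        significant = lo > null or hi < null
        if significant:
            direction = "sig_to_nonsig"
            if th > null:
                target, watch = "left", "lower"
                stop = lambda fit: fit.comparison(tid1, tid2)[2] <= null  # noqa: E731
            else:
                target, watch = "right", "upper"
                stop = lambda fit: fit.comparison(tid1, tid2)[3] >= null  # noqa: E731
            fi, steps, final, fits, reason = _run_pair_direction(
                dataset, tid1, tid2, target, watch, stop, cap, fit_kw)
            fits_total = fits
        else:
            direction = "nonsig_to_sig"
            if mod_dir == "one":
                dirs = ["right"] if th >= null else ["left"]
            elif mod_dir == "both":
                dirs = ["left", "right"]
            else:
                dirs = [mod_dir]
            runs = []
            fits_total = 0
            for d in dirs:
                if d == "left":
                    watch = "upper"
                    stop = lambda fit: fit.comparison(tid1, tid2)[3] < null  # noqa: E731
                else:
                    watch = "lower"
                    stop = lambda fit: fit.comparison(tid1, tid2)[2] > null  # noqa: E731
                r = _run_pair_direction(dataset, tid1, tid2, d, watch, stop, cap, fit_kw)
                fits_total += r[3]
                runs.append(r)
            best = None
            for r in runs:
                if r[0] is not None and (best is None or r[0] < best[0]):
                    best = r
            if best is None:
                best = runs[0]
            fi, steps, final, fits, reason = best
        n_pair = dataset.n_in_treatments((tid1, tid2))
        fq_pair, fq_net = fq_nma(fi, n_pair, dataset.n_total)
        out.append(PairFragility(
            tid1=tid1, tid2=tid2, fi=fi, direction=direction,
            fq_pair=fq_pair, fq_network=fq_net, n_pair=n_pair,
            trajectory=steps, final_dataset=final, fits_performed=fits,
            fits_total=fits_total, na_reason=reason,
        ))
    return NMAFragilityResult(dataset=dataset, fit0=fit0, alpha=alpha, pairs=tuple(out))


@dataclass(frozen=True)
class NMASweepResult:
    dataset: NMADataset
    grid: AlphaGrid
    levels: np.ndarray
    #: per (tid1, tid2): float array of FIs over levels (NaN for NA)
    fis: dict
    directions: dict
    fi_avg: dict
    fq_pair_avg: dict


def fi_nma_alpha_sweep(
    dataset: NMADataset,
    grid: AlphaGrid = AlphaGrid(breaks=10),
    pairs: list[tuple[int, int]] | None = None,
    **kw,
) -> NMASweepResult:
    """fi_nma at each grid level; a modest number of levels is advisable
    because every level re-runs the full greedy search per comparison."""
    levels = grid.levels
    per_level = [
        fi_nma(dataset, alpha=float(a), pairs=pairs, **kw) for a in levels
    ]
    keys = [(p.tid1, p.tid2) for p in per_level[0].pairs]
    fis = {k: np.full(levels.shape, np.nan) for k in keys}
    directions = {k: [] for k in keys}
    for b, res in enumerate(per_level):
        for p in res.pairs:
            k = (p.tid1, p.tid2)
            if p.fi is not None:
                fis[k][b] = p.fi
            directions[k].append(p.direction)
    fi_avg = {}
    fq_pair_avg = {}
    for k in keys:
        defined = ~np.isnan(fis[k])
        fi_avg[k] = float(fis[k][defined].mean()) if defined.any() else None
        n_pair = dataset.n_in_treatments(k)
        fq_pair_avg[k] = None if fi_avg[k] is None else 100.0 * fi_avg[k] / n_pair
    return NMASweepResult(
        dataset=dataset, grid=grid, levels=levels, fis=fis,
        directions={k: tuple(v) for k, v in directions.items()},
        fi_avg=fi_avg, fq_pair_avg=fq_pair_avg,
    )
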