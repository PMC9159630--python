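"""Greedy CI-driven fragility assessment of a pairwise meta-analysis.

Exhaustively enumerating modification sequences needs up to (2N)^FI refits,
so the fragility index of a meta-analysis is derived by a greedy heuristic:
at each iteration every admissible single-event change (one event removed
from group 1 or one added to group 0, or the mirror image, in any study) is
tried, the meta-analysis is refit for each, and the change that moves the
watched confidence-interval bound furthest in the target direction is kept.
The iterations stop as soon as significance (CI vs the null) flips; the FI
is the number of kept changes, bounded work 2N x FI refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meta import MADataset, MAFit, ma_fit
from .study import AlphaGrid, fq

__all__ = [
    "TrajectoryStep",
    "FragilityTrajectory",
    "MAFragilityResult",
    "candidate_mods",
    "greedy_step",
    "fi_ma",
    "fi_ma_alpha_sweep",
    "fi_ma_batch",
]

MOD_DIRS = ("both", "left", "right", "one")


@dataclass(frozen=True)
class TrajectoryStep:
    """One kept single-event modification and the refitted summary after it."""

    iteration: int
    study_id: int
    group: int
    delta: int
    theta_hat: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class FragilityTrajectory:
    steps: tuple[TrajectoryStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def replay(self, dataset: MADataset) -> MADataset:
        """Apply the recorded steps to a dataset (validity check helper)."""
        id_to_index = {sid: i for i, sid in enumerate(dataset.ids)}
        out = dataset
        for st in self.steps:
            out = out.with_event_change(id_to_index[st.study_id], st.group, st.delta)
        return out


@dataclass(frozen=True)
class MAFragilityResult:
    dataset: MADataset
    fit0: MAFit
    alpha: float
    fi: int | None
    fq: float | None
    direction: str
    trajectory: FragilityTrajectory
    final_dataset: MADataset
    #: refits of the reported (winning) run; bounded by 2N x FI
    fits_performed: int
    #: refits across all directional runs (equals fits_performed unless
    #: a non-significant result was pushed in both directions)
    fits_total: int
    mod_dir: str
    na_reason: str | None = None


def candidate_mods(
    state: MADataset, target: str
) -> list[tuple[int, int, int]]:
    """Admissible single-event changes ``(study_index, group, delta)``.

    ``target='left'`` pulls the pooled estimate of group 1 vs group 0 down:
    remove an event from group 1 (if any) or add one to group 0 (if room);
    ``'right'`` is the mirror image.  At most 2N candidates; studies at the
    count bounds contribute fewer.  Group-1 candidates are listed first
    within each study, which is also the deterministic tie order.
    """
    if target not in ("left", "right"):
        raise ValueError("target must be 'left' or 'right'")
    out: list[tuple[int, int, int]] = []
    for i, t in enumerate(state.studies):
        if target == "left":
            if t.e1 > 0:
                out.append((i, 1, -1))
            if t.e0 < t.n0:
                out.append((i, 0, +1))
        else:
            if t.e1 < t.n1:
                out.append((i, 1, +1))
            if t.e0 > 0:
                out.append((i, 0, -1))
    return out


def _refit(state: MADataset, **fit_kw) -> MAFit:
    return ma_fit(state, **fit_kw)


def greedy_step(
    state: MADataset,
    target: str,
    watch: str,
    **fit_kw,
) -> tuple[tuple[int, int, int], MADataset, MAFit, int]:
    """Try every candidate, refit each, keep the best mover.

    ``watch`` names the CI bound whose crossing of the null ends the run
    ('lower' or 'upper'); moving left means minimising that bound, moving
    right maximising it.  Ties keep the earliest candidate in the
    deterministic order (lowest study id, group 1 before group 0).
    Returns (chosen modification, new state, new fit, number of refits).
    """
    cands = candidate_mods(state, target)
    if not cands:
        raise _NoCandidates()
    best = None
    best_val = None
    best_state = None
    best_fit = None
    for cand in cands:
        i, grp, delta = cand
        new_state = state.with_event_change(i, grp, delta)
        fit = _refit(new_state, **fit_kw)
        val = fit.ci_low if watch == "lower" else fit.ci_high
        if target == "right":
            val = -val  # maximise by minimising the negation
        if best_val is None or val < best_val:
            best, best_val, best_state, best_fit = cand, val, new_state, fit
    return best, best_state, best_fit, len(cands)


class _NoCandidates(Exception):
    pass


def _run_direction(
    dataset: MADataset,
    fit0: MAFit,
    target: str,
    watch: str,
    stop,
    max_iter: int,
    fit_kw: dict,
) -> tuple[int | None, FragilityTrajectory, MADataset, int, str | None]:
    """Iterate greedy steps until ``stop(fit)`` is true; NA on exhaustion."""
    state = dataset
    steps: list[TrajectoryStep] = []
    fits = 0
    it = 0
    while True:
        if it >= max_iter:
            return None, FragilityTrajectory(tuple(steps)), state, fits, "iteration cap reached"
        it += 1
        try:
            cand, state, fit, n = greedy_step(state, target, watch, **fit_kw)
        except _NoCandidates:
            return None, FragilityTrajectory(tuple(steps)), state, fits, "no admissible modification left"
        fits += n
        i, grp, delta = cand
        steps.append(TrajectoryStep(
            iteration=it, study_id=dataset.ids[i], group=grp, delta=delta,
            theta_hat=fit.theta_hat, ci_low=fit.ci_low, ci_high=fit.ci_high,
        ))
        if stop(fit):
            return it, FragilityTrajectory(tuple(steps)), state, fits, None


def fi_ma(
    dataset: MADataset,
    measure: str = "OR",
    alpha: float = 0.05,
    mod_dir: str = "both",
    tau2_method: str = "DL",
    ci_method: str = "z",
    null_value: float | None = None,
    incr: float = 0.5,
    max_iter: int | None = None,
) -> MAFragilityResult:
    """Fragility index of a pairwise meta-analysis via the greedy algorithm.

    Significance is judged by the CI against the null.  A significant
    original result is pushed toward the null (one direction); a
    non-significant one can be pushed toward either side per ``mod_dir``:
    'both' runs left and right independently from the original data and
    takes the smaller FI, 'one' follows the sign of the original point
    estimate, 'left'/'right' force that side.  FI is NA when a run exhausts
    its candidates or hits the iteration cap (default: total sample size).
    """
    if mod_dir not in MOD_DIRS:
        raise ValueError(f"mod_dir must be one of {MOD_DIRS}")
    fit_kw = dict(measure=measure, tau2_method=tau2_method, ci_method=ci_method,
                  alpha=alpha, incr=incr, null_value=null_value)
    fit0 = ma_fit(dataset, **fit_kw)
    null = fit0.null_on_scale
    cap = dataset.n_total if max_iter is None else max_iter

    if fit0.significant:
        direction = "sig_to_nonsig"
        if fit0.theta_hat > null:
            target, watch = "left", "lower"
        else:
            target, watch = "right", "upper"
        stop = lambda fit: not fit.significant  # noqa: E731
        fi, traj, final, fits, reason = _run_direction(
            dataset, fit0, target, watch, stop, cap, fit_kw)
        fits_total = fits
    else:
        direction = "nonsig_to_sig"
        runs = []
        if mod_dir == "one":
            import warnings

            if fit0.theta_hat == null:
                warnings.warn("point estimate equals the null; defaulting to 'right'",
                              stacklevel=2)
            dirs = ["right"] if fit0.theta_hat >= null else ["left"]
        elif mod_dir == "both":
            dirs = ["left", "right"]
        else:
            dirs = [mod_dir]
        fits_total = 0
        for d in dirs:
            if d == "left":
                watch = "upper"
                stop = lambda fit: fit.ci_high < null  # noqa: E731
            else:
                watch = "lower"
                stop = lambda fit: fit.ci_low > null  # noqa: E731
            r = _run_direction(dataset, fit0, d, watch, stop, cap, fit_kw)
            fits_total += r[3]
            runs.append(r)
        # keep the run with the smallest defined FI (first wins ties)
        best = None
        for r in runs:
            if r[0] is not None and (best is None or r[0] < best[0]):
                best = r
        if best is None:
            best = runs[0]
        fi, traj, final, fits, reason = best

    return MAFragilityResult(
        dataset=dataset, fit0=fit0, alpha=alpha, fi=fi,
        fq=fq(fi, dataset.n_total), direction=direction, trajectory=traj,
        final_dataset=final, fits_performed=fits, fits_total=fits_total,
        mod_dir=mod_dir, na_reason=reason,
    )


@dataclass(frozen=True)
class MASweepResult:
    dataset: MADataset
    grid: AlphaGrid
    levels: np.ndarray
    fis: np.ndarray
    directions: tuple[str, ...]
    fi_avg: float | None
    fq_avg: float | None
    n_na: int


def fi_ma_alpha_sweep(
    dataset: MADataset,
    measure: str = "OR",
    grid: AlphaGrid = AlphaGrid(),
    **kw,
) -> MASweepResult:
    """fi_ma at every grid level; averages over levels with a defined FI."""
    levels = grid.levels
    fis = np.full(levels.shape, np.nan)
    directions = []
    for b, alpha in enumerate(levels):
        r = fi_ma(dataset, measure=measure, alpha=float(alpha), **kw)
        directions.append(r.direction)
        if r.fi is not None:
            fis[b] = r.fi
    defined = ~np.isnan(fis)
    fi_avg = float(fis[defined].mean()) if defined.any() else None
    fq_avg = None if fi_avg is None else 100.0 * fi_avg / dataset.n_total
    return MASweepResult(dataset=dataset, grid=grid, levels=levels, fis=fis,
                         directions=tuple(directions), fi_avg=fi_avg,
                         fq_avg=fq_avg, n_na=int((~defined).sum()))


@dataclass
class MABatchResult:
    results: list[MAFragilityResult | None]
    errors: dict[int, str] = field(default_factory=dict)

    def summary(self):
        import pandas as pd

        rows = []
        ok = [r for r in self.results if r is not None]
        for sig, label in ((True, "significant"), (False, "non_significant")):
            sub = [r for r in ok if r.fit0.significant == sig]
            fis = np.array([r.fi for r in sub if r.fi is not None], dtype=float)
            fqs = np.array([r.fq for r in sub if r.fq is not None], dtype=float)
            row = {"original": label, "n": len(sub), "n_fi_na": len(sub) - fis.size}
            for name, v in (("fi", fis), ("fq", fqs)):
                if v.size:
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                    row.update({f"{name}_median": med, f"{name}_min": v.min(),
                                f"{name}_max": v.max(), f"{name}_q1": q1, f"{name}_q3": q3})
                else:
                    row.update({f"{name}_median": np.nan, f"{name}_min": np.nan,
                                f"{name}_max": np.nan, f"{name}_q1": np.nan,
                                f"{name}_q3": np.nan})
            rows.append(row)
        return pd.DataFrame(rows)


def fi_ma_batch(datasets: list[MADataset], **kw) -> MABatchResult:
    """fi_ma over many meta-analyses; failures recorded per dataset."""
    if not datasets:
        raise ValueError("need at least one dataset")
    results: list[MAFragilityResult | None] = []
    errors: dict[int, str] = {}
    for i, d in enumerate(datasets):
        try:
            results.append(fi_ma(d, **kw))
        except Exception as exc:  # noqa: BLE001
            results.append(None)
            errors[i] = str(exc)
    return MABatchResult(results=results, errors=errors)
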