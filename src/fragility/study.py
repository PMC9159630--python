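"""Fragility of a single 2x2 trial and batches of trials.

The fragility index (FI) of a trial is the minimal number of event-status
changes ``|f0| + |f1|`` that flips the result between significant
(``p < alpha``) and non-significant (``p >= alpha``).  Two equivalent search
strategies are provided: an exhaustive landscape over every legal
modification (which also yields the p-value grid used for plotting) and a
shell search that enumerates modifications of total size 1, 2, ... and stops
at the first size containing a flip.  The restricted indices FI0 and FI1
confine modifications to one group; the fragility quotient (FQ) expresses
the FI as a percentage of the total sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tables import (
    Modification,
    TestSpec,
    TwoByTwoTable,
    p_values_batch,
)

__all__ = [
    "ModificationConstraint",
    "AlphaGrid",
    "PGrid",
    "StudyFragilityResult",
    "StudySweepResult",
    "StudyBatchResult",
    "fi_exhaustive",
    "fi_search",
    "fi_restricted",
    "fq",
    "fi_alpha_sweep",
    "fi_batch",
]

_MODIFY_CHOICES = ("both", "increase", "decrease", "none")

#: Exhaustive grids above this many cells are refused (use fi_search).
DEFAULT_CELL_CAP = 1_000_000


@dataclass(frozen=True)
class ModificationConstraint:
    """Direction constraints on event-status modifications per group.

    ``both`` allows any legal change, ``increase`` only non-events to events
    (f >= 0), ``decrease`` only events to non-events (f <= 0), and ``none``
    freezes the group.  Ranges are always clipped to [-e_k, n_k - e_k].
    """

    group0: str = "both"
    group1: str = "both"

    def __post_init__(self) -> None:
        for name in ("group0", "group1"):
            if getattr(self, name) not in _MODIFY_CHOICES:
                raise ValueError(
                    f"{name} must be one of {_MODIFY_CHOICES}, got {getattr(self, name)!r}"
                )

    def f_range(self, table: TwoByTwoTable, group: int) -> tuple[int, int]:
        """Inclusive (low, high) range of f for the given group."""
        e, n = (table.e0, table.n0) if group == 0 else (table.e1, table.n1)
        mode = self.group0 if group == 0 else self.group1
        lo, hi = -e, n - e
        if mode == "increase":
            lo = 0
        elif mode == "decrease":
            hi = 0
        elif mode == "none":
            lo = hi = 0
        return lo, hi


@dataclass(frozen=True)
class AlphaGrid:
    """Equally spaced grid of significance levels, endpoints included."""

    alpha_from: float = 0.005
    alpha_to: float = 0.05
    breaks: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.alpha_from < self.alpha_to < 1):
            raise ValueError("need 0 < alpha_from < alpha_to < 1")
        if self.breaks < 2:
            raise ValueError("breaks must be >= 2")

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(self.alpha_from, self.alpha_to, self.breaks)


@dataclass(frozen=True)
class PGrid:
    """p-values over the full modification landscape (rows f0, columns f1)."""

    f0_values: np.ndarray
    f1_values: np.ndarray
    p: np.ndarray

    def lookup(self, f0: int, f1: int) -> float:
        i = int(np.where(self.f0_values == f0)[0][0])
        j = int(np.where(self.f1_values == f1)[0][0])
        return float(self.p[i, j])


@dataclass(frozen=True)
class StudyFragilityResult:
    """FI/FQ of one trial, with the modifications achieving the minimum."""

    table: TwoByTwoTable
    spec: TestSpec
    alpha: float
    constraint: ModificationConstraint
    p0: float
    direction: str
    fi: int | None
    fi0: int | None
    fi1: int | None
    fq: float | None
    minimal_mods: tuple[Modification, ...]
    p_grid: PGrid | None = None

    def __post_init__(self) -> None:
        if self.fi is not None and self.fi0 is not None and self.fi1 is not None:
            assert 1 <= self.fi <= min(self.fi0, self.fi1), (
                f"FI bound violated: FI={self.fi}, FI0={self.fi0}, FI1={self.fi1}"
            )


@dataclass(frozen=True)
class StudySweepResult:
    """FI across a grid of significance levels, with the grid average."""

    table: TwoByTwoTable
    spec: TestSpec
    grid: AlphaGrid
    p0: float
    levels: np.ndarray
    fis: np.ndarray  # float array; NaN where FI is NA
    directions: tuple[str, ...]
    fi_avg: float | None
    fq_avg: float | None
    n_na: int


@dataclass
class StudyBatchResult:
    """Per-trial fragility results plus direction-stratified summaries."""

    results: list[StudyFragilityResult | None]
    errors: dict[int, str] = field(default_factory=dict)

    def summary(self):
        """Direction-stratified counts and FI/FQ medians, ranges, IQRs."""
        import pandas as pd

        rows = []
        ok = [r for r in self.results if r is not None]
        for direction in ("sig_to_nonsig", "nonsig_to_sig"):
            sub = [r for r in ok if r.direction == direction]
            fis = np.array([r.fi for r in sub if r.fi is not None], dtype=float)
            fqs = np.array([r.fq for r in sub if r.fq is not None], dtype=float)
            row = {"direction": direction, "n": len(sub), "n_fi_na": len(sub) - fis.size}
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

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, r in enumerate(self.results):
            if r is None:
                rows.append({"trial": i + 1, "error": self.errors.get(i, "failed")})
                continue
            rows.append(
                {"trial": i + 1, "p0": r.p0, "direction": r.direction,
                 "fi": r.fi, "fi0": r.fi0, "fi1": r.fi1, "fq": r.fq}
            )
        return pd.DataFrame(rows)


def fq(fi: int | None, n_total: int) -> float | None:
    """Fragility quotient: FI as a percentage of the participants."""
    if fi is None:
        return None
    if fi < 1:
        raise ValueError("FI must be a positive integer")
    if n_total < 1:
        raise ValueError("n_total must be positive")
    return 100.0 * fi / n_total


def _direction(p0: float, alpha: float) -> str:
    # strict rule: p == alpha counts as non-significant
    return "sig_to_nonsig" if p0 < alpha else "nonsig_to_sig"


def _flips(p: np.ndarray, p0: float, alpha: float) -> np.ndarray:
    if p0 < alpha:
        return p >= alpha
    return p < alpha


def _p0(table: TwoByTwoTable, spec: TestSpec, incr: float) -> float:
    return float(p_values_batch(table, spec, np.array([0]), np.array([0]), incr=incr)[0])


def fi_exhaustive(
    table: TwoByTwoTable,
    spec: TestSpec,
    alpha: float = 0.05,
    constraint: ModificationConstraint = ModificationConstraint(),
    incr: float = 0.5,
    cell_cap: int = DEFAULT_CELL_CAP,
) -> StudyFragilityResult:
    """FI by evaluating the p-value of every legal modification.

    Keeps the full p-value grid (for landscape plots).  Refuses grids larger
    than ``cell_cap`` cells; use :func:`fi_search` for large trials.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    lo0, hi0 = constraint.f_range(table, 0)
    lo1, hi1 = constraint.f_range(table, 1)
    f0s = np.arange(lo0, hi0 + 1)
    f1s = np.arange(lo1, hi1 + 1)
    n_cells = f0s.size * f1s.size
    if n_cells > cell_cap:
        raise ValueError(
            f"exhaustive landscape would need {n_cells} cells (> cap {cell_cap}); "
            "use fi_search instead"
        )
    F0, F1 = np.meshgrid(f0s, f1s, indexing="ij")
    p = p_values_batch(table, spec, F0.ravel(), F1.ravel(), incr=incr).reshape(F0.shape)
    grid = PGrid(f0_values=f0s, f1_values=f1s, p=p)
    p0 = grid.lookup(0, 0)
    direction = _direction(p0, alpha)

    sizes = np.abs(F0) + np.abs(F1)
    flips = _flips(p, p0, alpha) & (sizes > 0)
    fi = None
    minimal: tuple[Modification, ...] = ()
    if flips.any():
        fi = int(sizes[flips].min())
        ii, jj = np.nonzero(flips & (sizes == fi))
        mods = sorted(
            (Modification(int(f0s[i]), int(f1s[j])) for i, j in zip(ii, jj)),
            key=lambda m: (m.f0, m.f1),
        )
        minimal = tuple(mods)

    fi0 = _restricted_from_axis(f0s, p[:, np.where(f1s == 0)[0][0]] if 0 in f1s else None,
                                p0, alpha)
    fi1 = _restricted_from_axis(f1s, p[np.where(f0s == 0)[0][0], :] if 0 in f0s else None,
                                p0, alpha)
    return StudyFragilityResult(
        table=table, spec=spec, alpha=alpha, constraint=constraint, p0=p0,
        direction=direction, fi=fi, fi0=fi0, fi1=fi1,
        fq=fq(fi, table.n_total), minimal_mods=minimal, p_grid=grid,
    )


def _restricted_from_axis(fs, p_axis, p0: float, alpha: float) -> int | None:
    if p_axis is None:
        return None
    sizes = np.abs(fs)
    flips = _flips(np.asarray(p_axis), p0, alpha) & (sizes > 0)
    if not flips.any():
        return None
    return int(sizes[flips].min())


def _shell_members(
    table: TwoByTwoTable, constraint: ModificationConstraint, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """All legal (f0, f1) with |f0| + |f1| = m, ordered f0 then f1 ascending."""
    lo0, hi0 = constraint.f_range(table, 0)
    lo1, hi1 = constraint.f_range(table, 1)
    f0_list: list[int] = []
    f1_list: list[int] = []
    for f0 in range(max(lo0, -m), min(hi0, m) + 1):
        r = m - abs(f0)
        cands = (0,) if r == 0 else (-r, r)
        for f1 in cands:
            if lo1 <= f1 <= hi1:
                f0_list.append(f0)
                f1_list.append(f1)
    return np.array(f0_list, dtype=int), np.array(f1_list, dtype=int)


def _max_shell(table: TwoByTwoTable, constraint: ModificationConstraint) -> int:
    lo0, hi0 = constraint.f_range(table, 0)
    lo1, hi1 = constraint.f_range(table, 1)
    return max(abs(lo0), abs(hi0)) + max(abs(lo1), abs(hi1))


def fi_search(
    table: TwoByTwoTable,
    spec: TestSpec,
    alpha: float = 0.05,
    constraint: ModificationConstraint = ModificationConstraint(),
    incr: float = 0.5,
    restricted: bool = True,
) -> StudyFragilityResult:
    """FI by shell search: test sizes m = 1, 2, ... and stop at the first flip.

    Produces the same FI, direction and minimal modifications as
    :func:`fi_exhaustive` without materialising the landscape.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    p0 = _p0(table, spec, incr)
    direction = _direction(p0, alpha)
    fi = None
    minimal: tuple[Modification, ...] = ()
    for m in range(1, _max_shell(table, constraint) + 1):
        f0s, f1s = _shell_members(table, constraint, m)
        if f0s.size == 0:
            continue
        p = p_values_batch(table, spec, f0s, f1s, incr=incr)
        hit = _flips(p, p0, alpha)
        if hit.any():
            fi = m
            minimal = tuple(
                Modification(int(a), int(b)) for a, b in zip(f0s[hit], f1s[hit])
            )
            break
    fi0 = fi1 = None
    if restricted:
        fi0 = fi_restricted(table, spec, alpha, group=0, constraint=constraint, incr=incr)
        fi1 = fi_restricted(table, spec, alpha, group=1, constraint=constraint, incr=incr)
    return StudyFragilityResult(
        table=table, spec=spec, alpha=alpha, constraint=constraint, p0=p0,
        direction=direction, fi=fi, fi0=fi0, fi1=fi1,
        fq=fq(fi, table.n_total), minimal_mods=minimal, p_grid=None,
    )


def fi_restricted(
    table: TwoByTwoTable,
    spec: TestSpec,
    alpha: float = 0.05,
    group: int = 0,
    constraint: ModificationConstraint = ModificationConstraint(),
    incr: float = 0.5,
) -> int | None:
    """FI with modifications confined to one group (FI0 or FI1)."""
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    sub = ModificationConstraint(
        group0=constraint.group0 if group == 0 else "none",
        group1=constraint.group1 if group == 1 else "none",
    )
    res = fi_search(table, spec, alpha, sub, incr=incr, restricted=False)
    return res.fi


def fi_alpha_sweep(
    table: TwoByTwoTable,
    spec: TestSpec,
    grid: AlphaGrid = AlphaGrid(),
    constraint: ModificationConstraint = ModificationConstraint(),
    incr: float = 0.5,
) -> StudySweepResult:
    """FI at every level of an alpha grid, plus the grid-average FI and FQ.

    The average is the arithmetic mean over levels where the FI is defined;
    the count of undefined (NA) levels is reported alongside.  Shells are
    evaluated once and shared across levels: FI(alpha) only depends on the
    running extrema of p within each shell.
    """
    levels = grid.levels
    p0 = _p0(table, spec, incr)
    m_max = _max_shell(table, constraint)
    # per-shell min/max of p, computed lazily up to the deepest level needed
    shell_min: list[float] = []
    shell_max: list[float] = []

    def ensure(m: int) -> bool:
        while len(shell_min) < m:
            mm = len(shell_min) + 1
            if mm > m_max:
                return False
            f0s, f1s = _shell_members(table, constraint, mm)
            if f0s.size == 0:
                shell_min.append(math.inf)
                shell_max.append(-math.inf)
            else:
                p = p_values_batch(table, spec, f0s, f1s, incr=incr)
                shell_min.append(float(p.min()))
                shell_max.append(float(p.max()))
        return True

    fis = np.full(levels.shape, np.nan)
    directions = []
    for b, alpha in enumerate(levels):
        directions.append(_direction(p0, alpha))
        m = 1
        while ensure(m):
            flip = (shell_max[m - 1] >= alpha) if p0 < alpha else (shell_min[m - 1] < alpha)
            if flip:
                fis[b] = m
                break
            m += 1
            if m > m_max:
                break
    defined = ~np.isnan(fis)
    fi_avg = float(fis[defined].mean()) if defined.any() else None
    fq_avg = None if fi_avg is None else 100.0 * fi_avg / table.n_total
    return StudySweepResult(
        table=table, spec=spec, grid=grid, p0=p0, levels=levels, fis=fis,
        directions=tuple(directions), fi_avg=fi_avg, fq_avg=fq_avg,
        n_na=int((~defined).sum()),
    )


def fi_batch(
    tables: list[TwoByTwoTable],
    spec: TestSpec,
    alpha: float = 0.05,
    constraint: ModificationConstraint = ModificationConstraint(),
    incr: float = 0.5,
) -> StudyBatchResult:
    """Fragility of many trials; per-trial failures are recorded, not raised."""
    if not tables:
        raise ValueError("need at least one table")
    results: list[StudyFragilityResult | None] = []
    errors: dict[int, str] = {}
    for i, t in enumerate(tables):
        try:
            results.append(fi_search(t, spec, alpha, constraint, incr=incr))
        except Exception as exc:  # noqa: BLE001 - batch keeps going by contract
            results.append(None)
            errors[i] = str(exc)
    return StudyBatchResult(results=results, errors=errors)
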