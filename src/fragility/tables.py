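"""2x2 contingency tables, event-status modifications, and association tests.

A two-arm trial with a binary outcome is summarised by the counts
``(e0, n0, e1, n1)``: events and sample size in treatment groups 0 and 1.
An *event status modification* ``(f0, f1)`` changes ``f_k`` non-events to
events in group ``k`` (negative values change events back to non-events),
leaving the sample sizes fixed.  Five association methods produce a p-value
for any (modified) table: Fisher's exact test, the Pearson chi-squared test,
and Wald tests on the log odds ratio, log relative risk, and risk difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "TwoByTwoTable",
    "Modification",
    "EffectEstimate",
    "TestSpec",
    "METHODS",
    "apply_modification",
    "continuity_correct",
    "fisher_p",
    "chisq_p",
    "effect_estimate",
    "wald_p",
    "p_value",
]

#: The five supported association methods.
METHODS = ("fisher", "chisq", "OR", "RR", "RD")

#: Effect measures analysed on a Wald (normal-approximation) scale.
WALD_MEASURES = ("OR", "RR", "RD")


class DegenerateTableWarning(UserWarning):
    """Raised when a test statistic is undefined (zero margin); p is set to 1."""


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts of one two-arm trial: events ``e_k`` out of ``n_k`` per group."""

    e0: int
    n0: int
    e1: int
    n1: int

    def __post_init__(self) -> None:
        for name in ("e0", "n0", "e1", "n1"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n0 <= 0 or self.n1 <= 0:
            raise ValueError("sample sizes n0, n1 must be positive")
        if not (0 <= self.e0 <= self.n0):
            raise ValueError(f"need 0 <= e0 <= n0, got e0={self.e0}, n0={self.n0}")
        if not (0 <= self.e1 <= self.n1):
            raise ValueError(f"need 0 <= e1 <= n1, got e1={self.e1}, n1={self.n1}")

    @property
    def n_total(self) -> int:
        return self.n0 + self.n1

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(events0, non-events0, events1, non-events1)."""
        return (self.e0, self.n0 - self.e0, self.e1, self.n1 - self.e1)

    def has_zero_cell(self) -> bool:
        return min(self.cells) == 0


@dataclass(frozen=True)
class Modification:
    """Signed event-count change per group; (0, 0) is the identity."""

    f0: int
    f1: int

    @property
    def size(self) -> int:
        """Number of participants whose status changes, |f0| + |f1|."""
        return abs(self.f0) + abs(self.f1)


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimate and standard error on the analysis scale.

    ``y`` is the log OR / log RR or the raw risk difference; ``corrected``
    records whether the 0.5 continuity correction fired.
    """

    measure: str
    y: float
    se: float
    corrected: bool


@dataclass(frozen=True)
class TestSpec:
    """Which association method to use and under what alternative/null.

    Fisher's exact test and the chi-squared test are inherently two-sided;
    requesting a one-sided alternative for them is an error.  ``null_value``
    is on the natural scale (OR/RR null 1, RD null 0) and defaults per method.
    ``yates`` controls the continuity correction of the chi-squared test only.
    """

    __test__ = False  # not a test case, despite the Test* name

    method: str
    alternative: str = "two_sided"
    null_value: float | None = None
    yates: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.alternative not in ("two_sided", "one_sided"):
            raise ValueError(f"alternative must be two_sided or one_sided, got {self.alternative!r}")
        if self.method in ("fisher", "chisq") and self.alternative != "two_sided":
            raise ValueError(f"{self.method} is two-sided only")
        if self.null_value is None:
            object.__setattr__(self, "null_value", 0.0 if self.method == "RD" else 1.0)

    @property
    def null_on_scale(self) -> float:
        """Null value on the analysis scale (log for OR/RR)."""
        if self.method in ("OR", "RR"):
            if self.null_value <= 0:
                raise ValueError("null OR/RR must be positive")
            return math.log(self.null_value)
        return float(self.null_value)


def apply_modification(table: TwoByTwoTable, mod: Modification) -> TwoByTwoTable:
    """Return the table with ``mod`` applied; sample sizes never change."""
    for k, (e, n, f) in enumerate(
        [(table.e0, table.n0, mod.f0), (table.e1, table.n1, mod.f1)]
    ):
        if not (-e <= f <= n - e):
            raise ValueError(
                f"modification f{k}={f} out of range [{-e}, {n - e}] for group {k}"
            )
    return replace(table, e0=table.e0 + mod.f0, e1=table.e1 + mod.f1)


def continuity_correct(
    table: TwoByTwoTable, incr: float = 0.5
) -> tuple[float, float, float, float]:
    """Cells with the 0.5-type correction applied when any cell is zero.

    Returns (e0, n0-e0, e1, n1-e1) as floats; if no cell is zero the counts
    are returned unchanged.  The correction applies only to effect-size
    estimation (OR/RR/RD), never to the exact or chi-squared tests.
    """
    if incr <= 0:
        raise ValueError("incr must be positive")
    cells = table.cells
    if min(cells) == 0:
        return tuple(c + incr for c in cells)
    return tuple(float(c) for c in cells)


#: Relative slack when comparing hypergeometric masses, as in R's fisher.test.
_FISHER_REL_TOL = 1.0 + 1e-7


def _fisher_two_sided(e0: np.ndarray, e1: np.ndarray, n0: int, n1: int) -> np.ndarray:
    """Two-sided exact conditional p for many tables sharing (n0, n1).

    Conditions on both margins and sums the hypergeometric probabilities of
    all tables whose probability is <= that of the observed one (with a tiny
    relative slack against floating-point ties, the fisher.test convention).
    Tables sharing a column margin share one support, so cells are grouped by
    total event count for speed.
    """
    e0 = np.asarray(e0, dtype=int)
    e1 = np.asarray(e1, dtype=int)
    out = np.empty(e0.shape, dtype=float)
    totals = e0 + e1
    for t in np.unique(totals):
        idx = totals == t
        if t == 0 or t == n0 + n1:
            out[idx] = 1.0
            continue
        lo = max(0, t - n1)
        hi = min(t, n0)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, n0 + n1, t, n0)
        obs = pmf[e0[idx] - lo]
        mask = pmf[None, :] <= obs[:, None] * _FISHER_REL_TOL
        out[idx] = np.minimum((pmf[None, :] * mask).sum(axis=1), 1.0)
    return out


def fisher_p(table: TwoByTwoTable) -> float:
    """Two-sided exact conditional p-value (probability-mass rule).

    With margins fixed, sums the hypergeometric probabilities of all tables
    whose probability does not exceed that of the observed table — the
    convention of standard statistical software.
    """
    return float(
        _fisher_two_sided(np.array([table.e0]), np.array([table.e1]), table.n0, table.n1)[0]
    )


def chisq_p(table: TwoByTwoTable, yates: bool = True) -> float:
    """Pearson chi-squared p-value on the 2x2 table (1 df).

    With ``yates`` the continuity-corrected statistic
    ``N * max(0, |ad-bc| - N/2)^2 / (r1 r2 c1 c2)`` is used, matching the
    common default for 2x2 tables.  A zero margin makes the statistic
    undefined; p = 1 is returned with a warning.
    """
    a, b, c, d = table.cells
    n = table.n_total
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        warnings.warn("zero margin: chi-squared statistic undefined, p set to 1",
                      DegenerateTableWarning, stacklevel=2)
        return 1.0
    det = abs(a * d - b * c)
    if yates:
        det = max(0.0, det - n / 2)
    x2 = n * det**2 / (table.n0 * table.n1 * col1 * col2)
    return float(stats.chi2.sf(x2, df=1))


def effect_estimate(
    table: TwoByTwoTable, measure: str, incr: float = 0.5
) -> EffectEstimate:
    """Estimate log OR, log RR, or RD with its large-sample standard error.

    Zero cells are handled by adding ``incr`` to all four cells first, which
    keeps both the estimate and its SE finite.
    """
    if measure not in WALD_MEASURES:
        raise ValueError(f"measure must be one of {WALD_MEASURES}, got {measure!r}")
    e0, ne0, e1, ne1 = continuity_correct(table, incr)
    corrected = table.has_zero_cell()
    n0, n1 = e0 + ne0, e1 + ne1
    if measure == "OR":
        y = math.log((e1 / ne1) / (e0 / ne0))
        se = math.sqrt(1 / e0 + 1 / ne0 + 1 / e1 + 1 / ne1)
    elif measure == "RR":
        y = math.log((e1 / n1) / (e0 / n0))
        se = math.sqrt(1 / e0 + 1 / e1 - 1 / n0 - 1 / n1)
    else:  # RD
        y = e1 / n1 - e0 / n0
        se = math.sqrt(e0 * ne0 / n0**3 + e1 * ne1 / n1**3)
    return EffectEstimate(measure=measure, y=y, se=se, corrected=corrected)


def wald_p(est: EffectEstimate, spec: TestSpec) -> float:
    """Normal-approximation p-value for an effect estimate against its null.

    Two-sided: ``2 * Phi(-|y - null| / s)``; one-sided is exactly half of
    that (the favourable tail, independent of the sign of the deviation).
    """
    if est.se <= 0:
        raise ValueError("standard error must be positive")
    z = abs(est.y - spec.null_on_scale) / est.se
    p = 2.0 * stats.norm.cdf(-z)
    if spec.alternative == "one_sided":
        p /= 2.0
    return float(p)


def p_value(table: TwoByTwoTable, spec: TestSpec, incr: float = 0.5) -> float:
    """Dispatch to the requested association method."""
    if spec.method == "fisher":
        return fisher_p(table)
    if spec.method == "chisq":
        return chisq_p(table, yates=spec.yates)
    return wald_p(effect_estimate(table, spec.method, incr=incr), spec)


def p_values_batch(
    table: TwoByTwoTable,
    spec: TestSpec,
    f0: np.ndarray,
    f1: np.ndarray,
    incr: float = 0.5,
) -> np.ndarray:
    """p-values of ``table`` under many modifications at once.

    ``f0`` and ``f1`` are equal-length arrays of legal event-count changes;
    element ``i`` yields the p-value of the table modified by
    ``(f0[i], f1[i])``.  This is the single code path behind both the
    exhaustive significance landscape and the shell search, so the two agree
    bit for bit.  Zero margins give p = 1 (without a warning here: landscapes
    legitimately sweep through degenerate corners).
    """
    f0 = np.asarray(f0, dtype=int)
    f1 = np.asarray(f1, dtype=int)
    e0 = table.e0 + f0
    e1 = table.e1 + f1
    if e0.min(initial=0) < 0 or (e0 - table.n0).max(initial=0) > 0:
        raise ValueError("modification out of range for group 0")
    if e1.min(initial=0) < 0 or (e1 - table.n1).max(initial=0) > 0:
        raise ValueError("modification out of range for group 1")
    n0, n1 = table.n0, table.n1

    if spec.method == "fisher":
        return _fisher_two_sided(e0, e1, n0, n1)

    if spec.method == "chisq":
        a, b, c, d = e0, n0 - e0, e1, n1 - e1
        n = n0 + n1
        col1, col2 = a + c, b + d
        det = np.abs(a * d - b * c).astype(float)
        if spec.yates:
            det = np.maximum(0.0, det - n / 2)
        denom = float(n0) * n1 * col1 * col2
        with np.errstate(divide="ignore", invalid="ignore"):
            x2 = np.where(denom > 0, n * det**2 / np.where(denom > 0, denom, 1.0), 0.0)
        p = stats.chi2.sf(x2, df=1)
        return np.where((col1 == 0) | (col2 == 0), 1.0, p)

    # Wald measures: per-table continuity correction where any cell is zero.
    a = e0.astype(float)
    b = (n0 - e0).astype(float)
    c = e1.astype(float)
    d = (n1 - e1).astype(float)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a, b, c, d = (x + np.where(zero, incr, 0.0) for x in (a, b, c, d))
    m0, m1 = a + b, c + d
    if spec.method == "OR":
        y = np.log((c / d) / (a / b))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    elif spec.method == "RR":
        y = np.log((c / m1) / (a / m0))
        se = np.sqrt(1 / a + 1 / c - 1 / m0 - 1 / m1)
    else:  # RD
        y = c / m1 - a / m0
        se = np.sqrt(a * b / m0**3 + c * d / m1**3)
    p = 2.0 * stats.norm.cdf(-np.abs(y - spec.null_on_scale) / se)
    if spec.alternative == "one_sided":
        p = p / 2.0
    return p
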