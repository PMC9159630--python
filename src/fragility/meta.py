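"""Inverse-variance pairwise meta-analysis.

Per-study effects (log OR / log RR / RD with large-sample SEs, continuity
correction per study where a zero cell occurs) are pooled under the usual
two-level normal model y_i ~ N(theta_i, s_i^2), theta_i ~ N(theta, tau^2).
The between-study variance can be estimated by DerSimonian-Laird moments or
REML (or forced to 0 for a common-effect fit), and the confidence interval
for the pooled effect uses either the normal quantile or the
Hartung-Knapp-Sidik-Jonkman t-based construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import TwoByTwoTable, effect_estimate

__all__ = [
    "MADataset",
    "MAFit",
    "study_effects",
    "tau2_dl",
    "tau2_reml",
    "pool",
    "ma_fit",
]

TAU2_METHODS = ("DL", "REML", "fixed")
CI_METHODS = ("z", "hksj")


@dataclass(frozen=True)
class MADataset:
    """An ordered collection of two-arm studies forming one meta-analysis."""

    studies: tuple[TwoByTwoTable, ...]
    ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        studies = tuple(self.studies)
        object.__setattr__(self, "studies", studies)
        if not studies:
            raise ValueError("a meta-analysis needs at least one study")
        ids = tuple(self.ids) if self.ids else tuple(range(1, len(studies) + 1))
        if len(ids) != len(studies) or len(set(ids)) != len(ids):
            raise ValueError("study ids must be unique and match the study count")
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.studies)

    @property
    def n_total(self) -> int:
        return sum(t.n_total for t in self.studies)

    def with_event_change(self, index: int, group: int, delta: int) -> "MADataset":
        """Copy with one event count changed by ``delta`` in one study/group."""
        t = self.studies[index]
        if group == 0:
            new = TwoByTwoTable(t.e0 + delta, t.n0, t.e1, t.n1)
        else:
            new = TwoByTwoTable(t.e0, t.n0, t.e1 + delta, t.n1)
        studies = list(self.studies)
        studies[index] = new
        return MADataset(studies=tuple(studies), ids=self.ids)


@dataclass(frozen=True)
class MAFit:
    """Pooled effect with its CI, weights, and heterogeneity estimate."""

    measure: str
    tau2: float
    tau2_method: str
    ci_method: str
    alpha: float
    theta_hat: float
    se_pooled: float
    ci_low: float
    ci_high: float
    weights: np.ndarray
    y: np.ndarray
    s: np.ndarray
    null_on_scale: float = 0.0

    @property
    def significant(self) -> bool:
        """CI excludes the null (boundary contact counts as covering)."""
        return self.ci_low > self.null_on_scale or self.ci_high < self.null_on_scale


def study_effects(
    dataset: MADataset, measure: str = "OR", incr: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-study effect estimates and SEs; correction fires study by study."""
    ests = [effect_estimate(t, measure, incr=incr) for t in dataset.studies]
    return np.array([e.y for e in ests]), np.array([e.se for e in ests])


def tau2_dl(y: np.ndarray, s: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator of tau^2, truncated at 0."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n = y.size
    if n <= 1:
        return 0.0
    w = 1.0 / s**2
    theta_fe = (w * y).sum() / w.sum()
    q = (w * (y - theta_fe) ** 2).sum()
    denom = w.sum() - (w**2).sum() / w.sum()
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (n - 1)) / denom))


def tau2_reml(
    y: np.ndarray, s: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> float:
    """REML estimator of tau^2 via the standard fixed-point iteration.

    Falls back to DerSimonian-Laird (with a warning) if the iteration does
    not converge within ``max_iter`` steps.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.size < 2:
        raise ValueError("REML needs at least two studies")
    tau2 = tau2_dl(y, s)
    for _ in range(max_iter):
        w = 1.0 / (s**2 + tau2)
        theta = (w * y).sum() / w.sum()
        num = (w**2 * ((y - theta) ** 2 - s**2)).sum()
        new = num / (w**2).sum() + 1.0 / w.sum()
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    warnings.warn("REML did not converge; falling back to DerSimonian-Laird",
                  stacklevel=2)
    return tau2_dl(y, s)


def pool(
    y: np.ndarray,
    s: np.ndarray,
    tau2: float,
    alpha: float = 0.05,
    ci_method: str = "z",
    measure: str = "OR",
    tau2_method: str = "DL",
    null_on_scale: float = 0.0,
) -> MAFit:
    """Inverse-variance pooled estimate with a z or HKSJ confidence interval.

    Weights are ``w_i = 1 / (s_i^2 + tau2)``.  The HKSJ interval uses the
    t quantile with N-1 degrees of freedom and the weighted residual scale,
    exactly as printed (no truncation variant): it collapses to zero width
    when all study effects coincide.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    n = y.size
    if ci_method not in CI_METHODS:
        raise ValueError(f"ci_method must be one of {CI_METHODS}")
    if ci_method == "hksj" and n < 2:
        raise ValueError("HKSJ needs at least two studies")
    w = 1.0 / (s**2 + tau2)
    theta = float((w * y).sum() / w.sum())
    se_z = float(w.sum() ** -0.5)
    if ci_method == "z":
        half = stats.norm.ppf(1 - alpha / 2) * se_z
        se_used = se_z
    else:
        scale = float(np.sqrt((w * (y - theta) ** 2).sum() / ((n - 1) * w.sum())))
        half = stats.t.ppf(1 - alpha / 2, df=n - 1) * scale
        se_used = scale
    return MAFit(
        measure=measure, tau2=float(tau2), tau2_method=tau2_method,
        ci_method=ci_method, alpha=alpha, theta_hat=theta, se_pooled=se_used,
        ci_low=theta - half, ci_high=theta + half, weights=w, y=y, s=s,
        null_on_scale=null_on_scale,
    )


def ma_fit(
    dataset: MADataset,
    measure: str = "OR",
    tau2_method: str = "DL",
    ci_method: str = "z",
    alpha: float = 0.05,
    incr: float = 0.5,
    null_value: float | None = None,
) -> MAFit:
    """Full pipeline: per-study effects -> tau^2 -> pooled effect and CI."""
    if tau2_method not in TAU2_METHODS:
        raise ValueError(f"tau2_method must be one of {TAU2_METHODS}")
    y, s = study_effects(dataset, measure, incr=incr)
    if tau2_method == "fixed" or len(dataset) == 1:
        tau2 = 0.0
    elif tau2_method == "DL":
        tau2 = tau2_dl(y, s)
    else:
        tau2 = tau2_reml(y, s)
    if null_value is None:
        null_value = 0.0 if measure == "RD" else 1.0
    null_on_scale = float(np.log(null_value)) if measure in ("OR", "RR") else float(null_value)
    return pool(y, s, tau2, alpha=alpha, ci_method=ci_method, measure=measure,
                tau2_method=tau2_method, null_on_scale=null_on_scale)
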