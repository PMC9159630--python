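"""Visualizations of fragility results.

Five plot families: the p-value landscape over all event-status
modifications of a trial; the one-group p-value profile; the FI (or FQ)
versus significance level step plot; the event-count trajectory of the
greedy (N)MA algorithm; and bar plots / histograms of fragility measures
across many datasets.  Red marks significant results and green
non-significant ones throughout (a colour-vision-safe alternative is
available); colour opacity scales linearly with -log10 p up to a
truncation exponent.  All functions are pure readers of result objects
and return a matplotlib Figure.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # render off-screen; figures are saved, not shown
import matplotlib.pyplot as plt
import numpy as np

from .ma import MAFragilityResult
from .nma_frag import PairFragility
from .study import StudyBatchResult, StudyFragilityResult, StudySweepResult

__all__ = [
    "PlotStyle",
    "plot_p_grid",
    "plot_p_line",
    "plot_fi_alpha",
    "plot_trajectory",
    "plot_distribution",
]


@dataclass(frozen=True)
class PlotStyle:
    """Colour and marker conventions shared by all plots.

    ``trun`` is the truncation exponent: p-values below ``10**-trun`` are
    drawn at full opacity and flagged with a plus marker in profiles.
    ``colorblind`` swaps the red/green pair for a vermillion/blue pair.
    """

    sig_color: str = "red"
    nonsig_color: str = "green"
    trun: float = 10.0
    marker_original: str = "s"
    marker_minimal: str = "^"
    marker_truncated: str = "+"
    point_size: float = 12.0
    colorblind: bool = False

    @property
    def colors(self) -> tuple[str, str]:
        if self.colorblind:
            return "#D55E00", "#0072B2"
        return self.sig_color, self.nonsig_color

    def opacity(self, p: np.ndarray, alpha: float) -> np.ndarray:
        """Linear in -log10 p from p = alpha (faint) to the truncation (full).

        Non-significant p (>= alpha) are mapped on their own ramp from
        p = 1 (faint) to p = alpha (full).
        """
        p = np.clip(np.asarray(p, dtype=float), 10.0 ** -self.trun, 1.0)
        lp = -np.log10(p)
        la = -np.log10(alpha)
        out = np.empty_like(lp)
        sig = lp > la
        out[sig] = np.clip((lp[sig] - la) / max(self.trun - la, 1e-12), 0.0, 1.0)
        out[~sig] = np.clip(1.0 - lp[~sig] / max(la, 1e-12), 0.0, 1.0)
        return 0.15 + 0.85 * out


def plot_p_grid(
    result: StudyFragilityResult, style: PlotStyle = PlotStyle(), ax=None
):
    """Significance landscape: one point per modification, coloured by p.

    Dashed lines mark no modification per group, crossing at the original
    p (square); triangles mark every minimal modification that flips
    significance.
    """
    if result.p_grid is None:
        raise ValueError("landscape plot needs a result from fi_exhaustive (p_grid)")
    grid = result.p_grid
    fig, ax = _fig_ax(ax)
    sig_c, non_c = style.colors
    F0, F1 = np.meshgrid(grid.f0_values, grid.f1_values, indexing="ij")
    p = grid.p
    colors = np.where(p < result.alpha, sig_c, non_c).ravel()
    ax.scatter(F0.ravel(), F1.ravel(), s=style.point_size, c=colors,
               alpha=style.opacity(p.ravel(), result.alpha), linewidths=0)
    ax.axvline(0, ls="--", c="k", lw=0.8)
    ax.axhline(0, ls="--", c="k", lw=0.8)
    ax.scatter([0], [0], marker=style.marker_original, s=60, facecolors="none",
               edgecolors="k", zorder=5, label="original")
    if result.minimal_mods:
        ax.scatter([m.f0 for m in result.minimal_mods],
                   [m.f1 for m in result.minimal_mods],
                   marker=style.marker_minimal, s=60, facecolors="none",
                   edgecolors="k", zorder=5, label="minimal flip")
    _p_legend(ax, style, result.alpha)
    ax.set_xlabel("event status modification, group 0")
    ax.set_ylabel("event status modification, group 1")
    fi_txt = "NA" if result.fi is None else str(result.fi)
    ax.set_title(f"{result.spec.method}: FI = {fi_txt}, {result.direction.replace('_', ' ')}")
    return fig


def plot_p_line(
    result: StudyFragilityResult, group: int = 0, style: PlotStyle = PlotStyle(), ax=None
):
    """-log10 p against modifications in one group only."""
    if result.p_grid is None:
        raise ValueError("profile plot needs a result from fi_exhaustive (p_grid)")
    if group not in (0, 1):
        raise ValueError("group must be 0 or 1")
    grid = result.p_grid
    if group == 0:
        j = int(np.where(grid.f1_values == 0)[0][0])
        fs, p = grid.f0_values, grid.p[:, j]
    else:
        i = int(np.where(grid.f0_values == 0)[0][0])
        fs, p = grid.f1_values, grid.p[i, :]
    fig, ax = _fig_ax(ax)
    sig_c, non_c = style.colors
    floor = 10.0 ** -style.trun
    truncated = p < floor
    lp = -np.log10(np.clip(p, floor, 1.0))
    la = -np.log10(result.alpha)
    ax.axhspan(la, max(style.trun, lp.max() + 0.5), color=sig_c, alpha=0.08)
    ax.axhspan(0, la, color=non_c, alpha=0.08)
    colors = np.where(p < result.alpha, sig_c, non_c)
    ok = ~truncated
    ax.scatter(fs[ok], lp[ok], c=colors[ok], s=style.point_size)
    if truncated.any():
        ax.scatter(fs[truncated], np.full(truncated.sum(), style.trun),
                   marker=style.marker_truncated, c="k", s=30, label="p truncated")
    ax.axvline(0, ls="--", c="k", lw=0.8)
    i0 = int(np.where(fs == 0)[0][0])
    ax.scatter([0], [lp[i0]], marker=style.marker_original, s=60,
               facecolors="none", edgecolors="k", zorder=5, label="original")
    # minimal restricted flip in this group
    restricted = result.fi0 if group == 0 else result.fi1
    if restricted is not None:
        sizes = np.abs(fs)
        flips = (p >= result.alpha) if result.p0 < result.alpha else (p < result.alpha)
        hit = flips & (sizes == restricted)
        ax.scatter(fs[hit], lp[hit], marker=style.marker_minimal, s=60,
                   facecolors="none", edgecolors="k", zorder=5, label="minimal flip")
    ax.axhline(la, ls=":", c="k", lw=0.8)
    ax.set_xlabel(f"event status modification, group {group}")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.legend(loc="best", fontsize=8)
    return fig


def plot_fi_alpha(
    sweep: StudySweepResult,
    fragility: str = "FI",
    style: PlotStyle = PlotStyle(),
    mark_p0: bool = True,
    log_x: bool = False,
    ax=None,
):
    """Step plot of FI (or FQ) against the significance level.

    Points are red where the original result is significant at that level
    (FI measures loss of significance) and green where it is not.
    """
    if fragility not in ("FI", "FQ"):
        raise ValueError("fragility must be 'FI' or 'FQ'")
    fig, ax = _fig_ax(ax)
    sig_c, non_c = style.colors
    vals = sweep.fis.copy()
    if fragility == "FQ":
        vals = 100.0 * vals / sweep.table.n_total
    colors = [sig_c if d == "sig_to_nonsig" else non_c for d in sweep.directions]
    ax.step(sweep.levels, vals, where="post", c="0.6", lw=0.8)
    ax.scatter(sweep.levels, vals, c=colors, s=style.point_size, zorder=3)
    if mark_p0 and sweep.levels.min() <= sweep.p0 <= sweep.levels.max():
        ax.axvline(sweep.p0, ls="--", c="k", lw=0.8)
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel("significance level")
    ax.set_ylabel("fragility index" if fragility == "FI" else "fragility quotient (%)")
    return fig


def plot_trajectory(
    result: MAFragilityResult | PairFragility,
    ybreaks: tuple[float, float] | None = None,
    style: PlotStyle = PlotStyle(),
    study_marker: bool = True,
):
    """Group-total event counts along the greedy iterations.

    One line per group; labels along the modified group name the studies
    involved, an asterisk meaning the same study as the previous step.
    With ``ybreaks`` the y axis is split into two panels over that range.
    """
    if isinstance(result, PairFragility):
        steps = result.trajectory
        labels = ("group " + str(result.tid2), "group " + str(result.tid1))
        groups = [st.tid for st in steps]
        key_low, key_high = result.tid2, result.tid1
        base = result.final_dataset  # totals reconstructed backwards below
        tot_high = sum(a.e for a in base.arms if a.tid == key_high)
        tot_low = sum(a.e for a in base.arms if a.tid == key_low)
        # walk backwards to the original totals
        for st in reversed(steps):
            if st.tid == key_high:
                tot_high -= st.delta
            else:
                tot_low -= st.delta
        series = {key_low: [tot_low], key_high: [tot_high]}
        for st in steps:
            for k in (key_low, key_high):
                series[k].append(series[k][-1] + (st.delta if st.tid == k else 0))
        lines = [series[key_low], series[key_high]]
        who = [0 if st.tid == key_low else 1 for st in steps]
        step_ids = [st.sid for st in steps]
    else:
        steps = result.trajectory.steps
        labels = ("group 0", "group 1")
        tot0 = sum(t.e0 for t in result.dataset.studies)
        tot1 = sum(t.e1 for t in result.dataset.studies)
        series = {0: [tot0], 1: [tot1]}
        for st in steps:
            for k in (0, 1):
                series[k].append(series[k][-1] + (st.delta if st.group == k else 0))
        lines = [series[0], series[1]]
        who = [st.group for st in steps]
        step_ids = [st.study_id for st in steps]
    if not steps:
        raise ValueError("trajectory is empty (FI undefined); nothing to plot")

    x = np.arange(len(steps) + 1)
    if ybreaks is None:
        fig, ax = plt.subplots()
        axes = [ax, ax]
    else:
        lo, hi = ybreaks
        if not lo < hi:
            raise ValueError("ybreaks must be an increasing (low, high) pair")
        fig, (ax_top, ax_bot) = plt.subplots(
            2, 1, sharex=True, gridspec_kw={"hspace": 0.08})
        ax_top.set_ylim(bottom=hi)
        ax_bot.set_ylim(top=lo)
        ax_top.spines.bottom.set_visible(False)
        ax_bot.spines.top.set_visible(False)
        ax_top.tick_params(labelbottom=False, bottom=False)
        _draw_break_marks(ax_top, ax_bot)
        axes = [ax_bot, ax_top]

    colors = ("tab:blue", "tab:red")
    for line, label, color in zip(lines, labels, colors):
        for ax in set(axes):
            ax.plot(x, line, c=color, label=label, marker=".", ms=4)
    if study_marker:
        prev = None
        for i, (g, sid) in enumerate(zip(who, step_ids)):
            txt = "*" if sid == prev else str(sid)
            prev = sid
            yv = lines[g][i + 1]
            ax = axes[0] if (ybreaks is None or yv <= ybreaks[0]) else axes[1]
            ax.annotate(txt, (x[i + 1], yv), textcoords="offset points",
                        xytext=(0, 6), ha="center", fontsize=8)
    axes[-1].legend(loc="best", fontsize=8)
    axes[0].set_xlabel("iteration")
    fig.supylabel("total event count")
    return fig


def _draw_break_marks(ax_top, ax_bot) -> None:
    kw = dict(marker=[(-1, -0.5), (1, 0.5)], markersize=10, linestyle="none",
              color="k", mec="k", mew=1, clip_on=False)
    ax_top.plot([0, 1], [0, 0], transform=ax_top.transAxes, **kw)
    ax_bot.plot([0, 1], [1, 1], transform=ax_bot.transAxes, **kw)


def plot_distribution(
    batch,
    fragility: str = "FI",
    direction: str = "both",
    max_f: float | None = None,
    breaks: int | None = None,
    style: PlotStyle = PlotStyle(),
    ax=None,
):
    """Distribution of FI (bar plot) or FQ (histogram) across datasets.

    Bars/hatches are split by original significance (red significant,
    green not); values above ``max_f`` are stacked into the rightmost,
    truncation-marked bar.  ``direction`` filters to 'sig2nonsig',
    'nonsig2sig', or keeps 'both'.
    """
    if fragility not in ("FI", "FQ"):
        raise ValueError("fragility must be 'FI' or 'FQ'")
    if direction not in ("both", "sig2nonsig", "nonsig2sig"):
        raise ValueError("direction must be both, sig2nonsig, or nonsig2sig")
    sig_c, non_c = style.colors
    sig_vals, non_vals = [], []
    if isinstance(batch, StudyBatchResult):
        items = [(r.direction == "sig_to_nonsig", r.fi, r.fq)
                 for r in batch.results if r is not None]
    else:  # MA batch
        items = [(r.fit0.significant, r.fi, r.fq)
                 for r in batch.results if r is not None]
    for was_sig, fi, fq_ in items:
        v = fi if fragility == "FI" else fq_
        if v is None:
            continue
        (sig_vals if was_sig else non_vals).append(float(v))
    if direction == "sig2nonsig":
        non_vals = []
    elif direction == "nonsig2sig":
        sig_vals = []
    fig, ax = _fig_ax(ax)
    if fragility == "FI":
        top = max(sig_vals + non_vals, default=1)
        cut = top if max_f is None else min(max_f, top)
        cats = np.arange(1, int(cut) + 1)
        width = 0.4
        for off, vals, color, label in (
            (-width / 2, sig_vals, sig_c, "originally significant"),
            (+width / 2, non_vals, non_c, "originally non-significant"),
        ):
            arr = np.array(vals)
            counts = [(np.sum(arr == c) if c < cut or max_f is None
                       else np.sum(arr >= cut)) for c in cats]
            ax.bar(cats + off, counts, width=width, color=color, label=label)
        labels = [str(c) for c in cats]
        if max_f is not None and top > cut:
            labels[-1] = f">={int(cut)}"
        ax.set_xticks(cats, labels)
        ax.set_xlabel("fragility index")
    else:
        allv = np.array(sig_vals + non_vals)
        if max_f is not None:
            allv = np.minimum(allv, max_f)
            sig_vals = list(np.minimum(sig_vals, max_f)) if sig_vals else []
            non_vals = list(np.minimum(non_vals, max_f)) if non_vals else []
        bins = breaks if breaks is not None else "auto"
        edges = np.histogram_bin_edges(allv, bins=bins)
        ax.hist([sig_vals, non_vals], bins=edges, stacked=True,
                color=[sig_c, non_c],
                label=["originally significant", "originally non-significant"])
        ax.set_xlabel("fragility quotient (%)")
    ax.set_ylabel("count")
    ax.legend(loc="best", fontsize=8)
    return fig


def _fig_ax(ax):
    if ax is None:
        fig, ax = plt.subplots()
    else:
        fig = ax.figure
    return fig, ax


def _p_legend(ax, style: PlotStyle, alpha: float) -> None:
    """Legend swatches relating colour opacity to p magnitude."""
    from matplotlib.lines import Line2D

    sig_c, non_c = style.colors
    handles = []
    for p in (1.0, alpha, alpha / 10, 10.0 ** -style.trun):
        color = sig_c if p < alpha else non_c
        a = float(style.opacity(np.array([p]), alpha)[0])
        lbl = f"p = {p:.3g}" if p > 10.0 ** -style.trun else f"p <= 1e-{style.trun:g}"
        handles.append(Line2D([], [], marker="o", linestyle="none",
                              color=color, alpha=a, label=lbl))
    handles.append(Line2D([], [], marker=style.marker_original, linestyle="none",
                          mfc="none", mec="k", label="original"))
    handles.append(Line2D([], [], marker=style.marker_minimal, linestyle="none",
                          mfc="none", mec="k", label="minimal flip"))
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5),
              fontsize=7, title="p value", title_fontsize=8)
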