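"""Matplotlib figure builders for report bundles.

Conventions: completion heatmaps show completed prompts in blue and
missed ones in grey; time-series panels shade weekends; network plots
draw positive partial correlations as solid blue edges and negative
ones as red dashed edges, with edge width proportional to |omega|.
"""

from __future__ import annotations

import datetime as dt

import matplotlib.dates as mdates
import numpy as np
from matplotlib.colors import ListedColormap
from matplotlib.figure import Figure

from .descriptives import ItemSummary, RelFreqTable
from .networks import ContemporaneousNetwork
from .schedule import CompletionMatrix
from .trend import TrendEstimate

_COMPLETION_CMAP = ListedColormap(["#bdbdbd", "#2166ac"])


def plot_completion_heatmap(matrix: CompletionMatrix) -> Figure:
    fig = Figure(figsize=(8, 2.4))
    ax = fig.subplots()
    ax.imshow(
        matrix.completed.T, aspect="auto", interpolation="nearest",
        cmap=_COMPLETION_CMAP, vmin=0, vmax=1,
    )
    ax.set_yticks(range(len(matrix.slots)), matrix.slots)
    ticks = np.linspace(0, len(matrix.dates) - 1, min(8, len(matrix.dates))).astype(int)
    ax.set_xticks(ticks, [matrix.dates[i].isoformat() for i in ticks], rotation=30)
    ax.set_xlabel("date")
    fig.tight_layout()
    return fig


def plot_item_summaries(summaries: list[ItemSummary],
                        scale: tuple[int, int] = (1, 7)) -> Figure:
    fig = Figure(figsize=(7, 0.6 * max(len(summaries), 2) + 1))
    ax = fig.subplots()
    rng = np.random.default_rng(0)
    for row, s in enumerate(summaries):
        ys = row + rng.uniform(-0.3, 0.3, size=s.n_obs)
        xs = [v for _, v in s.values_with_jitter]
        ax.scatter(xs, ys, s=8, alpha=0.35, color="#4393c3", linewidths=0)
        if s.has_mean:
            ax.plot([s.mean, s.mean], [row - 0.35, row + 0.35], color="black", lw=2)
    ax.set_yticks(range(len(summaries)), [s.variable for s in summaries])
    ax.set_xlim(scale[0] - 0.5, scale[1] + 0.5)
    ax.set_xlabel("score")
    fig.tight_layout()
    return fig


def plot_frequencies(table: RelFreqTable) -> Figure:
    cats = list(table.frequencies)
    vals = [table.frequencies[c] for c in cats]
    fig = Figure(figsize=(6, 3))
    ax = fig.subplots()
    ax.bar(range(len(cats)), vals, color="#4393c3")
    ax.set_xticks(range(len(cats)), cats, rotation=30, ha="right")
    ax.set_ylabel("relative frequency")
    ax.set_title(table.variable)
    fig.tight_layout()
    return fig


def _shade_weekends(ax, start: dt.date, end: dt.date) -> None:
    day = start
    while day <= end:
        if day.weekday() >= 5:
            ax.axvspan(day, day + dt.timedelta(days=1), color="0.85", zorder=0)
        day += dt.timedelta(days=1)


def plot_time_series(
    times: list, values: list[float], trend: TrendEstimate | None,
    variable: str, scale: tuple[int, int] = (1, 7),
) -> Figure:
    """Raw points plus trendline (when not gated out), weekends shaded."""
    fig = Figure(figsize=(8, 2.8))
    ax = fig.subplots()
    tnum = mdates.date2num(times)
    if len(times):
        _shade_weekends(ax, min(times).date(), max(times).date())
    ax.scatter(tnum, values, s=10, alpha=0.5, color="#4393c3", linewidths=0)
    if trend is not None and not trend.gated_out:
        ax.plot(trend.grid, trend.fitted, color="#b2182b", lw=2)
    ax.set_ylim(scale[0] - 0.5, scale[1] + 0.5)
    ax.set_ylabel(variable)
    ax.xaxis.set_major_formatter(mdates.DateFormatter("%Y-%m-%d"))
    fig.autofmt_xdate(rotation=30)
    fig.tight_layout()
    return fig


def plot_network(net: ContemporaneousNetwork) -> Figure:
    """Circular-layout partial-correlation network."""
    p = len(net.variables)
    angles = 2 * np.pi * np.arange(p) / p
    xy = np.c_[np.cos(angles), np.sin(angles)]
    fig = Figure(figsize=(4.5, 4.5))
    ax = fig.subplots()
    for a, b, w in net.edges():
        i, j = net.variables.index(a), net.variables.index(b)
        style = "-" if w > 0 else "--"
        color = "#2166ac" if w > 0 else "#b2182b"
        ax.plot(
            [xy[i, 0], xy[j, 0]], [xy[i, 1], xy[j, 1]],
            style, color=color, lw=0.5 + 6.0 * abs(w), zorder=1,
        )
    ax.scatter(xy[:, 0], xy[:, 1], s=900, color="#f7f7f7",
               edgecolors="black", zorder=2)
    for k, name in enumerate(net.variables):
        ax.text(xy[k, 0], xy[k, 1], name, ha="center", va="center",
                fontsize=7, zorder=3)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{net.mode} network")
    fig.tight_layout()
    return fig
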