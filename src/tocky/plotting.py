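"""Visualization surfaces: QC locus scatter, angle density, locus dynamics.

Plots are views, never sources: every number printed on a plot also exists
in a CSV-able table produced by :mod:`tocky.locus` / :mod:`tocky.stats`.
The locus colour palette is fixed and keyed by label so that the same locus
has the same colour in every figure.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from tocky.locus import LocusScheme, LocusTable, assign_locus, locus_table  # noqa: E402
from tocky.preprocess import TransformedSample  # noqa: E402
from tocky.stats import GroupComparisonResult  # noqa: E402

logger = logging.getLogger(__name__)

#: stable palette keyed by locus label (k=5 names first, generic C1..C5 after)
LOCUS_COLORS = {
    "New": "#1f77b4",
    "NP-t": "#17becf",
    "Persistent": "#2ca02c",
    "PA-t": "#ff7f0e",
    "Arrested": "#d62728",
    "C1": "#17becf",
    "C2": "#2ca02c",
    "C3": "#ff7f0e",
    "C4": "#9467bd",
    "C5": "#8c564b",
    "negative": "#bbbbbb",
}

__all__ = ["plot_timer_qc", "plot_angle_density", "plot_locus_dynamics", "LOCUS_COLORS"]


def _locus_color(label: str) -> str:
    return LOCUS_COLORS.get(label, "#333333")


def plot_timer_qc(
    samples: Iterable[TransformedSample],
    scheme: LocusScheme | None = None,
    denominator: str = "parent",
    max_points: int = 20000,
    seed: int = 0,
):
    """Per-sample normalized Blue-vs-Red scatter coloured by locus.

    Timer-negative cells are grey; per-locus percentages (from
    :func:`tocky.locus.locus_table`, the single source of truth) are
    annotated in the legend.  Returns one matplotlib Figure per sample.
    """
    scheme = scheme or LocusScheme()
    figures = {}
    rng = np.random.default_rng(seed)
    for ts in samples:
        fig, ax = plt.subplots(figsize=(5, 5))
        if ts.n_events == 0:
            ax.text(0.5, 0.5, f"{ts.sample_id}: no events", ha="center", va="center")
            logger.warning("QC plot: sample %r empty", ts.sample_id)
            figures[ts.sample_id] = fig
            continue
        data = ts.data
        if len(data) > max_points:
            data = data.iloc[rng.choice(len(data), max_points, replace=False)]
        table = locus_table(ts, scheme, denominator=denominator)
        neg = data[~data["timer_positive"]]
        ax.scatter(neg["b_norm"], neg["r_norm"], s=2, c=LOCUS_COLORS["negative"],
                   label=f"negative ({100 - table.percents.sum():.1f}%)"
                   if denominator == "parent" else "negative")
        pos = data[data["timer_positive"]]
        if len(pos):
            labels = assign_locus(pos["angle"].to_numpy(), scheme)
            for locus in scheme.labels:
                sel = pos[labels == locus]
                ax.scatter(sel["b_norm"], sel["r_norm"], s=2, c=_locus_color(locus),
                           label=f"{locus} ({table.percents[locus]:.1f}%)")
        else:
            for locus in scheme.labels:
                ax.scatter([], [], s=2, c=_locus_color(locus),
                           label=f"{locus} ({table.percents[locus]:.1f}%)")
        ax.set_xlabel("normalized Timer Blue")
        ax.set_ylabel("normalized Timer Red")
        ax.set_title(ts.sample_id)
        ax.legend(markerscale=4, fontsize=7, loc="upper right")
        figures[ts.sample_id] = fig
    return figures


def plot_angle_density(
    samples: Iterable[TransformedSample],
    by_group: bool = True,
    bandwidth: float | None = None,
):
    """Kernel density of Timer Angle over [0, 90] per group (or per sample).

    Samples with no Timer-positive cells are skipped with a log entry.
    Returns (Figure, bandwidth used).
    """
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.0, 90.0, 361)
    pooled: dict[str, list[np.ndarray]] = {}
    for ts in samples:
        angles = ts.angles()
        if angles.size == 0:
            logger.info("angle density: skipping all-negative sample %r", ts.sample_id)
            continue
        key = ts.group_id if by_group else ts.sample_id
        pooled.setdefault(key, []).append(angles)
    bw_used = None
    for key, chunks in pooled.items():
        angles = np.concatenate(chunks)
        if np.ptp(angles) == 0:  # point mass: kde undefined, draw a spike
            ax.axvline(angles[0], label=key)
            continue
        kde = gaussian_kde(angles, bw_method=bandwidth)
        bw_used = float(kde.factor)
        ax.plot(grid, kde(grid), label=key)
    ax.set_xlim(0.0, 90.0)
    ax.set_xlabel("Timer Angle (degrees)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return fig, bw_used


def plot_locus_dynamics(
    summary: pd.DataFrame,
    comparisons: GroupComparisonResult | None = None,
):
    """Mean +/- SD locus percentages per group, with significance asterisks.

    ``summary`` comes from :func:`tocky.locus.locus_dynamics`; if a
    locus-wise comparison result is supplied, loci with adjusted p < alpha
    get an asterisk above the larger group mean.  Loci must match between
    the two inputs.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    loci = list(summary["locus"].cat.categories
                if hasattr(summary["locus"], "cat") else summary["locus"].unique())
    xs = np.arange(len(loci))
    tops = np.zeros(len(loci))
    for group, sub in summary.groupby("group", sort=False):
        sub = sub.set_index("locus").reindex(loci)
        ax.errorbar(xs, sub["mean_percent"], yerr=sub["sd_percent"],
                    marker="o", capsize=3, label=str(group))
        tops = np.maximum(tops, (sub["mean_percent"] + sub["sd_percent"]).to_numpy())
    if comparisons is not None:
        comp = comparisons.table.set_index("locus")
        missing = [l for l in loci if l not in comp.index]
        if missing:
            raise ValueError(f"comparison result lacks loci {missing}")
        for i, locus in enumerate(loci):
            if bool(comp.loc[locus, "significant"]):
                ax.annotate("*", (xs[i], tops[i]), ha="center", fontsize=14,
                            xytext=(0, 4), textcoords="offset points")
    ax.set_xticks(xs, loci)
    ax.set_ylabel("% of cells")
    ax.legend(fontsize=8)
    return fig
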