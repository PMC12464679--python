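"""Tocky Locus categorization: biologically anchored binning of Timer Angle.

The angle axis [0, 90] degrees is partitioned into k loci (k in 3..7,
default 5).  The two anchors are singleton angles: the first locus is
exactly 0 deg (New: blue-only, freshly initiated transcription) and the
last exactly 90 deg (Arrested: red-only, transcription long ceased).  The
open interval (0, 90) between them is divided into k - 2 equal-width bins,
each open at its left edge and closed at its right edge, except that 90 deg
itself always belongs to Arrested.

For k = 5 the interior bins carry their biological names:
NP-t (0, 30], Persistent (30, 60], PA-t (60, 90).  For other k they are
labelled C1..C(k-2).  k = 3 is equivalent to classical quadrant analysis
(Blue+Red-, double-positive, Blue-Red+).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from tocky.preprocess import TransformedSample

FIVE_LOCUS_LABELS = ("New", "NP-t", "Persistent", "PA-t", "Arrested")

Denominator = Literal["parent", "timer"]

__all__ = [
    "LocusScheme",
    "LocusTable",
    "assign_locus",
    "locus_table",
    "locus_dynamics",
    "percent_matrix",
    "FIVE_LOCUS_LABELS",
]


@dataclass(frozen=True)
class LocusScheme:
    """A k-locus partition of the Timer Angle axis."""

    k: int = 5
    epsilon: float = 0.0  # tolerance for the 0/90 anchor comparison

    def __post_init__(self) -> None:
        if not 3 <= self.k <= 7:
            raise ValueError(f"k must be in [3, 7], got {self.k}")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.k == 5:
            return FIVE_LOCUS_LABELS
        interior = tuple(f"C{i}" for i in range(1, self.k - 1))
        return ("New",) + interior + ("Arrested",)

    @property
    def interior_edges(self) -> np.ndarray:
        """Edges of the k-2 equal-width interior bins, including 0 and 90."""
        return np.linspace(0.0, 90.0, self.k - 1)


def assign_locus(angle, scheme: LocusScheme):
    """Assign each angle (degrees in [0, 90]) to exactly one locus label.

    Anchors first: angle <= epsilon -> New, angle >= 90 - epsilon -> Arrested
    (default epsilon 0: exact comparison).  Interior angles fall into
    left-open right-closed equal-width bins.
    """
    arr = np.atleast_1d(np.asarray(angle, dtype=float))
    if np.any(np.isnan(arr)):
        raise ValueError("angle is NaN (Timer-negative cells have no locus)")
    if np.any((arr < 0) | (arr > 90)):
        raise ValueError("angles must lie in [0, 90] degrees")
    edges = scheme.interior_edges
    # (edges[i-1], edges[i]] -> interior label index i; anchors override below
    idx = np.searchsorted(edges, arr, side="left")
    idx = np.clip(idx, 1, scheme.k - 2)
    idx[arr <= scheme.epsilon] = 0
    idx[arr >= 90.0 - scheme.epsilon] = scheme.k - 1
    labels = np.asarray(scheme.labels, dtype=object)[idx]
    if np.asarray(angle).ndim == 0:
        return str(labels[0])
    return labels


@dataclass
class LocusTable:
    """Per-sample locus counts and percentages under a stated denominator."""

    sample_id: str
    group_id: str
    denominator: Denominator
    counts: pd.Series  # indexed by locus label, sums to n_timer
    n_parent: int
    n_timer: int
    scheme: LocusScheme = field(default_factory=LocusScheme)
    no_timer_cells: bool = False

    @property
    def percents(self) -> pd.Series:
        denom = self.n_parent if self.denominator == "parent" else self.n_timer
        if denom == 0:
            return pd.Series(0.0, index=self.counts.index, name="percent")
        return 100.0 * self.counts / denom

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "group": self.group_id,
                "locus": self.counts.index,
                "count": self.counts.to_numpy(),
                "percent": self.percents.to_numpy(),
                "denominator": self.denominator,
                "n_parent": self.n_parent,
                "n_timer": self.n_timer,
            }
        )


def locus_table(
    ts: TransformedSample,
    scheme: LocusScheme | None = None,
    denominator: Denominator = "parent",
) -> LocusTable:
    """Count Timer-positive cells per locus for one sample.

    Zero-count loci are retained (reported as 0, never dropped), so that
    downstream statistics see sparse bins explicitly.  With no
    Timer-positive cells, percents are 0 and ``no_timer_cells`` is set.
    """
    scheme = scheme or LocusScheme()
    if denominator not in ("parent", "timer"):
        raise ValueError(f"denominator must be 'parent' or 'timer', got {denominator!r}")
    angles = ts.angles()
    if angles.size:
        labels = assign_locus(angles, scheme)
        counts = pd.Series(labels).value_counts()
    else:
        counts = pd.Series(dtype=int)
    counts = counts.reindex(scheme.labels, fill_value=0).astype(int)
    counts.index.name = "locus"
    return LocusTable(
        sample_id=ts.sample_id,
        group_id=ts.group_id,
        denominator=denominator,
        counts=counts,
        n_parent=ts.n_events,
        n_timer=int(angles.size),
        scheme=scheme,
        no_timer_cells=angles.size == 0,
    )


def locus_dynamics(tables: Iterable[LocusTable]) -> pd.DataFrame:
    """Mean and sample SD of locus percentages per (group, locus).

    Groups with a single sample report SD 0 with ``n_samples`` = 1 so the
    caller can see the flag.  Locus order follows the scheme.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no locus tables supplied")
    scheme = tables[0].scheme
    long = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    summary = (
        long.groupby(["group", "locus"], sort=False)["percent"]
        .agg(mean_percent="mean", sd_percent=lambda v: v.std(ddof=1), n_samples="count")
        .reset_index()
    )
    summary["sd_percent"] = summary["sd_percent"].fillna(0.0)
    summary["locus"] = pd.Categorical(summary["locus"], categories=scheme.labels, ordered=True)
    return summary.sort_values(["group", "locus"]).reset_index(drop=True)


def percent_matrix(tables: Sequence[LocusTable], group_id: str | None = None) -> pd.DataFrame:
    """Samples x loci matrix of percentages, optionally restricted to a group."""
    rows = [t for t in tables if group_id is None or t.group_id == group_id]
    if not rows:
        raise ValueError(f"no locus tables for group {group_id!r}")
    scheme = rows[0].scheme
    return pd.DataFrame(
        {t.sample_id: t.percents for t in rows}, index=list(scheme.labels)
    ).T
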