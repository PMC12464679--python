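"""Spike-in power analysis of Tocky Locus binning schemes.

Hybrid samples are built by mixing a *background* angle pool with a known
fraction of cells from a distinct *spike-in* pool, then binned with k loci
(k = 3..7) and compared against pure-background samples: a global
chi-square on the pooled 2 x k counts, and locus-wise Mann-Whitney tests
across replicate samples.  Averaging -log10(p) over replicates maps
detection sensitivity across the number of loci, the spike fraction, and
the total cell number.

Under the null (spike pool == background pool) p is uniform and the mean
of -log10(p) is 1/ln(10) ~ 0.4343, which serves as the calibration floor.

The default pools are synthetic stand-ins emulating the qualitative
separation of real Tocky conditions: the background is a high-angle
population (transcription arrested after stimulus withdrawal) and the
spike a mid-angle population (cells under persistent stimulation).  Both
carry the same mass at exactly 90 deg and differ only inside (0, 90), so
the 3-locus (quadrant-equivalent) scheme is nearly blind to the spike
while k >= 4 resolves it — the locus-count sensitivity jump.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from tocky.locus import LocusScheme, assign_locus
from tocky.stats import UntestableError, chisq_global, wilcoxon_locuswise

logger = logging.getLogger(__name__)

#: chi-square expected-count rule of thumb for sparse-bin flagging
MIN_EXPECTED_COUNT = 5.0

__all__ = [
    "SpikeinConfig",
    "PowerGrid",
    "make_hybrid_sample",
    "power_scan",
    "locus_count_penalty_curve",
    "default_background_pool",
    "default_spike_pool",
]


def default_background_pool(n: int = 20000, seed: int | None = 0,
                            arrested_fraction: float = 0.15) -> np.ndarray:
    """High-angle background pool (post-withdrawal-like), in degrees."""
    rng = np.random.default_rng(seed)
    n_arr = int(round(arrested_fraction * n))
    interior = sps.truncnorm.rvs(
        (0.0 - 72.0) / 10.0, (90.0 - 72.0) / 10.0, loc=72.0, scale=10.0,
        size=n - n_arr, random_state=rng,
    )
    # keep interior angles strictly inside (0, 90)
    interior = np.clip(interior, 1e-6, 90.0 - 1e-6)
    return np.concatenate([interior, np.full(n_arr, 90.0)])


def default_spike_pool(n: int = 20000, seed: int | None = 1,
                       arrested_fraction: float = 0.15) -> np.ndarray:
    """Mid-angle spike-in pool (persistent-stimulation-like), in degrees."""
    rng = np.random.default_rng(seed)
    n_arr = int(round(arrested_fraction * n))
    interior = sps.truncnorm.rvs(
        (0.0 - 40.0) / 10.0, (90.0 - 40.0) / 10.0, loc=40.0, scale=10.0,
        size=n - n_arr, random_state=rng,
    )
    interior = np.clip(interior, 1e-6, 90.0 - 1e-6)
    return np.concatenate([interior, np.full(n_arr, 90.0)])


@dataclass
class SpikeinConfig:
    """Scan configuration.

    ``n_rep_samples`` is the number of replicate samples per side entering
    each locus-wise Mann-Whitney comparison; ``reps`` is the number of
    independent replicates over which -log10(p) is averaged.
    """

    background_pool: np.ndarray
    spike_pool: np.ndarray
    k_values: Sequence[int] = (3, 4, 5, 6, 7)
    fractions: Sequence[float] = (0.0, 0.05, 0.1, 0.2)
    n_totals: Sequence[int] = (10000,)
    reps: int = 50
    n_rep_samples: int = 6
    seed: int = 0
    metrics: Sequence[str] = ("chisq", "wilcoxon")

    def __post_init__(self) -> None:
        self.background_pool = np.asarray(self.background_pool, dtype=float)
        self.spike_pool = np.asarray(self.spike_pool, dtype=float)
        if self.background_pool.size == 0 or self.spike_pool.size == 0:
            raise ValueError("angle pools must be non-empty")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if any(not 3 <= k <= 7 for k in self.k_values):
            raise ValueError("k_values must lie in [3, 7]")


@dataclass
class PowerGrid:
    """Long-format sensitivity grid.

    Columns: ``k, fraction, n_total, locus`` ("global" for the chi-square),
    ``metric`` (``mean_neglog10_p_chisq`` / ``mean_neglog10_adjp_wilcoxon``),
    ``value``, ``reps``, ``sparse_bins`` (expected-count flag), ``seed``.
    Missing (untestable) conditions are recorded with value NaN.
    """

    table: pd.DataFrame
    config: SpikeinConfig

    def slice(self, metric: str | None = None, k: int | None = None) -> pd.DataFrame:
        t = self.table
        if metric is not None:
            t = t[t["metric"] == metric]
        if k is not None:
            t = t[t["k"] == k]
        return t.reset_index(drop=True)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def make_hybrid_sample(
    background_pool,
    spike_pool,
    fraction: float,
    n_total: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """One hybrid angle sample: round(fraction * n_total) spike draws (with
    replacement, round-half-away-from-zero) plus background for the rest."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    bg = np.asarray(background_pool, dtype=float)
    sp = np.asarray(spike_pool, dtype=float)
    if bg.size == 0 or sp.size == 0:
        raise ValueError("angle pools must be non-empty")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_spike = min(_round_half_away(fraction * n_total), n_total)
    draws = [sp[rng.integers(0, sp.size, n_spike)],
             bg[rng.integers(0, bg.size, n_total - n_spike)]]
    return np.concatenate(draws)


def _pool_locus_codes(pool: np.ndarray, scheme: LocusScheme) -> np.ndarray:
    labels = assign_locus(pool, scheme)
    lut = {lab: i for i, lab in enumerate(scheme.labels)}
    return np.asarray([lut[l] for l in labels], dtype=np.int64)


def _sample_counts(codes: np.ndarray, n: int, k: int, rng) -> np.ndarray:
    return np.bincount(codes[rng.integers(0, codes.size, n)], minlength=k)


def power_scan(cfg: SpikeinConfig) -> PowerGrid:
    """Run the full sensitivity scan over (k, fraction, n_total).

    Per replicate and condition, one hybrid and one equal-sized pure
    background sample are drawn, binned, and compared with the global
    chi-square; locus-wise Mann-Whitney comparisons use
    ``cfg.n_rep_samples`` replicate samples per side with BH adjustment
    across loci.  -log10(p) is averaged over ``cfg.reps`` replicates;
    everything is seeded from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    for k in cfg.k_values:
        scheme = LocusScheme(k=k)
        bg_codes = _pool_locus_codes(cfg.background_pool, scheme)
        sp_codes = _pool_locus_codes(cfg.spike_pool, scheme)
        for fraction in cfg.fractions:
            for n_total in cfg.n_totals:
                n_spike = min(_round_half_away(fraction * n_total), n_total)
                chisq_logs, wil_logs, sparse = [], [], False
                for _ in range(cfg.reps):
                    if "chisq" in cfg.metrics:
                        hyb = np.bincount(
                            np.concatenate([
                                sp_codes[rng.integers(0, sp_codes.size, n_spike)],
                                bg_codes[rng.integers(0, bg_codes.size, n_total - n_spike)],
                            ]), minlength=k)
                        bg = _sample_counts(bg_codes, n_total, k, rng)
                        expected_ok = _expected_counts_ok(hyb, bg)
                        sparse = sparse or not expected_ok
                        try:
                            res = chisq_global(hyb, bg, labels=scheme.labels)
                            chisq_logs.append(-np.log10(max(res.table["p"].iloc[0], 1e-300)))
                        except UntestableError:
                            pass
                    if "wilcoxon" in cfg.metrics:
                        wil_logs.append(_wilcoxon_rep(
                            bg_codes, sp_codes, n_spike, n_total, k, scheme, cfg, rng))
                if "chisq" in cfg.metrics:
                    rows.append(dict(
                        k=k, fraction=fraction, n_total=n_total, locus="global",
                        metric="mean_neglog10_p_chisq",
                        value=float(np.mean(chisq_logs)) if chisq_logs else np.nan,
                        reps=len(chisq_logs), sparse_bins=sparse, seed=cfg.seed,
                    ))
                if "wilcoxon" in cfg.metrics:
                    per_locus = pd.concat(wil_logs, axis=1)
                    for locus in scheme.labels:
                        vals = per_locus.loc[locus].dropna()
                        rows.append(dict(
                            k=k, fraction=fraction, n_total=n_total, locus=locus,
                            metric="mean_neglog10_adjp_wilcoxon",
                            value=float(vals.mean()) if len(vals) else np.nan,
                            reps=int(len(vals)), sparse_bins=sparse, seed=cfg.seed,
                        ))
    return PowerGrid(table=pd.DataFrame(rows), config=cfg)


def _expected_counts_ok(a: np.ndarray, b: np.ndarray) -> bool:
    tot = a + b
    keep = tot > 0
    if keep.sum() < 2:
        return False
    grand = a.sum() + b.sum()
    expected = np.outer([a.sum(), b.sum()], tot[keep]) / grand
    return bool((expected >= MIN_EXPECTED_COUNT).all())


def _wilcoxon_rep(bg_codes, sp_codes, n_spike, n_total, k, scheme, cfg, rng):
    """One locus-wise replicate: n_rep_samples hybrid vs background samples."""
    def percents(counts):
        return 100.0 * counts / n_total

    hybrid = pd.DataFrame(
        [percents(np.bincount(np.concatenate([
            sp_codes[rng.integers(0, sp_codes.size, n_spike)],
            bg_codes[rng.integers(0, bg_codes.size, n_total - n_spike)],
        ]), minlength=k)) for _ in range(cfg.n_rep_samples)],
        columns=list(scheme.labels),
    )
    background = pd.DataFrame(
        [percents(_sample_counts(bg_codes, n_total, k, rng))
         for _ in range(cfg.n_rep_samples)],
        columns=list(scheme.labels),
    )
    res = wilcoxon_locuswise(hybrid, background, adjust="BH")
    adj = res.table.set_index("locus")["p_adjusted"]
    return -np.log10(adj.clip(lower=1e-300))


def locus_count_penalty_curve(grid: PowerGrid) -> pd.DataFrame:
    """Mean -log10(p) of the global chi-square vs total cell number, per k.

    Requires a grid scanned over >= 2 ``n_totals``; the ``sparse_bins``
    column flags conditions where some chi-square expected count fell below
    5 (the classical reliability rule for sparse contingency tables).
    """
    t = grid.slice(metric="mean_neglog10_p_chisq")
    if t["n_total"].nunique() < 2:
        raise ValueError("need a scan over >= 2 n_total values")
    return (
        t[["k", "fraction", "n_total", "value", "reps", "sparse_bins"]]
        .sort_values(["k", "fraction", "n_total"])
        .reset_index(drop=True)
    )
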