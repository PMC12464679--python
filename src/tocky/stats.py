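"""Group comparison of Tocky Locus occupancies.

Three complementary routes are provided:

* a global chi-square test of independence on the pooled 2 x k count table
  (does the overall locus distribution differ between groups?),
* locus-wise two-sided Mann-Whitney (Wilcoxon rank-sum) tests on per-sample
  percentages, exact for small groups without ties,
* locus-wise Welch t-tests on variance-stabilized percentages (arcsine
  square root or logit transform), gated by a Shapiro-Wilk normality check
  on group-mean-centred residuals; loci failing the gate fall back to
  Mann-Whitney with a recorded flag.

All locus-wise p-values are adjusted across the k loci
(Benjamini-Hochberg by default; Holm and Bonferroni available) and flagged
significant at adjusted p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: exact Mann-Whitney enumeration is used up to this per-group size (no ties)
EXACT_MW_MAX_N = 8

_ADJUST_METHODS = {"BH": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}

__all__ = [
    "GroupComparisonResult",
    "chisq_global",
    "wilcoxon_locuswise",
    "parametric_locuswise",
    "asr_transform",
    "logit_transform",
    "adjust_pvalues",
]


class UntestableError(ValueError):
    """The comparison cannot be carried out on the given tables."""


@dataclass
class GroupComparisonResult:
    """Outcome of one group comparison.

    ``table`` has one row per locus (or a single ``global`` row for the
    chi-square) with columns ``locus, method, statistic, p, p_adjusted,
    significant, note``.
    """

    method: str
    table: pd.DataFrame
    adjust: str = "BH"
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.method} comparison (adjust={self.adjust}, alpha={self.alpha})"]
        lines.append(self.table.to_string(index=False))
        return "\n".join(lines)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default), Holm, or Bonferroni."""
    if method not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}; use one of {sorted(_ADJUST_METHODS)}")
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method=_ADJUST_METHODS[method])[1]


def asr_transform(percent):
    """Arcsine-square-root transform of a percentage: arcsin(sqrt(p/100))."""
    arr = np.asarray(percent, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percent must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return out if arr.ndim else float(out)


def logit_transform(percent, c: float = 0.001):
    """Shifted logit of a percentage: ln((p + c) / (100 - p + c)), c > 0."""
    if c <= 0:
        raise ValueError("shift constant c must be > 0")
    arr = np.asarray(percent, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percent must lie in [0, 100]")
    out = np.log((arr + c) / (100.0 - arr + c))
    return out if arr.ndim else float(out)


def chisq_global(counts_a, counts_b, labels=None) -> GroupComparisonResult:
    """Pearson chi-square of independence on the 2 x k pooled count table.

    Cells are pooled within each group; loci with zero total in both groups
    are dropped (and logged) before testing, so df = k' - 1 for k' retained
    loci.  No continuity correction is applied.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if labels is None:
        labels = [f"locus{i}" for i in range(a.size)]
    keep = (a + b) > 0
    dropped = [str(l) for l, k in zip(labels, keep) if not k]
    if dropped:
        logger.info("chi-square: dropping empty loci %s", dropped)
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise UntestableError("fewer than 2 non-empty loci; chi-square untestable")
    if a.sum() == 0 or b.sum() == 0:
        raise UntestableError("one group has no cells; chi-square untestable")
    if np.array_equal(a, b):
        stat, p, dof = 0.0, 1.0, a.size - 1
    else:
        stat, p, dof, _ = sps.chi2_contingency(np.vstack([a, b]), correction=False)
    table = pd.DataFrame(
        {
            "locus": ["global"],
            "method": ["chisq"],
            "statistic": [float(stat)],
            "p": [float(p)],
            "p_adjusted": [float(p)],
            "significant": [p < ALPHA],
            "note": [f"df={dof}" + (f"; dropped={dropped}" if dropped else "")],
        }
    )
    return GroupComparisonResult(
        method="chisq", table=table, extra={"df": int(dof), "dropped_loci": dropped}
    )


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U; exact for small untied groups, else normal
    approximation with continuity and tie correction."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0, "all values identical"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "normal approximation"


def _as_locus_frame(group) -> pd.DataFrame:
    """Coerce a samples x loci percent matrix (DataFrame or mapping)."""
    if isinstance(group, pd.DataFrame):
        return group
    # ragged mappings allowed: loci may have unequal sample counts
    return pd.DataFrame({k: pd.Series(np.asarray(v, dtype=float))
                         for k, v in dict(group).items()})


def _finalize_locuswise(
    rows: list[dict], method: str, adjust: str, alpha: float
) -> GroupComparisonResult:
    table = pd.DataFrame(rows)
    testable = table["p"].notna()
    adjusted = np.full(len(table), np.nan)
    if testable.any():
        adjusted[testable.to_numpy()] = adjust_pvalues(
            table.loc[testable, "p"].to_numpy(), method=adjust
        )
    table["p_adjusted"] = adjusted
    table["significant"] = (table["p_adjusted"] < alpha).fillna(False)
    return GroupComparisonResult(method=method, table=table, adjust=adjust, alpha=alpha)


def wilcoxon_locuswise(
    group_a, group_b, adjust: str = "BH", alpha: float = ALPHA
) -> GroupComparisonResult:
    """Locus-wise two-sided Mann-Whitney tests on per-sample percentages.

    ``group_a`` / ``group_b``: samples x loci percent matrices (DataFrame,
    e.g. from :func:`tocky.locus.percent_matrix`, or a mapping of locus ->
    values).  Loci with fewer than 2 samples in either group are flagged
    untestable and excluded from the adjustment.
    """
    a, b = _as_locus_frame(group_a), _as_locus_frame(group_b)
    if list(a.columns) != list(b.columns):
        raise ValueError("groups must share the same locus columns in the same order")
    rows = []
    for locus in a.columns:
        x = a[locus].dropna().to_numpy(dtype=float)
        y = b[locus].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            rows.append(
                dict(locus=locus, method="wilcoxon", statistic=np.nan, p=np.nan,
                     note="untestable: <2 samples in a group")
            )
            continue
        stat, p, note = _mannwhitney(x, y)
        rows.append(dict(locus=locus, method="wilcoxon", statistic=stat, p=p, note=note))
    return _finalize_locuswise(rows, "wilcoxon", adjust, alpha)


def parametric_locuswise(
    group_a,
    group_b,
    transform: str = "asr",
    adjust: str = "BH",
    c: float = 0.001,
    alpha: float = ALPHA,
    normality_alpha: float = 0.05,
) -> GroupComparisonResult:
    """Transform-gated Welch t-tests on per-sample locus percentages.

    Percentages are variance-stabilized (``asr`` or ``logit``), then per
    locus a Shapiro-Wilk test on the pooled group-mean-centred residuals
    gates the parametric path: if normality is not rejected
    (p > ``normality_alpha``) a Welch two-sample t-test is run, otherwise
    the locus falls back to Mann-Whitney with a recorded flag.
    """
    if transform == "asr":
        f = asr_transform
    elif transform == "logit":
        f = lambda v: logit_transform(v, c=c)  # noqa: E731
    else:
        raise ValueError(f"transform must be 'asr' or 'logit', got {transform!r}")
    a, b = _as_locus_frame(group_a), _as_locus_frame(group_b)
    if list(a.columns) != list(b.columns):
        raise ValueError("groups must share the same locus columns in the same order")
    rows = []
    for locus in a.columns:
        x = np.asarray(f(a[locus].dropna().to_numpy(dtype=float)))
        y = np.asarray(f(b[locus].dropna().to_numpy(dtype=float)))
        if len(x) < 3 or len(y) < 3:
            rows.append(
                dict(locus=locus, method="t_" + transform, statistic=np.nan, p=np.nan,
                     shapiro_p=np.nan, note="untestable: <3 samples in a group")
            )
            continue
        residuals = np.concatenate([x - x.mean(), y - y.mean()])
        if np.allclose(residuals, 0):
            shapiro_p = 1.0  # no within-group spread; nothing to reject
        else:
            shapiro_p = float(sps.shapiro(residuals).pvalue)
        if shapiro_p > normality_alpha:
            if np.allclose(np.concatenate([x, y]), np.concatenate([x, y])[0]):
                stat, p = 0.0, 1.0
            else:
                res = sps.ttest_ind(x, y, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
                if math.isnan(stat):  # zero variance in both groups, equal means
                    stat, p = 0.0, 1.0
            rows.append(
                dict(locus=locus, method="t_" + transform, statistic=stat, p=p,
                     shapiro_p=shapiro_p, note="welch t")
            )
        else:
            stat, p, note = _mannwhitney(
                a[locus].dropna().to_numpy(float), b[locus].dropna().to_numpy(float)
            )
            rows.append(
                dict(locus=locus, method="t_" + transform, statistic=stat, p=p,
                     shapiro_p=shapiro_p, note=f"normality rejected; fallback wilcoxon ({note})")
            )
    return _finalize_locuswise(rows, "t_" + transform, adjust, alpha)
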