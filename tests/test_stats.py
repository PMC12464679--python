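"""Statistics: chi-square, Mann-Whitney, transforms, adjustment — vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tocky.stats import (UntestableError, adjust_pvalues, asr_transform,
                         chisq_global, logit_transform, parametric_locuswise,
                         wilcoxon_locuswise)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pearson_chisq_oracle(table: np.ndarray) -> float:
    """Direct Pearson formula, no continuity correction."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def mannwhitney_exact_oracle(x, y) -> float:
    """Two-sided exact p by enumeration of all rank assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"

    def u_stat(xs):
        return sum(sum(1 for yy in pooled if yy not in xs and yy < xx) for xx in xs)

    observed = u_stat(x)
    n = len(x)
    us = [u_stat(c) for c in itertools.combinations(pooled, n)]
    lo = min(observed, len(x) * len(y) - observed)
    return sum(1 for u in us if min(u, len(x) * len(y) - u) <= lo) / len(us)


def bh_oracle(p):
    """Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        i = m - rank_from_end
        running = min(running, p[idx] * m / i)
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------


class TestChisqGlobal:
    def test_five_locus_df_is_four(self):
        res = chisq_global([50, 60, 70, 80, 90], [90, 80, 70, 60, 50])
        assert res.extra["df"] == 4

    def test_identical_tables_statistic_zero(self):
        res = chisq_global([10, 20, 30], [10, 20, 30])
        assert res.table["statistic"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == 1.0

    def test_hand_computed_two_by_two(self):
        res = chisq_global([20, 0], [0, 20])
        assert res.table["statistic"].iloc[0] == pytest.approx(40.0)

    def test_matches_pearson_oracle_on_random_tables(self, rng):
        for _ in range(100):
            k = rng.integers(2, 8)
            a = rng.integers(1, 50, size=k)
            b = rng.integers(1, 50, size=k)
            res = chisq_global(a, b)
            assert res.table["statistic"].iloc[0] == pytest.approx(
                pearson_chisq_oracle(np.vstack([a, b])), abs=1e-9)

    def test_group_order_invariance(self, rng):
        a, b = rng.integers(1, 100, 5), rng.integers(1, 100, 5)
        s1 = chisq_global(a, b).table["statistic"].iloc[0]
        s2 = chisq_global(b, a).table["statistic"].iloc[0]
        assert s1 == pytest.approx(s2)

    def test_empty_loci_dropped_with_df_reduction(self):
        res = chisq_global([10, 0, 30, 0, 50], [20, 0, 10, 0, 5],
                           labels=["a", "b", "c", "d", "e"])
        assert res.extra["df"] == 2
        assert res.extra["dropped_loci"] == ["b", "d"]

    def test_fewer_than_two_loci_untestable(self):
        with pytest.raises(UntestableError):
            chisq_global([10, 0], [20, 0])


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        res = wilcoxon_locuswise({"L": [1, 2, 3]}, {"L": [4, 5, 6]})
        row = res.table.iloc[0]
        assert row["statistic"] == 0.0
        assert row["p"] == pytest.approx(0.1)
        assert row["p"] == pytest.approx(mannwhitney_exact_oracle([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_p_one(self):
        res = wilcoxon_locuswise({"L": [5, 6, 7]}, {"L": [5, 6, 7]})
        assert res.table["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_all_identical_values_p_one(self):
        res = wilcoxon_locuswise({"L": [3, 3, 3]}, {"L": [3, 3, 3]})
        assert res.table["p"].iloc[0] == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            x = rng.permutation(100)[:4].astype(float)
            y = rng.permutation(100)[90:95].astype(float)
            if len(set(x) | set(y)) < 9:
                continue
            res = wilcoxon_locuswise({"L": x}, {"L": y})
            assert res.table["p"].iloc[0] == pytest.approx(
                mannwhitney_exact_oracle(x, y), abs=1e-12)

    def test_normal_approx_close_to_exact_small_n(self, rng):
        """Asymptotic path agrees with exact enumeration within 0.02 at n <= 5."""
        from tocky.stats import _mannwhitney
        for _ in range(20):
            x = rng.choice(1000, 5, replace=False).astype(float)
            y = rng.choice(np.arange(1000, 2000), 5, replace=False).astype(float)
            y[0] = float(rng.integers(0, 1000))  # mix ranks a bit
            if len(set(x) | set(y)) < 10:
                continue
            exact = mannwhitney_exact_oracle(x, y)
            import scipy.stats as sps
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(approx - exact) < 0.02

    def test_untestable_locus_flagged_not_adjusted(self):
        res = wilcoxon_locuswise({"A": [1, 2, 3], "B": [1.0]},
                                 {"A": [4, 5, 6], "B": [2.0]})
        tb = res.table.set_index("locus")
        assert np.isnan(tb.loc["B", "p"])
        assert "untestable" in tb.loc["B", "note"]
        assert not tb.loc["B", "significant"]
        # adjustment ran over the single testable locus only
        assert tb.loc["A", "p_adjusted"] == pytest.approx(tb.loc["A", "p"])


class TestTransforms:
    @pytest.mark.parametrize("pct,expected", [(0, 0.0), (100, np.pi / 2), (50, np.pi / 4)])
    def test_asr_known_values(self, pct, expected):
        assert asr_transform(pct) == pytest.approx(expected)

    def test_asr_domain(self):
        with pytest.raises(ValueError):
            asr_transform(101)

    def test_logit_known_values(self):
        assert logit_transform(50, 0.001) == 0.0
        assert logit_transform(0, 0.001) == pytest.approx(np.log(0.001 / 100.001))

    def test_logit_antisymmetry(self, rng):
        p = rng.uniform(0, 100, 200)
        np.testing.assert_allclose(logit_transform(p, 0.001),
                                   -logit_transform(100 - p, 0.001), atol=1e-10)

    def test_logit_rejects_nonpositive_c(self):
        with pytest.raises(ValueError):
            logit_transform(50, 0.0)

    def test_monotone(self, rng):
        p = np.sort(rng.uniform(0, 100, 100))
        assert np.all(np.diff(asr_transform(p)) >= 0)
        assert np.all(np.diff(logit_transform(p)) >= 0)


class TestAdjustPvalues:
    def test_single_p_unchanged_under_bh(self):
        np.testing.assert_allclose(adjust_pvalues([0.031]), [0.031])

    def test_bonferroni(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.04], "bonferroni"),
                                   [0.02, 0.08])

    def test_bh_step_up_oracle(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), [0.05] * 5)
        np.testing.assert_allclose(adjust_pvalues(p, "BH"), bh_oracle(p))

    def test_bh_matches_oracle_on_random_p(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            np.testing.assert_allclose(adjust_pvalues(p, "BH"), bh_oracle(p),
                                       atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        for method in ("BH", "holm", "bonferroni"):
            p = rng.uniform(0, 1, 20)
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-15)
            assert np.all((adj >= 0) & (adj <= 1))

    def test_empty_list(self):
        assert len(adjust_pvalues([])) == 0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], "tukey")


class TestParametricLocuswise:
    def test_identical_groups_t_zero_p_one(self):
        g = {"L": [10.0, 20.0, 30.0, 40.0]}
        res = parametric_locuswise(g, g, transform="asr")
        row = res.table.iloc[0]
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)
        assert row["note"] == "welch t"

    def test_bimodal_residuals_trigger_fallback(self, rng):
        # heavily bimodal within-group values: Shapiro rejects, MW fallback
        a = {"L": np.r_[rng.normal(1, 0.01, 15), rng.normal(80, 0.01, 15)]}
        b = {"L": np.r_[rng.normal(1, 0.01, 15), rng.normal(80, 0.01, 15)]}
        res = parametric_locuswise(a, b, transform="asr")
        assert "fallback" in res.table["note"].iloc[0]
        assert not np.isnan(res.table["p"].iloc[0])

    def test_small_groups_untestable(self):
        res = parametric_locuswise({"L": [1.0, 2.0]}, {"L": [3.0, 4.0]})
        assert "untestable" in res.table["note"].iloc[0]

    def test_logit_route(self):
        a = {"L": [10.0, 12.0, 14.0, 11.0]}
        b = {"L": [30.0, 32.0, 34.0, 31.0]}
        res = parametric_locuswise(a, b, transform="logit")
        assert res.table["p"].iloc[0] < 0.01

    def test_detects_clear_shift_via_welch(self):
        a = {"L": [10.0, 11.0, 12.0, 13.0]}
        b = {"L": [40.0, 41.0, 42.0, 43.0]}
        res = parametric_locuswise(a, b, transform="asr")
        assert res.table["note"].iloc[0] == "welch t"
        assert res.table["p"].iloc[0] < 0.001
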