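import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxyphen.group_comparisons import (
    adjust_pvalues,
    cohens_d,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    normality_gate,
    prevalence_table,
    spearman_matrix,
)


class TestNormalityGate:
    def test_skewed_lognormal_fails(self, rng):
        res = normality_gate(rng.lognormal(0, 1.2, size=99))
        assert not res.is_normal

    def test_near_linear_sequence_passes_often(self, rng):
        # arithmetic sequence + tiny jitter is indistinguishable from uniform;
        # Shapiro-Wilk should not reject a clean normal sample most of the time
        hits = sum(
            normality_gate(rng.normal(size=50)).is_normal for _ in range(50)
        )
        assert hits >= 45

    def test_constant_flagged_degenerate(self):
        res = normality_gate(np.full(10, 3.0))
        assert res.degenerate and not res.is_normal

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])


class TestKruskalWallis:
    def test_hand_rank_formula_three_groups(self):
        # groups {1,2,3},{4,5,6},{7,8,9}: rank sums 6,15,24 → H = 7.2
        vals = np.arange(1.0, 10.0)
        labels = np.repeat(["a", "b", "c"], 3)
        h, p = kruskal_wallis(vals, labels)
        assert h == pytest.approx(7.2, rel=1e-12)

    def test_all_identical_degenerate(self):
        h, p = kruskal_wallis(np.ones(9), np.repeat(["a", "b", "c"], 3))
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_with_ties(self, rng):
        from scipy import stats

        vals = np.round(rng.normal(size=60), 1)  # induces ties
        labels = rng.choice(["a", "b", "c"], size=60)
        h, p = kruskal_wallis(vals, labels)
        ref = stats.kruskal(*[vals[labels == g] for g in ["a", "b", "c"]])
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_sim = 600
        for _ in range(n_sim):
            vals = rng.normal(size=40)
            labels = np.repeat(["a", "b"], 20)
            _, p = kruskal_wallis(vals, labels)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.array([1.0, np.nan]), np.array(["a", "b"]))


class TestDunn:
    def test_pair_count_four_groups(self, rng):
        vals = rng.normal(size=40)
        labels = np.repeat(list("abcd"), 10)
        assert len(dunn_posthoc(vals, labels)) == 6

    def test_two_groups_z_squared_equals_h(self, rng):
        vals = rng.permutation(np.arange(30.0))  # no ties
        labels = np.repeat(["a", "b"], 15)
        h, _ = kruskal_wallis(vals, labels)
        (pair,) = dunn_posthoc(vals, labels)
        assert pair.z**2 == pytest.approx(h, rel=1e-10)

    def test_tie_corrected_hand_values(self):
        # hand-computed from the tie-corrected formula (frozen oracle)
        vals = [1, 2, 2, 5, 2, 3, 4, 4, 6, 7, 8, 8]
        labels = np.repeat(["a", "b", "c"], 4)
        pairs = {(p.group_a, p.group_b): p for p in dunn_posthoc(vals, labels)}
        assert pairs[("a", "b")].z == pytest.approx(-0.594619, abs=1e-6)
        assert pairs[("a", "c")].z == pytest.approx(-2.675784, abs=1e-6)
        assert pairs[("b", "c")].z == pytest.approx(-2.081166, abs=1e-6)
        assert pairs[("a", "c")].p == pytest.approx(0.007455, abs=1e-6)

    def test_adjusted_never_below_raw(self, rng):
        vals = rng.normal(size=44)
        labels = np.repeat(list("abcd"), 11)
        for pair in dunn_posthoc(vals, labels, adjust="bonferroni"):
            assert pair.p_adjusted >= pair.p - 1e-15


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_bonferroni_triples(self):
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.06, 0.09])

    def test_bh_step_up_hand_values(self):
        # direct step-up definition on (0.01, 0.02, 0.04, 0.80)
        out = adjust_pvalues([0.01, 0.02, 0.04, 0.80], method="bh")
        assert out == pytest.approx([0.04, 0.04, 0.0533333333, 0.80], rel=1e-9)

    def test_bh_not_above_bonferroni_for_smallest(self, rng):
        p = rng.random(8)
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        i = int(np.argmin(p))
        assert bh[i] <= bonf[i] + 1e-15

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_significance_order_preserved(self, ps):
        bh = adjust_pvalues(ps, "bh")
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(bh)[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


class TestSpearman:
    def test_self_and_negation(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "neg": -x, "expx": np.exp(x)})
        rho, p = spearman_matrix(df, ["x", "neg", "expx"])
        assert rho.loc["x", "x"] == 1.0
        assert rho.loc["x", "neg"] == pytest.approx(-1.0)
        assert rho.loc["x", "expx"] == pytest.approx(1.0)  # monotone invariance

    def test_constant_column_flagged_nan(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "c": np.ones(20)})
        rho, _ = spearman_matrix(df, ["x", "c"])
        assert np.isnan(rho.loc["x", "c"])

    def test_pairwise_complete(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.1, 40)
        y[:5] = np.nan
        df = pd.DataFrame({"x": x, "y": y})
        rho, _ = spearman_matrix(df, ["x", "y"])
        assert rho.loc["x", "y"] > 0.9


class TestPrevalence:
    def test_counts_use_geq(self):
        df = pd.DataFrame({"s": [1.0, 4.0, 5.0]})
        out = prevalence_table(df, {"s": 4.0})
        assert out.loc[0, "count"] == 2
        assert out.loc[0, "percent"] == pytest.approx(66.6666666, rel=1e-6)

    def test_empty_table(self):
        out = prevalence_table(pd.DataFrame({"s": []}), {"s": 4.0})
        assert out.loc[0, "count"] == 0

    def test_unknown_subscale(self):
        with pytest.raises(KeyError):
            prevalence_table(pd.DataFrame({"s": [1.0]}), {"t": 4.0})


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_unit_difference_unit_sd(self):
        assert cohens_d([-1, 0, 1], [0, 1, 2]) == pytest.approx(-1.0)

    def test_hand_pooled_sd_value(self):
        a, b = [2.0, 4.0, 6.0], [1.0, 2.0]
        # pooled var = (2·4 + 1·0.5)/3 = 17/6; d = (4 − 1.5)/sqrt(17/6)
        assert cohens_d(a, b) == pytest.approx(2.5 / np.sqrt(17 / 6), rel=1e-12)

    def test_zero_spread_degenerate(self):
        assert np.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


def test_compare_groups_tidy_output(cohort99):
    out = compare_groups(cohort99, ["oxytocin", "leptin"], "phenotype")
    assert set(out["variable"]) == {"oxytocin", "leptin"}
    # 4 phenotype groups → 6 pairs per variable
    assert (out.groupby("variable").size() == 6).all()
    assert {"H", "kw_p", "kw_q", "p_adjusted", "cohens_d"} <= set(out.columns)
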