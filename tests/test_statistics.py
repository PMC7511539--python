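import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from melodylearn.cohort import CohortConfig, simulate_study
from melodylearn.pipeline import summarize_retention, summarize_transfer
from melodylearn.statistics import (
    block_slopes,
    ks_normality,
    rank_mixed_model,
    sample_size_two_groups,
    table1_summary,
    two_sample_t,
    wilcoxon_rank_sum,
)
from melodylearn.fixtures import load_table1


def pooled_t_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestTwoSampleT:
    def test_identical_samples(self):
        r = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0 and r.p_value == 1

    def test_textbook_hand_computation(self):
        r = two_sample_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.674, abs=5e-4)
        assert r.df == 4

    @given(
        st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    )
    def test_matches_closed_form(self, x, y):
        if np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
            return
        r = two_sample_t(x, y)
        assert r.statistic == pytest.approx(pooled_t_by_hand(x, y), rel=1e-9, abs=1e-9)
        assert r.df == len(x) + len(y) - 2

    def test_zero_variance_unequal_means_signals(self):
        with pytest.raises(FloatingPointError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


def rank_sum_p_by_enumeration(x, y):
    """Exact two-sided p by enumerating all assignments of pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mean_w = ranks.sum() * n1 / len(pooled)
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(abs(s - mean_w) >= abs(observed - mean_w) - 1e-9 for s in sums)
    return extreme / len(sums)


class TestWilcoxonRankSum:
    def test_identical_multisets_give_p_1(self):
        r = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_fully_separated_3v3_exact(self):
        r = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert r.statistic == 6.0  # minimal possible rank sum
        assert r.p_value == pytest.approx(rank_sum_p_by_enumeration([1, 2, 3], [10, 11, 12]))
        assert r.p_value == pytest.approx(2 / 20)

    def test_exact_p_matches_enumeration_without_ties(self):
        x, y = [0.3, 2.2, 4.1, 5.0], [1.7, 3.3, 6.4]
        r = wilcoxon_rank_sum(x, y)
        assert r.p_value == pytest.approx(rank_sum_p_by_enumeration(x, y))

    def test_tie_heavy_statistic_uses_midranks(self):
        x, y = [1.0, 1.0, 2.0], [1.0, 2.0, 2.0]
        r = wilcoxon_rank_sum(x, y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        assert r.statistic == ranks[:3].sum()


class TestKsNormality:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(4).normal(size=400)
        r = ks_normality(x)
        assert r.p_value > 0.05 and r.flags == ()

    def test_bimodal_bounded_sample_fails(self):
        x = np.concatenate([np.zeros(15), np.full(15, 100.0)]) + np.random.default_rng(0).normal(0, 1, 30)
        r = ks_normality(x)
        assert r.p_value < 0.05
        assert "rank_based_recommended" in r.flags

    def test_statistic_equals_brute_force_sup(self):
        x = np.random.default_rng(9).normal(3, 2, size=20)
        r = ks_normality(x)
        xs = np.sort(x)
        cdf = sps.norm.cdf(xs, x.mean(), x.std(ddof=1))
        n = len(x)
        d_plus = np.max(np.arange(1, n + 1) / n - cdf)
        d_minus = np.max(cdf - np.arange(0, n) / n)
        assert r.statistic == pytest.approx(max(d_plus, d_minus), abs=1e-10)

    def test_constant_sample_degenerate(self):
        with pytest.raises(ValueError):
            ks_normality([5.0] * 10)


def _cohort_summary(seed=3, n=5):
    df = simulate_study(CohortConfig(seed=seed, n_hiit=n, n_liit=n))
    return summarize_retention(df)


class TestRankMixedModel:
    def test_one_way_equals_rank_transform_anova(self):
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 12)])
        df = pd.DataFrame(
            {"y": y, "g": ["A"] * 10 + ["B"] * 12, "s": [f"S{i}" for i in range(22)]}
        )
        m = rank_mixed_model(df, "y", subject="s", between="g")
        ranks = sps.rankdata(y)
        f_direct = sps.f_oneway(ranks[:10], ranks[10:])
        eff = m.effects[0]
        assert eff.F == pytest.approx(f_direct.statistic)
        assert (eff.df_num, eff.df_den) == (1, 20)
        assert eff.p_value == pytest.approx(f_direct.pvalue)

    def test_rank_idempotence(self):
        data = _cohort_summary()
        m1 = rank_mixed_model(data, "pitch_accuracy", subject="participant",
                              between="group", within="session")
        data2 = data.assign(pitch_accuracy=sps.rankdata(data["pitch_accuracy"]))
        m2 = rank_mixed_model(data2, "pitch_accuracy", subject="participant",
                              between="group", within="session")
        for a, b in zip(m1.effects, m2.effects):
            assert a.F == pytest.approx(b.F)

    def test_invariant_to_monotone_transform(self):
        data = _cohort_summary(seed=8)
        m1 = rank_mixed_model(data, "pitch_accuracy", subject="participant",
                              between="group", within="session")
        data2 = data.assign(pitch_accuracy=np.exp(data["pitch_accuracy"] / 25.0))
        m2 = rank_mixed_model(data2, "pitch_accuracy", subject="participant",
                              between="group", within="session")
        for a, b in zip(m1.effects, m2.effects):
            assert a.F == pytest.approx(b.F)

    def test_study_shaped_dfs_match_containment_scheme(self):
        df = simulate_study(CohortConfig(seed=21))  # 13 + 12 participants
        ret = summarize_retention(df)
        m = rank_mixed_model(ret, "pitch_accuracy", subject="participant",
                             between="group", within="session",
                             covariate="musical_training", reduce_if_ns=False)
        by_name = {e.name: e for e in m.effects}
        assert (by_name["group"].df_num, by_name["group"].df_den) == (1, 22)
        assert (by_name["session"].df_num, by_name["session"].df_den) == (3, 69)
        assert (by_name["group:session"].df_num, by_name["group:session"].df_den) == (3, 69)
        m_red = rank_mixed_model(ret, "pitch_accuracy", subject="participant",
                                 between="group", within="session",
                                 covariate="musical_training", interaction=False)
        assert {e.name: (e.df_num, e.df_den) for e in m_red.effects}["session"] == (3, 72)

    def test_interaction_reduction_rule(self):
        data = _cohort_summary(seed=30)
        m = rank_mixed_model(data, "pitch_accuracy", subject="participant",
                             between="group", within="session")
        if m.interaction_test.p_value > 0.05:
            assert m.interaction_removed
            assert all(e.name != "group:session" for e in m.effects)
        else:
            assert not m.interaction_removed

    def test_reml_engine_agrees_with_anova_route(self):
        data = _cohort_summary(seed=3)
        kw = dict(subject="participant", between="group", within="session",
                  covariate="musical_training", reduce_if_ns=False)
        m1 = rank_mixed_model(data, "pitch_accuracy", engine="anova", **kw)
        m2 = rank_mixed_model(data, "pitch_accuracy", engine="reml", **kw)
        f1 = {e.name: e.F for e in m1.effects}
        f2 = {e.name: e.F for e in m2.effects}
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=0.05, abs=0.05)

    def test_empty_cell_reported(self):
        data = _cohort_summary()
        broken = data[~((data["group"] == "HIIT") & (data["session"] == "R24"))]
        with pytest.raises(ValueError, match="empty design cell"):
            rank_mixed_model(broken, "pitch_accuracy", subject="participant",
                             between="group", within="session")

    def test_contrasts_cover_session_pairs(self):
        data = _cohort_summary(seed=14)
        m = rank_mixed_model(data, "pitch_accuracy", subject="participant",
                             between="group", within="session")
        labels = {c.label for c in m.contrasts}
        assert len(labels) == 6  # all pairs of Acq, R1, R24, R7
        for c in m.contrasts:
            assert 0 <= c.p_value <= 1


class TestBlockSlopes:
    @staticmethod
    def _noiseless(slopes_by_group):
        rows = []
        for g, slope in slopes_by_group.items():
            for s in range(4):
                base = 10.0 * s
                for b in range(1, 7):
                    rows.append({"participant": f"{g}{s}", "group": g, "block": b,
                                 "acc": base + slope * b})
        return pd.DataFrame(rows)

    def test_noiseless_recovery(self):
        df = self._noiseless({"HIIT": 5.0, "LIIT": 5.0})
        s = block_slopes(df, "acc", subject="participant", group="group", block="block")
        assert s["HIIT"] == pytest.approx(5.0)
        assert s["difference"] == pytest.approx(0.0, abs=1e-9)

    def test_flat_data(self):
        df = self._noiseless({"HIIT": 0.0, "LIIT": 0.0})
        s = block_slopes(df, "acc", subject="participant", group="group", block="block")
        assert s["HIIT"] == pytest.approx(0.0, abs=1e-12)

    def test_configured_difference(self):
        df = self._noiseless({"HIIT": 7.9, "LIIT": 5.2})
        s = block_slopes(df, "acc", subject="participant", group="group", block="block")
        assert s["difference"] == pytest.approx(2.7)

    def test_too_few_blocks_rejected(self):
        df = self._noiseless({"HIIT": 1.0})
        with pytest.raises(ValueError):
            block_slopes(df[df.block <= 2], "acc", subject="participant",
                         group="group", block="block")


class TestSampleSize:
    def test_unit_standardized_difference(self):
        assert sample_size_two_groups(1.0, 1.0, power=0.8, alpha=0.05) == 17

    def test_small_effect(self):
        assert sample_size_two_groups(0.2, 1.0, power=0.8, alpha=0.05) == 394

    def test_half_power_large_n_limit(self):
        # at power 0.5 the noncentrality sits at the critical value:
        # n ~ 2 * (z_{alpha/2} * sd / diff)^2
        n = sample_size_two_groups(0.1, 1.0, power=0.5, alpha=0.05)
        approx = 2 * (1.959964 / 0.1) ** 2
        assert n == pytest.approx(approx, rel=0.01)

    def test_zero_effect_signals(self):
        with pytest.raises(OverflowError):
            sample_size_two_groups(0.0, 1.0)

    def test_scaling_in_sd(self):
        assert sample_size_two_groups(5.0, 10.0) == sample_size_two_groups(0.5, 1.0)


class TestTable1Summary:
    def test_age_of_low_group(self):
        t1 = load_table1()
        mean, sd = table1_summary(t1, "age", "Low")
        assert round(mean, 1) == 21.5

    def test_iet_hrmax_high_group(self):
        t1 = load_table1()
        mean, sd = table1_summary(t1, "iet_hrmax", "High")
        assert round(mean, 1) == 178.2
        assert round(sd, 1) == 11.1

    def test_single_row_group_flags_sd(self):
        df = pd.DataFrame({"group": ["A", "B"], "v": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            mean, sd = table1_summary(df, "v", "A")
        assert mean == 1.0 and math.isnan(sd)

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            table1_summary(load_table1(), "nope", "High")
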