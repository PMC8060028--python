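"""Branch gate, post-hoc adjustments, Dunn's test, summaries."""

import numpy as np
import pytest
from scipy import stats as sps

import zfassay as zf
from zfassay.stats import GateResult, StatConfig, dunn_pairwise, holm_adjust


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        assert zf.holm_sidak_adjust([0.03])[0] == pytest.approx(0.03)

    def test_stepdown_formula_oracle(self):
        # direct evaluation: sorted p (.01,.02,.04), m=3
        # adj1 = 1-(1-.01)^3; adj2 = max(adj1, 1-(1-.02)^2); adj3 = max(adj2, .04)
        p = [0.04, 0.01, 0.02]
        expected_sorted = [
            1 - 0.99**3,
            max(1 - 0.99**3, 1 - 0.98**2),
            max(1 - 0.98**2, 0.04),
        ]
        got = zf.holm_sidak_adjust(p)
        assert got[1] == pytest.approx(expected_sorted[0])
        assert got[2] == pytest.approx(expected_sorted[1])
        assert got[0] == pytest.approx(expected_sorted[2])

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(2, 8))
            adj = zf.holm_sidak_adjust(p)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_holm_matches_direct_computation(self):
        p = np.array([0.01, 0.04, 0.03])
        # sorted: .01*3=.03; .03*2=.06; max(.06,.04)=.06
        assert holm_adjust(p) == pytest.approx([0.03, 0.06, 0.06])


class TestNormalityGate:
    def test_nominal_size_under_normality(self, rng):
        # gate requires 3 Shapiro passes and one Brown-Forsythe pass at
        # alpha=0.05; under normality pass rate ~ 0.95**4 = 0.81
        hits = 0
        reps = 300
        for _ in range(reps):
            groups = [rng.normal(0, 1, 50) for _ in range(3)]
            hits += zf.normality_gate(groups).parametric
        assert 0.70 <= hits / reps <= 0.92

    def test_lognormal_routed_to_rank(self, rng):
        fails = 0
        for _ in range(50):
            groups = [rng.lognormal(0, 1, 50) for _ in range(3)]
            fails += not zf.normality_gate(groups).parametric
        assert fails >= 45

    def test_brown_forsythe_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0, 2, 30)
        g1 = zf.normality_gate([a, b])
        g2 = zf.normality_gate([a + 10.0, b - 3.0])
        assert g1.bf_stat == pytest.approx(g2.bf_stat)

    def test_constant_group_fails_gate_without_raising(self):
        gate = zf.normality_gate([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        assert isinstance(gate, GateResult)
        assert not gate.parametric
        assert "constant" in gate.per_group["note"].tolist()


class TestAnovaHolmSidak:
    def test_identical_groups_nothing_significant(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = zf.anova_holm_sidak({"a": g, "b": g})
        assert not res.pairwise["significant"].any()
        assert res.omnibus_p > 0.9

    def test_f_equals_t_squared_on_two_groups(self, rng):
        for _ in range(20):
            a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
            res = zf.anova_holm_sidak({"a": a, "b": b})
            t = res.pairwise["statistic"].iloc[0]
            assert res.omnibus_stat == pytest.approx(t**2)

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            zf.anova_holm_sidak({"only": [1.0, 2.0]})

    def test_pairwise_row_counts(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 8) for i in range(4)}
        assert len(zf.anova_holm_sidak(groups).pairwise) == 6  # 4*3/2
        cfg = StatConfig(control_label="g0", comparisons="control")
        assert len(zf.anova_holm_sidak(groups, cfg=cfg).pairwise) == 3


class TestRankDunn:
    def test_identical_groups_zero_z(self):
        shared = [1.0, 2.0, 3.0]
        res = zf.rank_dunn({"a": shared, "b": shared, "c": [4.0, 5.0, 6.0]})
        row = res.pairwise.set_index(["group_a", "group_b"]).loc[("a", "b")]
        assert row["statistic"] == pytest.approx(0.0)

    def test_tiny_groups_match_bruteforce_ranking(self):
        # groups [1,2],[3,4],[5,6]: pooled ranks 1..6, mean ranks 1.5/3.5/5.5
        res = zf.rank_dunn({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        table = res.pairwise.set_index(["group_a", "group_b"])
        var_term = 6 * 7 / 12.0  # no ties
        z_ab = (1.5 - 3.5) / np.sqrt(var_term * (1 / 2 + 1 / 2))
        z_ac = (1.5 - 5.5) / np.sqrt(var_term * (1 / 2 + 1 / 2))
        assert table.loc[("a", "b"), "statistic"] == pytest.approx(z_ab)
        assert table.loc[("a", "c"), "statistic"] == pytest.approx(z_ac)

    def test_complete_separation_small_groups(self):
        a = np.arange(10.0)
        b = a + 100.0
        res = zf.rank_dunn({"lo": a, "hi": b})
        assert res.omnibus_test == "Wilcoxon rank-sum"
        assert res.omnibus_p < 0.001  # exact enumeration: 2/C(20,10)

    def test_monotone_transform_invariance(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 10) for i in range(3)}
        res1 = zf.rank_dunn(groups)
        res2 = zf.rank_dunn({k: np.exp(v) for k, v in groups.items()})
        assert np.allclose(
            res1.pairwise["statistic"], res2.pairwise["statistic"]
        )
        assert res1.omnibus_stat == pytest.approx(res2.omnibus_stat)

    def test_tie_correction_against_scipy_kruskal(self, rng):
        # Dunn variance uses the same tie term as tie-corrected Kruskal-Wallis;
        # sanity-check z against a direct computation with ties present
        groups = {
            "a": [1.0, 2.0, 2.0, 3.0],
            "b": [2.0, 3.0, 3.0, 4.0],
            "c": [5.0, 5.0, 6.0, 7.0],
        }
        table = dunn_pairwise(
            {k: np.asarray(v) for k, v in groups.items()},
            [("a", "b"), ("a", "c"), ("b", "c")],
        )
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        mr = {"a": ranks[:4].mean(), "b": ranks[4:8].mean(), "c": ranks[8:].mean()}
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts)
        n = pooled.size
        var = n * (n + 1) / 12 - tie / (12 * (n - 1))
        z_ab = (mr["a"] - mr["b"]) / np.sqrt(var * 0.5)
        got = table.set_index(["group_a", "group_b"]).loc[("a", "b"), "statistic"]
        assert got == pytest.approx(z_ab)


class TestSummaries:
    def test_parametric_summary(self):
        s = zf.summarize_groups({"g": [1.0, 2.0, 3.0]}, "parametric").iloc[0]
        assert s["mean"] == 2.0
        assert s["sd"] == pytest.approx(1.0)

    def test_rank_summary_interpolated_quartiles(self):
        s = zf.summarize_groups({"g": [1.0, 2.0, 3.0, 4.0]}, "rank").iloc[0]
        assert s["median"] == 2.5
        assert s["q1"] == pytest.approx(1.75)
        assert s["q3"] == pytest.approx(3.25)

    def test_singleton_group_sd_missing(self):
        s = zf.summarize_groups({"g": [5.0]}, "parametric").iloc[0]
        assert s["mean"] == 5.0
        assert np.isnan(s["sd"])


class TestCompareGroups:
    def test_forced_branch_recorded(self, rng):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
        assert zf.compare_groups(groups, StatConfig(branch="parametric")).branch == "parametric"
        assert zf.compare_groups(groups, StatConfig(branch="rank")).branch == "rank"

    def test_auto_branch_attaches_gate(self, rng):
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20)}
        res = zf.compare_groups(groups)
        assert res.gate is not None
        assert res.branch in ("parametric", "rank")

    def test_strong_effect_detected(self, rng):
        # configured 60% depression, group sizes 10 vs 9
        control = rng.normal(100, 8, 10)
        drug = rng.normal(40, 8, 9)
        res = zf.compare_groups(
            {"control": control, "drug": drug},
            StatConfig(control_label="control", comparisons="control"),
        )
        assert res.pairwise["significant"].all()

    def test_adjusted_never_below_raw(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 8) for i in range(4)}
        res = zf.compare_groups(groups)
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()
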