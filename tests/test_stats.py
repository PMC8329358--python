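"""The mixed ANOVA against independent oracles, and the classical tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from efaa.stats import (holm_adjust, levene_median, mixed_anova, rank_tests,
                        run_full_inference, spearman, welch_t)
from tests.oracles import levene_median_oracle, mixed_anova_oracle, welch_oracle


def _long(y, groups, within_levels):
    """Build a long frame from y[subject, cell] and per-subject groups."""
    rows = []
    for s in range(y.shape[0]):
        for c, levels in enumerate(within_levels):
            rows.append((f"s{s}", groups[s], *levels, y[s, c]))
    wcols = [f"w{i}" for i in range(len(within_levels[0]))]
    return pd.DataFrame(rows, columns=["sub", "grp", *wcols, "y"])


def _random_design(rng, two_within=True):
    a = int(rng.integers(2, 4))
    sizes = rng.integers(3, 8, size=a)
    groups = sum([[f"g{i}"] * n for i, n in enumerate(sizes)], [])
    q = 4 if two_within else 2
    y = rng.normal(0, 1, size=(len(groups), q))
    # add random group offsets and within effects so all strata are active
    for i, g in enumerate(sorted(set(groups))):
        y[np.array(groups) == g] += rng.normal(0, 1)
    y += rng.normal(0, 1, size=q)
    if two_within:
        levels = [("b1", "c1"), ("b1", "c2"), ("b2", "c1"), ("b2", "c2")]
    else:
        levels = [("b1",), ("b2",)]
    return _long(y, groups, levels)


class TestMixedAnova:
    def test_agrees_with_projection_oracle_on_random_designs(self, rng):
        for k in range(100):
            df = _random_design(rng, two_within=bool(k % 2))
            within = ["w0", "w1"] if (k % 2) else ["w0"]
            mine = mixed_anova(df, "y", "sub", "grp", within)
            oracle = mixed_anova_oracle(df, "y", "sub", "grp", within)
            for eff in oracle:
                f_o, p_o = oracle[eff]
                row = mine[eff.replace("w0:w1", "w0:w1")]
                assert row.f == pytest.approx(f_o, rel=1e-8), (k, eff)
                assert row.p == pytest.approx(p_o, rel=1e-6, abs=1e-12)

    def test_balanced_group_effect_with_null_within(self, rng):
        # additive group offset, no within effects: Group F large, within ≈ 0
        groups = ["a"] * 4 + ["b"] * 4
        y = np.zeros((8, 4))
        y[4:] += 1.0
        y += rng.normal(0, 1e-6, size=y.shape)
        df = _long(y, groups, [("b1", "c1"), ("b1", "c2"),
                               ("b2", "c1"), ("b2", "c2")])
        res = mixed_anova(df, "y", "sub", "grp", ["w0", "w1"])
        oracle = mixed_anova_oracle(df, "y", "sub", "grp", ["w0", "w1"])
        assert res["grp"].f == pytest.approx(oracle["grp"][0], rel=1e-10)
        assert res["grp"].p < 1e-6
        # the within-effect signal is exactly zero: its SS is jitter-sized
        assert res["w0"].ss < 1e-9 and res["w1"].ss < 1e-9

    def test_all_identical_responses_degenerate(self):
        groups = ["a"] * 3 + ["b"] * 3
        y = np.full((6, 2), 2.5)
        df = _long(y, groups, [("b1",), ("b2",)])
        res = mixed_anova(df, "y", "sub", "grp", ["w0"])
        assert res["grp"].f == 0.0
        assert res["grp"].note == "degenerate-variance"

    def test_pure_between_effect_ges_one(self):
        # no residual variability anywhere: Group explains everything
        groups = ["a"] * 3 + ["b"] * 3
        y = np.zeros((6, 2))
        y[3:] = 1.0
        df = _long(y, groups, [("b1",), ("b2",)])
        res = mixed_anova(df, "y", "sub", "grp", ["w0"])
        assert res["grp"].ges == pytest.approx(1.0)

    def test_matches_pingouin_where_conventions_coincide(self, rng):
        pg = pytest.importorskip("pingouin")
        # balanced groups: every SS convention coincides
        groups = ["a"] * 6 + ["b"] * 6
        y = rng.normal(0, 1, size=(12, 2))
        y[6:, :] += 0.8
        y[:, 0] += 0.4
        df = _long(y, groups, [("b1",), ("b2",)])
        res = mixed_anova(df, "y", "sub", "grp", ["w0"])
        ref = pg.mixed_anova(data=df, dv="y", within="w0", subject="sub",
                             between="grp")
        ref = ref.set_index("Source")
        assert res["grp"].f == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert res["w0"].f == pytest.approx(ref.loc["w0", "F"], rel=1e-9)
        assert res["grp:w0"].f == pytest.approx(ref.loc["Interaction", "F"],
                                                rel=1e-9)

    def test_ges_invariant_to_affine_rescaling(self, rng):
        df = _random_design(rng)
        res1 = mixed_anova(df, "y", "sub", "grp", ["w0", "w1"])
        df2 = df.assign(y=3.7 * df["y"] - 11.0)
        res2 = mixed_anova(df2, "y", "sub", "grp", ["w0", "w1"])
        for e1, e2 in zip(res1.effects, res2.effects):
            assert e1.ges == pytest.approx(e2.ges, rel=1e-9)

    def test_missing_cell_rejected(self):
        df = _long(np.zeros((4, 2)), ["a", "a", "b", "b"],
                   [("b1",), ("b2",)]).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(df, "y", "sub", "grp", ["w0"])

    def test_singleton_group_rejected(self):
        df = _long(np.zeros((3, 2)), ["a", "a", "b"], [("b1",), ("b2",)])
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova(df, "y", "sub", "grp", ["w0"])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula(self):
        t, df, p = welch_t([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        t_o, df_o = welch_oracle([0, 1, 2], [10, 11, 12])
        assert t == pytest.approx(t_o, abs=1e-12)
        assert df == pytest.approx(df_o, abs=1e-12)
        ref = sps.ttest_ind([0, 1, 2], [10, 11, 12], equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 7)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)


class TestHolm:
    def test_two_values(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.3]), [0.3])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 12)
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_dominance_and_rank_preservation(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestLevene:
    def test_identical_spread_pattern(self):
        w, p = levene_median([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_oracle(self):
        w, _ = levene_median([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert w == pytest.approx(
            levene_median_oracle([1, 2, 3], [10, 20, 30]), rel=1e-12)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 12)
        w1, _ = levene_median(a, b)
        w2, _ = levene_median(a + 100.0, b)
        assert w1 == pytest.approx(w2, rel=1e-9)


class TestRankTests:
    def test_identical_distributions_p_one(self):
        res = rank_tests([np.array([1.0, 2.0, 3.0]),
                          np.array([1.0, 2.0, 3.0])])
        assert res["p"] == pytest.approx(1.0)

    def test_fully_separated_exact_p(self):
        res = rank_tests([np.array([1.0, 2.0, 3.0]),
                          np.array([4.0, 5.0, 6.0])])
        # 2 of the 20 equally likely assignments are this extreme (two-sided)
        assert res["p"] == pytest.approx(0.1)

    def test_kruskal_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = rank_tests([g, g + 0.0, g.copy()])
        assert res["test"] == "kruskal-wallis"
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_tests([np.array([]), np.array([1.0])])


class TestSpearman:
    def test_monotone_gives_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])["rho"] == 1.0

    def test_printed_micro_example(self):
        # Σd² = 4 → ρ = 1 − 6·4/(4·15) = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3])["rho"] == \
            pytest.approx(0.6)

    def test_reversal_negates(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = spearman(x, y)["rho"]
        r2 = spearman(x, -y)["rho"]
        assert r1 == pytest.approx(-r2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestFullInference:
    def _scores(self, seed=3):
        from efaa.synthetic_data import CohortSpec, cohort_scores_frame
        return cohort_scores_frame(CohortSpec(seed=seed))

    def test_report_structure_and_exclusion_accounting(self):
        rep = run_full_inference(self._scores())
        for key in ("faa_two_group", "faa_three_group", "efaa_anova",
                    "efaa_posthoc", "levene_faa", "spearman", "exclusions"):
            assert key in rep
        assert rep["faa_two_group"]["effects"]["group_level"]["df"][0] == 1
        assert len(rep["efaa_posthoc"]) == 3
        assert set(rep["spearman"]) >= {"efaa_vs_bdi", "efaa_vs_rpq",
                                        "efaa_vs_pta_hours"}
        # holm-adjusted post-hocs dominate raw ps
        for row in rep["efaa_posthoc"]:
            assert row["p_holm"] >= row["p"] - 1e-15

    def test_report_is_json_serialisable(self):
        import json
        json.dumps(run_full_inference(self._scores()))

    def test_depression_exclusion_removes_high_bdi(self):
        sc = self._scores()
        rep = run_full_inference(sc)
        excluded = set(rep["exclusions"]["bdi_depression"])
        high = set(sc.loc[sc.bdi >= 10, "subject_id"])
        assert excluded <= high
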