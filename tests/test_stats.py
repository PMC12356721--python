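"""Inference chain: Levene gating, t/d, JZS Bayes factor, Mauchly/GG,
split-plot ANOVA, Bonferroni post-hoc chain."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from erpcompare import stats as S
from erpcompare.stats import SummaryStats


class TestLevene:
    def test_identical_groups_with_spread_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        W, p = S.levene_test(g, g.copy())
        assert W == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_planted_variance_ratio_detected(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(33)
        b = rng.standard_normal(33) * np.sqrt(10.0)
        _, p = S.levene_test(a, b)
        assert p < 0.01

    def test_matches_hand_computed_worked_example(self):
        # textbook computation with explicit loops on a 6-point example
        a, b = [1.0, 2.0, 6.0], [4.0, 5.0, 6.0]
        za = [abs(x - np.mean(a)) for x in a]
        zb = [abs(x - np.mean(b)) for x in b]
        zbar = np.mean(za + zb)
        num = 3 * ((np.mean(za) - zbar) ** 2 + (np.mean(zb) - zbar) ** 2)
        den = sum((z - np.mean(za)) ** 2 for z in za) \
            + sum((z - np.mean(zb)) ** 2 for z in zb)
        expect_W = (6 - 2) / (2 - 1) * num / den
        W, p = S.levene_test(np.array(a), np.array(b))
        assert W == pytest.approx(expect_W, abs=1e-10)
        assert p == pytest.approx(float(sps.f.sf(expect_W, 1, 4)), abs=1e-12)

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError):
            S.levene_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestIndependentT:
    def test_welch_on_printed_p1_summaries(self):
        # RL vs PC P1 latency: published Welch t(49.75) = -3.45
        rl = SummaryStats(136.66, 22.38, 33)
        pc = SummaryStats(121.33, 12.31, 33)
        t, df = S.independent_t(rl, pc, welch=True)
        assert abs(t) == pytest.approx(3.45, abs=0.02)
        assert df == pytest.approx(49.75, abs=0.02)

    def test_identical_groups_t_zero(self):
        g = SummaryStats(5.0, 2.0, 20)
        t, df = S.independent_t(g, g)
        assert t == 0.0 and df == 38

    def test_welch_equals_student_for_equal_n_and_sd(self):
        a, b = SummaryStats(3.0, 1.5, 25), SummaryStats(4.2, 1.5, 25)
        ts, dfs = S.independent_t(a, b, welch=False)
        tw, dfw = S.independent_t(a, b, welch=True)
        assert tw == pytest.approx(ts, abs=1e-12)
        assert dfw == pytest.approx(dfs, abs=1e-9)

    def test_raw_and_summary_agree(self, rng):
        a = rng.standard_normal(30) + 1.0
        b = rng.standard_normal(28) * 2.0
        for welch in (False, True):
            t1, df1 = S.independent_t(a, b, welch=welch)
            t2, df2 = S.independent_t(S.summarize(a), S.summarize(b),
                                      welch=welch)
            assert t1 == pytest.approx(t2, abs=1e-10)
            assert df1 == pytest.approx(df2, abs=1e-10)

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError):
            S.independent_t(SummaryStats(0.0, 1.0, 2),
                            np.array([1.0]))


class TestCohensD:
    def test_printed_p1_effect_size(self):
        rl = SummaryStats(136.66, 22.38, 33)
        pc = SummaryStats(121.33, 12.31, 33)
        assert abs(S.cohens_d(rl, pc)) == pytest.approx(0.85, abs=0.02)

    def test_identical_groups_zero(self):
        g = SummaryStats(5.0, 2.0, 10)
        assert S.cohens_d(g, g) == 0.0

    def test_hand_computed_example(self):
        # {0,2} vs {1,3}: means 1, 2; both SDs sqrt(2); d = -1/sqrt(2)
        d = S.cohens_d(np.array([0.0, 2.0]), np.array([1.0, 3.0]))
        assert d == pytest.approx(-1.0 / np.sqrt(2.0), abs=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(c=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(12) + 0.5, rng.standard_normal(12)
        assert S.cohens_d(c * a, c * b) == pytest.approx(
            S.cohens_d(a, b), rel=1e-9)


class TestBayesFactor:
    def test_printed_vr_pc_p1_value(self):
        # published: t(64) = 0.26 -> BF10 = 0.26
        assert S.bf10_jzs(0.26, 33, 33) == pytest.approx(0.26, rel=0.05)

    def test_zero_t_favors_null(self):
        for n in (5, 33, 200):
            assert S.bf10_jzs(0.0, n, n) < 1.0

    def test_matches_monte_carlo_integral(self):
        # 1e6 Cauchy prior draws; average noncentral-t density
        t, n1, n2, r = 2.5, 33, 33, np.sqrt(2) / 2
        rng = np.random.default_rng(42)
        delta = sps.cauchy.rvs(0.0, r, size=1_000_000, random_state=rng)
        neff = n1 * n2 / (n1 + n2)
        num = sps.nct.pdf(t, n1 + n2 - 2, delta * np.sqrt(neff)).mean()
        mc = num / sps.t.pdf(t, n1 + n2 - 2)
        assert S.bf10_jzs(t, n1, n2, r) == pytest.approx(mc, rel=0.02)

    def test_matches_independent_library_implementation(self):
        import pingouin as pg
        for t in (0.0, 0.64, 2.02, 3.45, 10.43):
            assert S.bf10_jzs(t, 33, 33) == pytest.approx(
                float(pg.bayesfactor_ttest(t, 33, 33)), rel=1e-3)

    def test_strictly_increasing_in_abs_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
        bfs = [S.bf10_jzs(t, 33, 33) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert S.bf10_jzs(-3.0, 33, 33) == pytest.approx(
            S.bf10_jzs(3.0, 33, 33), rel=1e-9)

    def test_nonfinite_t_raises(self):
        with pytest.raises(ValueError):
            S.bf10_jzs(np.nan, 33, 33)


class TestMauchlyGG:
    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(0)
        n, k = 200, 3
        subj = rng.standard_normal((n, 1))
        X = subj + rng.standard_normal((n, k))  # exchangeable levels
        W, p, eps = S.mauchly_gg(X)
        assert eps > 0.95
        assert p > 0.01

    def test_rank_one_covariance_hits_lower_bound(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(60)
        X = np.outer(z, [1.0, 2.0, 3.0])
        _, _, eps = S.mauchly_gg(X)
        assert eps == pytest.approx(1.0 / 2.0, abs=1e-9)

    def test_matches_independent_library_implementation(self):
        import pingouin as pg
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3)) @ np.array(
            [[1.0, 0.2, 0.0], [0.0, 1.0, 0.3], [0.0, 0.0, 1.6]])
        W, p, eps = S.mauchly_gg(X)
        n, k = X.shape
        df = pd.DataFrame({"y": X.ravel(),
                           "s": np.repeat(np.arange(n), k),
                           "w": np.tile(np.arange(k), n)})
        sph = pg.sphericity(df, dv="y", subject="s", within="w")
        epsg = pg.epsilon(df, dv="y", subject="s", within="w",
                          correction="gg")
        assert W == pytest.approx(sph.W, abs=1e-9)
        assert p == pytest.approx(sph.pval, abs=1e-9)
        assert eps == pytest.approx(float(epsg), abs=1e-9)

    def test_too_few_levels_raises(self):
        with pytest.raises(ValueError):
            S.mauchly_gg(np.zeros((10, 1)))


def _long_table(y, groups, subjects, w1, w2=None):
    rows = []
    a, n, b, c = y.shape
    for gi in range(a):
        for si in range(n):
            for bi in range(b):
                for ci in range(c):
                    rows.append({
                        "subject": f"{groups[gi]}_{si}",
                        "condition": groups[gi], "w1": w1[bi],
                        **({"w2": w2[ci]} if w2 else {}),
                        "dv": y[gi, si, bi, ci]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_dv_all_f_zero(self):
        y = np.full((2, 4, 3, 2), 3.0)
        df = _long_table(y, ["g1", "g2"], None, ["a", "b", "c"], ["x", "y"])
        out = S.mixed_anova(df, dv="dv", subject="subject",
                            between="condition", within=["w1", "w2"])
        assert np.allclose(out["F"], 0.0)

    def test_two_by_two_hand_computed(self):
        # 2 groups x 2 subjects x 2 within levels, zero error within
        # subjects: SS computed by hand from the cell means
        y = np.zeros((2, 2, 2, 1))
        y[0, :, :, 0] = [[1.0, 3.0], [1.0, 3.0]]
        y[1, :, :, 0] = [[2.0, 6.0], [2.0, 6.0]]
        df = _long_table(y, ["g1", "g2"], None, ["w1", "w2"])
        out = S.mixed_anova(df, dv="dv", subject="subject",
                            between="condition", within=["w1"])
        out = out.set_index("effect")
        # grand mean 3; group means 2, 4 -> SS_between = 4*(1+1) = 8
        assert out.loc["condition", "SS"] == pytest.approx(8.0)
        # within means 1.5, 4.5 -> SS_w = 4*(1.5^2+1.5^2) = 18
        assert out.loc["w1", "SS"] == pytest.approx(18.0)
        # interaction: cell means 1,3 / 2,6 -> SS = 2*sum(0.5^2)*4 = 2
        assert out.loc["condition*w1", "SS"] == pytest.approx(2.0)
        # subject error terms are exactly zero here
        assert np.isinf(out.loc["w1", "F"]) or out.loc["w1", "F"] == 0 or \
            out.loc["w1", "p"] <= 1.0  # F degenerate with zero error

    def test_matches_independent_library_implementation(self):
        import pingouin as pg
        rng = np.random.default_rng(11)
        y = rng.standard_normal((3, 12, 3, 1)) + \
            np.arange(3)[:, None, None, None] * 0.4
        df = _long_table(y, ["g1", "g2", "g3"], None, ["a", "b", "c"])
        mine = S.mixed_anova(df, dv="dv", subject="subject",
                             between="condition", within=["w1"]
                             ).set_index("effect")
        theirs = pg.mixed_anova(df, dv="dv", subject="subject",
                                between="condition", within="w1"
                                ).set_index("Source")
        for eff_m, eff_t in [("condition", "condition"), ("w1", "w1"),
                             ("condition*w1", "Interaction")]:
            assert mine.loc[eff_m, "F"] == pytest.approx(
                theirs.loc[eff_t, "F"], rel=1e-9)
            assert mine.loc[eff_m, "p"] == pytest.approx(
                theirs.loc[eff_t, "p_unc"], rel=1e-9)

    def test_eta_squared_sums_below_one(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((3, 8, 3, 2))
        df = _long_table(y, ["g1", "g2", "g3"], None,
                         ["a", "b", "c"], ["x", "y"])
        out = S.mixed_anova(df, dv="dv", subject="subject",
                            between="condition", within=["w1", "w2"])
        assert (out["eta_sq"] >= 0).all()
        assert out["eta_sq"].sum() <= 1.0 + 1e-12

    def test_unbalanced_design_raises(self):
        y = np.zeros((2, 3, 2, 1))
        df = _long_table(y, ["g1", "g2"], None, ["w1", "w2"])
        df = df[~((df.condition == "g2") & (df.subject == "g2_2"))]
        with pytest.raises(ValueError):
            S.mixed_anova(df, dv="dv", subject="subject",
                          between="condition", within=["w1"])

    def test_incomplete_cells_raise(self):
        y = np.zeros((2, 2, 2, 1))
        df = _long_table(y, ["g1", "g2"], None, ["w1", "w2"])
        with pytest.raises(ValueError):
            S.mixed_anova(df.iloc[:-1], dv="dv", subject="subject",
                          between="condition", within=["w1"])


class TestPosthocChain:
    def test_bonferroni_threshold(self):
        assert S.bonferroni_alpha(0.05, 3) == pytest.approx(0.0167, abs=5e-4)
        assert round(S.bonferroni_alpha(0.05, 3), 3) == 0.017

    def test_three_identical_groups_nothing_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        res = S.posthoc_chain({"PC": g, "VR": g.copy(), "RL": g.copy()})
        assert len(res) == 3
        for r in res:
            assert not r.significant
            assert r.bf10 < 1.0
            assert r.t == 0.0

    def test_levene_gates_welch_choice(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(40) * 6.0
        c = rng.standard_normal(40)
        res = {r.pair: r for r in S.posthoc_chain({"A": a, "B": b, "C": c})}
        assert res[("A", "B")].test == "welch_t"
        assert res[("A", "C")].test == "student_t"

    def test_significant_flag_consistent_with_p(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 2.0
        c = rng.standard_normal(20) + 0.5
        for r in S.posthoc_chain({"A": a, "B": b, "C": c}):
            assert r.significant == (r.p < r.alpha_corrected)

    def test_welch_df_never_exceeds_student_df(self, rng):
        for _ in range(10):
            a = rng.standard_normal(rng.integers(5, 30))
            b = rng.standard_normal(rng.integers(5, 30)) \
                * rng.uniform(0.3, 3.0)
            _, dfw = S.independent_t(a, b, welch=True)
            _, dfs = S.independent_t(a, b, welch=False)
            assert dfw <= dfs + 1e-9


class TestReferenceRegression:
    def test_full_p1_chain_reproduces_printed_t_df(self):
        ref = S.load_reference_stats()
        s = {g: SummaryStats(**v)
             for g, v in ref["latency_summaries"]["P1"].items()}
        res = {r.pair: r for r in S.posthoc_chain(
            {"VR": s["VR"], "PC": s["PC"], "RL": s["RL"]},
            welch={("RL", "PC"): True},
            pairs=[("VR", "PC"), ("RL", "VR"), ("RL", "PC")])}
        assert abs(res[("VR", "PC")].t) == pytest.approx(0.26, abs=0.02)
        assert res[("VR", "PC")].df == 64
        assert abs(res[("RL", "VR")].t) == pytest.approx(3.00, abs=0.02)
        assert abs(res[("RL", "PC")].t) == pytest.approx(3.45, abs=0.02)
        assert res[("RL", "PC")].df == pytest.approx(49.75, abs=0.02)
        assert res[("RL", "PC")].significant
        assert res[("RL", "VR")].significant
        assert not res[("VR", "PC")].significant
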