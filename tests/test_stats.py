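"""t tests, summary-statistic reconstruction, two-way ANOVA, post hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from visiomod.stats import (
    SummaryStats,
    anova2,
    posthoc,
    t_from_summary,
    t_paired,
    t_unpaired,
)


def balanced_table(rng, n_per_cell=11, effect=0.0):
    rows = []
    for g in ("WT", "AS"):
        for s in (0.0, 5.0, 7.5, 10.0):
            mu = effect * s * (g == "WT")
            for _ in range(n_per_cell):
                rows.append({"value": rng.normal(mu, 1.0), "factorA": g, "factorB": s})
    return pd.DataFrame(rows)


class TestTUnpaired:
    def test_identical_samples_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = t_unpaired(x, x.copy())
        assert res.statistic["t"] == 0.0
        assert res.p["t"] == 1.0

    def test_eleven_vs_eleven_has_df_twenty(self):
        rng = np.random.default_rng(0)
        res = t_unpaired(rng.normal(size=11), rng.normal(size=11))
        assert res.df["t"] == 20

    def test_antisymmetry_and_p_invariance_under_swap(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 13)
        r1, r2 = t_unpaired(x, y), t_unpaired(y, x)
        assert r1.statistic["t"] == pytest.approx(-r2.statistic["t"])
        assert r1.p["t"] == pytest.approx(r2.p["t"])

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(0.9, 1, 8)
        res = t_unpaired(x, y)
        perm = sps.permutation_test(
            (x, y), lambda a, b: a.mean() - b.mean(),
            n_resamples=20000, alternative="two-sided", random_state=3,
        )
        assert res.p["t"] == pytest.approx(perm.pvalue, abs=0.02)

    def test_zero_variance_unequal_means_degenerate(self):
        res = t_unpaired([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate
        assert res.p["t"] == 0.0

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            t_unpaired([1.0], [1.0, 2.0])


class TestTFromSummary:
    def test_equal_means_give_zero_t(self):
        a = SummaryStats("a", 1.0, 0.1, 10)
        b = SummaryStats("b", 1.0, 0.2, 10)
        assert t_from_summary(a, b).statistic["t"] == 0.0

    def test_reconstructs_printed_equal_n_comparison(self):
        # published group summaries for the still-fast AL comparison
        wt = SummaryStats("WT", 0.705, 0.072, 11)
        as_ = SummaryStats("AS", 0.477, 0.044, 11)
        res = t_from_summary(wt, as_)
        assert res.df["t"] == 20
        assert res.statistic["t"] == pytest.approx(2.679, rel=0.02)

    def test_reconstructs_printed_unequal_n_comparison(self):
        wt = SummaryStats("WT", 0.397, 0.033, 11)
        as_ = SummaryStats("AS", 0.266, 0.047, 9)
        res = t_from_summary(wt, as_)
        assert res.df["t"] == 18
        assert res.statistic["t"] == pytest.approx(2.327, rel=0.02)

    def test_agrees_with_raw_sample_t(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1.5, 12)
        raw = t_unpaired(x, y)
        summ = t_from_summary(
            SummaryStats("x", x.mean(), x.std(ddof=1) / np.sqrt(len(x)), len(x)),
            SummaryStats("y", y.mean(), y.std(ddof=1) / np.sqrt(len(y)), len(y)),
        )
        assert summ.statistic["t"] == pytest.approx(raw.statistic["t"], rel=1e-10)
        assert summ.p["t"] == pytest.approx(raw.p["t"], rel=1e-9)


class TestTPaired:
    def test_identical_pairs_degenerate_t_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = t_paired(x, x.copy())
        assert res.degenerate and res.statistic["t"] == 0.0 and res.p["t"] == 1.0

    def test_constant_shift_degenerate_p_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        res = t_paired(x, x + 0.5)
        assert res.degenerate and res.p["t"] == 0.0

    def test_matches_one_sample_t_on_differences(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        res = t_paired(x, y)
        t_direct, p_direct = sps.ttest_1samp(x - y, 0.0)
        assert res.statistic["t"] == pytest.approx(t_direct, rel=1e-12)
        assert res.p["t"] == pytest.approx(p_direct, rel=1e-12)
        assert res.df["t"] == 14

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            t_paired([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova2:
    def test_published_design_degrees_of_freedom(self):
        df = balanced_table(np.random.default_rng(6))
        res = anova2(df)
        assert res.df["interaction"] == (3.0, 80.0)
        assert res.df["factorA"] == (1.0, 80.0)
        assert res.df["factorB"] == (3.0, 80.0)

    def test_zero_between_group_variation_gives_zero_f(self):
        rows = [{"value": 1.0, "factorA": g, "factorB": s}
                for g in "AB" for s in "XY" for _ in range(3)]
        res = anova2(pd.DataFrame(rows))
        for eff in res.effects:
            assert res.statistic[eff] == 0.0
            assert res.p[eff] == 1.0

    def test_matches_hand_rolled_sums_of_squares(self):
        rng = np.random.default_rng(7)
        df = balanced_table(rng, n_per_cell=5, effect=0.1)
        res = anova2(df)
        # oracle: direct balanced two-way SS decomposition
        y = df["value"].to_numpy()
        A = df["factorA"].to_numpy()
        B = df["factorB"].to_numpy()
        grand = y.mean()
        a_lv, b_lv = np.unique(A), np.unique(B)
        n = len(y) / (len(a_lv) * len(b_lv))
        ss_a = sum(len(y[A == a]) * (y[A == a].mean() - grand) ** 2 for a in a_lv)
        ss_b = sum(len(y[B == b]) * (y[B == b].mean() - grand) ** 2 for b in b_lv)
        ss_cells = sum(
            len(y[(A == a) & (B == b)]) * (y[(A == a) & (B == b)].mean() - grand) ** 2
            for a in a_lv for b in b_lv
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = sum(
            ((y[(A == a) & (B == b)] - y[(A == a) & (B == b)].mean()) ** 2).sum()
            for a in a_lv for b in b_lv
        )
        df_err = len(y) - len(a_lv) * len(b_lv)
        for eff, ss, d in [("factorA", ss_a, len(a_lv) - 1),
                           ("factorB", ss_b, len(b_lv) - 1),
                           ("interaction", ss_ab, (len(a_lv) - 1) * (len(b_lv) - 1))]:
            f_expect = (ss / d) / (ss_err / df_err)
            assert res.statistic[eff] == pytest.approx(f_expect, abs=1e-10)

    def test_balanced_type_i_equals_type_iii(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        df = balanced_table(rng, n_per_cell=4, effect=0.2)
        d = df.rename(columns={"value": "y", "factorA": "a", "factorB": "b"})
        m1 = smf.ols("y ~ C(a) * C(b)", data=d).fit()
        t1 = sm.stats.anova_lm(m1, typ=1)
        m3 = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=d).fit()
        t3 = sm.stats.anova_lm(m3, typ=3).drop(index="Intercept")
        assert np.allclose(t1["F"].iloc[:3].to_numpy(), t3["F"].iloc[:3].to_numpy())

    def test_collapsed_factor_reproduces_one_way_f(self):
        rng = np.random.default_rng(9)
        rows = [{"value": rng.normal(0.3 * (g == "WT")), "factorA": g, "factorB": "only"}
                for g in ("WT", "AS") for _ in range(10)]
        df = pd.DataFrame(rows)
        with pytest.raises(ValueError, match=">= 2 levels"):
            anova2(df)
        # one-way equivalence checked through the responsiveness path instead:
        x = df.loc[df.factorA == "WT", "value"]
        y = df.loc[df.factorA == "AS", "value"]
        f1, p1 = sps.f_oneway(x, y)
        t, p2 = sps.ttest_ind(x, y)
        assert f1 == pytest.approx(t ** 2, rel=1e-10)

    def test_empty_cell_is_named_error(self):
        rows = [{"value": 1.0, "factorA": "WT", "factorB": "x"},
                {"value": 2.0, "factorA": "WT", "factorB": "y"},
                {"value": 1.5, "factorA": "AS", "factorB": "x"}]
        with pytest.raises(ValueError, match="AS.*y"):
            anova2(pd.DataFrame(rows))

    def test_unbalanced_uses_type_iii(self):
        rng = np.random.default_rng(10)
        rows = []
        for g, s, n in [("WT", "x", 5), ("WT", "y", 8), ("AS", "x", 6), ("AS", "y", 4)]:
            for _ in range(n):
                rows.append({"value": rng.normal(), "factorA": g, "factorB": s})
        res = anova2(pd.DataFrame(rows))
        assert "III" in res.notes["ss_type"]
        assert res.notes["residual_df"] == 23 - 4  # N - cells


class TestPosthoc:
    def test_bonferroni_multiplies_p_and_caps(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({
            "value": np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10),
                                     rng.normal(0.1, 1, 10)]),
            "group": ["a"] * 10 + ["b"] * 10 + ["c"] * 10,
        })
        out = posthoc(df, method="bonferroni")
        assert len(out) == 3
        for _, row in out.iterrows():
            raw = t_unpaired(df[df.group == row.group1].value,
                             df[df.group == row.group2].value).p["t"]
            assert row.p_adj == pytest.approx(min(1.0, 3 * raw))

    def test_tukey_on_identical_groups_p_one(self):
        df = pd.DataFrame({"value": [1.0, 1.0, 1.0] * 3,
                           "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3})
        out = posthoc(df, method="tukey")
        assert np.allclose(out["p_adj"], 1.0)

    def test_tukey_matches_studentized_range_oracle(self):
        from scipy.integrate import quad

        rng = np.random.default_rng(12)
        groups = {g: rng.normal(mu, 1.0, 8) for g, mu in [("a", 0), ("b", 1.0), ("c", 0.5)]}
        df = pd.DataFrame({
            "value": np.concatenate(list(groups.values())),
            "group": np.repeat(list(groups), 8),
        })
        out = posthoc(df, method="tukey")
        k, df_w = 3, 21
        ms_w = np.mean([np.var(v, ddof=1) for v in groups.values()])
        for _, row in out.iterrows():
            diff = abs(groups[row.group1].mean() - groups[row.group2].mean())
            q_obs = diff / np.sqrt(ms_w / 8)
            p_oracle = sps.studentized_range.sf(q_obs, k, df_w)
            assert row.p_adj == pytest.approx(p_oracle, abs=1e-6)

    def test_scipy_tukey_hsd_agreement(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(mu, 1.0, 9) for mu in (0.0, 0.8, 0.3)]
        df = pd.DataFrame({
            "value": np.concatenate(groups),
            "group": np.repeat(["a", "b", "c"], 9),
        })
        out = posthoc(df, method="tukey").set_index(["group1", "group2"])
        ref = sps.tukey_hsd(*groups)
        pairs = {("a", "b"): (0, 1), ("a", "c"): (0, 2), ("b", "c"): (1, 2)}
        for (g1, g2), (i, j) in pairs.items():
            assert out.loc[(g1, g2), "p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            posthoc(pd.DataFrame({"value": [1.0, 2.0], "group": ["a", "b"]}), method="sidak")
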