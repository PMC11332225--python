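import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from srttlearn.stats import (
    bf_model_comparison,
    hedges_g,
    jzs_bf_ttest,
    mixed_anova,
    moderated_regression,
    one_sample_t,
    one_way_anova,
    tukey_pairwise,
)


def brute_force_oneway(samples):
    """Independent sums-of-squares computation for a one-way layout."""
    allv = np.concatenate(samples)
    grand = allv.mean()
    ssb = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ssw = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples)
    k, n = len(samples), len(allv)
    F = (ssb / (k - 1)) / (ssw / (n - k))
    return F, ssb / (ssb + ssw)


def brute_force_mixed(df):
    """Cell-means mixed-ANOVA decomposition (balanced groups, one obs/cell)."""
    subjects = df["subject"].unique()
    levels = sorted(df["within"].unique())
    k = df["group"].nunique()
    m = len(levels)
    N = len(subjects)
    grand = df["y"].mean()
    subj_mean = df.groupby("subject")["y"].mean()
    group_of = df.drop_duplicates("subject").set_index("subject")["group"]
    group_mean = df.groupby("group")["y"].mean()
    level_mean = df.groupby("within")["y"].mean()
    cell_mean = df.groupby(["group", "within"])["y"].mean()
    n_per_group = df.groupby("group")["subject"].nunique()

    ss_total = ((df["y"] - grand) ** 2).sum()
    ss_subjects = m * ((subj_mean - grand) ** 2).sum()
    ss_group = m * sum(n_per_group[g] * (group_mean[g] - grand) ** 2 for g in group_mean.index)
    ss_subj_err = ss_subjects - ss_group
    ss_within = N * ((level_mean - grand) ** 2).sum()
    ss_cells = sum(
        n_per_group[g] * (cell_mean[(g, w)] - grand) ** 2 for g, w in cell_mean.index
    )
    ss_inter = ss_cells - ss_group - ss_within
    ss_err = ss_total - ss_subjects - ss_within - ss_inter
    f_group = (ss_group / (k - 1)) / (ss_subj_err / (N - k))
    f_within = (ss_within / (m - 1)) / (ss_err / ((N - k) * (m - 1)))
    f_inter = (ss_inter / ((k - 1) * (m - 1))) / (ss_err / ((N - k) * (m - 1)))
    return f_group, f_within, f_inter


def mixed_long(rng, k=2, n_per=6, m=3, group_effect=0.0, within_effect=0.0, inter=0.0):
    rows = []
    sid = 0
    for gi in range(k):
        for _ in range(n_per):
            subj_base = rng.normal(0, 1) + group_effect * gi
            for wi in range(m):
                y = subj_base + within_effect * wi + inter * gi * wi + rng.normal(0, 0.5)
                rows.append((f"S{sid:03d}", f"g{gi}", f"w{wi}", y))
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", "within", "y"])


class TestOneWay:
    def test_hand_computed_example(self):
        vals = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        grp = list("AAABBBCCC")
        res = one_way_anova(vals, grp)
        assert res.F == pytest.approx(3.0)
        assert (res.df1, res.df2) == (2.0, 6.0)
        assert res.eta2 == pytest.approx(0.5)
        assert res.eta2_ci[0] <= res.eta2 <= res.eta2_ci[1]

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([1, 2, 3] * 3, list("AAABBBCCC"), compute_bf=False)
        assert res.F == pytest.approx(0.0)
        assert res.eta2 == pytest.approx(0.0)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0, 3.0], ["A", "A", "B"])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0] * 6, list("AAABBB"))

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_instances(self, data):
        k = data.draw(st.integers(2, 4))
        samples = [
            data.draw(
                st.lists(st.floats(-50, 50), min_size=2, max_size=8).filter(
                    lambda s: np.std(s) > 1e-9
                )
            )
            for _ in range(k)
        ]
        vals = np.concatenate(samples)
        grp = np.concatenate([[f"g{i}"] * len(s) for i, s in enumerate(samples)])
        res = one_way_anova(vals, grp, compute_bf=False)
        F, eta2 = brute_force_oneway(samples)
        assert res.F == pytest.approx(F, rel=1e-9)
        assert res.eta2 == pytest.approx(eta2, rel=1e-9)
        # cross-check against scipy's independent implementation
        F2, p2 = sps.f_oneway(*samples)
        assert res.F == pytest.approx(F2, rel=1e-9)
        if np.isfinite(p2):  # scipy emits NaN p in degenerate equal-mean cases
            assert res.p == pytest.approx(p2, rel=1e-9, abs=1e-12)


class TestMixedAnova:
    def test_two_level_within_has_unit_epsilon_and_raw_dfs(self, rng):
        d = mixed_long(np.random.default_rng(0), k=3, n_per=8, m=2)
        res = mixed_anova(d, "y", "within", "group", "subject", compute_bf=False)
        within = next(r for r in res if r.effect == "within")
        assert within.epsilon_gg == 1.0
        assert not within.gg_applied
        assert within.df1 == 1.0 and within.df2 == 21.0  # (m-1), (N-k)(m-1)

    def test_matches_brute_force_cell_means(self):
        d = mixed_long(np.random.default_rng(7), k=2, n_per=5, m=2, group_effect=0.8, inter=0.5)
        res = {r.effect: r for r in mixed_anova(d, "y", "within", "group", "subject", compute_bf=False)}
        f_g, f_w, f_i = brute_force_mixed(d)
        assert res["group"].F == pytest.approx(f_g, rel=1e-6)
        assert res["within"].F == pytest.approx(f_w, rel=1e-6)
        assert res["interaction"].F == pytest.approx(f_i, rel=1e-6)

    def test_matches_brute_force_with_more_levels(self):
        d = mixed_long(np.random.default_rng(3), k=3, n_per=6, m=4, within_effect=0.4)
        res = {r.effect: r for r in mixed_anova(d, "y", "within", "group", "subject", compute_bf=False, gg_alpha=1e-12)}
        f_g, f_w, f_i = brute_force_mixed(d)
        assert res["group"].F == pytest.approx(f_g, rel=1e-6)
        assert res["within"].F == pytest.approx(f_w, rel=1e-6)
        assert res["interaction"].F == pytest.approx(f_i, rel=1e-6)

    def test_gg_correction_shrinks_dfs_when_sphericity_violated(self):
        rng = np.random.default_rng(11)
        rows = []
        # strongly non-spherical: level 3 variance much larger
        for sid in range(24):
            g = "g0" if sid < 12 else "g1"
            base = rng.normal()
            vals = [base + rng.normal(0, 0.1), base + rng.normal(0, 0.1), base + rng.normal(0, 4.0), base + rng.normal(0, 8.0)]
            rows += [(f"S{sid}", g, f"w{i}", v) for i, v in enumerate(vals)]
        d = pd.DataFrame(rows, columns=["subject", "group", "within", "y"])
        res = mixed_anova(d, "y", "within", "group", "subject", compute_bf=False)
        within = next(r for r in res if r.effect == "within")
        if within.sphericity_p is not None and within.sphericity_p < 0.05:
            assert within.gg_applied
            assert within.df1 < 3.0
            assert 1 / 3 <= within.epsilon_gg <= 1.0

    def test_single_within_level_degenerates_to_oneway(self):
        d = mixed_long(np.random.default_rng(1), k=3, n_per=6, m=1, group_effect=1.0)
        res = mixed_anova(d, "y", "within", "group", "subject", compute_bf=False)
        assert len(res) == 1
        ref = one_way_anova(d["y"], d["group"], compute_bf=False)
        assert res[0].F == pytest.approx(ref.F)

    def test_missing_cells_rejected_with_instruction(self):
        d = mixed_long(np.random.default_rng(2), k=2, n_per=5, m=3)
        with pytest.raises(ValueError, match="listwise"):
            mixed_anova(d.iloc[:-1], "y", "within", "group", "subject")

    def test_strong_group_effect_earns_large_bf(self):
        d = mixed_long(np.random.default_rng(4), k=2, n_per=14, m=2, group_effect=3.0)
        res = {r.effect: r for r in mixed_anova(d, "y", "within", "group", "subject")}
        assert res["group"].bf10 > 10


class TestTukeyAndEffectSizes:
    def test_identical_groups_have_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 3
        grp = np.repeat(["A", "B", "C"], 4)
        for pr in tukey_pairwise(vals, grp, compute_bf=False):
            assert pr.tukey_p == pytest.approx(1.0, abs=1e-9)
            assert pr.hedges_g == pytest.approx(0.0, abs=1e-12)

    def test_far_separated_groups_reject(self, rng):
        a = rng.normal(0, 0.1, 5)
        b = rng.normal(10, 0.1, 5)
        out = tukey_pairwise(np.r_[a, b], ["A"] * 5 + ["B"] * 5, compute_bf=False)
        assert out[0].tukey_p < 0.001

    def test_matches_studentized_range_oracle(self, rng):
        samples = [rng.normal(m, 1.0, 7) for m in (0.0, 0.6, 1.4)]
        vals = np.concatenate(samples)
        grp = np.concatenate([[f"g{i}"] * 7 for i in range(3)])
        out = {(p.group_a, p.group_b): p for p in tukey_pairwise(vals, grp, compute_bf=False)}
        msw = np.mean([np.var(s, ddof=1) for s in samples])
        dof = len(vals) - 3
        for (i, j) in itertools.combinations(range(3), 2):
            q = abs(np.mean(samples[i]) - np.mean(samples[j])) / np.sqrt(msw / 7)
            p_oracle = sps.studentized_range.sf(q, 3, dof)
            assert out[(f"g{i}", f"g{j}")].tukey_p == pytest.approx(p_oracle, abs=1e-6)

    def test_tukey_p_invariant_to_relabeling(self, rng):
        vals = rng.normal(0, 1, 18)
        grp = np.repeat(["A", "B", "C"], 6)
        out1 = {frozenset((p.group_a, p.group_b)): p.tukey_p for p in tukey_pairwise(vals, grp, compute_bf=False)}
        relab = {"A": "Z", "B": "Y", "C": "X"}
        grp2 = np.array([relab[g] for g in grp])
        out2 = {
            frozenset((relab_inv(p.group_a), relab_inv(p.group_b))): p.tukey_p
            for p in tukey_pairwise(vals, grp2, compute_bf=False)
        }
        for key, p1 in out1.items():
            key2 = frozenset(key)
            assert out2[key2] == pytest.approx(p1, rel=1e-9)

    def test_hedges_g_hand_example(self):
        g, ci = hedges_g([0, 0, 1, 1], [1, 1, 2, 2])
        # d = -sqrt(3), J = 1 - 3/23
        assert g == pytest.approx(-np.sqrt(3) * (1 - 3 / 23), abs=1e-4)
        assert g == pytest.approx(-1.506, abs=2e-3)
        assert ci[0] < g < ci[1]

    def test_hedges_g_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        g1, ci1 = hedges_g(a, b)
        g2, ci2 = hedges_g(b, a)
        assert g1 == pytest.approx(-g2)
        assert ci1[0] == pytest.approx(-ci2[1], abs=1e-6)

    def test_identical_samples_give_zero(self):
        g, ci = hedges_g([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert g == 0.0 and ci == (0.0, 0.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            hedges_g([1.0, 1.0], [2.0, 2.0])


def relab_inv(lbl):
    return {"Z": "A", "Y": "B", "X": "C"}[lbl]


class TestOneSampleT:
    def test_mean_equal_to_mu0(self):
        t, df, p, g = one_sample_t([1, 2, 3], 2.0)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 2

    def test_hand_example(self):
        t, df, p, g = one_sample_t([1, 2, 3], 0.0)
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0], 0.0)


class TestJZSBayesFactor:
    def test_t_zero_favors_null_for_all_n(self):
        for n in (3, 5, 10, 20, 100, 500):
            assert jzs_bf_ttest(0.0, n) < 1.0
            assert jzs_bf_ttest(0.0, n, n) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf_ttest(t, 15, 15) for t in np.linspace(0, 6, 13)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("t,n1,n2", [(2.0, 20, 20), (3.5, 12, 15), (0.8, 30, None), (5.0, 27, 27)])
    def test_matches_independent_quadratures(self, t, n1, n2):
        bf = jzs_bf_ttest(t, n1, n2)
        # oracle 1: pingouin's JZS implementation
        nx, ny = (n1, n2) if n2 is not None else (n1, None)
        paired = n2 is None
        bf_pg = float(pg.bayesfactor_ttest(t, nx, ny, paired=paired))
        assert bf == pytest.approx(bf_pg, rel=1e-3)
        # oracle 2: fine-grid log-substitution quadrature
        neff = n1 if n2 is None else n1 * n2 / (n1 + n2)
        nu = (n1 - 1) if n2 is None else (n1 + n2 - 2)
        r2 = 0.5
        u = np.linspace(-12, 12, 200_001)
        gv = np.exp(u)
        c = 1 + neff * gv * r2
        integrand = (
            c**-0.5
            * (1 + t * t / (c * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * gv**-1.5
            * np.exp(-1 / (2 * gv))
            * gv  # jacobian
        )
        alt = np.trapezoid(integrand, u)
        null = (1 + t * t / nu) ** (-(nu + 1) / 2)
        assert bf == pytest.approx(alt / null, rel=1e-4)

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(np.inf, 10)


class TestModelComparisonBF:
    def test_equal_models_give_unit_bf(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 40), "x": rng.normal(0, 1, 40)})
        assert bf_model_comparison(df, "y", ["x"], ["x"]) == pytest.approx(1.0)

    def test_non_nested_specs_rejected(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 30), "x": rng.normal(0, 1, 30), "z": rng.normal(0, 1, 30)})
        with pytest.raises(ValueError, match="subset"):
            bf_model_comparison(df, "y", ["x"], ["z"])

    def test_strong_effect_gives_large_bf_and_null_small(self):
        rng = np.random.default_rng(0)
        n = 27
        strong, null = [], []
        for rep in range(10):
            g = np.repeat(list("ABCD"), n)
            eff = {"A": 0, "B": 1, "C": 2, "D": 3}
            y1 = np.array([eff[x] for x in g]) + rng.normal(0, 1, 4 * n)
            y0 = rng.normal(0, 1, 4 * n)
            df1 = pd.DataFrame({"y": y1, "g": g})
            df0 = pd.DataFrame({"y": y0, "g": g})
            strong.append(bf_model_comparison(df1, "y", ["g"], []))
            null.append(bf_model_comparison(df0, "y", ["g"], []))
        assert min(strong) > 10
        assert np.median(null) < 1


class TestModeratedRegression:
    def test_common_slope_no_interactions(self):
        rng = np.random.default_rng(0)
        micro = rng.normal(0, 1, 80)
        groups = np.repeat(["CH", "AD", "YA", "OA"], 20)
        macro = 0.5 * micro
        table, bf = moderated_regression(macro, micro, groups)
        coef = table.set_index("term")["b"]
        assert coef["micro"] == pytest.approx(0.5, abs=1e-10)
        for g in ("CH", "AD", "OA"):
            assert coef[f"group[{g}]:micro"] == pytest.approx(0.0, abs=1e-10)

    def test_group_specific_slope_lands_on_interaction(self):
        rng = np.random.default_rng(1)
        micro = rng.normal(0, 1, 60)
        groups = np.repeat(["CH", "YA", "OA"], 20)
        slope = np.where(groups == "YA", 0.6, np.where(groups == "CH", 0.0, 0.6))
        macro = slope * micro
        table, _ = moderated_regression(macro, micro, groups)
        coef = table.set_index("term")["b"]
        assert coef["micro"] == pytest.approx(0.6, abs=1e-10)  # YA reference slope
        assert coef["group[CH]:micro"] == pytest.approx(-0.6, abs=1e-10)
        assert coef["group[OA]:micro"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            moderated_regression([1.0] * 8, [2.0] * 8, ["YA"] * 4 + ["CH"] * 4)
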