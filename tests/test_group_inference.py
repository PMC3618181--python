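"""Split-plot and repeated-measures ANOVA against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

import pbifpet as p
from pbifpet.io_core import SubjectMeta


def two_group_table(values_a, values_b):
    va, vb = np.asarray(values_a, float), np.asarray(values_b, float)
    subjects = ([SubjectMeta(f"a{i}", group="healthy") for i in range(len(va))]
                + [SubjectMeta(f"b{i}", group="cannabis") for i in range(len(vb))])
    regions = [f"r{j}" for j in range(va.shape[1])]
    return p.VTTable(subjects=subjects, regions=regions,
                     values=np.vstack([va, vb]))


def single_group(values, group="healthy", prefix="s"):
    values = np.asarray(values, float)
    return p.VTTable(
        subjects=[SubjectMeta(f"{prefix}{i}", group=group)
                  for i in range(values.shape[0])],
        regions=[f"r{j}" for j in range(values.shape[1])], values=values)


def split_plot_oracle(y, gidx, n_groups):
    """Textbook split-plot sums of squares by explicit loops."""
    n, r = y.shape
    grand = y.mean()
    ss = dict.fromkeys(["group", "subj", "region", "int", "resid"], 0.0)
    gmean = {g: y[gidx == g].mean() for g in range(n_groups)}
    rmean = {k: y[:, k].mean() for k in range(r)}
    cmean = {(g, k): y[gidx == g, k].mean()
             for g in range(n_groups) for k in range(r)}
    for g in range(n_groups):
        ss["group"] += r * (gidx == g).sum() * (gmean[g] - grand) ** 2
    for i in range(n):
        ss["subj"] += r * (y[i].mean() - gmean[gidx[i]]) ** 2
    for k in range(r):
        ss["region"] += n * (rmean[k] - grand) ** 2
    for g in range(n_groups):
        for k in range(r):
            ss["int"] += ((gidx == g).sum()
                          * (cmean[g, k] - gmean[g] - rmean[k] + grand) ** 2)
    for i in range(n):
        for k in range(r):
            ss["resid"] += (y[i, k] - y[i].mean() - cmean[gidx[i], k]
                            + gmean[gidx[i]]) ** 2
    return ss


class TestMixedAnova:
    def test_toy_table_matches_textbook_oracle(self):
        va = [[10.0, 12.0], [11.0, 15.0], [9.0, 10.0]]
        vb = [[8.0, 9.0], [7.0, 10.0], [9.5, 8.5]]
        vt = two_group_table(va, vb)
        res = p.mixed_anova(vt)
        y = vt.values
        gidx = np.array([0, 0, 0, 1, 1, 1])
        oracle = split_plot_oracle(y, gidx, 2)
        assert res.ss["group"] == pytest.approx(oracle["group"], abs=1e-10)
        assert res.ss["subjects_within_group"] == pytest.approx(
            oracle["subj"], abs=1e-10)
        assert res.ss["region"] == pytest.approx(oracle["region"], abs=1e-10)
        assert res.ss["group_x_region"] == pytest.approx(oracle["int"], abs=1e-10)
        assert res.ss["region_x_subjects_within_group"] == pytest.approx(
            oracle["resid"], abs=1e-10)

    def test_unbalanced_oracle_and_statsmodels_cross_check(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        va = rng.lognormal(2.5, 0.3, (7, 3))
        vb = rng.lognormal(2.4, 0.3, (4, 3))
        vt = two_group_table(va, vb)
        res = p.mixed_anova(vt)
        gidx = np.array([0] * 7 + [1] * 4)
        oracle = split_plot_oracle(vt.values, gidx, 2)
        for mine, theirs in [("group", "group"), ("region", "region"),
                             ("group_x_region", "int")]:
            assert res.ss[mine] == pytest.approx(oracle[theirs], rel=1e-10)
        # independent route: OLS Type II SS for the within-stratum terms
        rows = [(f"s{i}", "g0" if gidx[i] == 0 else "g1", f"r{k}", vt.values[i, k])
                for i in range(11) for k in range(3)]
        df = pd.DataFrame(rows, columns=["subject", "group", "region", "y"])
        fit = ols("y ~ C(group) * C(region)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.ss["region"] == pytest.approx(
            tab.loc["C(region)", "sum_sq"], rel=1e-8)
        assert res.ss["group_x_region"] == pytest.approx(
            tab.loc["C(group):C(region)", "sum_sq"], rel=1e-8)

    def test_partition_sums_to_total(self, rng):
        for _ in range(5):
            vt = two_group_table(rng.lognormal(2.5, 0.3, (6, 4)),
                                 rng.lognormal(2.5, 0.3, (9, 4)))
            res = p.mixed_anova(vt)
            parts = sum(v for k, v in res.ss.items() if k != "total")
            assert parts == pytest.approx(res.ss["total"], abs=1e-8)

    def test_additive_shift_gives_group_effect_no_interaction(self, rng):
        base = rng.lognormal(2.5, 0.2, (10, 4))
        vt = two_group_table(base, base + 2.0)
        res = p.mixed_anova(vt)
        f_group = res.effects["group"][0]
        f_int, _, _, p_int = res.effects["group_x_region"]
        assert res.significant("group")
        assert f_int == pytest.approx(0.0, abs=1e-18)
        assert f_group > 10

    def test_f_invariant_to_common_rescaling(self, rng):
        vt = two_group_table(rng.lognormal(2.5, 0.3, (5, 3)),
                             rng.lognormal(2.4, 0.3, (6, 3)))
        scaled = p.VTTable(subjects=vt.subjects, regions=vt.regions,
                           values=vt.values * 3.7)
        r1, r2 = p.mixed_anova(vt), p.mixed_anova(scaled)
        for eff in r1.effects:
            assert r1.effects[eff][0] == pytest.approx(r2.effects[eff][0],
                                                       rel=1e-9)

    def test_null_p_values_uniform(self):
        """Under the null (identical group distributions) the group-effect p
        value is uniform: KS test over 300 simulated studies."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(300):
            vt = two_group_table(rng.normal(13.0, 3.0, (12, 4)).clip(0.5),
                                 rng.normal(13.0, 3.0, (12, 4)).clip(0.5))
            pvals.append(p.mixed_anova(vt).effects["group"][3])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_covariate_adjustment_matches_statsmodels_ancova(self, rng):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        vt = two_group_table(rng.lognormal(2.5, 0.3, (8, 3)),
                             rng.lognormal(2.4, 0.3, (6, 3)))
        bmi = rng.normal(26.0, 4.0, 14)
        res = p.mixed_anova(vt, covariate=bmi)
        assert res.covariate_used
        df = pd.DataFrame({"u": vt.values.mean(axis=1), "x": bmi,
                           "g": ["a"] * 8 + ["b"] * 6})
        tab = sm.stats.anova_lm(ols("u ~ x + C(g)", data=df).fit(), typ=2)
        f_oracle = tab.loc["C(g)", "F"]
        assert res.effects["group"][0] == pytest.approx(f_oracle, rel=1e-9)
        assert res.effects["group"][2] == 14 - 2 - 1

    def test_singular_covariate_rejected(self, rng):
        vt = two_group_table(rng.lognormal(2.5, 0.3, (3, 2)),
                             rng.lognormal(2.5, 0.3, (3, 2)))
        with pytest.raises(ValueError, match="singular"):
            p.mixed_anova(vt, covariate=np.ones(6))


def within_oracle(y):
    """Loop-based repeated-measures two-way sums of squares for (n, 2, r)."""
    n, t, r = y.shape
    grand = y.mean()
    ss_rep = sum(n * r * (y[:, j, :].mean() - grand) ** 2 for j in range(t))
    ss_rep_subj = 0.0
    for i in range(n):
        for j in range(t):
            ss_rep_subj += r * (y[i, j].mean() - y[i].mean()
                                - y[:, j, :].mean() + grand) ** 2
    ss_rep_region = 0.0
    for j in range(t):
        for k in range(r):
            ss_rep_region += n * (y[:, j, k].mean() - y[:, j, :].mean()
                                  - y[:, :, k].mean() + grand) ** 2
    return ss_rep, ss_rep_subj, ss_rep_region


class TestWithinAnova:
    def test_identical_sessions_zero_f(self, rng):
        base = single_group(rng.lognormal(2.5, 0.3, (6, 4)))
        res = p.within_anova(base, base)
        assert res.effects["repetition"][0] == 0.0
        assert res.effects["repetition_x_region"][0] == 0.0

    def test_toy_matches_loop_oracle(self, rng):
        base = single_group(rng.lognormal(2.5, 0.3, (3, 2)))
        follow = single_group(rng.lognormal(2.6, 0.3, (3, 2)))
        res = p.within_anova(base, follow)
        y = np.stack([base.values, follow.values], axis=1)
        ss_rep, ss_rep_subj, ss_rep_region = within_oracle(y)
        assert res.ss["repetition"] == pytest.approx(ss_rep, abs=1e-10)
        assert res.ss["repetition_x_subjects"] == pytest.approx(
            ss_rep_subj, abs=1e-10)
        assert res.ss["repetition_x_region"] == pytest.approx(
            ss_rep_region, abs=1e-10)

    def test_partition_sums_to_total(self, rng):
        base = single_group(rng.lognormal(2.5, 0.3, (7, 5)))
        follow = single_group(rng.lognormal(2.55, 0.3, (7, 5)))
        res = p.within_anova(base, follow)
        parts = sum(v for k, v in res.ss.items() if k != "total")
        assert parts == pytest.approx(res.ss["total"], abs=1e-8)

    def test_region_specific_change_detected(self, rng):
        base_vals = rng.lognormal(2.5, 0.1, (10, 4))
        shift = np.array([2.0, 0.0, 2.0, 0.0]) * base_vals.std()
        follow_vals = base_vals + shift
        res = p.within_anova(single_group(base_vals),
                             single_group(follow_vals))
        assert res.effects["repetition_x_region"][3] < 0.05

    def test_session_subject_mismatch_rejected(self, rng):
        base = single_group(rng.lognormal(2.5, 0.3, (3, 2)))
        other = single_group(rng.lognormal(2.5, 0.3, (3, 2)), prefix="x")
        with pytest.raises(ValueError, match="subject"):
            p.within_anova(base, other)


class TestPerRegionTests:
    def test_identical_tables_no_effects(self, rng):
        t = single_group(rng.lognormal(2.5, 0.3, (6, 3)))
        out = p.per_region_tests(t, t, paired=True)
        for effect, pval, sig in out.per_region.values():
            assert effect == 0.0 and not sig

    def test_twenty_percent_reduction_recovered(self, rng):
        # the widespread-downregulation pattern as a noiseless limit:
        # patient values are exactly 0.8x, with within-group spread
        base = rng.lognormal(np.log(13.0), 0.25, (40, 4))
        out = p.per_region_tests(single_group(base),
                                 single_group(0.8 * base, group="alcohol",
                                              prefix="c"))
        for effect, pval, sig in out.per_region.values():
            assert effect == pytest.approx(-20.0, abs=1e-9)
            assert sig

    def test_welch_statistic_matches_hand_computation(self, rng):
        a = single_group(rng.lognormal(2.5, 0.3, (8, 1)))
        b = single_group(rng.lognormal(2.4, 0.3, (6, 1)), group="cannabis",
                         prefix="c")
        out = p.per_region_tests(a, b)
        va, vb = a.values[:, 0], b.values[:, 0]
        t_hand = (vb.mean() - va.mean()) / np.sqrt(
            vb.var(ddof=1) / 6 + va.var(ddof=1) / 8)
        t_scipy = sps.ttest_ind(vb, va, equal_var=False).statistic
        assert t_scipy == pytest.approx(t_hand, abs=1e-12)
        # the table's p agrees with the Welch p for this region
        assert out.per_region["r0"][1] == pytest.approx(
            sps.ttest_ind(vb, va, equal_var=False).pvalue, abs=1e-12)

    def test_significance_flag_matches_alpha(self, rng):
        a = single_group(rng.lognormal(2.5, 0.05, (10, 2)))
        b = single_group(0.7 * rng.lognormal(2.5, 0.05, (10, 2)),
                         group="alcohol", prefix="c")
        out = p.per_region_tests(a, b, alpha=0.05)
        for _, pval, sig in out.per_region.values():
            assert sig == (pval < 0.05)
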