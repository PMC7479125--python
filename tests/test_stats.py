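import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

from hemirc import (
    asymmetry_score,
    asymmetry_tests,
    bonferroni,
    edgewise_census,
    mixed_anova,
    partial_spearman,
    posthoc_tests,
)
from hemirc.pipeline import _full_classification
from hemirc.richclub import select_hubs
from conftest import random_network
from oracles import partial_spearman_bruteforce


def _metric_table(rng, n_per_group=12, group_shift=0.0, hemi_shift=0.0,
                  interaction=0.0, covariates=False):
    rows = []
    for i in range(2 * n_per_group):
        g = "NC" if i < n_per_group else "BD"
        base = rng.normal(10, 2)
        gs = group_shift if g == "BD" else 0.0
        ints = interaction if g == "BD" else 0.0
        row_cov = {"age": float(rng.uniform(20, 50)), "sex": "MF"[i % 2],
                   "handscore": float(rng.uniform(0.75, 1))} if covariates else {}
        for hemi, hs in (("L", 0.0), ("R", hemi_shift + ints)):
            rows.append({"subject_id": f"s{i}", "group": g, "hemisphere": hemi,
                         "value": base + gs + hs + rng.normal(0, 1), **row_cov})
    return pd.DataFrame(rows)


class TestAsymmetryScore:
    def test_symmetric_inputs_give_zero(self):
        assert asymmetry_score(0.7, 0.7) == 0.0

    def test_worked_example(self):
        # AS = 100 * (3 - 1)/(3 + 1) = 50, rightward
        assert asymmetry_score(3.0, 1.0) == pytest.approx(50.0)

    def test_both_zero_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(asymmetry_score(0.0, 0.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        r=st_h.floats(0, 1e6, allow_nan=False),
        l=st_h.floats(0, 1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, r, l):
        if r + l == 0:
            return
        a = asymmetry_score(r, l)
        assert -100.0 <= a <= 100.0
        assert a == pytest.approx(-asymmetry_score(l, r), abs=1e-9)
        if r == l:
            assert a == 0.0

    def test_vectorized(self):
        out = asymmetry_score(np.array([3.0, 1.0]), np.array([1.0, 1.0]))
        np.testing.assert_allclose(out, [50.0, 0.0])


class TestMixedAnova:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_pingouin_balanced(self, seed):
        df = _metric_table(np.random.default_rng(seed))
        res = mixed_anova(df)
        aov = pg.mixed_anova(
            data=df, dv="value", within="hemisphere",
            subject="subject_id", between="group",
        ).set_index("Source")
        assert res.F_group == pytest.approx(aov.loc["group", "F"], rel=1e-10)
        assert res.F_hemisphere == pytest.approx(aov.loc["hemisphere", "F"], rel=1e-10)
        assert res.F_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-10)

    def test_interaction_equals_t_squared_on_differences(self, rng):
        df = _metric_table(rng, interaction=1.0)
        res = mixed_anova(df)
        wide = df.pivot_table(
            index=["subject_id", "group"], columns="hemisphere", values="value"
        ).reset_index()
        d = wide["R"] - wide["L"]
        t = sps.ttest_ind(d[wide["group"] == "NC"], d[wide["group"] == "BD"]).statistic
        assert res.F_interaction == pytest.approx(t**2, rel=1e-10)

    def test_location_invariance_of_within_tests(self, rng):
        df = _metric_table(rng, hemi_shift=0.5)
        res1 = mixed_anova(df)
        df2 = df.copy()
        df2["value"] += 1000.0
        res2 = mixed_anova(df2)
        assert res1.F_hemisphere == pytest.approx(res2.F_hemisphere, rel=1e-8)
        assert res1.F_interaction == pytest.approx(res2.F_interaction, rel=1e-8)

    def test_covariates_reduce_between_df(self, rng):
        # the study's df pattern: N=104 subjects, 3 covariates -> df 99
        df = _metric_table(rng, n_per_group=52, covariates=True)
        res = mixed_anova(df, covariates=["age", "sex", "handscore"])
        assert res.df_group == (1, 99)
        assert res.df_interaction == (1, 102)

    def test_unbalanced_hemispheres_rejected(self, rng):
        df = _metric_table(rng).iloc[:-1]  # drop one hemisphere row
        with pytest.raises(ValueError):
            mixed_anova(df)

    def test_tiny_group_rejected(self, rng):
        df = _metric_table(rng, n_per_group=6)
        df = df[(df.group == "NC") | (df.subject_id == "s6")]
        with pytest.raises(ValueError):
            mixed_anova(df)


class TestPosthoc:
    def test_identical_hemispheres_give_t0_p1(self, rng):
        df = _metric_table(rng)
        wide = df.pivot_table(
            index=["subject_id", "group"], columns="hemisphere", values="value"
        ).reset_index()
        wide["R"] = wide["L"]
        long = wide.melt(
            id_vars=["subject_id", "group"], value_vars=["L", "R"],
            var_name="hemisphere", value_name="value",
        )
        res = posthoc_tests(long)
        paired = res[res.comparison == "hemisphere"]
        assert np.allclose(paired["t"], 0.0)
        assert np.allclose(paired["p"], 1.0)

    def test_paired_t_equals_one_sample_t_of_differences(self, rng):
        df = _metric_table(rng, hemi_shift=0.8)
        res = posthoc_tests(df)
        wide = df.pivot_table(
            index=["subject_id", "group"], columns="hemisphere", values="value"
        ).reset_index()
        for grp in ("NC", "BD"):
            d = wide.loc[wide.group == grp, "R"] - wide.loc[wide.group == grp, "L"]
            expected = sps.ttest_1samp(d, 0.0)
            got = res[(res.comparison == "hemisphere") & (res.stratum == grp)].iloc[0]
            assert got["t"] == pytest.approx(expected.statistic, rel=1e-10)
            assert got["p"] == pytest.approx(expected.pvalue, rel=1e-10)

    def test_independent_t_matches_scipy_without_covariates(self, rng):
        df = _metric_table(rng, group_shift=1.0)
        res = posthoc_tests(df)
        wide = df.pivot_table(
            index=["subject_id", "group"], columns="hemisphere", values="value"
        ).reset_index()
        for hemi in ("L", "R"):
            x = wide.loc[wide.group == "NC", hemi]
            y = wide.loc[wide.group == "BD", hemi]
            expected = sps.ttest_ind(x, y)
            got = res[(res.comparison == "group") & (res.stratum == hemi)].iloc[0]
            assert got["t"] == pytest.approx(expected.statistic, rel=1e-10)


class TestAsymmetryTests:
    def test_zero_as_gives_t0(self):
        rec = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)],
             "group": ["NC"] * 10, "as_value": [0.0] * 10}
        )
        res = asymmetry_tests(rec)
        one = res[res.comparison == "one_sample"].iloc[0]
        assert one["t"] == 0.0

    def test_df_is_n_minus_one(self, rng):
        # a 55-subject group tests on 54 degrees of freedom
        rec = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(55)],
             "group": ["NC"] * 55, "as_value": rng.normal(0, 5, 55)}
        )
        res = asymmetry_tests(rec)
        assert int(res[res.comparison == "one_sample"].iloc[0]["df"]) == 54

    def test_power_at_moderate_effect(self):
        # AS ~ N(5, 5), n=50: one-sample t rejects essentially always
        rej = 0
        n_rep = 500
        for s in range(n_rep):
            r = np.random.default_rng(s)
            rec = pd.DataFrame(
                {"subject_id": [f"s{i}" for i in range(50)],
                 "group": ["BD"] * 50, "as_value": r.normal(5, 5, 50)}
            )
            res = asymmetry_tests(rec)
            if res[res.comparison == "one_sample"].iloc[0]["p"] < 0.05:
                rej += 1
        assert rej / n_rep >= 0.99

    def test_all_missing_skipped_with_warning(self):
        rec = pd.DataFrame(
            {"subject_id": ["a", "b"], "group": ["NC", "NC"],
             "as_value": [np.nan, np.nan]}
        )
        with pytest.warns(UserWarning, match="missing"):
            res = asymmetry_tests(rec)
        assert res.empty


class TestBonferroni:
    def test_direct_arithmetic(self):
        assert bonferroni(0.001, 45) == pytest.approx(0.045)

    def test_capped_at_one(self):
        assert bonferroni(0.5, 45) == 1.0

    def test_m_one_is_identity(self):
        assert bonferroni(0.0123, 1) == pytest.approx(0.0123)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    @settings(max_examples=100, derandomize=True)
    @given(p=st_h.floats(0, 1), m1=st_h.integers(1, 100), m2=st_h.integers(1, 100))
    def test_never_decreases_and_monotone_in_m(self, p, m1, m2):
        assert bonferroni(p, m1) >= p
        if m1 <= m2:
            assert bonferroni(p, m1) <= bonferroni(p, m2)


class TestPartialSpearman:
    def test_constant_covariate_reduces_to_plain_spearman(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, _ = partial_spearman(x, y, covariates=np.ones((40, 1)))
        expected = sps.spearmanr(x, y).statistic
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_monotone_function_gives_rho_one(self, rng):
        x = rng.normal(size=30)
        rho, p = partial_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(size=35)
            y = rng.normal(size=35)
            cov = rng.normal(size=(35, 2))
            rho, _ = partial_spearman(x, y, covariates=cov)
            assert rho == pytest.approx(
                partial_spearman_bruteforce(x, y, cov), abs=1e-12
            )

    def test_invariant_to_monotone_transforms(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        cov = rng.normal(size=(40, 1))
        rho1, _ = partial_spearman(x, y, covariates=cov)
        rho2, _ = partial_spearman(np.exp(x), y**3, covariates=cov)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_input_gives_nan_with_warning(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = partial_spearman(np.ones(10), rng.normal(size=10))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_spearman([1, 2, 3], [3, 2, 1])


class TestEdgewiseCensus:
    def _setup(self, rng, n_sub=20, n_nodes=20):
        net = random_network(n_nodes, 0.4, rng)
        hubs = select_hubs(net, fraction=0.2)
        cls = _full_classification(n_nodes, hubs)
        base = net.weights[cls.i_idx, cls.j_idx]
        left = base * rng.lognormal(0, 0.1, (n_sub, len(base)))
        right = base * rng.lognormal(0, 0.1, (n_sub, len(base)))
        groups = np.array(["NC"] * (n_sub // 2) + ["BD"] * (n_sub - n_sub // 2))
        return cls, left, right, groups

    def test_identical_cohorts_nothing_significant(self, rng):
        cls, left, right, groups = self._setup(rng)
        # make BD an exact copy of NC: group t is identically zero
        half = len(groups) // 2
        left[half:] = left[:half]
        right[half:] = right[:half]
        out = edgewise_census(left, right, groups, cls)
        grp = out[out.effect.isin(["group", "asymmetry_group"])]
        assert int(grp["n_significant"].sum()) == 0

    def test_injected_local_effect_localizes(self, rng):
        cls, left, right, groups = self._setup(rng, n_sub=40)
        local = cls.mask("local")
        bd = groups == "BD"
        left[np.ix_(bd, local)] *= 0.6
        right[np.ix_(bd, local)] *= 0.6
        out = edgewise_census(left, right, groups, cls)
        grp = out[out.effect == "group"].set_index("class")
        assert (
            grp.loc["local", "proportion_pct"]
            > max(grp.loc["feeder", "proportion_pct"], grp.loc["rich_club", "proportion_pct"])
        )

    def test_counts_sum_per_effect(self, rng):
        cls, left, right, groups = self._setup(rng)
        out = edgewise_census(left, right, groups, cls)
        for _eff, sub in out.groupby("effect"):
            assert sub["n_total"].sum() == cls.n_edges
            assert sub["n_significant"].sum() == sub["n_significant"].clip(lower=0).sum()

    def test_fdr_correction_is_more_conservative(self, rng):
        cls, left, right, groups = self._setup(rng, n_sub=40)
        local = cls.mask("local")
        bd = groups == "BD"
        left[np.ix_(bd, local)] *= 0.8
        right[np.ix_(bd, local)] *= 0.8
        raw = edgewise_census(left, right, groups, cls)
        fdr = edgewise_census(left, right, groups, cls, correction="fdr_bh")
        assert (
            fdr["n_significant"].sum() <= raw["n_significant"].sum()
        )
        with pytest.raises(ValueError):
            edgewise_census(left, right, groups, cls, correction="holm")

    def test_misaligned_edges_rejected(self, rng):
        cls, left, right, groups = self._setup(rng)
        with pytest.raises(ValueError):
            edgewise_census(left[:, :-1], right[:, :-1], groups, cls)
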