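"""Nested/one-way ANOVA, Tukey-Kramer HSD and relative-trait summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bergerac.phenostats import (nested_anova, oneway_anova, pearson_test,
                                 relative_change, tukey_kramer)
from bergerac.simulate import PhenotypeDesign, simulate_phenotypes
from bergerac.te_calls import round_half_up


def balanced_frame(rng, a=4, b=5, n=5, group_effects=None, s_line=1.0, s_err=1.0):
    rows = []
    effects = group_effects or [10.0 * i for i in range(a)]
    for gi in range(a):
        for li in range(b):
            line_eff = rng.normal(0, s_line)
            for si in range(n):
                rows.append({
                    "strain": f"g{gi}", "line": f"g{gi}_l{li}", "subline": f"s{si}",
                    "value": effects[gi] + line_eff + rng.normal(0, s_err),
                })
    return pd.DataFrame(rows)


class TestNestedAnova:
    def test_balanced_matches_closed_forms(self):
        """Balanced 4x5x5 design: SS/MS/F match the textbook balanced
        formulas to 1e-9 and the quasi-F reduces to MS_groups/MS_lines."""
        rng = np.random.default_rng(17)
        df = balanced_frame(rng)
        tab = nested_anova(df)
        y = df["value"].to_numpy()
        grand = y.mean()
        gmeans = df.groupby("strain")["value"].mean()
        lmeans = df.groupby(["strain", "line"])["value"].mean()
        b, n = 5, 5
        ss_groups = b * n * ((gmeans - grand) ** 2).sum()
        ss_lines = n * sum(
            (lmeans[g] - gmeans[g]).pow(2).sum() for g in gmeans.index)
        cell = df.groupby(["strain", "line"])["value"].transform("mean")
        ss_within = ((y - cell) ** 2).sum()
        assert tab.ss_groups == pytest.approx(ss_groups, abs=1e-9 * ss_groups)
        assert tab.ss_subgroups == pytest.approx(ss_lines, rel=1e-9)
        assert tab.ss_within == pytest.approx(ss_within, rel=1e-9)
        assert (tab.df_groups, tab.df_subgroups, tab.df_within) == (3, 16, 80)
        assert tab.f_s == pytest.approx(tab.ms_groups / tab.ms_within, rel=1e-12)
        # balanced quasi-F collapses to the exact among-lines denominator
        assert tab.f_s_prime == pytest.approx(
            tab.ms_groups / tab.ms_subgroups, rel=1e-9)
        assert tab.df_denom_prime == pytest.approx(16.0, rel=1e-9)

    def test_ss_decomposition_exact(self):
        rng = np.random.default_rng(29)
        df = simulate_phenotypes(PhenotypeDesign(dropout=0.2), rng)
        tab = nested_anova(df)
        y = df["value"].to_numpy()
        assert tab.ss_total == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-10)
        assert tab.df_groups + tab.df_subgroups + tab.df_within == len(df) - 1

    def test_published_table_arithmetic(self):
        """The printed source tables obey MS = SS/df and F = MS ratio:
        productivity among-groups 3,069,207/3 -> 1,023,069 and
        F = MS_groups/MS_within ~ 403.8 with MS_within 2,533."""
        ms_groups = 3_069_207 / 3
        assert round_half_up(ms_groups) == 1_023_069
        assert ms_groups / 2533 == pytest.approx(403.83, abs=0.1)

    def test_null_type_i_error(self):
        """No strain or line effects at the study design sizes: the
        quasi-F group test rejects at ~alpha over 1,000 replicates."""
        rng = np.random.default_rng(555)
        design = PhenotypeDesign(
            group_effects={"a": 0.0, "b": 0.0, "c": 0.0, "d": 0.0},
            lines_per_group={"a": 15, "b": 20, "c": 20, "d": 20},
            sigma2_line=1.0, sigma2_error=1.0,
        )
        rejections = 0
        reps = 1000
        for _ in range(reps):
            tab = nested_anova(simulate_phenotypes(design, rng))
            rejections += tab.p_groups_fs_prime < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_variance_component_recovery(self):
        """Method-of-moments recovery of (sigma2_strain, sigma2_line,
        sigma2_error) = (4, 1, 1) within 20% over 200 replicates."""
        rng = np.random.default_rng(314)
        comps = []
        for _ in range(200):
            effects = {g: rng.normal(0, 2.0) for g in ("a", "b", "c", "d")}
            design = PhenotypeDesign(
                group_effects=effects,
                lines_per_group={"a": 15, "b": 20, "c": 20, "d": 20},
                sigma2_line=1.0, sigma2_error=1.0,
            )
            tab = nested_anova(simulate_phenotypes(design, rng))
            vc = tab.variance_components()
            comps.append([vc["group"], vc["subgroup"], vc["error"]])
        mean = np.mean(comps, axis=0)
        for est, truth in zip(mean, (4.0, 1.0, 1.0)):
            assert abs(est - truth) / truth < 0.20

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(2718)
        rates = []
        for delta in (0.0, 0.5, 1.5):
            design = PhenotypeDesign(
                group_effects={"a": 0.0, "b": delta, "c": 0.0, "d": delta},
                lines_per_group={g: 8 for g in "abcd"},
                sigma2_line=1.0, sigma2_error=1.0,
            )
            rej = sum(
                nested_anova(simulate_phenotypes(design, rng)).p_groups_fs_prime < 0.05
                for _ in range(60)
            )
            rates.append(rej / 60)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame({
            "strain": ["a"] * 4 + ["b"],
            "line": ["a1", "a1", "a2", "a2", "b1"],
            "value": [1.0, 2.0, 3.0, 4.0, 5.0],
        })
        with pytest.raises(ValueError, match="single observation"):
            nested_anova(df)
        const = pd.DataFrame({
            "strain": ["a"] * 4 + ["b"] * 4,
            "line": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
            "value": [1.0] * 8,
        })
        with pytest.raises(ValueError, match="zero total variance"):
            nested_anova(const)


class TestTukeyKramer:
    def test_identical_means_not_significant(self):
        df = pd.DataFrame({
            "strain": ["a"] * 3 + ["b"] * 3,
            "value": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        })
        pairs = tukey_kramer(df, error_ms=1.0, error_df=4)
        assert pairs[0].q == pytest.approx(0.0)
        assert pairs[0].p == pytest.approx(1.0)
        assert not pairs[0].significant

    def test_q_equals_sqrt2_times_t_for_two_equal_groups(self):
        # algebraic identity on a hand-checkable 3-point-per-group example
        df = pd.DataFrame({
            "strain": ["a"] * 3 + ["b"] * 3,
            "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        _, _, _, table = oneway_anova(df)
        ms_within = table.loc[1, "MS"]
        pairs = tukey_kramer(df, error_ms=ms_within, error_df=4)
        t_stat = stats.ttest_ind(df[df.strain == "b"].value,
                                 df[df.strain == "a"].value).statistic
        assert pairs[0].q == pytest.approx(np.sqrt(2) * abs(t_stat), rel=1e-10)

    def test_experimentwise_error_near_alpha(self):
        """Null data: probability that any pair is flagged stays near the
        5% experiment-wise level."""
        rng = np.random.default_rng(161)
        any_sig = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame({
                "strain": np.repeat(list("abcd"), 10),
                "value": rng.normal(size=40),
            })
            _, (df1, df2), _, table = oneway_anova(df)
            pairs = tukey_kramer(df, error_ms=table.loc[1, "MS"], error_df=df2)
            any_sig += any(p.significant for p in pairs)
        assert 0.02 <= any_sig / reps <= 0.08

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"strain": ["a", "a"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            tukey_kramer(df, error_ms=1.0, error_df=2)


class TestOnewayAnova:
    def test_published_table_arithmetic(self):
        # speed: among-groups 96,109/3 -> 32,036; over within-MS 852 -> ~37.6
        ms = 96_109 / 3
        assert round_half_up(ms) == 32_036
        assert ms / 852 == pytest.approx(37.57, abs=0.05)

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({
            "strain": np.repeat(list("abcd"), 10),
            "value": rng.normal(np.repeat([0, 1, 2, 3], 10), 1.0),
        })
        f, (df1, df2), p, table = oneway_anova(df)
        f_scipy, p_scipy = stats.f_oneway(
            *[df[df.strain == g].value for g in "abcd"])
        assert f == pytest.approx(f_scipy, rel=1e-12)
        assert p == pytest.approx(p_scipy, rel=1e-9)
        assert (df1, df2) == (3, 36)

    def test_constant_data_rejected(self):
        df = pd.DataFrame({"strain": ["a", "a", "b", "b"], "value": [1.0] * 4})
        with pytest.raises(ValueError):
            oneway_anova(df)


class TestPearsonAndRelativeChange:
    def test_collinear(self):
        r, p = pearson_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        r, p = pearson_test(x, y)
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(271)
        pvals = [pearson_test(rng.normal(size=30), rng.normal(size=30))[1]
                 for _ in range(300)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.parametrize("treat,ctrl,pct", [
        (42.3, 308.7, 86),   # largest productivity reduction
        (83.2, 98.1, 15),    # largest survivorship reduction
        (100.0, 100.0, 0),
    ])
    def test_relative_reduction_display(self, treat, ctrl, pct):
        assert round_half_up(relative_change(treat, ctrl, "reduction")) == pct

    def test_increase_direction_and_zero_control(self):
        assert relative_change(150, 100, "increase") == pytest.approx(50.0)
        with pytest.raises(ValueError):
            relative_change(1.0, 0.0)
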