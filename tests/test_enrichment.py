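"""Observed-vs-expected statistics, exact tests and multiple-testing control."""

import numpy as np
import pytest
from scipy import stats

from bergerac.enrichment import (CategoryCounts, binary_category_counts, chisq_gof,
                                 classify_sites, enrich_test, expected_from_exposure,
                                 fisher_exact_2x2, fold_enrichment, g_test,
                                 holm_bonferroni, r_squared)
from bergerac.genome import FeatureTrack, Interval


class TestExpected:
    def test_equal_exposure(self):
        cc = CategoryCounts(["A", "B"], [10, 10], [1, 1])
        assert expected_from_exposure(cc) == pytest.approx([10, 10])

    def test_genome_domain_proportions(self):
        # arms/cores/tips cover 45.7/47/7.3% of the genome: 100 insertions
        # expect 45.7/47/7.3 under the length model
        cc = CategoryCounts(["arm", "core", "tip"], [40, 50, 10], [45.7, 47.0, 7.3])
        assert expected_from_exposure(cc) == pytest.approx([45.7, 47.0, 7.3])

    def test_total_conservation(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = rng.integers(2, 8)
            obs = rng.integers(0, 100, size=k)
            if obs.sum() == 0:
                obs[0] = 1
            exp = rng.uniform(0.1, 10, size=k)
            cc = CategoryCounts([f"c{i}" for i in range(k)], obs, exp)
            assert expected_from_exposure(cc).sum() == pytest.approx(
                obs.sum(), abs=1e-9)


class TestChisq:
    def test_perfect_fit(self):
        chi2, df, p = chisq_gof([10, 20, 30], [10, 20, 30])
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and df == 2

    def test_hand_computed(self):
        chi2, df, p = chisq_gof([10, 20], [15, 15])
        assert chi2 == pytest.approx(10 / 3)
        assert df == 1

    def test_warns_on_small_expected(self):
        with pytest.warns(UserWarning, match="below 5"):
            chisq_gof([3, 30], [2, 31])

    def test_null_type_i_error(self):
        """1,000 multinomial draws from E: rejection at alpha = 0.05
        lands in [0.035, 0.065]."""
        rng = np.random.default_rng(2024)
        probs = np.array([0.457, 0.47, 0.073])
        n, reps = 400, 1000
        draws = rng.multinomial(n, probs, size=reps)
        expected = n * probs
        stat = ((draws - expected) ** 2 / expected).sum(axis=1)
        pvals = stats.chi2.sf(stat, df=2)
        # cross-check the vectorized null against the implementation on a few draws
        for row in draws[:5]:
            chi2, df, p = chisq_gof(row, expected)
            assert chi2 == pytest.approx(((row - expected) ** 2 / expected).sum())
        rate = float((pvals < 0.05).mean())
        assert 0.035 <= rate <= 0.065


class TestGTest:
    def test_proportional_rows_give_zero(self):
        g, df, p = g_test([[10, 20, 30], [20, 40, 60]])
        assert g == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        table = np.array([[10.0, 20.0], [20.0, 10.0]])
        expected = np.array([[15.0, 15.0], [15.0, 15.0]])
        g_hand = 2 * (table * np.log(table / expected)).sum()
        g, df, p = g_test(table)
        assert g == pytest.approx(g_hand, rel=1e-12)
        assert df == 1

    def test_zero_cells_contribute_zero(self):
        g, df, p = g_test([[0, 10], [10, 10]])
        assert np.isfinite(g) and g > 0

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            g_test([[0, 0], [5, 5]])

    def test_null_type_i_error(self):
        """G on 2x3 tables simulated under independence keeps type-I
        error near alpha."""
        rng = np.random.default_rng(4096)
        row_p = np.array([0.5, 0.5])
        col_p = np.array([0.3, 0.3, 0.4])
        cell_p = np.outer(row_p, col_p).ravel()
        reps, n = 1000, 600
        rejections = 0
        for counts in rng.multinomial(n, cell_p, size=reps):
            table = counts.reshape(2, 3)
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, _, p = g_test(table)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_chisq_and_g_agree_asymptotically(self):
        """With all expected cells >= 50, |chi2 - G|/chi2 < 5% in >= 95%
        of seeded multinomial draws."""
        rng = np.random.default_rng(888)
        probs = np.array([0.25, 0.35, 0.4])
        n, reps = 1000, 500
        ok = 0
        for counts in rng.multinomial(n, probs, size=reps):
            exp = n * probs
            chi2 = ((counts - exp) ** 2 / exp).sum()
            nz = counts > 0
            g = 2 * (counts[nz] * np.log(counts[nz] / exp[nz])).sum()
            if chi2 == 0 or abs(chi2 - g) / chi2 < 0.05:
                ok += 1
        assert ok / reps >= 0.95


class TestFisher:
    def test_extreme_table(self):
        # full enumeration over C(10,5) = 252 tables: only the two
        # diagonal extremes are as extreme -> p = 2/252
        assert fisher_exact_2x2([[0, 5], [5, 0]]) == pytest.approx(2 / 252)

    def test_identical_rows(self):
        assert fisher_exact_2x2([[7, 3], [7, 3]]) == pytest.approx(1.0)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    def test_matches_enumeration_oracle(self):
        """Two-sided point-probability p equals brute-force hypergeometric
        enumeration on 100 random small tables."""
        rng = np.random.default_rng(321)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0:
                continue
            r1, r2 = a + b, c + d
            c1 = a + c
            n = table.sum()
            lo, hi = max(0, c1 - r2), min(r1, c1)
            pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
            p_obs = pmf[a]
            p_oracle = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-7))
            assert fisher_exact_2x2(table) == pytest.approx(
                min(p_oracle, 1.0), abs=1e-12)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.04]) == pytest.approx([0.04])

    def test_step_down_hand_computation(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_adjusted_dominates_raw_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, size=25)
        adj = holm_bonferroni(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestClassifySites:
    def test_exon_precedence_over_intron(self):
        exon = FeatureTrack.from_intervals("exon", [Interval("chrI", 100, 200)])
        intron = FeatureTrack.from_intervals("intron", [Interval("chrI", 50, 250)])
        counts = classify_sites([Interval("chrI", 150, 151)], exon, intron)
        assert counts == {"exon": 1, "intron": 0, "intergenic": 0}

    def test_intron_exclusive_and_intergenic(self):
        exon = FeatureTrack.from_intervals("exon", [Interval("chrI", 100, 200)])
        intron = FeatureTrack.from_intervals("intron", [Interval("chrI", 50, 250)])
        calls = [Interval("chrI", 60, 61), Interval("chrI", 300, 301)]
        counts = classify_sites(calls, exon, intron)
        assert counts == {"exon": 0, "intron": 1, "intergenic": 1}

    def test_counts_sum_and_match_mask_oracle(self):
        rng = np.random.default_rng(14)
        exon_ivs = [Interval("chrI", int(s), int(s) + 50)
                    for s in rng.integers(0, 9000, size=30)]
        intron_ivs = [Interval("chrI", int(s), int(s) + 80)
                      for s in rng.integers(0, 9000, size=30)]
        exon = FeatureTrack.from_intervals("exon", exon_ivs)
        intron = FeatureTrack.from_intervals("intron", intron_ivs)
        calls = [Interval("chrI", int(p), int(p) + 1)
                 for p in rng.integers(0, 10_000, size=200)]
        counts = classify_sites(calls, exon, intron)
        assert sum(counts.values()) == len(calls)
        exon_mask = np.zeros(10_000, dtype=bool)
        intron_mask = np.zeros(10_000, dtype=bool)
        for iv in exon.intervals:
            exon_mask[iv.start:iv.end] = True
        for iv in intron.intervals:
            intron_mask[iv.start:iv.end] = True
        oracle = {"exon": 0, "intron": 0, "intergenic": 0}
        for c in calls:
            if exon_mask[c.start]:
                oracle["exon"] += 1
            elif intron_mask[c.start]:
                oracle["intron"] += 1
            else:
                oracle["intergenic"] += 1
        assert counts == oracle


class TestFoldAndCorrelation:
    def test_fold(self):
        assert fold_enrichment([148], [100]) == pytest.approx([1.48])
        assert fold_enrichment([10], [10]) == pytest.approx([1.0])

    def test_r_squared_exact_line(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x) == pytest.approx(1.0)

    def test_r_squared_independent_near_zero(self):
        rng = np.random.default_rng(77)
        assert r_squared(rng.normal(size=5000), rng.normal(size=5000)) < 0.01

    def test_r_squared_hand_computed(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 7, 8])
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        oracle = sxy ** 2 / (((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r_squared(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_r_squared_degenerate_inputs(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])


class TestEnrichTest:
    def test_planted_excess_recovered(self):
        # observed 148 in a category expected to hold 100 of 248: +48%
        cc = CategoryCounts(["inside", "outside"], [148, 100],
                            [100.0, 148.0])
        res = enrich_test(cc)
        assert res.expected[0] == pytest.approx(100.0)
        assert (res.fold[0] - 1) * 100 == pytest.approx(48.0)
        assert res.expected.sum() == pytest.approx(res.observed.sum())

    def test_binary_counts_from_track(self):
        track = FeatureTrack.from_intervals("state", [Interval("chrI", 0, 2500)])
        calls = [Interval("chrI", int(p), int(p) + 1) for p in range(0, 10_000, 100)]
        cc = binary_category_counts(calls, track, genome_bp=10_000, label="state")
        assert cc.observed[0] == 25 and cc.observed[1] == 75
        assert cc.exposure[0] == 2500 and cc.exposure[1] == 7500
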