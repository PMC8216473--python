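"""Benchmark statistics: precision, Wilcoxon, Spearman, quantile normalization."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agoclip.duplex import ImportedSite
from agoclip.io_formats import GenomicInterval
from agoclip.occupancy import BindingSite
from agoclip.peaks import Peak
from agoclip.evaluation import (
    multiplicity_promiscuity,
    precision_distances,
    quantile_normalize,
    sensitivity_summary,
    site_spacing,
    spearman_rho,
    specificity_test,
    top_expressed_mirnas,
    wilcoxon_signed_rank,
)


def brute_wilcoxon(x, y, alternative="greater"):
    """Exact one-sided p by enumerating all 2^n sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if alternative == "less":
        d = -d
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            n_ge += 1
    return n_ge / 2**n


def make_site(peak_id, start, end, mirnas=("m1",)):
    siv = GenomicInterval(peak_id, start, end, "+")
    coalitions = [ImportedSite(peak_id, m, siv, 1.0) for m in mirnas]
    return BindingSite(peak_id=peak_id, site_iv=siv, coalitions=coalitions)


class TestPrecisionDistances:
    def test_worked_example(self):
        # peak [0,80): midpoint 39; site [25,45): midpoint 34 -> distance 5
        peaks = {"p1": Peak(GenomicInterval("c", 0, 80, "+"), "p1")}
        sites = [make_site("p1", 25, 45)]
        assert precision_distances(sites, peaks) == [5]

    def test_centered_site_distance_zero(self):
        peaks = {"p1": Peak(GenomicInterval("c", 0, 80, "+"), "p1")}
        sites = [make_site("p1", 25, 55)]  # midpoint (25+54)//2 = 39
        assert precision_distances(sites, peaks) == [0]

    def test_strand_independent_30nt_case(self):
        # same coordinates on +/- strands give identical distances
        for strand in "+-":
            peaks = {"p1": Peak(GenomicInterval("c", 100, 130, strand), "p1")}
            siv = GenomicInterval("c", 100, 110, strand)
            site = BindingSite("p1", siv, [ImportedSite("p1", "m", siv, 1.0)])
            # peak midpoint (100+129)//2=114, site midpoint (100+109)//2=104
            assert precision_distances([site], peaks) == [10]

    def test_unknown_peak_rejected(self):
        with pytest.raises(ValueError):
            precision_distances([make_site("ghost", 0, 10)], {})


class TestWilcoxonSignedRank:
    def test_six_concordant_pairs_give_one_sixtyfourth(self):
        x = [5, 6, 7, 8, 9, 10]
        y = [1, 2, 3, 4, 5, 6]
        assert wilcoxon_signed_rank(x, y) == pytest.approx(1 / 64)

    def test_all_discordant_gives_one(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [5, 6, 7, 8, 9, 10]
        assert wilcoxon_signed_rank(x, y) == pytest.approx(1.0)

    def test_all_zero_differences_warns_p_one(self):
        with pytest.warns(UserWarning):
            p = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_matches_scipy_exact_no_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.normal(0.5, 1.0, size=n)
            y = rng.normal(0.0, 1.0, size=n)
            p = wilcoxon_signed_rank(x, y)
            ref = stats.wilcoxon(x, y, alternative="greater", mode="exact").pvalue
            assert p == pytest.approx(ref, abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if np.all(x == y):
                with pytest.warns(UserWarning):
                    p = wilcoxon_signed_rank(x, y)
            else:
                p = wilcoxon_signed_rank(x, y)
            assert p == pytest.approx(brute_wilcoxon(x, y), abs=1e-12)

    def test_less_alternative_mirrors_greater(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [5, 6, 7, 8, 9, 10]
        assert wilcoxon_signed_rank(x, y, alternative="less") == pytest.approx(1 / 64)

    def test_large_n_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0.3, 1.0, size=60)
        y = rng.normal(0.0, 1.0, size=60)
        p = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(
            x, y, alternative="greater", mode="approx", correction=True
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-6)

    def test_invalid_alternative(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [0.0], alternative="two-sided")


class TestSpecificityTest:
    def test_reference_dominating_every_shuffle(self):
        ref = {f"d{i}": 100 + i for i in range(6)}
        shuf = {f"d{i}": {k: 10 + k for k in range(5)} for i in range(6)}
        pvals = specificity_test(ref, shuf)
        assert set(pvals) == set(range(5))
        for p in pvals.values():
            assert p == pytest.approx(1 / 64)

    def test_requires_five_datasets(self):
        ref = {f"d{i}": 10 for i in range(4)}
        shuf = {f"d{i}": {0: 1} for i in range(4)}
        with pytest.raises(ValueError):
            specificity_test(ref, shuf)


class TestMultiplicityPromiscuity:
    def test_counts_fractions_and_rho(self):
        sites_by_peak = {
            "p1": [make_site("p1", 0, 10)],
            "p2": [make_site("p2", 0, 10), make_site("p2", 20, 30, ("a", "b"))],
            "p3": [
                make_site("p3", 0, 10, ("a", "b")),
                make_site("p3", 20, 30, ("a", "c")),
                make_site("p3", 40, 50),
            ],
            "p4": [make_site("p4", 0, 10)],
        }
        out = multiplicity_promiscuity(sites_by_peak)
        assert out["m"] == [1, 2, 3, 1]
        assert out["promiscuous"] == [0, 1, 2, 0]
        assert out["m_fractions"] == {1: 0.5, 2: 0.25, 3: 0.25}
        assert out["fraction_peaks_promiscuous"] == 0.5
        assert out["total_sites"] == 7
        # interactions: 1 + (1+2) + (2+2+1) + 1 = 10 over 4 peaks
        assert out["normalized_site_count"] == pytest.approx(2.5)
        once = multiplicity_promiscuity(sites_by_peak, count_promiscuous_once=True)
        assert once["normalized_site_count"] == pytest.approx(7 / 4)
        assert out["spearman_rho"] == pytest.approx(
            stats.spearmanr(out["m"], out["promiscuous"]).statistic
        )

    def test_constant_vectors_give_nan_rho(self):
        sites_by_peak = {"p1": [make_site("p1", 0, 10)], "p2": [make_site("p2", 0, 10)]}
        out = multiplicity_promiscuity(sites_by_peak)
        assert math.isnan(out["spearman_rho"])


class TestSpearman:
    def test_tied_example_perfect_anticorrelation(self):
        assert spearman_rho([1, 2, 2, 3], [3, 2, 2, 1]) == pytest.approx(-1.0)

    def test_equals_pearson_of_average_ranks(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            assert spearman_rho(x, y) == pytest.approx(
                np.corrcoef(rx, ry)[0, 1], abs=1e-12
            )


class TestQuantileNormalize:
    def test_two_column_worked_example(self):
        df = pd.DataFrame({"a": [2, 4, 6], "b": [1, 5, 9]})
        out = quantile_normalize(df)
        expected = [1.5, 4.5, 7.5]
        assert list(out["a"]) == pytest.approx(expected)
        assert list(out["b"]) == pytest.approx(expected)

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_ties_get_mean_of_occupied_reference_positions(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[2] == pytest.approx(ref[2])

    def test_columns_share_distribution_after_normalization(self):
        # tie-free columns: every column takes exactly the reference values
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"a": rng.normal(20, 3, 50), "b": rng.normal(60, 9, 50), "c": rng.normal(5, 1, 50)}
        )
        out = quantile_normalize(df)
        sa, sb, sc = (np.sort(out[c].values) for c in "abc")
        assert sa == pytest.approx(sb) and sb == pytest.approx(sc)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        out = quantile_normalize(df)
        for c in df.columns:
            assert list(stats.rankdata(out[c])) == list(stats.rankdata(df[c]))


class TestTopExpressedMirnas:
    def test_ranking_and_alphabetical_tie_break(self):
        counts = {
            "rep1": {"mirC": 100.0, "mirA": 100.0, "mirB": 10.0},
            "rep2": {"mirC": 90.0, "mirA": 90.0, "mirB": 20.0},
        }
        top = top_expressed_mirnas(counts, k=2)
        assert top == ["mirA", "mirC"]

    def test_k_larger_than_available_warns(self):
        counts = {"rep1": {"mirA": 5.0}, "rep2": {"mirA": 7.0}}
        with pytest.warns(UserWarning):
            top = top_expressed_mirnas(counts, k=25)
        assert top == ["mirA"]

    def test_missing_mirna_treated_as_zero(self):
        counts = {"rep1": {"mirA": 5.0, "mirB": 50.0}, "rep2": {"mirB": 60.0}}
        assert top_expressed_mirnas(counts, k=1) == ["mirB"]


class TestSensitivitySummary:
    def test_worked_percentages(self):
        peaks = [
            Peak(GenomicInterval("c", i * 100, i * 100 + 80, "+"), f"p{i}",
                 region="3UTR" if i < 3 else "CDS")
            for i in range(5)
        ]
        sites_by_peak = {
            "p0": [make_site("p0", 0, 10)],
            "p1": [make_site("p1", 0, 10), make_site("p1", 20, 30)],
        }
        s = sensitivity_summary("ds", peaks, sites_by_peak)
        assert s.n_peaks == 5 and s.n_sites == 3
        assert s.sites_per_peak == pytest.approx(0.6)
        assert s.pct_peaks_with_sites == pytest.approx(40.0)
        assert s.region_fractions == {"3UTR": 0.6, "CDS": 0.4}
        assert s.site_region_fractions == {"3UTR": 1.0}


class TestSiteSpacing:
    def test_median_of_per_peak_medians(self):
        sites_by_peak = {
            "p1": [make_site("p1", 0, 10), make_site("p1", 40, 50)],   # 40
            "p2": [make_site("p2", 0, 10), make_site("p2", 80, 90)],   # 80
            "p3": [make_site("p3", 0, 10), make_site("p3", 40, 50)],   # 40
        }
        med, per_peak = site_spacing(sites_by_peak)
        assert per_peak == {"p1": 40.0, "p2": 80.0, "p3": 40.0}
        assert med == 40.0

    def test_overlapping_pairs_excluded(self):
        sites_by_peak = {"p1": [make_site("p1", 0, 20), make_site("p1", 10, 30)]}
        with pytest.warns(UserWarning):
            med, per_peak = site_spacing(sites_by_peak)
        assert math.isnan(med) and per_peak == {}

    def test_single_site_peaks_ignored(self):
        sites_by_peak = {
            "p1": [make_site("p1", 0, 10)],
            "p2": [make_site("p2", 0, 10), make_site("p2", 30, 40)],
        }
        med, per_peak = site_spacing(sites_by_peak)
        assert med == 30.0 and set(per_peak) == {"p2"}
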