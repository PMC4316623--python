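"""Per-SNP statistics, the composite score, and region/gene calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcosel import (
    HaplotypePanel,
    call_regions,
    cms,
    daf,
    delta_daf,
    ehhs,
    empirical_p,
    fst_per_snp,
    ies,
    ln_rsb,
    make_gene_table,
)
from netcosel.scan import (
    SelectionRegion,
    assign_gene,
    assign_gene_lengthfree,
    candidate_genes,
    standardize_lnrsb,
)

from oracles import cms_factor, ehhs_brute, ies_brute, wc_theta_haploid


class TestDaf:
    def test_all_ancestral_column_is_zero(self):
        panel = HaplotypePanel("EAS", "chr1", [100, 200], np.zeros((4, 2), dtype=np.uint8))
        assert daf(panel, 0) == 0.0

    def test_three_of_four_derived(self):
        alleles = np.array([[1, 0], [1, 0], [1, 0], [0, 0]], dtype=np.uint8)
        panel = HaplotypePanel("EAS", "chr1", [100, 200], alleles)
        assert daf(panel, 0) == 0.75


class TestDeltaDaf:
    def test_equal_dafs_zero(self):
        assert delta_daf(0.4, [[0.4], [0.4]])[0] == pytest.approx(0.0)

    def test_mean_of_others_convention(self):
        assert delta_daf(np.array([0.9]), np.array([[0.1], [0.3]]))[0] == pytest.approx(0.7)

    def test_two_population_antisymmetry(self):
        a, b = np.array([0.8]), np.array([[0.3]])
        assert delta_daf(a, b)[0] == pytest.approx(-delta_daf(b[0], [a])[0])


class TestFst:
    @staticmethod
    def _two_pop_panels(count1, count2, n1, n2):
        a1 = np.zeros((n1, 1), dtype=np.uint8)
        a1[:count1, 0] = 1
        a2 = np.zeros((n2, 1), dtype=np.uint8)
        a2[:count2, 0] = 1
        return (
            HaplotypePanel("A", "chr1", [100], a1),
            HaplotypePanel("B", "chr1", [100], a2),
        )

    def test_fixed_difference_is_one(self):
        p1, p2 = self._two_pop_panels(50, 0, 50, 50)
        assert fst_per_snp([p1, p2])[0] == pytest.approx(1.0)

    def test_equal_frequencies_nonpositive(self):
        p1, p2 = self._two_pop_panels(10, 10, 20, 20)
        assert fst_per_snp([p1, p2])[0] <= 0.0

    def test_matches_independent_wc_oracle(self):
        p1, p2 = self._two_pop_panels(8, 2, 10, 10)
        expected = wc_theta_haploid([p1.alleles[:, 0], p2.alleles[:, 0]])
        assert fst_per_snp([p1, p2])[0] == pytest.approx(expected, abs=1e-12)

    @given(
        c1=st.integers(1, 19),
        c2=st.integers(1, 14),
        n1=st.just(20),
        n2=st.just(15),
    )
    @settings(max_examples=30, deadline=None)
    def test_oracle_agreement_property(self, c1, c2, n1, n2):
        p1, p2 = self._two_pop_panels(c1, c2, n1, n2)
        expected = wc_theta_haploid([p1.alleles[:, 0], p2.alleles[:, 0]])
        assert fst_per_snp([p1, p2])[0] == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_everywhere_is_nan(self):
        p1, p2 = self._two_pop_panels(0, 0, 10, 10)
        assert np.isnan(fst_per_snp([p1, p2])[0])


class TestEhhs:
    def test_identical_haplotypes_profile_is_one(self):
        alleles = np.tile(np.array([[0, 1, 0, 1]], dtype=np.uint8), (5, 1))
        panel = HaplotypePanel("EAS", "chr1", [1, 2, 3, 4], alleles)
        assert np.allclose(ehhs(panel, 0, +1), 1.0)
        assert np.allclose(ies(panel), 3.0)  # full span, EHHS = 1 throughout

    def test_matches_pair_counting_oracle(self, tiny_panel):
        for core in range(tiny_panel.n_snps):
            for direction in (-1, 1):
                profile = ehhs(tiny_panel, core, direction)
                for step, value in enumerate(profile, start=1):
                    expected = ehhs_brute(tiny_panel.alleles, core, core + direction * step)
                    assert value == pytest.approx(expected)

    def test_profile_non_increasing(self, tiny_panel):
        for core in range(tiny_panel.n_snps):
            profile = ehhs(tiny_panel, core, +1)
            assert np.all(np.diff(profile) <= 1e-12)

    def test_hand_enumerated_four_haplotypes(self):
        # haplotypes: two identical, two distinct over the 3-SNP segment
        alleles = np.array([[1, 0, 1], [1, 0, 1], [0, 0, 1], [1, 1, 1]], dtype=np.uint8)
        panel = HaplotypePanel("EAS", "chr1", [10, 20, 30], alleles)
        profile = ehhs(panel, 0, +1)
        # segment 0..1: pairs identical -> only (h0,h1): 1 of 6
        assert profile[0] == pytest.approx(1 / 6)
        assert profile[1] == pytest.approx(1 / 6)


class TestLnRsb:
    def test_identical_panels_zero_everywhere(self, tiny_panel):
        other = tiny_panel.copy()
        other.population = "CEU"
        raw = ln_rsb(tiny_panel, other)
        assert np.allclose(raw, 0.0)

    def test_matches_brute_force_ies(self, tiny_panel):
        rng = np.random.default_rng(3)
        other_alleles = (rng.random(tiny_panel.alleles.shape) < 0.5).astype(np.uint8)
        other = HaplotypePanel("CEU", "chr1", tiny_panel.positions, other_alleles)
        raw = ln_rsb(tiny_panel, other)
        for snp in range(tiny_panel.n_snps):
            ies_t = ies_brute(tiny_panel.alleles, tiny_panel.positions, snp)
            ies_o = ies_brute(other.alleles, other.positions, snp)
            assert raw[snp] == pytest.approx(np.log(ies_t / ies_o))

    def test_standardized_median_zero_sd_one(self):
        rng = np.random.default_rng(5)
        raw = rng.normal(2.0, 3.0, size=500)
        std = standardize_lnrsb(raw)
        assert np.median(std) == pytest.approx(0.0, abs=1e-12)
        assert std.std() == pytest.approx(1.0)


class TestEmpiricalP:
    def test_maximum_of_nine(self):
        values = np.arange(9, dtype=float)
        p = empirical_p(values)
        assert p[-1] == pytest.approx(1 / 10)

    def test_all_tied_gives_half(self):
        p = empirical_p(np.full(7, 3.3))
        assert np.allclose(p, 0.5)

    def test_shuffle_is_permutation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=50)
        p = empirical_p(values)
        perm = rng.permutation(50)
        assert np.allclose(np.sort(empirical_p(values[perm])), np.sort(p))

    def test_open_unit_interval(self):
        p = empirical_p(np.arange(100, dtype=float))
        assert np.all((p > 0) & (p < 1))


class TestCms:
    def test_symmetry_point_p_equals_pi(self):
        assert cms_factor(0.01, 0.01) == pytest.approx(0.5)
        assert cms(np.array([0.01]), pi=0.01, form="odds") == pytest.approx(1.0)
        assert cms(np.array([0.01]), pi=0.01, form="posterior") == pytest.approx(0.5)

    def test_prior_to_zero_kills_score(self):
        p = np.array([0.2])
        scores = [cms(p, pi=eps, form="odds") for eps in (1e-3, 1e-6, 1e-9)]
        assert scores[0] > scores[1] > scores[2]
        assert scores[2] < 1e-6

    def test_four_test_worked_example_both_forms(self):
        p = np.array([0.001, 0.01, 0.05, 0.2])
        fs = np.array([cms_factor(x, 0.01) for x in p])
        assert cms(p, pi=0.01, form="posterior") == pytest.approx(np.prod(fs))
        assert cms(p, pi=0.01, form="odds") == pytest.approx(np.prod(fs / (1 - fs)))
        assert cms(p, pi=0.01, form="log10") == pytest.approx(
            np.log10(np.prod(fs / (1 - fs)))
        )

    @given(
        p=st.lists(st.floats(0.001, 0.999), min_size=2, max_size=6),
        which=st.integers(0, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_in_each_p(self, p, which):
        which = which % len(p)
        base = cms(np.array(p))
        lowered = list(p)
        lowered[which] *= 0.5
        assert cms(np.array(lowered)) > base

    def test_rejects_boundary_p(self):
        with pytest.raises(ValueError):
            cms(np.array([0.0, 0.5]))

    def test_missing_any_statistic_gives_nan(self):
        p = np.array([[0.1, np.nan], [0.2, 0.2]])
        out = cms(p)
        assert np.isfinite(out[0]) and np.isnan(out[1])


def stats_table(positions, scores, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "cms": scores})


class TestCallRegions:
    def test_chain_and_drop_singleton(self):
        table = stats_table([100, 5000, 30_000], [12.0, 11.0, 15.0])
        regions = call_regions(table, cms_threshold=10)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 5000)
        assert regions[0].peak_pos == 100

    def test_gap_of_exactly_ten_kb_not_connected(self):
        table = stats_table([1000, 11_000], [12.0, 12.0])
        assert call_regions(table, cms_threshold=10) == []
        table2 = stats_table([1000, 10_999], [12.0, 12.0])
        assert len(call_regions(table2, cms_threshold=10)) == 1

    def test_no_top_snps_empty(self):
        table = stats_table([100, 200], [1.0, 2.0])
        assert call_regions(table, cms_threshold=10) == []

    def test_peak_is_leftmost_max(self):
        table = stats_table([100, 200, 300], [11.0, 20.0, 20.0])
        (region,) = call_regions(table, cms_threshold=10)
        assert region.peak_pos == 200
        assert region.peak_cms == 20.0

    def test_top_fraction_mode(self):
        scores = np.arange(100, dtype=float)
        table = stats_table(100 * (1 + np.arange(100)), scores)
        regions = call_regions(table, cms_threshold=0.05, threshold_mode="top_fraction")
        member_count = sum(r.snp_positions.size for r in regions)
        assert member_count >= 5  # top 5% chained (all within 10 kb here)


def region(chrom, peak, peak_cms=12.0):
    return SelectionRegion(chrom, peak - 50, peak + 50, np.array([peak]), peak, peak_cms)


class TestAssignGene:
    def test_peak_inside_gene_body(self, three_gene_table):
        assert assign_gene(region("chr1", 2_000), three_gene_table) == "GA"

    def test_beyond_twenty_kb_none(self, three_gene_table):
        assert assign_gene(region("chr2", 34_000), three_gene_table) is None

    def test_nearest_boundary_wins(self, three_gene_table):
        # 10 kb downstream of GA's end, 15 kb upstream of GB's start
        assert assign_gene(region("chr1", 15_000), three_gene_table) == "GA"

    def test_duplicate_regions_keep_max_cms(self, three_gene_table):
        regions = [region("chr1", 2_000, 12.0), region("chr1", 3_000, 30.0)]
        out = candidate_genes(regions, three_gene_table, "EAS")
        assert len(out) == 1
        assert out.iloc[0]["peak_cms"] == 30.0


class TestAssignGeneLengthFree:
    def test_within_150kb_assigned(self, three_gene_table):
        # GA midpoint 3000; peak 100 kb away, GB midpoint at 32 kb is nearer
        out = assign_gene_lengthfree([region("chr1", 103_000)], three_gene_table, "EAS")
        assert list(out["gene"]) == ["GB"]

    def test_beyond_150kb_unassigned(self, three_gene_table):
        out = assign_gene_lengthfree([region("chr1", 400_000)], three_gene_table, "EAS")
        assert out.empty

    def test_two_regions_one_gene_dedup(self, three_gene_table):
        regions = [region("chr1", 2_000, 5.0), region("chr1", 4_000, 9.0)]
        out = assign_gene_lengthfree(regions, three_gene_table, "EAS")
        assert len(out) == 1
        assert out.iloc[0]["peak_cms"] == 9.0


class TestNullScanRegions:
    def test_region_positions_uniform_on_null_panels(self):
        """On sweep-free panels region peaks show no positional preference."""
        from scipy.stats import chisquare

        from netcosel import SimConfig, run_scan, simulate_study

        peaks = []
        for seed in range(40):
            cfg = SimConfig(
                n_genes=60, genes_per_chrom=60, snps_per_gene=12,
                n_haplotypes=40, founder_haplotypes=10, n_sweeps=0, seed=1000 + seed,
            )
            study = simulate_study(cfg)
            res = run_scan(study, cms_threshold=0.05)
            peaks.extend(r.peak_pos for r in res.regions)
        span = 60 * (11 * 150 + 25_000)
        counts, _ = np.histogram(peaks, bins=5, range=(0, span))
        assert chisquare(counts).pvalue > 0.01
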