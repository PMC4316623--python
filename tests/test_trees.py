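"""Trifurcate divergence trees, RTD and Syn similarity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netcosel import (
    HaplotypePanel,
    gene_fst,
    rtd,
    syn,
    syn_pairs,
    trifurcate_tree,
)
from netcosel.scan import fst_per_snp
from netcosel.trees import _rtd_pairs, divergence_tree_table, tree_summary

from oracles import wc_theta_haploid

finite = st.floats(-0.2, 1.0, allow_nan=False)


def tree_table(d_values: dict[str, list[float]]) -> pd.DataFrame:
    """Build a minimal tree table from per-population D vectors."""
    n = len(next(iter(d_values.values())))
    return pd.DataFrame(
        {"gene": [f"G{i}" for i in range(n)],
         **{f"d_{p}": v for p, v in d_values.items()}}
    )


class TestTrifurcateTree:
    def test_worked_example(self):
        assert trifurcate_tree(0.10, 0.12, 0.08) == pytest.approx((0.07, 0.03, 0.05))

    def test_symmetric_fst_gives_half(self):
        assert trifurcate_tree(0.3, 0.3, 0.3) == pytest.approx((0.15, 0.15, 0.15))

    @given(f12=finite, f13=finite, f23=finite)
    @settings(max_examples=100, deadline=None)
    def test_additivity_exact(self, f12, f13, f23):
        d1, d2, d3 = trifurcate_tree(f12, f13, f23)
        assert d1 + d2 == pytest.approx(f12, abs=1e-12)
        assert d1 + d3 == pytest.approx(f13, abs=1e-12)
        assert d2 + d3 == pytest.approx(f23, abs=1e-12)


class TestGeneFst:
    @staticmethod
    def _panels(mats):
        return {
            pop: [HaplotypePanel(pop, "chr1", 100 * (1 + np.arange(m.shape[1])), m)]
            for pop, m in mats.items()
        }

    @staticmethod
    def _gene(n_snp):
        return pd.Series({"gene": "G", "chrom": "chr1", "start": 1, "end": 100 * (n_snp + 1)})

    def test_single_snp_reduces_to_per_snp(self):
        rng = np.random.default_rng(1)
        mats = {p: (rng.random((12, 1)) < 0.5).astype(np.uint8) for p in ("A", "B", "C")}
        panels = self._panels(mats)
        out = gene_fst(panels, self._gene(1))
        per_snp = fst_per_snp([panels["A"][0], panels["B"][0]])[0]
        assert out[("A", "B")] == pytest.approx(per_snp)

    def test_two_snp_ratio_of_sums_matches_oracle(self):
        a = np.array([[1, 1], [1, 0], [0, 1], [0, 0], [1, 1], [1, 1]], dtype=np.uint8)
        b = np.array([[0, 0], [0, 1], [0, 0], [1, 0], [0, 0], [0, 0]], dtype=np.uint8)
        c = np.array([[1, 0], [0, 0], [1, 0], [1, 1], [0, 0], [1, 0]], dtype=np.uint8)
        panels = self._panels({"A": a, "B": b, "C": c})
        out = gene_fst(panels, self._gene(2))
        from oracles import wc_theta_ratio_of_sums

        assert out[("A", "B")] == pytest.approx(wc_theta_ratio_of_sums([a, b]), abs=1e-12)
        assert out[("A", "C")] == pytest.approx(wc_theta_ratio_of_sums([a, c]), abs=1e-12)
        assert out[("B", "C")] == pytest.approx(wc_theta_ratio_of_sums([b, c]), abs=1e-12)

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(3)
        mats = {p: (rng.random((10, 6)) < 0.4).astype(np.uint8) for p in ("A", "B", "C")}
        panels = self._panels(mats)
        out1 = gene_fst(panels, self._gene(6))
        flipped = {p: [HaplotypePanel(p, "chr1", panels[p][0].positions,
                                      panels[p][0].alleles[:, ::-1].copy())]
                   for p in panels}
        out2 = gene_fst(flipped, self._gene(6))
        for key in out1:
            assert out1[key] == pytest.approx(out2[key])

    def test_monomorphic_gene_excluded(self):
        mats = {p: np.zeros((8, 3), dtype=np.uint8) for p in ("A", "B", "C")}
        assert gene_fst(self._panels(mats), self._gene(3)) is None


class TestRtd:
    def test_gene_with_itself_is_minimum(self):
        table = tree_table({"A": [0.1, 0.5, 0.9], "B": [0.2, 0.4, 0.6], "C": [0.3, 0.2, 0.1]})
        assert rtd("G0", "G0", table, normalized=False) == 0.0

    def test_hand_computed_ranks(self):
        # population A ranks: G0=1, G1=2, G2=3; B same; C reversed
        table = tree_table({"A": [0.1, 0.5, 0.9], "B": [0.0, 0.3, 0.7], "C": [0.9, 0.5, 0.1]})
        # |1-3| + |1-3| + |3-1| over 3 populations / 3 = 2
        assert rtd("G0", "G2", table, normalized=False) == pytest.approx(2.0)
        assert rtd("G0", "G1", table, normalized=False) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        d = {p: list(rng.random(8)) for p in ("A", "B", "C")}
        table = tree_table(d)
        table2 = tree_table({p: list(np.exp(3 * np.asarray(v))) for p, v in d.items()})
        assert rtd("G1", "G5", table, normalized=False) == pytest.approx(
            rtd("G1", "G5", table2, normalized=False)
        )

    def test_normalized_pairs_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(6)
        table = tree_table({p: list(rng.random(20)) for p in ("A", "B", "C")})
        raw = _rtd_pairs(table)
        normed = (raw - raw.mean()) / raw.std(ddof=0)
        assert normed.mean() == pytest.approx(0.0, abs=1e-12)
        assert normed.std(ddof=0) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        table = tree_table({p: list(rng.random(6)) for p in ("A", "B", "C")})
        assert rtd("G1", "G4", table) == pytest.approx(rtd("G4", "G1", table))


class TestSyn:
    def test_unit_residuals_give_one(self):
        # D values [-1,-1,1,1] in each population: median 0, SD 1
        table = tree_table({p: [-1.0, -1.0, 1.0, 1.0] for p in ("A", "B", "C")})
        assert syn("G2", "G3", table) == pytest.approx(1.0)

    def test_opposite_residuals_give_minus_one(self):
        table = tree_table({p: [-1.0, -1.0, 1.0, 1.0] for p in ("A", "B", "C")})
        assert syn("G0", "G2", table) == pytest.approx(-1.0)

    def test_gene_at_median_gives_zero(self):
        table = tree_table({p: [5.0, 5.0, 3.0, 7.0] for p in ("A", "B", "C")})
        assert syn("G0", "G2", table) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        table = tree_table({p: list(rng.random(7)) for p in ("A", "B", "C")})
        assert syn("G1", "G3", table) == pytest.approx(syn("G3", "G1", table))

    def test_degenerate_cohort_rejected(self):
        table = tree_table({"A": [1.0, 1.0, 1.0], "B": [0.1, 0.2, 0.3], "C": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="degenerate"):
            syn("G0", "G1", table)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        table = tree_table({p: list(rng.random(10)) for p in ("A", "B", "C")})
        pairs = [("G0", "G3"), ("G2", "G7"), ("G5", "G6")]
        vec = syn_pairs(table, pairs)
        for (a, b), v in zip(pairs, vec):
            assert syn(a, b, table) == pytest.approx(v)

    def test_rtd_and_syn_anticorrelated_over_random_cohorts(self):
        """High similarity means low RTD but high Syn: negative rank correlation."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(10)
        rhos = []
        for _ in range(5):
            table = tree_table({p: list(rng.normal(size=15)) for p in ("A", "B", "C")})
            raw_rtd = _rtd_pairs(table)
            genes = list(table["gene"])
            iu = np.triu_indices(len(genes), k=1)
            pairs = [(genes[i], genes[j]) for i, j in zip(*iu)]
            syn_vals = syn_pairs(table, pairs)
            rhos.append(spearmanr(raw_rtd, syn_vals).statistic)
        assert np.mean(rhos) < -0.3


class TestTreeSimilarityProfile:
    @pytest.fixture(scope="class")
    def network_study(self):
        import netcosel

        return netcosel.simulate_study(netcosel.SimConfig(
            n_genes=150, genes_per_chrom=75, snps_per_gene=8, n_haplotypes=30,
            founder_haplotypes=8, n_sweeps=0, seed=33,
        ))

    def test_null_bin_means_within_bands_and_rtd_normalized(self, network_study):
        from netcosel import largest_connected_component, shortest_path_lengths, tree_similarity_vs_spl

        lcc = largest_connected_component(network_study.network)
        spl = shortest_path_lengths(lcc)
        table = divergence_tree_table(network_study.panels, network_study.genes,
                                      restrict_to=set(spl.nodes))
        out = tree_similarity_vs_spl(table, spl, n_perm=100, seed=1)
        prof = out["profile"]
        ok = prof[~prof["low_support"]]
        # a sweep-free cohort should sit inside its own permutation bands
        assert (ok["p_rtd"] > 0.05).mean() >= 0.8
        assert (ok["p_syn"] > 0.05).mean() >= 0.8
        # RTD normalization: pair-count-weighted mean ~ 0
        w = prof["n_pairs"] / prof["n_pairs"].sum()
        assert (prof["mean_rtd"] * w).sum() == pytest.approx(0.0, abs=1e-9)

    def test_reshuffling_null_syn_matches_permutation_expectation(self, network_study):
        """Under the reshuffling null every bin's Syn mean equals the
        distinct-pair expectation sum_i ((sum z)^2 - sum z^2) / (n(n-1)) / 3.

        This is zero only for mean-centered residuals; Syn centers on the
        median, and skewed divergence rates shift every bin by the same
        constant, which the permutation null reproduces exactly.
        """
        from netcosel import largest_connected_component, shortest_path_lengths, tree_similarity_vs_spl
        from scipy.stats import rankdata  # noqa: F401  (parallel import kept light)

        lcc = largest_connected_component(network_study.network)
        spl = shortest_path_lengths(lcc)
        table = divergence_tree_table(network_study.panels, network_study.genes,
                                      restrict_to=set(spl.nodes))
        genes_on_net = table[table["gene"].isin(spl.nodes)]
        d = genes_on_net[[c for c in table.columns if c.startswith("d_")]].to_numpy()
        z = (d - np.median(d, axis=0)) / d.std(axis=0, ddof=0)
        n = z.shape[0]
        expected = np.mean([(z[:, i].sum() ** 2 - (z[:, i] ** 2).sum()) / (n * (n - 1))
                            for i in range(3)])
        out = tree_similarity_vs_spl(table, spl, n_perm=300, seed=2)
        ok = out["profile"][~out["profile"]["low_support"]]
        se = ok["null_syn_sd"] / np.sqrt(300)
        assert ((ok["null_syn_mean"] - expected).abs() < 4 * se + 1e-12).all()

    def test_requires_minimum_network_genes(self, network_study):
        from netcosel import largest_connected_component, shortest_path_lengths, tree_similarity_vs_spl

        lcc = largest_connected_component(network_study.network)
        spl = shortest_path_lengths(lcc)
        table = divergence_tree_table(network_study.panels, network_study.genes.head(20),
                                      restrict_to=set(spl.nodes))
        with pytest.raises(ValueError, match="network genes"):
            tree_similarity_vs_spl(table, spl)


class TestTreeTable:
    def test_additivity_on_simulated_study(self, small_study):
        table = divergence_tree_table(small_study.panels, small_study.genes)
        pops = list(small_study.panels)
        f01 = table[f"fst_{pops[0]}_{pops[1]}"]
        assert np.allclose(table[f"d_{pops[0]}"] + table[f"d_{pops[1]}"], f01, atol=1e-12)

    def test_summary_matches_pandas(self):
        rng = np.random.default_rng(11)
        table = tree_table({p: list(rng.random(9)) for p in ("A", "B", "C")})
        summary = tree_summary(table).set_index("population")
        assert summary.loc["A", "median"] == pytest.approx(table["d_A"].median())
        assert summary.loc["B", "sd"] == pytest.approx(table["d_B"].std(ddof=0))
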