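import numpy as np
import pytest

from netcosel import HaplotypePanel, SimConfig, make_gene_table, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A fast study: 60 genes, 4 sweeps in one planted cluster pair."""
    return SimConfig(
        n_genes=60,
        genes_per_chrom=30,
        snps_per_gene=12,
        n_haplotypes=40,
        founder_haplotypes=10,
        n_sweeps=4,
        n_clusters=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def tiny_panel():
    """6 haplotypes x 5 SNPs, hand-written; used by the worked EHH examples."""
    alleles = np.array(
        [
            [0, 1, 1, 0, 1],
            [0, 1, 1, 0, 1],
            [1, 0, 1, 1, 0],
            [1, 0, 1, 0, 0],
            [0, 1, 0, 0, 1],
            [1, 1, 1, 0, 1],
        ],
        dtype=np.uint8,
    )
    return HaplotypePanel("EAS", "chr1", np.array([100, 600, 1400, 2500, 4000]), alleles)


@pytest.fixture()
def three_gene_table():
    return make_gene_table(
        [
            ("GA", "chr1", 1_000, 5_000),
            ("GB", "chr1", 30_000, 34_000),
            ("GC", "chr2", 1_000, 9_000),
        ]
    )
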