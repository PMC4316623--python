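"""Phased haplotype panels and gene annotation tables.

A :class:`HaplotypePanel` holds the phased haplotypes of one population on one
chromosome, with alleles coded relative to the ancestral state (0 = ancestral,
1 = derived).  All per-SNP selection statistics are computed from this
container.  Gene annotations travel as a plain :class:`pandas.DataFrame` with
columns ``gene, chrom, start, end`` (1-based inclusive coordinates internally;
BED input is converted on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ("gene", "chrom", "start", "end")


@dataclass
class HaplotypePanel:
    """Phased haplotypes of one population over one chromosome.

    Parameters
    ----------
    population : str
        Population label (e.g. ``"EAS"``).
    chrom : str
        Chromosome name.
    positions : ndarray of int
        1-based physical positions, strictly increasing.
    alleles : ndarray of uint8, shape (n_haplotypes, n_snps)
        0 = ancestral allele, 1 = derived allele.
    """

    population: str
    chrom: str
    positions: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x SNP matrix")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions and allele matrix disagree on SNP count")
        if self.alleles.shape[0] < 2:
            raise ValueError("a panel needs at least two haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.max(initial=0) > 1:
            raise ValueError("alleles must be coded 0 (ancestral) / 1 (derived)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.positions.size

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            self.population, self.chrom, self.positions.copy(), self.alleles.copy()
        )


def pool_panels(panels: list[HaplotypePanel], population: str = "pooled") -> HaplotypePanel:
    """Stack the haplotypes of several same-chromosome panels into one panel.

    Used to form the "all other populations" comparison group for the
    cross-population statistics.  Panels must share positions exactly.
    """
    if not panels:
        raise ValueError("no panels to pool")
    first = panels[0]
    for p in panels[1:]:
        if p.chrom != first.chrom or not np.array_equal(p.positions, first.positions):
            raise ValueError("pooled panels must share chromosome and positions")
    alleles = np.vstack([p.alleles for p in panels])
    return HaplotypePanel(population, first.chrom, first.positions.copy(), alleles)


def make_gene_table(records: list[tuple[str, str, int, int]]) -> pd.DataFrame:
    """Build a gene annotation table from ``(gene, chrom, start, end)`` records.

    Coordinates are 1-based inclusive.  A ``midpoint`` column is added; gene
    midpoints drive the length-free candidate assignment and the cis-edge
    filter of the network analysis.
    """
    df = pd.DataFrame(records, columns=list(GENE_COLUMNS))
    return finish_gene_table(df)


def finish_gene_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if (df["end"] < df["start"]).any():
        raise ValueError("gene end before start")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene identifiers in annotation")
    df["midpoint"] = (df["start"] + df["end"]) // 2
    return df.reset_index(drop=True)
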