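"""Readers and writers for the standard interchange formats.

Phased VCF (with ancestral-allele ``AA`` INFO tags), BED gene annotations
(0-based half-open on disk, 1-based inclusive in memory), two-column edge
lists and the HPRD flat-file dialect.  The VCF reader uses cyvcf2; writing
is plain text since the panels are synthetic and fully in memory.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panels import HaplotypePanel, finish_gene_table

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(panels: dict[str, list[HaplotypePanel]], path: str, popmap_path: str | None = None) -> None:
    """Write phased diploid VCF for all populations (haplotypes paired in order).

    Sample names are ``<POP>_<k>``; an optional two-column population-sample
    map TSV is written alongside.  The ancestral allele is REF ('A'), the
    derived allele ALT ('G'), and every site carries ``AA=A``.
    """
    pops = list(panels)
    for pop in pops:
        if panels[pop][0].n_haplotypes % 2:
            raise ValueError("diploid VCF output needs an even haplotype count")
    samples = [f"{pop}_{k}" for pop in pops for k in range(panels[pop][0].n_haplotypes // 2)]
    lines = [_VCF_HEADER]
    for i in range(len(panels[pops[0]])):
        for pop in pops[1:]:
            if not np.array_equal(panels[pop][i].positions, panels[pops[0]][i].positions):
                raise ValueError("populations must share positions")
        lines.append(f"##contig=<ID={panels[pops[0]][i].chrom}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    for i, ref_panel in enumerate(panels[pops[0]]):
        chrom = ref_panel.chrom
        mats = [panels[pop][i].alleles for pop in pops]
        for j, pos in enumerate(ref_panel.positions):
            gts = []
            for mat in mats:
                col = mat[:, j]
                gts.extend(f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(col.size // 2))
            lines.append(
                f"{chrom}\t{pos}\tsnp_{chrom}_{pos}\tA\tG\t.\tPASS\tAA=A\tGT\t" + "\t".join(gts) + "\n"
            )
    with open(path, "w") as fh:
        fh.writelines(lines)
    if popmap_path:
        with open(popmap_path, "w") as fh:
            for pop in pops:
                for k in range(panels[pop][0].n_haplotypes // 2):
                    fh.write(f"{pop}_{k}\t{pop}\n")


def read_popmap(path: str) -> dict[str, str]:
    """Two-column sample-to-population TSV."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sample, pop = line.split()[:2]
                out[sample] = pop
    return out


def read_vcf(path: str, popmap: dict[str, str]) -> dict[str, list[HaplotypePanel]]:
    """Read a phased VCF into per-population, per-chromosome panels.

    Alleles are recoded against the ``AA`` ancestral-allele INFO tag; sites
    without an AA tag (or with an AA matching neither allele) are dropped
    with a logged count.
    """
    vcf = VCF(path)
    samples = vcf.samples
    pops = sorted(set(popmap.values()))
    sample_cols = {
        pop: [i for i, s in enumerate(samples) if popmap.get(s) == pop] for pop in pops
    }
    per_chrom: dict[str, dict] = {}
    n_dropped = 0
    for var in vcf:
        aa = var.INFO.get("AA")
        if aa is None:
            n_dropped += 1
            continue
        aa = str(aa).upper()
        if aa == var.REF.upper():
            flip = False
        elif var.ALT and aa == var.ALT[0].upper():
            flip = True
        else:
            n_dropped += 1
            continue
        gt = np.array(var.genotypes)[:, :2]  # (n_samples, 2)
        store = per_chrom.setdefault(var.CHROM, {"pos": [], "gt": []})
        store["pos"].append(var.POS)
        store["gt"].append(1 - gt if flip else gt)
    if n_dropped:
        logger.info("dropped %d sites without a usable ancestral-allele tag", n_dropped)
    panels: dict[str, list[HaplotypePanel]] = {pop: [] for pop in pops}
    for chrom, store in per_chrom.items():
        gt = np.stack(store["gt"])  # (n_snps, n_samples, 2)
        pos = np.array(store["pos"])
        for pop in pops:
            cols = sample_cols[pop]
            mat = gt[:, cols, :].reshape(len(pos), -1).T.astype(np.uint8)
            panels[pop].append(HaplotypePanel(pop, chrom, pos, mat))
    return panels


def write_bed(genes: pd.DataFrame, path: str) -> None:
    """Gene annotations as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in genes.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


def read_bed(path: str) -> pd.DataFrame:
    """BED gene annotations -> 1-based inclusive gene table."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom, start, end, name")
            records.append((fields[3], fields[0], int(fields[1]) + 1, int(fields[2])))
    df = pd.DataFrame(records, columns=["gene", "chrom", "start", "end"])
    return finish_gene_table(df)


def write_edgelist(graph, path: str) -> None:
    """Two-column tab-separated edge list (sorted, deterministic)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def write_hprd_flat(graph, path: str) -> None:
    """HPRD binary-interaction flat-file dialect (symbols in columns 1 and 4)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t-\t-\t{b}\t-\t-\tin vitro\t-\n")
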