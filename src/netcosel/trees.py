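"""Per-gene trifurcate divergence trees and network-distance similarity tests.

For three populations, the gene-level pairwise FST values determine a
three-branch tree by the three-point formula::

    D_i = (FST(i,j) + FST(i,k) - FST(j,k)) / 2

where ``D_i`` is the branch (divergence rate) of population ``i`` from the
common ancestor; additivity ``D_i + D_j = FST(i,j)`` is exact and negative
branches are retained.  Gene-level FST is the Weir-Cockerham ratio of sums
over the SNPs inside the annotated gene span (haploid formulation).

Two pairwise tree-similarity statistics:

* **RTD** (ranked tree distance) — genes are ranked by ``D_i`` within each
  population; RTD is the mean absolute rank difference over the three
  populations, normalized over all pairs to zero mean and unit variance.
  Low RTD = similar recent evolutionary paths.
* **Syn** (synergy score) — the mean over populations of the product of the
  two genes' divergence residuals from the genome median, scaled by the
  population variance:  Syn = (1/3) sum_i (D_ai - D'_i)(D_bi - D'_i)/SD_i^2.
  Positive Syn = the pair deviates from the median tree in the same
  direction.

``tree_similarity_vs_spl`` profiles the mean RTD and Syn per shortest-path
distance against a null in which each population's divergence rates are
reshuffled across the network genes independently (1,000 reshuffles by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coselection import SPL_POOL_FROM, _empirical_p, spearman_trend
from .network import SplIndex
from .panels import HaplotypePanel
from .scan import _fst_components

PAIRS = ((0, 1), (0, 2), (1, 2))


def gene_fst(
    panels: dict[str, list[HaplotypePanel]], gene: pd.Series
) -> dict[tuple[str, str], float] | None:
    """Pairwise gene-level WC FST (ratio of sums over SNPs in the gene span).

    Returns None when the gene has no SNP that is polymorphic in the pooled
    sample (such genes are excluded from the tree table).
    """
    pops = list(panels)
    chrom_index = {p.chrom: i for i, p in enumerate(panels[pops[0]])}
    if gene["chrom"] not in chrom_index:
        return None
    ci = chrom_index[gene["chrom"]]
    sub = {}
    any_poly = False
    for pop in pops:
        panel = panels[pop][ci]
        sel = (panel.positions >= gene["start"]) & (panel.positions <= gene["end"])
        if not sel.any():
            return None
        sub[pop] = panel.alleles[:, sel]
    pooled = np.vstack([sub[pop] for pop in pops])
    poly = (pooled.min(axis=0) == 0) & (pooled.max(axis=0) == 1)
    if not poly.any():
        return None
    out = {}
    for i, j in PAIRS:
        a, b = _fst_components(
            [
                HaplotypePanel(pops[i], "g", np.arange(1, poly.sum() + 1), sub[pops[i]][:, poly]),
                HaplotypePanel(pops[j], "g", np.arange(1, poly.sum() + 1), sub[pops[j]][:, poly]),
            ]
        )
        denom = b.sum()
        out[(pops[i], pops[j])] = float(a.sum() / denom) if denom != 0 else 0.0
    return out


def trifurcate_tree(fst_ij: float, fst_ik: float, fst_jk: float) -> tuple[float, float, float]:
    """Branch lengths (D_i, D_j, D_k) from the three pairwise FST values."""
    d_i = 0.5 * (fst_ij + fst_ik - fst_jk)
    d_j = 0.5 * (fst_ij + fst_jk - fst_ik)
    d_k = 0.5 * (fst_ik + fst_jk - fst_ij)
    return d_i, d_j, d_k


def divergence_tree_table(
    panels: dict[str, list[HaplotypePanel]],
    genes: pd.DataFrame,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Per-gene pairwise FST and branch lengths for all usable genes.

    ``restrict_to`` (typically the network node set — the reshuffling
    universe) limits the table; genes without a usable SNP are dropped.
    Columns: gene, fst_<i>_<j> for the three pairs, d_<pop> per population.
    """
    pops = list(panels)
    rows = []
    for row in genes.itertuples():
        if restrict_to is not None and row.gene not in restrict_to:
            continue
        fst = gene_fst(panels, pd.Series({"gene": row.gene, "chrom": row.chrom,
                                          "start": row.start, "end": row.end}))
        if fst is None:
            continue
        f01 = fst[(pops[0], pops[1])]
        f02 = fst[(pops[0], pops[2])]
        f12 = fst[(pops[1], pops[2])]
        d0, d1, d2 = trifurcate_tree(f01, f02, f12)
        rows.append((row.gene, f01, f02, f12, d0, d1, d2))
    cols = ["gene",
            f"fst_{pops[0]}_{pops[1]}", f"fst_{pops[0]}_{pops[2]}", f"fst_{pops[1]}_{pops[2]}",
            *(f"d_{p}" for p in pops)]
    return pd.DataFrame(rows, columns=cols)


def tree_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Genome median D' and SD per population over the table's gene universe."""
    d_cols = [c for c in table.columns if c.startswith("d_")]
    return pd.DataFrame(
        {
            "population": [c[2:] for c in d_cols],
            "median": [float(table[c].median()) for c in d_cols],
            "sd": [float(table[c].std(ddof=0)) for c in d_cols],
        }
    )


def _d_matrix(table: pd.DataFrame) -> np.ndarray:
    d_cols = [c for c in table.columns if c.startswith("d_")]
    return table[d_cols].to_numpy(dtype=float)


def rtd(gene_a: str, gene_b: str, table: pd.DataFrame, normalized: bool = True) -> float:
    """Ranked tree distance between two genes (normalized over all pairs)."""
    raw = _rtd_pairs(table)
    genes = list(table["gene"])
    ia, ib = genes.index(gene_a), genes.index(gene_b)
    ranks = np.stack([rankdata(c, method="average") for c in _d_matrix(table).T])
    value = float(np.mean(np.abs(ranks[:, ia] - ranks[:, ib])))
    if not normalized:
        return value
    return float((value - raw.mean()) / raw.std(ddof=0))


def syn(gene_a: str, gene_b: str, table: pd.DataFrame) -> float:
    """Synergy score of two genes' divergence residuals from the genome median."""
    summary = tree_summary(table)
    if (summary["sd"] == 0).any():
        raise ValueError("degenerate cohort: a population has zero divergence SD")
    d = _d_matrix(table)
    z = (d - summary["median"].to_numpy()) / summary["sd"].to_numpy()
    genes = list(table["gene"])
    ia, ib = genes.index(gene_a), genes.index(gene_b)
    return float(np.mean(z[ia] * z[ib]))


def syn_pairs(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> np.ndarray:
    """Vectorized Syn for a list of gene pairs."""
    summary = tree_summary(table)
    if (summary["sd"] == 0).any():
        raise ValueError("degenerate cohort: a population has zero divergence SD")
    d = _d_matrix(table)
    z = (d - summary["median"].to_numpy()) / summary["sd"].to_numpy()
    index = {g: i for i, g in enumerate(table["gene"])}
    ia = np.array([index[a] for a, _ in pairs])
    ib = np.array([index[b] for _, b in pairs])
    return (z[ia] * z[ib]).mean(axis=1)


def _rtd_pairs(table: pd.DataFrame) -> np.ndarray:
    """Raw RTD for all unordered gene pairs of the table (row order of triu)."""
    d = _d_matrix(table)
    ranks = np.stack([rankdata(c, method="average") for c in d.T])
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return np.mean(np.abs(ranks[:, iu[0]] - ranks[:, iu[1]]), axis=0)


def tree_similarity_vs_spl(
    table: pd.DataFrame,
    spl: SplIndex,
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 100,
    trend_min_share: float = 0.001,
) -> dict:
    """Mean RTD and Syn per SPL bin against a divergence-reshuffling null.

    Genes present both in the tree table and on the network are paired; bins
    with SPL >= 9 are pooled.  In each of ``n_perm`` reshuffles every
    population's divergence-rate vector is permuted across the genes
    independently and the bin means recomputed; empirical p-values are
    two-sided by rank with the add-one rule.  Also reports the Spearman
    trend of the observed bin means against SPL; bins holding less than
    ``trend_min_share`` of all pairs are reported but excluded from the
    trend (their means are sampling noise on the scale of the signal).
    """
    genes = [g for g in table["gene"] if g in spl.index]
    if len(genes) < min_genes:
        raise ValueError(f"need trees for >= {min_genes} network genes, got {len(genes)}")
    sub = table[table["gene"].isin(genes)].reset_index(drop=True)
    d = _d_matrix(sub)
    n = d.shape[0]
    ranks = np.stack([rankdata(c, method="average") for c in d.T])  # (3, n)
    med = np.median(d, axis=0)
    sd = d.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("degenerate cohort: a population has zero divergence SD")
    z = (d - med) / sd  # (n, 3)

    dist = spl.submatrix(list(sub["gene"]))
    iu = np.triu_indices(n, k=1)
    bins = np.minimum(dist[iu], SPL_POOL_FROM)
    n_bins = SPL_POOL_FROM + 1
    pair_counts = np.bincount(bins, minlength=n_bins)

    def bin_means(rank_mat: np.ndarray, z_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raw_rtd = np.mean(np.abs(rank_mat[:, iu[0]] - rank_mat[:, iu[1]]), axis=0)
        norm_rtd = (raw_rtd - raw_rtd.mean()) / raw_rtd.std(ddof=0)
        syn_vals = (z_mat[iu[0]] * z_mat[iu[1]]).mean(axis=1)
        with np.errstate(invalid="ignore"):
            mean_rtd = np.bincount(bins, weights=norm_rtd, minlength=n_bins) / pair_counts
            mean_syn = np.bincount(bins, weights=syn_vals, minlength=n_bins) / pair_counts
        return mean_rtd, mean_syn

    obs_rtd, obs_syn = bin_means(ranks, z)

    rng = np.random.default_rng(seed)
    null_rtd = np.empty((n_perm, n_bins))
    null_syn = np.empty((n_perm, n_bins))
    for t in range(n_perm):
        perms = [rng.permutation(n) for _ in range(ranks.shape[0])]
        rp = np.stack([ranks[i, p] for i, p in enumerate(perms)])
        zp = np.stack([z[p, i] for i, p in enumerate(perms)], axis=1)
        null_rtd[t], null_syn[t] = bin_means(rp, zp)

    keep = pair_counts > 0
    keep[0] = False  # no self-pairs
    idx = np.flatnonzero(keep)
    profile = pd.DataFrame(
        {
            "spl": [str(b) if b < SPL_POOL_FROM else f"{SPL_POOL_FROM}+" for b in idx],
            "n_pairs": pair_counts[idx],
            "mean_rtd": obs_rtd[idx],
            "mean_syn": obs_syn[idx],
            "null_rtd_mean": null_rtd[:, idx].mean(axis=0),
            "null_rtd_sd": null_rtd[:, idx].std(axis=0),
            "null_syn_mean": null_syn[:, idx].mean(axis=0),
            "null_syn_sd": null_syn[:, idx].std(axis=0),
            "p_rtd": _empirical_p(obs_rtd[idx], null_rtd[:, idx], "two-sided"),
            "p_syn": _empirical_p(obs_syn[idx], null_syn[:, idx], "two-sided"),
            "low_support": pair_counts[idx] < 10,
            "in_trend": pair_counts[idx] >= trend_min_share * pair_counts.sum(),
        }
    )
    spl_vals = idx.astype(float)
    use = profile["in_trend"].to_numpy()
    rho_rtd, p_rho_rtd = spearman_trend(obs_rtd[idx][use], spl_vals[use])
    rho_syn, p_rho_syn = spearman_trend(obs_syn[idx][use], spl_vals[use])
    return {
        "profile": profile,
        "rtd_trend": (rho_rtd, p_rho_rtd),
        "syn_trend": (rho_syn, p_rho_syn),
    }
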