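"""End-to-end driver: simulated study -> scan -> network coselection -> trees.

Convenience layer used by the examples and the acceptance experiments; each
step is a thin call into the corresponding module so any stage can be
re-run or swapped in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import clusters as _clusters
from . import coselection as _cosel
from . import network as _network
from . import scan as _scan
from . import trees as _trees
from .synthetic import SimStudy


@dataclass
class ScanResult:
    """Per-SNP stats, candidate regions, and the candidate gene set."""

    stats: pd.DataFrame
    regions: list[_scan.SelectionRegion]
    candidates: pd.DataFrame  # gene, peak_cms, population

    def candidate_set(self, on_network: nx.Graph | None = None) -> set[str]:
        genes = set(self.candidates["gene"])
        if on_network is not None:
            genes &= set(on_network.nodes())
        return genes


def run_scan(
    study: SimStudy,
    target: str | None = None,
    cms_threshold: float = 0.001,
    threshold_mode: str = "top_fraction",
    pi: float = 0.01,
) -> ScanResult:
    """Scan a simulated study for sweeps in the target population.

    The default cutoff takes the top 0.1% of CMS scores (rank semantics);
    pass ``threshold_mode="absolute"`` with e.g. ``cms_threshold=10`` for
    the conventional absolute-score cutoff.
    """
    target = target or study.config.sweep_population
    stats = _scan.compute_snp_stats(study.panels, target, pi=pi)
    regions = _scan.call_regions(stats, cms_threshold, threshold_mode)
    candidates = _scan.candidate_genes(regions, study.genes, target)
    return ScanResult(stats=stats, regions=regions, candidates=candidates)


@dataclass
class CoselectionResult:
    spl: _network.SplIndex
    centrality: pd.DataFrame
    enrichment_dc: pd.DataFrame
    enrichment_bc: pd.DataFrame
    spl_profile: pd.DataFrame
    mean_spl: dict
    trend: tuple[float, float]


def run_coselection(
    study: SimStudy,
    candidates: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> CoselectionResult:
    """Centrality enrichment and SPL coselection of a candidate set."""
    lcc = _network.largest_connected_component(study.network)
    cand = set(candidates) & set(lcc.nodes())
    centrality = _network.centralities(lcc)
    spl = _network.shortest_path_lengths(lcc)
    scheme = _cosel.IntervalScheme()
    return CoselectionResult(
        spl=spl,
        centrality=centrality,
        enrichment_dc=_cosel.centrality_enrichment(cand, centrality, scheme, "dc", n_perm, seed),
        enrichment_bc=_cosel.centrality_enrichment(cand, centrality, scheme, "bc", n_perm, seed + 1),
        spl_profile=(profile := _cosel.spl_coselection(cand, spl, n_perm, seed + 2)),
        mean_spl=_cosel.mean_spl_test(cand, spl, n_perm, seed + 3),
        trend=_cosel.spearman_trend(
            profile["relative"].to_numpy(),
            profile["spl"].str.rstrip("+").astype(float).to_numpy(),
        ),
    )


def run_trees(
    study: SimStudy,
    spl: _network.SplIndex,
    n_perm: int = 200,
    seed: int = 0,
) -> dict:
    """Divergence-tree table and its SPL similarity profile."""
    table = _trees.divergence_tree_table(study.panels, study.genes, restrict_to=set(spl.nodes))
    result = _trees.tree_similarity_vs_spl(table, spl, n_perm=n_perm, seed=seed)
    result["table"] = table
    return result


def run_syn_clusters(
    study: SimStudy,
    candidates: set[str],
    tree_table: pd.DataFrame,
    scan_result: ScanResult,
    threshold: float = 1.5,
) -> tuple[list[_clusters.CoselectionCluster], float]:
    """Extract Syn-thresholded coselection clusters among the candidates."""
    lcc = _network.largest_connected_component(study.network)
    cand = set(candidates) & set(lcc.nodes()) & set(tree_table["gene"])
    subnets = _clusters.candidate_subnetworks(cand, lcc)
    pairs = [tuple(sorted(e)) for sub in subnets for e in sub.edges()]
    scores = dict(zip(pairs, _trees.syn_pairs(tree_table, pairs))) if pairs else {}
    found, fraction = _clusters.syn_clusters(subnets, scores, threshold)
    cms_by_gene = dict(zip(scan_result.candidates["gene"], scan_result.candidates["peak_cms"]))
    for cluster in found:
        _clusters.annotate_cluster(cluster, cms_by_gene)
    return found, fraction
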