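"""Coselection subnetworks: candidate-induced components and Syn clusters.

Candidate genes of recent positive selection frequently form large connected
subnetworks through single-step interactions.  Filtering those one-step
edges by the Syn score of their endpoint pair (strictly above a threshold)
breaks the subnetworks into coselection clusters — groups of candidates that
both interact directly and deviated from the genome-median divergence tree
in the same direction.  Clusters are decorated with per-gene composite
scores; the hub (top within-cluster degree) and the peak (top CMS) member
are flagged, and plain-text gene lists are exported for external functional
enrichment tools.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


def candidate_subnetworks(candidates: set[str], graph: nx.Graph) -> list[nx.Graph]:
    """Connected components of the candidate-induced subgraph, largest first.

    Ties in size break lexicographically on the sorted node set, so the
    order is deterministic.
    """
    unknown = set(candidates) - set(graph.nodes())
    if unknown:
        raise ValueError(f"candidates not on the network: {sorted(unknown)[:5]}")
    sub = graph.subgraph(candidates)
    components = [sorted(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), c))
    return [sub.subgraph(c).copy() for c in components]


@dataclass
class CoselectionCluster:
    """A connected set of candidate genes joined by high-Syn one-step edges."""

    members: list[str]
    edges: list[tuple[str, str, float]]  # (gene_a, gene_b, syn)
    cms: dict[str, float] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)
    peak: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def mean_syn(self) -> float:
        return sum(s for _, _, s in self.edges) / len(self.edges) if self.edges else float("nan")


def syn_clusters(
    subnetworks: list[nx.Graph],
    syn_scores: dict[tuple[str, str], float],
    threshold: float,
) -> tuple[list[CoselectionCluster], float]:
    """Components of the candidate subnetworks after Syn-filtering the edges.

    Edges are kept when their Syn score is strictly above ``threshold``;
    higher thresholds only refine clusters (never merge them).  Returns the
    clusters (largest first) and the fraction of coselection edges retained.
    """
    total = kept = 0
    filtered = nx.Graph()
    for sub in subnetworks:
        for a, b in sub.edges():
            total += 1
            s = syn_scores.get((a, b), syn_scores.get((b, a)))
            if s is None:
                raise KeyError(f"no Syn score for candidate edge {a}-{b}")
            if s > threshold:
                kept += 1
                filtered.add_edge(a, b, syn=float(s))
    components = [sorted(c) for c in nx.connected_components(filtered)]
    components.sort(key=lambda c: (-len(c), c))
    clusters = [
        CoselectionCluster(
            members=c,
            edges=[(a, b, filtered[a][b]["syn"]) for a, b in filtered.subgraph(c).edges()],
        )
        for c in components
    ]
    fraction = kept / total if total else 0.0
    return clusters, fraction


def annotate_cluster(
    cluster: CoselectionCluster, cms_by_gene: dict[str, float]
) -> CoselectionCluster:
    """Attach CMS scores; flag hub (max within-cluster degree, ties all) and
    peak (max CMS) members."""
    if not cluster.members:
        raise ValueError("empty cluster")
    degree = {m: 0 for m in cluster.members}
    for a, b, _ in cluster.edges:
        degree[a] += 1
        degree[b] += 1
    top = max(degree.values())
    cluster.hubs = sorted(m for m, d in degree.items() if d == top)
    cluster.cms = {m: float(cms_by_gene.get(m, float("nan"))) for m in cluster.members}
    cluster.peak = max(cluster.members, key=lambda m: (cluster.cms.get(m, float("-inf")), m))
    return cluster


def export_gene_lists(clusters: list[CoselectionCluster], out_dir: str) -> pd.DataFrame:
    """One uppercase symbol list per cluster plus a summary TSV.

    Returns the summary table (cluster id, size, edge count, mean Syn, hub,
    peak); written even when the cluster list is empty (header only).
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, cluster in enumerate(clusters, start=1):
        symbols = sorted({m.upper() for m in cluster.members})
        with open(os.path.join(out_dir, f"cluster_{i:02d}.txt"), "w") as fh:
            fh.write("\n".join(symbols) + "\n")
        rows.append(
            (
                i,
                cluster.size,
                len(cluster.edges),
                cluster.mean_syn(),
                ";".join(cluster.hubs),
                cluster.peak or "",
            )
        )
    summary = pd.DataFrame(
        rows, columns=["cluster", "size", "n_edges", "mean_syn", "hubs", "peak"]
    )
    summary.to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
    return summary
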