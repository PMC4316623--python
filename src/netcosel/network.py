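"""Protein-protein-interaction network: parsing, LCC, centralities, distances.

Nodes are uppercase gene symbols; the graph is simple and undirected.  Three
input dialects are supported: the HPRD binary-interaction flat file
(tab-separated, symbols in columns 1 and 4), SIF, and a two-column edge list.

Betweenness follows the igraph/networkx convention for undirected graphs —
per unordered pair (s, t), the transit count of v is split among equal-length
shortest paths (sigma_st(v) / sigma_st) and summed, unnormalized — so leaves
have BC 0 and the center of a star over k leaves has BC C(k, 2).  Shortest
path lengths are unweighted BFS distances; the network mean SPL is the mean
over unordered node pairs of the LCC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

DIALECTS = ("hprd-flat", "sif", "edgelist")


def read_network(path: str, dialect: str = "edgelist") -> nx.Graph:
    """Parse a PPI file into a simple undirected graph of uppercase symbols.

    Self-loops and duplicate edges are removed (counts logged); malformed
    lines raise with their line number; an empty result graph is an error.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "hprd-flat":
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated columns")
                pairs.append((fields[0], fields[3]))
            elif dialect == "sif":
                fields = line.split()
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF needs node, relation, node(s)")
                for other in fields[2:]:
                    pairs.append((fields[0], other))
            else:
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                pairs.append((fields[0], fields[1]))
    return build_graph(pairs)


def build_graph(pairs: list[tuple[str, str]]) -> nx.Graph:
    """Assemble a simple graph from symbol pairs (uppercased, cleaned)."""
    graph = nx.Graph()
    n_self = n_dup = 0
    for a, b in pairs:
        a, b = a.strip().upper(), b.strip().upper()
        if not a or not b:
            continue
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
    if graph.number_of_nodes() == 0:
        raise ValueError("no usable interactions: the parsed graph is empty")
    return graph


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Node-maximal connected component (ties: lexicographically smallest set)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c))
    lcc = graph.subgraph(components[0]).copy()
    lcc.graph["is_lcc"] = True
    return lcc


def centralities(lcc: nx.Graph) -> pd.DataFrame:
    """Degree and (unnormalized, unordered-pair) betweenness per node."""
    bc = nx.betweenness_centrality(lcc, normalized=False)
    nodes = sorted(lcc.nodes())
    return pd.DataFrame(
        {
            "node": nodes,
            "dc": [lcc.degree(n) for n in nodes],
            "bc": [bc[n] for n in nodes],
        }
    )


@dataclass
class SplIndex:
    """All-pairs shortest path lengths over the LCC, plus the network mean."""

    nodes: list[str]
    index: dict[str, int]
    d: np.ndarray  # (n, n) int16, BFS distances
    mean_spl: float

    def distance(self, a: str, b: str) -> int:
        return int(self.d[self.index[a], self.index[b]])

    def pair_distance_counts(self) -> np.ndarray:
        """Count of unordered pairs at each distance d = 0, 1, 2, ..."""
        iu = np.triu_indices(len(self.nodes), k=1)
        return np.bincount(self.d[iu])

    def submatrix(self, members: list[str]) -> np.ndarray:
        idx = np.array([self.index[m] for m in members])
        return self.d[np.ix_(idx, idx)]


def shortest_path_lengths(lcc: nx.Graph) -> SplIndex:
    """BFS from every node of a connected graph; mean over unordered pairs."""
    nodes = sorted(lcc.nodes())
    adj = nx.to_scipy_sparse_array(lcc, nodelist=nodes, format="csr")
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        raise ValueError("graph is not connected; extract the LCC first")
    d = dist.astype(np.int16)
    iu = np.triu_indices(len(nodes), k=1)
    mean_spl = float(d[iu].mean()) if len(nodes) > 1 else 0.0
    return SplIndex(nodes=nodes, index={n: i for i, n in enumerate(nodes)}, d=d, mean_spl=mean_spl)


def bc_strata(
    centrality_table: pd.DataFrame, cuts: tuple[float, float] = (100.0, 20_000.0)
) -> dict[str, set[str]]:
    """Partition nodes by betweenness: peripheral (BC <= low), intermediate
    (low < BC <= high), core (BC > high).  Downstream SPL analyses within a
    stratum keep the global distances."""
    low, high = cuts
    bc = centrality_table["bc"]
    return {
        "peripheral": set(centrality_table.loc[bc <= low, "node"]),
        "intermediate": set(centrality_table.loc[(bc > low) & (bc <= high), "node"]),
        "core": set(centrality_table.loc[bc > high, "node"]),
    }


def filter_ld_edges(
    graph: nx.Graph, genes: pd.DataFrame, window_bp: int = 500_000
) -> tuple[nx.Graph, int]:
    """Drop edges whose endpoint genes sit within ``window_bp`` on one chromosome.

    Gene proximity is measured between midpoints; nodes without coordinates
    keep their edges (counted in the log).  Returns the filtered copy and the
    number of removed edges; the graph may fragment, so downstream analyses
    re-run on its largest connected component.
    """
    loc = genes.set_index("gene")[["chrom", "midpoint"]]
    out = graph.copy()
    out.graph.pop("is_lcc", None)
    to_drop = []
    n_unlocated = 0
    for a, b in out.edges():
        if a not in loc.index or b not in loc.index:
            n_unlocated += 1
            continue
        ca, cb = loc.at[a, "chrom"], loc.at[b, "chrom"]
        if ca == cb and abs(int(loc.at[a, "midpoint"]) - int(loc.at[b, "midpoint"])) < window_bp:
            to_drop.append((a, b))
    out.remove_edges_from(to_drop)
    if n_unlocated:
        logger.info("%d edges kept with unlocated endpoints", n_unlocated)
    return out, len(to_drop)


def write_node_table(centrality_table: pd.DataFrame, path: str) -> None:
    centrality_table.to_csv(path, sep="\t", index=False)
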