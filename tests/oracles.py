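"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written from first principles (pair enumeration,
O(n^3) dynamic programming, explicit ANOVA sums) and shares no code with the
package modules it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def wc_theta_haploid(allele_matrices: list[np.ndarray]) -> float:
    """Weir-Cockerham theta for haploid 0/1 data via explicit ANOVA sums."""
    r = len(allele_matrices)
    n = np.array([m.size for m in allele_matrices], dtype=float)
    ntot = n.sum()
    means = np.array([m.mean() for m in allele_matrices])
    grand = sum(m.sum() for m in allele_matrices) / ntot
    ssb = float(sum(ni * (mi - grand) ** 2 for ni, mi in zip(n, means)))
    ssw = float(sum(((m - m.mean()) ** 2).sum() for m in allele_matrices))
    msb = ssb / (r - 1)
    msw = ssw / (ntot - r)
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    return (msb - msw) / (msb + (nc - 1) * msw)


def wc_theta_ratio_of_sums(allele_matrices: list[np.ndarray]) -> float:
    """Multi-SNP WC theta: per-SNP ANOVA components summed before the ratio.

    ``allele_matrices[i]`` is the (haplotypes x SNPs) 0/1 matrix of
    population i; monomorphic-overall SNPs contribute zero to both sums.
    """
    r = len(allele_matrices)
    n = np.array([m.shape[0] for m in allele_matrices], dtype=float)
    ntot = n.sum()
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    num = den = 0.0
    for j in range(allele_matrices[0].shape[1]):
        cols = [m[:, j] for m in allele_matrices]
        means = np.array([c.mean() for c in cols])
        grand = sum(c.sum() for c in cols) / ntot
        msb = float(sum(ni * (mi - grand) ** 2 for ni, mi in zip(n, means))) / (r - 1)
        msw = float(sum(((c - c.mean()) ** 2).sum() for c in cols)) / (ntot - r)
        num += msb - msw
        den += msb + (nc - 1) * msw
    return num / den


def ehhs_brute(alleles: np.ndarray, core: int, target: int) -> float:
    """P(two random haplotypes identical over SNPs core..target inclusive)."""
    lo, hi = min(core, target), max(core, target)
    seg = alleles[:, lo : hi + 1]
    n = seg.shape[0]
    same = sum(
        1
        for i, j in itertools.combinations(range(n), 2)
        if np.array_equal(seg[i], seg[j])
    )
    return same / (n * (n - 1) / 2)


def ies_brute(alleles: np.ndarray, positions: np.ndarray, core: int,
              decay: float = 0.05, max_bp: int = 500_000) -> float:
    """Trapezoid-integrated EHHS at one core SNP, by pair enumeration."""
    total = 0.0
    for direction in (-1, 1):
        prev_e, prev_x = 1.0, positions[core]
        j = core
        while True:
            j += direction
            if j < 0 or j >= alleles.shape[1]:
                break
            if abs(positions[j] - positions[core]) > max_bp:
                break
            e = ehhs_brute(alleles, core, j)
            total += 0.5 * (prev_e + e) * abs(positions[j] - prev_x)
            prev_e, prev_x = e, positions[j]
            if e < decay:
                break
    return total


def floyd_warshall(n_nodes: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs shortest path lengths by O(n^3) relaxation."""
    d = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(d, 0.0)
    for a, b in edges:
        d[a, b] = d[b, a] = 1.0
    for k in range(n_nodes):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def brute_betweenness(n_nodes: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """Unordered-pair betweenness by exhaustive shortest-path enumeration."""
    adj = [[] for _ in range(n_nodes)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    bc = np.zeros(n_nodes)
    for s, t in itertools.combinations(range(n_nodes), 2):
        # BFS to find all shortest s-t paths
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n_nodes):
            if v in (s, t):
                continue
            transit = sum(1 for p in paths if v in p)
            bc[v] += transit / len(paths)
    return bc


def _all_shortest_paths(adj, s, t):
    from collections import deque

    dist = {s: 0}
    parents: dict[int, list[int]] = {s: []}
    queue = deque([s])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    if t not in dist:
        return []
    paths = []

    def backtrack(v, acc):
        if v == s:
            paths.append(set(acc))
            return
        for u in parents[v]:
            backtrack(u, acc + [u])

    backtrack(t, [t])
    return paths


def union_find_components(nodes: list, edges: list[tuple]) -> list[set]:
    """Connected components by union-find with path compression."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def bh_stepup(p_values: list[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up recursion."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def cms_factor(p: float, pi: float) -> float:
    """One posterior factor of the composite score, by direct arithmetic."""
    return (1 - p) * pi / ((1 - p) * pi + p * (1 - pi))
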