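"""Where selected genes sit on the network, and whether they cluster.

Two families of resampling tests against a null of uniformly drawn node sets
of the same size as the candidate list:

* **Centrality-interval enrichment** — the proportion of candidates falling
  in each degree- or betweenness-centrality interval, expressed as a Z-score
  against the resampled null and an empirical rank p-value, BH-FDR-corrected
  across intervals.
* **SPL coselection** — for each shortest-path-length d, the proportion of
  node pairs at distance d in which both genes are candidates, normalized by
  the expected proportion under no coselection, C(k,2)/C(n,2); a relative
  proportion above 1 marks overrepresented coselection at that distance.
  Z-scores and p-values come from the same equal-size resampling scheme, and
  the mean pairwise SPL among candidates is tested against resampled means.

Nominal p-values use the add-one rule (1 + count) / (1 + n_perm) so they are
never zero; the default is two-sided (min tail doubled, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .network import SplIndex

SPL_POOL_FROM = 9  # SPL bins >= this value are pooled into one "9+" bin


@dataclass(frozen=True)
class IntervalScheme:
    """Centrality bin edges: 6 degree intervals and 7 betweenness intervals.

    Edges are right-inclusive: a value v falls in bin i when
    ``edges[i] < v <= edges[i+1]``.  The defaults keep roughly comparable
    node counts per interval on a scale-free PPI network.
    """

    dc_edges: tuple[float, ...] = (0, 1, 3, 5, 9, 20, np.inf)
    bc_edges: tuple[float, ...] = (-1, 0, 10, 100, 500, 2000, 20_000, np.inf)

    def labels(self, which: str) -> list[str]:
        edges = self.dc_edges if which == "dc" else self.bc_edges
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi == np.inf:
                out.append(f">{lo:g}")
            elif hi - lo == 1 and float(lo).is_integer():
                out.append(f"{hi:g}")
            else:
                out.append(f"{lo:g}<x<={hi:g}")
        return out

    def bin_ids(self, values: np.ndarray, which: str) -> np.ndarray:
        edges = np.asarray(self.dc_edges if which == "dc" else self.bc_edges, dtype=float)
        ids = np.searchsorted(edges, values, side="left") - 1
        if (ids < 0).any() or (ids >= len(edges) - 1).any():
            raise ValueError("centrality values outside the interval scheme")
        return ids


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _empirical_p(observed: np.ndarray, null: np.ndarray, sided: str) -> np.ndarray:
    """Add-one empirical p-values of observed values against null columns."""
    n_perm = null.shape[0]
    ge = (null >= observed).sum(axis=0)
    le = (null <= observed).sum(axis=0)
    p_hi = (1.0 + ge) / (1.0 + n_perm)
    p_lo = (1.0 + le) / (1.0 + n_perm)
    if sided == "greater":
        return p_hi
    if sided == "less":
        return p_lo
    return np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))


def _resample_indices(
    rng: np.random.Generator, n: int, k: int, n_perm: int
) -> np.ndarray:
    out = np.empty((n_perm, k), dtype=np.int64)
    for i in range(n_perm):
        out[i] = rng.choice(n, size=k, replace=False)
    return out


def centrality_enrichment(
    candidates: set[str],
    centrality_table: pd.DataFrame,
    scheme: IntervalScheme | None = None,
    which: str = "dc",
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "two-sided",
) -> pd.DataFrame:
    """Per-interval candidate proportions vs equal-size random node sets.

    Returns one row per centrality interval with the empirical proportion
    ``p_s``, the null mean and SD, the Z-score, the nominal p and the BH-FDR
    adjusted p.  Intervals whose null SD is zero get NaN Z (flagged).
    """
    if scheme is None:
        scheme = IntervalScheme()
    nodes = centrality_table["node"].to_numpy()
    unknown = candidates - set(nodes)
    if unknown:
        raise ValueError(f"candidates not on the network: {sorted(unknown)[:5]}")
    values = centrality_table[which].to_numpy(dtype=float)
    bin_ids = scheme.bin_ids(values, which)
    n_bins = len(scheme.labels(which))
    n = nodes.size
    k = len(candidates)
    is_cand = np.isin(nodes, sorted(candidates))
    obs = np.bincount(bin_ids[is_cand], minlength=n_bins) / k

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_bins))
    for i, idx in enumerate(_resample_indices(rng, n, k, n_perm)):
        null[i] = np.bincount(bin_ids[idx], minlength=n_bins) / k
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - null_mean) / null_sd
    z[null_sd <= 1e-12] = np.nan  # degenerate null (includes float dust)
    p = _empirical_p(obs, null, sided)
    return pd.DataFrame(
        {
            "bin": scheme.labels(which),
            "n_nodes": np.bincount(bin_ids, minlength=n_bins),
            "p_s": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "p_adj": bh_fdr(p),
        }
    )


def mw_test_centrality(
    candidates: set[str], centrality_table: pd.DataFrame
) -> dict[str, float]:
    """Two-sided Mann-Whitney U p-values comparing DC and BC between the
    candidate and non-candidate node groups (exact for small tie-free
    samples, otherwise normal approximation with tie correction)."""
    is_cand = centrality_table["node"].isin(candidates).to_numpy()
    if is_cand.all() or not is_cand.any():
        raise ValueError("both candidate and non-candidate groups must be nonempty")
    out = {}
    for which in ("dc", "bc"):
        values = centrality_table[which].to_numpy(dtype=float)
        out[which] = float(
            mannwhitneyu(values[is_cand], values[~is_cand], alternative="two-sided").pvalue
        )
    return out


def _pool_spl(d: np.ndarray) -> np.ndarray:
    return np.minimum(d, SPL_POOL_FROM)


def _pair_bincount(d_sub: np.ndarray, n_bins: int) -> np.ndarray:
    iu = np.triu_indices(d_sub.shape[0], k=1)
    return np.bincount(_pool_spl(d_sub[iu]), minlength=n_bins)


def spl_coselection(
    candidates: set[str],
    spl: SplIndex,
    n_perm: int = 10_000,
    seed: int = 0,
    sided: str = "two-sided",
    within: set[str] | None = None,
) -> pd.DataFrame:
    """Coselection proportions per SPL with resampling Z-scores and FDR.

    For each distance d (d >= 9 pooled into one bin), ``p_s`` is the fraction
    of node pairs at that distance in which both members are candidates; the
    relative proportion divides it by the no-coselection expectation
    C(k,2)/C(n,2).  ``within`` restricts the analysis to a node stratum
    (e.g. a betweenness stratum) while keeping the global SPL distances.
    """
    universe = sorted(within) if within is not None else spl.nodes
    cand = sorted(set(candidates) & set(universe)) if within is not None else sorted(candidates)
    if not set(cand) <= set(spl.nodes):
        raise ValueError("candidates must be LCC nodes")
    n = len(universe)
    k = len(cand)
    if k < 2:
        raise ValueError("need at least two candidates")
    d_universe = spl.submatrix(universe)
    n_bins = SPL_POOL_FROM + 1
    total_pairs = _pair_bincount(d_universe, n_bins)

    uni_index = {node: i for i, node in enumerate(universe)}
    cand_idx = np.array([uni_index[c] for c in cand])
    cand_pairs = _pair_bincount(d_universe[np.ix_(cand_idx, cand_idx)], n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs = cand_pairs / total_pairs
    expected = (k * (k - 1)) / (n * (n - 1))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_bins))
    for i, idx in enumerate(_resample_indices(rng, n, k, n_perm)):
        with np.errstate(invalid="ignore", divide="ignore"):
            null[i] = _pair_bincount(d_universe[np.ix_(idx, idx)], n_bins) / total_pairs
    keep = total_pairs > 0
    null_mean = np.full(n_bins, np.nan)
    null_sd = np.full(n_bins, np.nan)
    null_mean[keep] = null[:, keep].mean(axis=0)
    null_sd[keep] = null[:, keep].std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - null_mean) / null_sd
    z[~keep | (null_sd <= 1e-12)] = np.nan
    p = np.full(n_bins, np.nan)
    p[keep] = _empirical_p(obs[keep], null[:, keep], sided)
    labels = [str(d) if d < SPL_POOL_FROM else f"{SPL_POOL_FROM}+" for d in range(n_bins)]
    table = pd.DataFrame(
        {
            "spl": labels,
            "n_pairs": total_pairs,
            "cand_pairs": cand_pairs,
            "p_s": obs,
            "expected": expected,
            "relative": obs / expected,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "low_support": total_pairs < 10,
        }
    )
    table = table[(table.index > 0) & keep].reset_index(drop=True)
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    return table


def mean_spl_test(
    candidates: set[str],
    spl: SplIndex,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean pairwise SPL among candidates vs equal-size resampled node sets.

    The p-value is one-sided for shorter-than-expected distances:
    ``(1 + #{null <= observed}) / (n_perm + 1)``.
    """
    cand = sorted(candidates)
    k = len(cand)
    if k < 2:
        raise ValueError("need at least two candidates")
    iu = np.triu_indices(k, k=1)
    observed = float(spl.submatrix(cand)[iu].mean())
    rng = np.random.default_rng(seed)
    n = len(spl.nodes)
    null = np.empty(n_perm)
    for i, idx in enumerate(_resample_indices(rng, n, k, n_perm)):
        null[i] = spl.d[np.ix_(idx, idx)][iu].mean()
    p = (1.0 + (null <= observed).sum()) / (n_perm + 1.0)
    return {
        "observed_mean_spl": observed,
        "null_mean_spl": float(null.mean()),
        "p": float(p),
        "null": null,
    }


def spearman_trend(relative: np.ndarray, spl_values: np.ndarray | None = None) -> tuple[float, float]:
    """Spearman rank correlation of the per-SPL profile against SPL.

    Constant input has undefined rho (returned as NaN)."""
    y = np.asarray(relative, dtype=float)
    if y.size < 3:
        raise ValueError("need at least three points for a trend test")
    x = np.arange(1, y.size + 1) if spl_values is None else np.asarray(spl_values, dtype=float)
    if np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
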