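"""Genome-wide scan for recent positive selection (composite-score method).

Four per-SNP signals of a recent sweep in a target population are combined
into a single composite score (CMS):

* ``DAF`` — derived allele frequency in the target population,
* ``dDAF`` — DAF in the target minus the mean DAF of the other populations,
* ``FST`` — Weir-Cockerham differentiation between the target and the pooled
  other populations (haploid formulation, ratio of variance components),
* ``lnRsb`` — genome-standardized log ratio of integrated EHHS (iES) between
  the target and the pooled other populations (long-haplotype signal).

Each statistic is converted to a one-sided empirical p-value ``p_i`` by rank
(large = sweep-like).  With a prior fraction ``pi`` of the genome under
selection, the per-test posterior factor is::

    f_i = (1 - p_i) * pi / ((1 - p_i) * pi + p_i * (1 - pi))

and the default CMS is the product over tests of the posterior odds
``f_i / (1 - f_i)``, an unbounded score on which an absolute threshold (the
conventional value is 10) or a top-rank-fraction cutoff can be applied.  The
literal posterior-probability product and its log10 are available as
alternative score forms.

Top-scoring SNPs closer than 10 kb are chained into candidate regions,
single-SNP regions are dropped, and each region's peak SNP is mapped to a
candidate gene (span containment, then nearest boundary within 20 kb).  A
length-free assignment by gene midpoints within 150 kb is provided as a
gene-length confounder control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._ehh import ehhs_profile, ies_scan
from .panels import HaplotypePanel, pool_panels

logger = logging.getLogger(__name__)

STAT_COLUMNS = ("daf", "ddaf", "fst", "lnrsb")


# ---------------------------------------------------------------------------
# per-SNP statistics


def daf(panel: HaplotypePanel, snp: int | None = None) -> np.ndarray | float:
    """Derived allele frequency; the whole vector, or one SNP if ``snp`` given."""
    freqs = panel.alleles.mean(axis=0)
    return freqs if snp is None else float(freqs[snp])


def delta_daf(target_daf, other_dafs) -> np.ndarray:
    """DAF in the target population minus the mean DAF of the others."""
    others = np.asarray(other_dafs, dtype=float)
    if others.ndim == 1:
        others = others[None, :]
    if others.shape[0] < 1:
        raise ValueError("delta_daf needs at least one other population")
    return np.asarray(target_daf, dtype=float) - others.mean(axis=0)


def fst_per_snp(panels: list[HaplotypePanel]) -> np.ndarray:
    """Weir-Cockerham theta-hat per SNP from haplotype (haploid) counts.

    Ratio of variance components (between-population MSP vs within MSG);
    negative estimates are retained for ranking.  SNPs monomorphic in every
    population have no information and are returned as NaN.
    """
    if len(panels) < 2:
        raise ValueError("FST needs at least two populations")
    a, b = _fst_components(panels)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / b
    theta[b == 0] = np.nan
    return theta


def _fst_components(panels: list[HaplotypePanel]) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP numerator/denominator of the haploid WC ANOVA estimator."""
    r = len(panels)
    n = np.array([p.n_haplotypes for p in panels], dtype=float)
    freqs = np.stack([p.alleles.mean(axis=0) for p in panels])  # (r, n_snp)
    ntot = n.sum()
    nc = (ntot - (n**2).sum() / ntot) / (r - 1)
    pbar = (n[:, None] * freqs).sum(axis=0) / ntot
    msp = (n[:, None] * (freqs - pbar) ** 2).sum(axis=0) / (r - 1)
    msg = (n[:, None] * freqs * (1.0 - freqs)).sum(axis=0) / (ntot - r)
    a = msp - msg
    b = msp + (nc - 1.0) * msg
    return a, b


def ehhs(panel: HaplotypePanel, core_snp: int, direction: int, max_steps: int | None = None) -> np.ndarray:
    """EHHS profile at 1..k SNPs from the core in one direction (+1 right, -1 left).

    Value at distance d is the probability that two random haplotypes are
    identical at every SNP from the core (included) out to d; non-increasing.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    if max_steps is None:
        max_steps = panel.n_snps
    return ehhs_profile(panel.alleles, core_snp, direction, max_steps)


def ies(panel: HaplotypePanel, decay: float = 0.05, max_extension_bp: int = 500_000) -> np.ndarray:
    """Integrated EHHS (bp units) at every SNP, both directions summed."""
    return ies_scan(panel.alleles, panel.positions, decay, max_extension_bp)


def ln_rsb(
    panel_target: HaplotypePanel,
    panel_other: HaplotypePanel,
    decay: float = 0.05,
    max_extension_bp: int = 500_000,
    standardize: bool = False,
) -> np.ndarray:
    """ln(iES_target / iES_other) per SNP (unstandardized unless requested).

    In the full scan the log ratios are standardized genome-wide (median 0,
    SD 1) across chromosomes; pass ``standardize=True`` when a single panel
    pair is the whole genome.  SNPs where either iES is zero are NaN.
    """
    if not np.array_equal(panel_target.positions, panel_other.positions):
        raise ValueError("panels must share positions")
    ies_t = ies(panel_target, decay, max_extension_bp)
    ies_o = ies(panel_other, decay, max_extension_bp)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log(ies_t / ies_o)
    raw[(ies_t <= 0) | (ies_o <= 0)] = np.nan
    return standardize_lnrsb(raw) if standardize else raw


def standardize_lnrsb(raw: np.ndarray) -> np.ndarray:
    """Genome standardization: subtract the median, divide by the SD."""
    ok = np.isfinite(raw)
    if ok.sum() < 2:
        return np.full_like(raw, np.nan)
    med = np.median(raw[ok])
    sd = raw[ok].std()
    if sd == 0:
        out = np.full_like(raw, np.nan)
        out[ok] = 0.0
        return out
    return (raw - med) / sd


# ---------------------------------------------------------------------------
# composite score


def empirical_p(values: np.ndarray) -> np.ndarray:
    """One-sided empirical p-values by rank, large = extreme.

    ``p_i = rank_from_top(i) / (N + 1)`` with average ranks on ties, so p is
    always strictly inside (0, 1) and the composite score stays finite.
    Missing (NaN) entries get NaN p-values and are excluded from N.
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("empirical_p needs at least two non-missing values")
    out = np.full(values.shape, np.nan)
    ranks = rankdata(-values[ok], method="average")
    out[ok] = ranks / (n + 1.0)
    return out


def cms(p_values: np.ndarray, pi: float = 0.01, form: str = "odds") -> np.ndarray:
    """Composite score from per-test empirical p-values.

    Parameters
    ----------
    p_values : array, shape (n_tests, n_snps) or (n_tests,)
        Empirical p-values of the individual tests, all strictly in (0, 1).
        A SNP missing any test (NaN) gets no score.
    pi : float
        Prior fraction of the genome under positive selection.
    form : {"odds", "posterior", "log10"}
        "odds" (default): product of posterior odds ``f_i / (1 - f_i)`` —
        unbounded, so an absolute threshold such as 10 is meaningful.
        "posterior": literal product of the posterior factors ``f_i`` (in
        (0, 1)).  "log10": log10 of the odds product.
    """
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    single = p.ndim == 1
    if single:
        p = p[:, None]
    finite = np.isfinite(p)
    if np.any((p[finite] <= 0.0) | (p[finite] >= 1.0)):
        raise ValueError("empirical p-values must lie strictly in (0, 1)")
    with np.errstate(invalid="ignore"):
        f = (1.0 - p) * pi / ((1.0 - p) * pi + p * (1.0 - pi))
        if form == "posterior":
            score = np.prod(f, axis=0)
        elif form == "odds":
            score = np.prod(f / (1.0 - f), axis=0)
        elif form == "log10":
            score = np.log10(np.prod(f / (1.0 - f), axis=0))
        else:
            raise ValueError(f"unknown CMS form: {form!r}")
    score = np.where(finite.all(axis=0), score, np.nan)
    return float(score[0]) if single else score


# ---------------------------------------------------------------------------
# scan driver


def compute_snp_stats(
    panels: dict[str, list[HaplotypePanel]],
    target: str,
    pi: float = 0.01,
    cms_form: str = "odds",
    decay: float = 0.05,
    max_extension_bp: int = 500_000,
) -> pd.DataFrame:
    """Per-SNP statistics and CMS for one target population.

    ``panels`` maps population label to its per-chromosome panels; all
    populations must cover the same chromosomes/positions.  Empirical
    p-values and the lnRsb standardization are computed genome-wide (all
    chromosomes pooled).
    """
    if target not in panels:
        raise KeyError(f"target population {target!r} not in panels")
    others = [p for p in panels if p != target]
    if not others:
        raise ValueError("need at least two populations")
    chrom_tables = []
    for i, tpanel in enumerate(panels[target]):
        opanels = [panels[o][i] for o in others]
        pooled = pool_panels(opanels)
        daf_t = daf(tpanel)
        ddaf = delta_daf(daf_t, np.stack([daf(op) for op in opanels]))
        fst = fst_per_snp([tpanel, pooled])
        lnrsb_raw = ln_rsb(tpanel, pooled, decay, max_extension_bp)
        chrom_tables.append(
            pd.DataFrame(
                {
                    "chrom": tpanel.chrom,
                    "pos": tpanel.positions,
                    "daf": daf_t,
                    "ddaf": ddaf,
                    "fst": fst,
                    "lnrsb": lnrsb_raw,
                }
            )
        )
    table = pd.concat(chrom_tables, ignore_index=True)
    table["lnrsb"] = standardize_lnrsb(table["lnrsb"].to_numpy())
    for col in STAT_COLUMNS:
        table[f"p_{col}"] = empirical_p(table[col].to_numpy())
    pmat = table[[f"p_{c}" for c in STAT_COLUMNS]].to_numpy().T
    table["cms"] = cms(pmat, pi=pi, form=cms_form)
    n_dropped = int(table["cms"].isna().sum())
    if n_dropped:
        logger.info("%d SNPs lack a statistic and get no CMS", n_dropped)
    return table


@dataclass
class SelectionRegion:
    """A run of top SNPs (< 10 kb apart, >= 2 SNPs) with its peak."""

    chrom: str
    start: int
    end: int
    snp_positions: np.ndarray
    peak_pos: int
    peak_cms: float
    gene: str | None = None


def cms_cutoff(table: pd.DataFrame, threshold: float = 10.0, mode: str = "absolute") -> float:
    """Resolve the top-SNP cutoff: an absolute score or a top rank fraction."""
    if mode == "absolute":
        return float(threshold)
    if mode == "top_fraction":
        scores = table["cms"].dropna().to_numpy()
        if scores.size == 0:
            return np.inf
        return float(np.quantile(scores, 1.0 - threshold))
    raise ValueError(f"unknown threshold mode: {mode!r}")


def call_regions(
    table: pd.DataFrame,
    cms_threshold: float = 10.0,
    threshold_mode: str = "absolute",
    max_gap_bp: int = 10_000,
) -> list[SelectionRegion]:
    """Chain top SNPs into candidate regions.

    Top SNPs are those with CMS at or above the cutoff; consecutive top SNPs
    strictly less than ``max_gap_bp`` apart are connected; single-SNP regions
    are removed.  The peak SNP is the member with the highest CMS (leftmost
    on ties).
    """
    cut = cms_cutoff(table, cms_threshold, threshold_mode)
    regions: list[SelectionRegion] = []
    top = table[table["cms"] >= cut]
    for chrom, sub in top.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        score = sub["cms"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, score = pos[order], score[order]
        breaks = np.flatnonzero(np.diff(pos) >= max_gap_bp)
        for chunk in np.split(np.arange(pos.size), breaks + 1):
            if chunk.size < 2:
                continue
            cpos, cscore = pos[chunk], score[chunk]
            peak = int(np.argmax(cscore))  # argmax takes the leftmost maximum
            regions.append(
                SelectionRegion(
                    chrom=str(chrom),
                    start=int(cpos[0]),
                    end=int(cpos[-1]),
                    snp_positions=cpos,
                    peak_pos=int(cpos[peak]),
                    peak_cms=float(cscore[peak]),
                )
            )
    return regions


def assign_gene(region: SelectionRegion, genes: pd.DataFrame, max_dist: int = 20_000) -> str | None:
    """Candidate gene of a region: span containment, else nearest boundary <= 20 kb."""
    sub = genes[genes["chrom"] == region.chrom]
    if sub.empty:
        return None
    inside = sub[(sub["start"] <= region.peak_pos) & (region.peak_pos <= sub["end"])]
    if not inside.empty:
        return str(inside.sort_values("start").iloc[0]["gene"])
    dist = np.maximum(sub["start"] - region.peak_pos, region.peak_pos - sub["end"])
    best = dist.min()
    if best > max_dist:
        return None
    nearest = sub[dist == best]
    return str(nearest.sort_values("start").iloc[0]["gene"])


def candidate_genes(
    regions: list[SelectionRegion],
    genes: pd.DataFrame,
    population: str,
    max_dist: int = 20_000,
) -> pd.DataFrame:
    """Map every region to its candidate gene; one row per gene (max peak CMS)."""
    rows = []
    for region in regions:
        g = assign_gene(region, genes, max_dist)
        region.gene = g
        if g is not None:
            rows.append((g, region.peak_cms))
    return _dedup_candidates(rows, population)


def assign_gene_lengthfree(
    regions: list[SelectionRegion],
    genes: pd.DataFrame,
    population: str,
    max_dist: int = 150_000,
) -> pd.DataFrame:
    """Length-free candidate set: nearest gene midpoint to each region peak.

    Genes are surrogated by their central position so gene length carries no
    weight; a region is assigned only if the nearest midpoint lies within
    ``max_dist`` (150 kb by default).  Each gene keeps its best peak CMS.
    """
    rows = []
    for region in regions:
        sub = genes[genes["chrom"] == region.chrom]
        if sub.empty:
            continue
        dist = (sub["midpoint"] - region.peak_pos).abs()
        best = dist.min()
        if best > max_dist:
            continue
        nearest = sub[dist == best].sort_values("start").iloc[0]
        rows.append((str(nearest["gene"]), region.peak_cms))
    return _dedup_candidates(rows, population)


def _dedup_candidates(rows: list[tuple[str, float]], population: str) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["gene", "peak_cms"])
    if not df.empty:
        df = (
            df.sort_values(["gene", "peak_cms"], ascending=[True, False])
            .drop_duplicates("gene")
            .reset_index(drop=True)
        )
    df["population"] = population
    return df
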