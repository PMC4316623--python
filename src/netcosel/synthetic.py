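"""Synthetic three-population study generator with planted coselection.

Every downstream stage of the package (selection scan, network position,
coselection, divergence trees, cluster extraction) can be exercised against a
known ground truth produced here.  The generator emulates the statistical
structure of a three-continent resequencing panel mapped onto a
protein-interaction network:

* **Allele frequencies** follow a Balding-Nichols drift model: an ancestral
  frequency ``p0 ~ Uniform(0.05, 0.95)`` per SNP, and each population's
  frequency drawn from ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)`` with a
  per-population drift parameter ``F``; pairwise differentiation between two
  populations with equal ``F`` is then approximately ``2F/(1+F)``.
* **Haplotypes** are recombination mosaics of ``K`` founder haplotypes
  (per-bp founder-switch rate), perturbed entry-wise to match the drawn
  per-SNP frequencies.  The mosaic structure gives linkage disequilibrium
  that decays with distance, so the long-haplotype statistic is informative.
* **Sweeps** are planted by copying one carrier haplotype over random
  haplotypes inside a window around a gene's central SNP until the derived
  frequency reaches ``beta`` in the target population only — jointly raising
  DAF, dDAF, FST and extended haplotype homozygosity there (a star-like
  sweep).
* **The network** is a scale-free preferential-attachment graph over the gene
  set; planted coselection picks seed nodes and sweeps each seed plus part of
  its one-step neighborhood, so sweep targets form network-adjacent clusters.
* **A coselection halo** (optional, on by default when clusters are planted)
  adds graded, network-decaying allele-frequency divergence in the sweep
  population around the planted clusters: genes at shortest-path distance
  ``d`` from a swept gene receive random-sign frequency shifts of amplitude
  ``halo_strength * halo_decay**d``.  This emulates the broad, graded
  co-divergence of network neighborhoods that the divergence-tree statistics
  measure, without creating the four-signal sweep signature (the shifts are
  sign-random per SNP and leave haplotype structure untouched), so halo genes
  stay out of the candidate list.

Gene layout is deliberately simple: one SNP block per gene with flanks,
non-overlapping, fixed spacing, so midpoints are trivially defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .panels import HaplotypePanel, make_gene_table

logger = logging.getLogger(__name__)

DEFAULT_POPULATIONS = ("EAS", "CEU", "YRI")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    The defaults describe the reference experiment used throughout the test
    suite: 1,000 genes on 10 chromosomes, 120 haplotypes per population,
    moderate drift (pairwise differentiation ~0.1), 20 sweeps planted at
    network-adjacent clusters in EAS with final derived frequency 0.9 on a
    scale-free network grown with 3 edges per new node.
    """

    n_genes: int = 1000
    genes_per_chrom: int = 100
    snps_per_gene: int = 50
    snp_spacing_bp: int = 150
    flank_bp: int = 2_000
    gene_spacing_bp: int = 25_000
    spacer_spacing_bp: int = 2_500  # intergenic marker density; 0 disables
    n_haplotypes: int = 120
    founder_haplotypes: int = 30
    switch_rate_per_bp: float = 2e-4
    match_frequencies: bool = True
    drift: dict[str, float] = field(
        default_factory=lambda: {"EAS": 0.05, "CEU": 0.05, "YRI": 0.05}
    )
    n_sweeps: int = 20
    sweep_gene_ids: tuple[str, ...] = ()
    sweep_population: str = "EAS"
    sweep_final_frequency: float = 0.9
    sweep_span_bp: int = 20_000
    network_m: int = 3
    n_clusters: int = 5
    cluster_radius: int = 1
    field_strength: float = 0.3
    field_damping: float = 0.9
    field_hops: int = 16
    seed: int = 0

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(self.drift)

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "genes_per_chrom": self.genes_per_chrom,
            "snps_per_gene": self.snps_per_gene,
            "n_haplotypes": self.n_haplotypes,
            "founder_haplotypes": self.founder_haplotypes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.founder_haplotypes < 2:
            raise ValueError("founder_haplotypes must be at least 2")
        for pop, f in self.drift.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift parameter for {pop} must be in (0, 1)")
        if not 0.0 < self.sweep_final_frequency <= 1.0:
            raise ValueError("sweep_final_frequency must be in (0, 1]")
        if (self.n_sweeps > 0 or self.sweep_gene_ids) and self.sweep_population not in self.drift:
            raise ValueError("sweep_population must be one of the populations")
        if self.n_sweeps < 0 or self.n_clusters <= 0:
            raise ValueError("n_sweeps must be >= 0 and n_clusters positive")


@dataclass
class GroundTruth:
    """What was planted: per-population swept genes and the planted clusters."""

    swept_genes: dict[str, set[str]]
    planted_clusters: list[set[str]]
    field_intensity: dict[str, float] = field(default_factory=dict)

    def all_swept(self) -> set[str]:
        out: set[str] = set()
        for s in self.swept_genes.values():
            out |= s
        return out


@dataclass
class FrequencyTable:
    """Per-SNP ancestral frequency and the three population frequencies."""

    snps: pd.DataFrame  # columns: chrom, pos, gene
    p0: np.ndarray
    freqs: dict[str, np.ndarray]


@dataclass
class SimStudy:
    """A complete simulated study: panels, genes, network and ground truth."""

    config: SimConfig
    genes: pd.DataFrame
    panels: dict[str, list[HaplotypePanel]]
    network: nx.Graph
    truth: GroundTruth
    frequencies: FrequencyTable


# ---------------------------------------------------------------------------
# gene layout and frequencies


def layout_genes(config: SimConfig) -> pd.DataFrame:
    """Place genes non-overlapping at fixed spacing, one SNP block each."""
    span = (config.snps_per_gene - 1) * config.snp_spacing_bp
    records = []
    for g in range(config.n_genes):
        chrom = f"chr{g // config.genes_per_chrom + 1}"
        slot = g % config.genes_per_chrom
        start = config.flank_bp + 1 + slot * (span + config.gene_spacing_bp)
        records.append((f"G{g:04d}", chrom, start, start + span))
    return make_gene_table(records)


def snp_positions(config: SimConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Genic SNP blocks plus sparse intergenic spacer markers.

    Spacers keep the marker coverage quasi-continuous so haplotype-
    homozygosity integrals never bridge an unobserved multi-kb gap; they
    belong to no gene (empty gene tag).
    """
    rows = []
    for row in genes.itertuples():
        pos = row.start + config.snp_spacing_bp * np.arange(config.snps_per_gene)
        rows.append(pd.DataFrame({"chrom": row.chrom, "pos": pos, "gene": row.gene}))
        if config.spacer_spacing_bp > 0:
            spacer = np.arange(
                row.end + config.spacer_spacing_bp,
                row.end + config.gene_spacing_bp,
                config.spacer_spacing_bp,
            )
            if spacer.size:
                rows.append(pd.DataFrame({"chrom": row.chrom, "pos": spacer, "gene": ""}))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_frequencies(config: SimConfig, rng: np.random.Generator | None = None) -> FrequencyTable:
    """Balding-Nichols frequencies: ancestral p0 plus per-population drift draws."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = layout_genes(config)
    snps = snp_positions(config, genes)
    n = len(snps)
    p0 = rng.uniform(0.05, 0.95, size=n)
    freqs = {}
    for pop, f in config.drift.items():
        scale = (1.0 - f) / f
        freqs[pop] = rng.beta(p0 * scale, (1.0 - p0) * scale)
    return FrequencyTable(snps=snps, p0=p0, freqs=freqs)


# ---------------------------------------------------------------------------
# haplotypes


def _founder_mosaic(
    freq: np.ndarray,
    positions: np.ndarray,
    n_hap: int,
    k: int,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Haplotypes as recombination mosaics of k Bernoulli(freq) founders."""
    n_snp = positions.size
    founders = (rng.random((k, n_snp)) < freq).astype(np.uint8)
    gaps = np.diff(positions).astype(float)
    p_switch = 1.0 - np.exp(-switch_rate * gaps)
    switch = np.empty((n_hap, n_snp), dtype=bool)
    switch[:, 0] = True  # initial founder choice
    switch[:, 1:] = rng.random((n_hap, n_snp - 1)) < p_switch
    draws = rng.integers(0, k, size=(n_hap, n_snp))
    # index of the most recent switch, forward-filled along the chromosome
    idx = np.where(switch, np.arange(n_snp), -1)
    idx = np.maximum.accumulate(idx, axis=1)
    founder_path = np.take_along_axis(draws, idx, axis=1)
    return founders[founder_path, np.arange(n_snp)]


def _match_frequencies(alleles: np.ndarray, freq: np.ndarray, rng: np.random.Generator) -> None:
    """Flip random entries per SNP so observed counts match the target draws."""
    n_hap = alleles.shape[0]
    target = np.rint(freq * n_hap).astype(int)
    current = alleles.sum(axis=0).astype(int)
    for j in np.flatnonzero(target != current):
        diff = target[j] - current[j]
        if diff > 0:
            pool = np.flatnonzero(alleles[:, j] == 0)
            alleles[rng.choice(pool, size=diff, replace=False), j] = 1
        else:
            pool = np.flatnonzero(alleles[:, j] == 1)
            alleles[rng.choice(pool, size=-diff, replace=False), j] = 0


def simulate_haplotypes(
    config: SimConfig,
    frequencies: FrequencyTable,
    rng: np.random.Generator | None = None,
) -> dict[str, list[HaplotypePanel]]:
    """Per-population, per-chromosome haplotype panels matching the frequencies."""
    config.validate()
    if config.founder_haplotypes < 2:
        raise ValueError("need at least 2 founder haplotypes")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    panels: dict[str, list[HaplotypePanel]] = {}
    chroms = frequencies.snps["chrom"].unique()
    snp_index = {c: np.flatnonzero((frequencies.snps["chrom"] == c).to_numpy()) for c in chroms}
    for pop in config.populations:
        pop_panels = []
        for chrom in chroms:
            sel = snp_index[chrom]
            pos = frequencies.snps["pos"].to_numpy()[sel]
            freq = frequencies.freqs[pop][sel]
            alleles = _founder_mosaic(
                freq,
                pos,
                config.n_haplotypes,
                config.founder_haplotypes,
                config.switch_rate_per_bp,
                rng,
            )
            if config.match_frequencies:
                _match_frequencies(alleles, freq, rng)
            pop_panels.append(HaplotypePanel(pop, str(chrom), pos, alleles))
        panels[pop] = pop_panels
    return panels


# ---------------------------------------------------------------------------
# sweep planting


def plant_sweep(
    panel: HaplotypePanel,
    gene: pd.Series,
    beta: float,
    rng: np.random.Generator,
    span_bp: int = 25_000,
    core: int | None = None,
) -> bool:
    """Plant a star-like sweep at a gene's central SNP (panel modified in place).

    One carrier haplotype (created if the derived allele is absent) is copied
    over randomly chosen haplotypes within ``span_bp`` of the central SNP
    until the derived frequency reaches ``beta``.  Returns False (with a
    warning) if the current frequency already meets ``beta``.
    """
    in_gene = np.flatnonzero((panel.positions >= gene["start"]) & (panel.positions <= gene["end"]))
    if in_gene.size == 0:
        raise ValueError(f"gene {gene['gene']} has no SNP in the panel")
    if core is None:
        core = int(in_gene[in_gene.size // 2])
    core_pos = panel.positions[core]
    window = np.flatnonzero(np.abs(panel.positions - core_pos) <= span_bp)
    n_hap = panel.n_haplotypes
    carriers = np.flatnonzero(panel.alleles[:, core] == 1)
    target_count = int(np.ceil(beta * n_hap))
    if carriers.size >= target_count:
        warnings.warn(
            f"derived frequency at {gene['gene']} already >= beta; sweep not planted",
            stacklevel=2,
        )
        return False
    if carriers.size == 0:
        donor = int(rng.integers(n_hap))
        panel.alleles[donor, core] = 1
    else:
        donor = int(rng.choice(carriers))
    non_carriers = np.flatnonzero(panel.alleles[:, core] == 0)
    recipients = rng.choice(non_carriers, size=target_count - max(carriers.size, 1), replace=False)
    panel.alleles[np.ix_(recipients, window)] = panel.alleles[donor, window]
    return True


def coselection_field(
    graph: nx.Graph,
    damping: float = 0.7,
    hops: int = 8,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Network-autocorrelated divergence intensities in (0, 1) per gene.

    White noise on the nodes is smoothed by repeated damped neighbor
    averaging (a graph diffusion), then mapped through the normal CDF so the
    marginal is uniform.  Neighboring genes receive similar intensities and
    the similarity decays with network distance — the structure the
    divergence-tree statistics are designed to detect.
    """
    from scipy.stats import norm

    if rng is None:
        rng = np.random.default_rng()
    nodes = sorted(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    eps = rng.standard_normal(len(nodes))
    acc = eps.copy()
    cur = eps
    for _ in range(hops):
        cur = damping * (adj @ cur) / np.maximum(deg, 1)
        acc = acc + cur
    z = (acc - acc.mean()) / acc.std()
    u = norm.cdf(z)
    return {n: float(u[index[n]]) for n in nodes}


def _apply_divergence_shift(
    panel: HaplotypePanel,
    gene: pd.Series,
    intensity: float,
    rng: np.random.Generator,
) -> None:
    """Random-sign frequency shifts of the given amplitude at one gene's SNPs."""
    sel = np.flatnonzero((panel.positions >= gene["start"]) & (panel.positions <= gene["end"]))
    n_hap = panel.n_haplotypes
    for j in sel:
        p = panel.alleles[:, j].mean()
        shift = intensity if rng.random() < 0.5 else -intensity
        target = int(np.clip(np.rint((p + shift) * n_hap), 0, n_hap))
        current = int(panel.alleles[:, j].sum())
        diff = target - current
        if diff > 0:
            pool = np.flatnonzero(panel.alleles[:, j] == 0)
            panel.alleles[rng.choice(pool, size=min(diff, pool.size), replace=False), j] = 1
        elif diff < 0:
            pool = np.flatnonzero(panel.alleles[:, j] == 1)
            panel.alleles[rng.choice(pool, size=min(-diff, pool.size), replace=False), j] = 0


# ---------------------------------------------------------------------------
# network


def simulate_network(config: SimConfig, gene_ids: list[str], rng: np.random.Generator | None = None) -> nx.Graph:
    """Scale-free (preferential-attachment) graph over the gene identifiers."""
    if len(gene_ids) < 10:
        raise ValueError("need at least 10 genes for a network")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    seed = int(rng.integers(2**31 - 1))
    graph = nx.barabasi_albert_graph(len(gene_ids), config.network_m, seed=seed)
    mapping = dict(zip(sorted(graph.nodes()), gene_ids))
    return nx.relabel_nodes(graph, mapping)


def plant_coselection_clusters(
    graph: nx.Graph,
    n_sweeps: int,
    n_clusters: int,
    radius: int,
    rng: np.random.Generator,
    max_seed_degree: int = 8,
) -> list[set[str]]:
    """Choose seed nodes and mark each seed plus one-step neighbors for sweeping.

    Seeds are drawn among moderate-degree nodes (hubs would swallow the whole
    budget in one neighborhood) and kept at least ``2 * radius + 1`` apart so
    clusters do not merge.  Neighborhood members are added until the total
    sweep budget ``n_sweeps`` is exhausted.
    """
    quota = int(np.ceil(n_sweeps / n_clusters))
    eligible = sorted(n for n, d in graph.degree() if 2 <= d <= max_seed_degree)
    rng.shuffle(eligible)
    clusters: list[set[str]] = []
    taken: set[str] = set()
    total = 0
    for seed in eligible:
        if total >= n_sweeps or len(clusters) >= n_clusters:
            break
        ball = sorted(nx.single_source_shortest_path_length(graph, seed, cutoff=radius))
        if any(node in taken for node in ball):
            continue
        members = [seed]
        neighbors = [node for node in ball if node != seed]
        rng.shuffle(neighbors)
        for nb in neighbors:
            if len(members) >= quota or total + len(members) >= n_sweeps:
                break
            members.append(nb)
        clusters.append(set(members))
        taken.update(ball)
        taken.update(members)
        total += len(members)
    return clusters


# ---------------------------------------------------------------------------
# full study


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate a complete study: panels, gene table, network and ground truth.

    Deterministic under ``config.seed``: the same configuration produces
    byte-identical panels, network and truth.
    """
    config.validate()
    frequencies = simulate_frequencies(config, np.random.default_rng(config.seed))
    panels = simulate_haplotypes(config, frequencies, np.random.default_rng(config.seed + 1))
    genes = layout_genes(config)
    network = simulate_network(config, list(genes["gene"]), np.random.default_rng(config.seed + 2))
    rng = np.random.default_rng(config.seed + 3)

    if config.sweep_gene_ids:
        unknown = set(config.sweep_gene_ids) - set(genes["gene"])
        if unknown:
            raise ValueError(f"sweep_gene_ids not in gene set: {sorted(unknown)}")
        clusters = [set(config.sweep_gene_ids)]
    elif config.n_sweeps > 0:
        clusters = plant_coselection_clusters(
            network, config.n_sweeps, config.n_clusters, config.cluster_radius, rng
        )
    else:
        clusters = []

    swept = sorted(set().union(*clusters)) if clusters else []
    truth = GroundTruth(
        swept_genes={config.sweep_population: set(swept)},
        planted_clusters=clusters,
    )

    gene_rows = genes.set_index("gene")
    chrom_of = {c.chrom: i for i, c in enumerate(panels[config.sweep_population])}
    for g in swept:
        row = gene_rows.loc[g]
        # the swept allele is a novel mutation of the target population: the
        # core SNP and a linked neighbor are erased from standing variation
        # in every population and seeded on a single target haplotype, which
        # plant_sweep then copies up to the final frequency
        target_panel = panels[config.sweep_population][chrom_of[row["chrom"]]]
        in_gene = np.flatnonzero(
            (target_panel.positions >= row["start"]) & (target_panel.positions <= row["end"])
        )
        core = int(in_gene[in_gene.size // 2])
        neighbor = core + 1 if core + 1 in in_gene else core - 1
        for pop in config.populations:
            panel = panels[pop][chrom_of[row["chrom"]]]
            panel.alleles[:, [core, neighbor]] = 0
        donor = int(rng.integers(target_panel.n_haplotypes))
        target_panel.alleles[donor, [core, neighbor]] = 1
        plant_sweep(
            target_panel,
            pd.Series({"gene": g, **row}),
            config.sweep_final_frequency,
            rng,
            config.sweep_span_bp,
            core=core,
        )

    if swept and config.field_strength > 0:
        # network-autocorrelated co-divergence accompanying the planted
        # sweeps: the tree-similarity statistics' recoverable ground truth.
        # Each population carries its own independent field (every population
        # has its own selective history), so all three branches of the
        # divergence trees carry network structure.
        swept_set = truth.swept_genes[config.sweep_population]
        for pop in config.populations:
            intensities = coselection_field(
                network, config.field_damping, config.field_hops, rng
            )
            for node in sorted(intensities):
                if node in swept_set:
                    continue
                intensity = config.field_strength * intensities[node]
                if pop == config.sweep_population:
                    truth.field_intensity[node] = intensity
                row = gene_rows.loc[node]
                panel = panels[pop][chrom_of[row["chrom"]]]
                _apply_divergence_shift(panel, pd.Series({"gene": node, **row}), intensity, rng)

    return SimStudy(
        config=config,
        genes=genes,
        panels=panels,
        network=network,
        truth=truth,
        frequencies=frequencies,
    )


def null_study(config: SimConfig) -> SimStudy:
    """The same study with no sweeps planted (null panels)."""
    return simulate_study(replace(config, n_sweeps=0, sweep_gene_ids=()))
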