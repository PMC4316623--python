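# Methods

## The analysis in one paragraph

`netcosel` asks whether genes carrying signals of recent positive selection
are arranged non-randomly on a protein–protein-interaction (PPI) network.
It (1) scans phased three-population haplotype panels for sweeps with a
composite score (CMS) built from four per-SNP statistics, (2) maps candidate
genes onto the network and tests their centrality placement and mutual
shortest-path distances against equal-size resampling nulls, (3) builds a
per-gene trifurcate divergence tree from pairwise gene-level F_ST and tests
whether tree similarity between two genes decays with their network
distance, and (4) extracts "coselection clusters" — candidate genes joined
by direct interactions whose divergence trees deviated from the genome
median in the same direction.  A synthetic-data generator with planted
ground truth drives all testing.

## Selection scan

Per SNP in a target population, four sweep signals are computed:

* **DAF** — derived allele frequency (ancestral/derived coding comes from
  the `AA` tag of the input VCF, or from the simulator).
* **dDAF** — `DAF(target) − mean(DAF(other populations))`.  The mean-of-
  others convention is one of several defensible poolings; it is symmetric
  in the others and cheap.
* **F_ST** — Weir–Cockerham θ̂ between the target and the *pooled* other
  populations.  The haploid (haplotype-count) ANOVA formulation is used:
  θ̂ = (MSP − MSG) / (MSP + (n_c − 1)·MSG).  Negative estimates are kept
  (they are informative for ranking); SNPs monomorphic everywhere are
  undefined and carry no score.
* **lnRsb** — log-ratio of integrated site-specific extended haplotype
  homozygosity (iES) between target and pooled others, genome-standardized
  (median 0, SD 1).  EHHS at distance d from a core SNP is the probability
  that two random haplotypes are identical over every SNP from the core to
  d; iES integrates the profile in bp by the trapezoid rule in both
  directions, truncated when EHHS < 0.05 (the first sub-threshold point is
  included), at 500 kb, or at the chromosome end.  Both cutoffs are
  configurable; the decay threshold matters most and 0.05 is the
  conventional choice.

Each statistic is mapped to a one-sided empirical p-value by rank
(large = sweep-like), `p = rank_from_top / (N + 1)` with average ranks on
ties, so p ∈ (0,1) strictly and the composite never degenerates.  The
composite per-test factor is

    f_i = (1 − p_i)·π / ((1 − p_i)·π + p_i·(1 − π)),   π = 0.01 by default

(π is the prior fraction of the genome under selection).  The default CMS
is the product over the four tests of the posterior odds `f_i/(1 − f_i)`.
The literal product of the `f_i` is bounded by 1, which is incompatible
with the conventional absolute threshold of 10; the odds product is a
strictly monotone per-factor transform that makes absolute thresholds
meaningful while leaving all rankings identical.  Both forms (and a log10
variant) are exposed; threshold semantics are configurable as an absolute
score or a top-rank fraction.

Top SNPs closer than 10 kb (strict) are chained into regions; single-SNP
regions are dropped; the peak is the member with maximal CMS (leftmost on
ties).  A region's candidate gene is the gene whose span contains the peak,
else the nearest gene boundary within 20 kb (leftmost start on ties), else
none.  The length-free variant assigns the gene whose *midpoint* is nearest
the peak within 150 kb, removing gene-length bias; duplicates keep the
higher peak CMS.

## Network analyses

Networks are simple undirected graphs over uppercase gene symbols, parsed
from HPRD-flat, SIF or two-column edge-list files (self-loops and duplicate
edges dropped with logged counts).  All statistics run on the largest
connected component.  Betweenness uses the igraph/networkx convention —
unordered pairs, equal shortest paths split as σ_st(v)/σ_st, unnormalized —
and all-pairs shortest path lengths come from BFS (scipy.sparse.csgraph).

Enrichment tests resample node sets of the same size as the candidate list
(10,000 draws by default; experiments here scale that down).  Per
centrality interval or per SPL value d, the observed candidate proportion
is compared with the resampled null by a Z-score and an add-one empirical
rank p-value ((1+count)/(1+n_perm)), two-sided by default (min tail
doubled, capped at 1), BH-FDR-corrected across bins.  SPL ≥ 9 is pooled.
For SPL coselection the "relative proportion" divides the observed
proportion by the no-coselection expectation C(k,2)/C(n,2); its pair-count-
weighted average is exactly 1, a conservation identity the tests assert.
Intervals with zero occupancy or zero null SD are flagged and carry no
Z/p; bins with fewer than 10 pairs are flagged low-support.

Degree intervals default to {1},{2–3},{4–5},{6–9},{10–20},{>20} and
betweenness intervals to {0},(0–10],(10–100],(100–500],(500–2000],
(2000–20000],{>20000}; both are configurable.  Betweenness strata
(peripheral ≤ 100 < intermediate ≤ 20,000 < core) and the 500-kb cis-edge
filter (drop edges whose endpoint gene midpoints are within 500 kb on one
chromosome) are provided as confounder controls; stratified analyses reuse
the global distances.

## Divergence trees

Gene-level pairwise F_ST is the WC ratio of sums over the SNPs inside the
annotated gene span (no flanks; the window is configurable).  Branch
lengths follow the three-point formula D_i = ½(F_ST(i,j) + F_ST(i,k) −
F_ST(j,k)); additivity D_i + D_j = F_ST(i,j) is exact by construction and
negative branches are retained.

* **RTD**: genes are ranked by D_i within each population (average ranks on
  ties); RTD is the mean absolute rank difference over the three
  populations, normalized over all pairs to mean 0 / SD 1.
* **Syn**: (1/3)·Σ_i (D_ai − D′_i)(D_bi − D′_i)/SD_i², with D′_i the
  genome median and SD_i the population SD over the analysis cohort (the
  network-mapped genes, matching the reshuffling universe).

Profiles of mean RTD/Syn per SPL bin are tested against a null in which
each population's divergence-rate vector is independently permuted across
the network genes (1,000 reshuffles by default), with add-one two-sided
rank p-values per bin.  Two numerical points are worth knowing:

* Because Syn centers on the *median* and gene-level F_ST is right-skewed,
  the permutation-null mean of Syn is not 0 but the constant distinct-pair
  expectation Σ_i((Σz)² − Σz²)/(n(n−1))/3 — identical in every bin, so
  empirical p-values are unaffected.
* The headline Spearman trend of bin means vs SPL excludes bins holding
  under 0.1% of all pairs (flagged `in_trend=False`).  On a 1,000-node
  scale-free graph the SPL-6 bin holds ~40 of ~500,000 pairs; its mean is
  sampling noise on the scale of the whole signal and would otherwise get
  the same Spearman vote as a 200,000-pair bin.

## Coselection clusters

Candidate genes induce a subgraph of the LCC; its connected components are
the candidate subnetworks (largest first, lexicographic tie-break).  Edges
are then kept only when the endpoint pair's Syn score is strictly above a
threshold (1.5 is the conventional operating point; the retained-edge
fraction is reported so users can calibrate their own threshold), and the
resulting components are the coselection clusters.  Raising the threshold
only refines clusters, never merges them.  Each cluster is annotated with
per-gene CMS, its hubs (maximal within-cluster degree, ties keep all) and
its peak (maximal CMS) member; plain-text symbol lists and a summary TSV
are exported for external enrichment tools (enrichment itself is out of
scope).

## The synthetic generator

The generator emulates the statistical structure the pipeline consumes,
not demography:

* **Frequencies**: Balding–Nichols drift — p0 ~ U(0.05, 0.95) per SNP,
  population frequency ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F).  Note that the
  mean pairwise WC θ̂ between two populations with equal F is ≈ F (the
  between-population variance component is F·p0q0 on a total of p0q0).
  Default F = 0.05 per population gives differentiation near the
  continental-human scale.
* **Haplotypes**: mosaics of K = 30 founders with a per-bp founder-switch
  rate of 2×10⁻⁴, then entry-flips to match the drawn frequencies
  (optional).  This yields r² decaying with distance and EHHS decaying
  within a few kb — enough LD for lnRsb to be informative.  Gene layout is
  one 50-SNP block per gene (150 bp spacing) with 2 kb flanks and 25 kb
  spacing, 100 genes per chromosome; sparse intergenic "spacer" markers
  every 2.5 kb keep marker coverage quasi-continuous so iES never bridges
  an unobserved multi-kb gap in one trapezoid step (without them the null
  lnRsb acquires a heavy artifactual tail).
* **Sweeps**: star-like haplotype copying.  The swept allele is modelled as
  a novel mutation of the target population: the core SNP and one linked
  neighbor are erased from standing variation in all populations, seeded on
  one target haplotype, and that haplotype's ±20 kb window is copied over
  random haplotypes until the derived frequency reaches β (0.9 by
  default).  This is the textbook strong-sweep signature (a nearly fixed
  population-specific difference, EDAR-style) and gives each swept gene a
  reproducible two-SNP peak; sweeps on standing variation vary so much in
  cross-population signal that a fixed top-rank cutoff concentrates on a
  few genes.
* **Network and planting**: Barabási–Albert graph (m = 3) over the genes;
  coselection is planted by choosing moderate-degree seed nodes and
  sweeping each seed plus part of its one-step neighborhood (20 swept genes
  in 5 clusters by default), so within-cluster SPL ≤ 2.
* **Coselection field**: whenever sweeps are planted, each population also
  receives an independent network-autocorrelated divergence field —
  white noise on the nodes smoothed by damped neighbor averaging (damping
  0.9, 16 hops), mapped through the normal CDF and scaled to 0.3 —
  applied as random-sign allele-frequency shifts per gene.  This creates
  graded co-divergence whose pairwise similarity decays with network
  distance at all scales, which is the structure the divergence-tree
  statistics measure.  Twenty isolated cluster pairs among half a million
  cannot move bin means measurably (a ~0.005σ shift against a ~0.02σ bin
  SE), so without the field the tree-similarity trend would be
  statistically unrecoverable at this problem size.  The shifts are
  sign-random per SNP and leave haplotype structure untouched, so field
  genes do not acquire the four-signal sweep signature and stay out of the
  candidate list.  Null (sweep-free) studies carry no field.

What the generator does **not** emulate: growth, migration, recurrent
mutation, background selection, realistic recombination maps, gene-length
variation, or identifier ambiguity in the PPI network.  Passing tests
therefore demonstrate that the statistics recover the structure they are
designed for under a controlled model — not that real 1000-Genomes/HPRD
analyses would reach nominal power.

## Problem sizes and determinism

The test and acceptance experiments use, as this package's own reference
conditions: signal recovery on 1,000-gene studies (50 SNPs/gene plus
spacers ≈ 60k SNPs, 120 haplotypes × 3 populations, 20 replicates), and
null calibration on 400-gene studies (12 SNPs/gene, 60 haplotypes,
top-5% cutoff so candidate sets are large enough for the rank tests to
leave the discrete small-count regime).  Every stochastic routine takes an
explicit seed; identical configurations produce byte-identical panels,
networks and ground truth.  All resampling nulls use `numpy`'s PCG64
streams seeded from the caller.

## Known limitations

* The empirical-p/CMS scale depends on the SNP universe scanned; analyses
  mixing frequency-filtered and unfiltered inputs are not comparable.
* The add-one two-sided rank test is conservative for bins with few
  countable pairs (discrete nulls with large atoms).
* iES near chromosome ends is truncated, slightly deflating lnRsb there.
* `gene_fst` requires at least one SNP polymorphic in the pooled sample;
  dropped genes shrink the tree cohort and are only logged.
* The HPRD flat-file parser keys nodes by gene symbol and performs no
  alias resolution; unmapped candidate symbols are simply off-network.
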