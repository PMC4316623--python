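# netcosel

Recent-selection scans meet the protein–protein-interaction (PPI) network:
`netcosel` tests whether genes under recent positive selection in human-like
three-population data sit at particular network positions, lie closer to
each other than chance allows ("coselection"), and share recent
evolutionary paths with their network neighbors.  It is a library for
population geneticists and systems biologists who want to run this class of
analysis end to end on their own panels and networks — or on fully
synthetic data with planted ground truth.

## What it computes

**Composite selection scan.**  Per SNP and target population, four sweep
signals — derived allele frequency (DAF), its cross-population difference
(ΔDAF), Weir–Cockerham F_ST, and the long-haplotype statistic lnRsb
(log-ratio of integrated EHHS) — are converted to empirical p-values
p_i and combined with a prior π (default 0.01) through

    f_i = (1 − p_i)·π / ((1 − p_i)·π + p_i·(1 − π)),   CMS = ∏ f_i/(1 − f_i)

Top SNPs are chained into candidate regions (< 10 kb gaps, ≥ 2 SNPs) and
region peaks mapped to candidate genes.

**Network position and coselection.**  Degree/betweenness centralities on
the network's largest connected component; Mann–Whitney and resampling
enrichment tests per centrality interval; per-SPL (shortest path length)
coselection proportions normalized by the no-coselection expectation
C(k,2)/C(n,2), with resampling Z-scores, add-one empirical p-values and
BH-FDR; mean candidate-pair SPL against resampled node sets; betweenness
strata and a 500-kb cis-edge filter as confounder controls.

**Divergence trees.**  Per gene, branch lengths of the three-population
trifurcate tree, D_i = ½(F_ST(i,j) + F_ST(i,k) − F_ST(j,k)), from
gene-level F_ST; pairwise tree similarity via RTD (mean absolute rank
difference of divergence rates; low = similar) and Syn (mean standardized
residual product; positive = synergic divergence), profiled over SPL
against a divergence-reshuffling null.

**Coselection clusters.**  Candidate subnetworks filtered to one-step edges
with Syn above a threshold; clusters annotated with hub and peak-CMS
members and exported as gene lists for external enrichment tools.

**Synthetic studies.**  A generator producing three drifted populations
(Balding–Nichols frequencies, founder-mosaic haplotypes with realistic LD
decay), planted star-like sweeps at network-adjacent gene clusters on a
scale-free PPI graph, and a network-autocorrelated co-divergence field —
so every downstream statistic has a recoverable ground truth.  See
`docs/methods.md` for the model details and design rationale.

## Worked example

```python
from netcosel import (SimConfig, simulate_study, run_scan,
                      largest_connected_component, shortest_path_lengths,
                      spl_coselection, mean_spl_test)

study = simulate_study(SimConfig(seed=1))       # 1,000 genes, 20 planted sweeps
result = run_scan(study)                        # top 0.1% CMS cutoff
lcc = largest_connected_component(study.network)
spl = shortest_path_lengths(lcc)
cand = result.candidate_set(lcc)
profile = spl_coselection(cand, spl, n_perm=2000, seed=0)
print(profile[["spl", "n_pairs", "relative", "z", "p_adj"]].round(3).to_string(index=False))
m = mean_spl_test(cand, spl, n_perm=2000, seed=1)
print(f"mean SPL among candidates: {m['observed_mean_spl']:.2f} "
      f"vs network {spl.mean_spl:.2f} (p = {m['p']:.4f})")
```

prints (seed 1):

```
spl  n_pairs  relative      z  p_adj
  1     2991    14.942 13.057  0.006
  2    35368     2.453  3.292  0.033
  3   198486     0.967 -0.196  1.000
  4   236749     0.688 -2.043  0.114
  5    25839     0.509 -0.786  0.768
  6       67     0.000 -0.149  1.000

mean SPL among candidates: 3.03 vs network 3.50 (p = 0.0010)
```

Candidate pairs are ~15× overrepresented at direct interactions (SPL 1),
the excess decays monotonically with network distance, and the mean
network distance between candidates is significantly shorter than for
random gene sets — the coselection signature the planted clusters were
designed to produce.  The scan itself recovered all 20 planted sweeps
(`examples/02_selection_scan.py`), and the divergence-tree profile
(`examples/05_divergence_trees.py`) shows RTD rising with SPL (rho = +1.0)
and Syn falling — network-near genes share recent evolutionary paths.

Each script in `examples/` is a short narrative for one capability:
simulation and file export, the scan, network position, SPL coselection,
divergence trees, and Syn clusters.

Real data enter through the same surfaces: `netcosel.io.read_vcf` (phased
VCF with `AA` ancestral-allele tags plus a sample–population map),
`read_bed` for gene spans, and `netcosel.read_network` for HPRD-flat, SIF
or two-column edge-list PPI files.

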