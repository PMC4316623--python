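"""Numba kernel for site-specific extended haplotype homozygosity (EHHS).

EHHS at distance d from a core SNP is the probability that two haplotypes
drawn at random from the panel are identical over every SNP from the core out
to d (core included).  iES is the physical-distance (bp) trapezoid integral of
the EHHS profile away from the core in both directions, truncated where the
profile decays below a cutoff or a maximum extension is reached.  The
cross-population lnRsb statistic is the genome-standardized log ratio of iES
between two panels.

The kernel tracks haplotype identity classes incrementally: extending the
segment by one SNP refines the current partition by that SNP's alleles, and
EHHS is the unordered-pair homozygosity of the partition.  Identity classes
only split, so the profile is non-increasing by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _refine(labels, alleles_col, counts, remap):
    """Refine identity classes by one SNP column; return number of classes."""
    n = labels.shape[0]
    # tentative labels in [0, 2*n): old label * 2 + allele
    counts[:] = 0
    for i in range(n):
        labels[i] = labels[i] * 2 + alleles_col[i]
        counts[labels[i]] += 1
    # compact to [0, n_classes)
    k = 0
    for v in range(2 * n):
        if counts[v] > 0:
            remap[v] = k
            k += 1
    for i in range(n):
        labels[i] = remap[labels[i]]
    return k


@njit(cache=True)
def _homozygosity(labels, counts, n_classes):
    n = labels.shape[0]
    counts[:] = 0
    for i in range(n):
        counts[labels[i]] += 1
    s = 0.0
    for c in range(n_classes):
        s += counts[c] * (counts[c] - 1.0)
    return s / (n * (n - 1.0))


@njit(cache=True)
def ehhs_profile(alleles, core, direction, max_steps):
    """EHHS values at 1..max_steps SNPs away from ``core`` (core allele included)."""
    n_hap, n_snp = alleles.shape
    labels = np.zeros(n_hap, dtype=np.int64)
    counts = np.zeros(2 * n_hap, dtype=np.int64)
    remap = np.zeros(2 * n_hap, dtype=np.int64)
    k = _refine(labels, alleles[:, core], counts, remap)
    out = np.empty(max_steps, dtype=np.float64)
    m = 0
    j = core
    for _ in range(max_steps):
        j += direction
        if j < 0 or j >= n_snp:
            break
        k = _refine(labels, alleles[:, j], counts, remap)
        out[m] = _homozygosity(labels, counts, k)
        m += 1
    return out[:m]


@njit(cache=True)
def ies_scan(alleles, positions, decay, max_bp):
    """iES (integrated EHHS, bp units) at every SNP of a panel.

    For each core SNP the EHHS profile is extended in each direction until it
    drops below ``decay`` (the first sub-threshold point is included in the
    integral), the extension exceeds ``max_bp``, or the chromosome ends.  The
    profile is anchored at the core with EHHS = 1.
    """
    n_hap, n_snp = alleles.shape
    ies = np.zeros(n_snp, dtype=np.float64)
    labels = np.zeros(n_hap, dtype=np.int64)
    counts = np.zeros(2 * n_hap, dtype=np.int64)
    remap = np.zeros(2 * n_hap, dtype=np.int64)
    for core in range(n_snp):
        total = 0.0
        for direction in (-1, 1):
            # partition by the core allele itself; EHHS at the core is 1 by definition
            labels[:] = 0
            k = _refine(labels, alleles[:, core], counts, remap)
            prev_e = 1.0
            prev_x = positions[core]
            j = core
            while True:
                j += direction
                if j < 0 or j >= n_snp:
                    break
                if abs(positions[j] - positions[core]) > max_bp:
                    break
                k = _refine(labels, alleles[:, j], counts, remap)
                e = _homozygosity(labels, counts, k)
                x = positions[j]
                total += 0.5 * (prev_e + e) * abs(x - prev_x)
                prev_e = e
                prev_x = x
                if e < decay:
                    break
        ies[core] = total
    return ies
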