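"""Independent brute-force oracles for the differentiation statistics.

These are deliberately separate, loop-based transcriptions of the published
formulas (and exhaustive enumerations where feasible), kept free of any code
from the package so they can serve as cross-checks.
"""

from itertools import combinations
from math import comb, pi, sqrt


def wc_theta_oracle(pop1, pop2):
    """Weir & Cockerham (1984) multilocus theta for two samples.

    ``pop1``/``pop2`` are lists (one entry per locus) of lists of diploid
    genotype tuples; ``None`` marks a missing call.
    """
    num = den = 0.0
    for geno1, geno2 in zip(pop1, pop2):
        g1 = [g for g in geno1 if g is not None]
        g2 = [g for g in geno2 if g is not None]
        n1, n2 = len(g1), len(g2)
        if n1 < 1 or n2 < 1:
            continue
        alleles = sorted({a for g in g1 + g2 for a in g})
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        for al in alleles:
            p1 = sum(g.count(al) for g in g1) / (2 * n1)
            p2 = sum(g.count(al) for g in g2) / (2 * n2)
            h1 = sum(1 for g in g1 if (g[0] == al) != (g[1] == al)) / n1
            h2 = sum(1 for g in g2 if (g[0] == al) != (g[1] == al)) / n2
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def dest_oracle(pop1, pop2):
    """Jost's D_est (Nei–Chesser corrected, 2 demes, harmonic mean over loci)."""
    per_locus = []
    for geno1, geno2 in zip(pop1, pop2):
        g1 = [g for g in geno1 if g is not None]
        g2 = [g for g in geno2 if g is not None]
        n1, n2 = len(g1), len(g2)
        if n1 < 1 or n2 < 1:
            continue
        alleles = sorted({a for g in g1 + g2 for a in g})
        p1 = {al: sum(g.count(al) for g in g1) / (2 * n1) for al in alleles}
        p2 = {al: sum(g.count(al) for g in g2) / (2 * n2) for al in alleles}
        n_harm = 2 / (1 / n1 + 1 / n2)
        hs_plug = 1 - 0.5 * (sum(v**2 for v in p1.values()) + sum(v**2 for v in p2.values()))
        ht_plug = 1 - sum(((p1[al] + p2[al]) / 2) ** 2 for al in alleles)
        hs = (2 * n_harm / (2 * n_harm - 1)) * hs_plug
        ht = ht_plug + hs / (4 * n_harm)
        if 1 - hs == 0:
            continue
        d = (ht - hs) / (1 - hs) * 2
        per_locus.append(max(d, 0.0))
    if not per_locus:
        return 0.0
    if any(d == 0 for d in per_locus):
        return 0.0
    return len(per_locus) / sum(1 / d for d in per_locus)


def dce_oracle(freqs1, freqs2):
    """Cavalli-Sforza & Edwards chord distance from per-locus frequency dicts."""
    L = len(freqs1)
    total = 0.0
    for f1, f2 in zip(freqs1, freqs2):
        alleles = set(f1) | set(f2)
        f = 1.0 - sum(sqrt(f1.get(a, 0.0) * f2.get(a, 0.0)) for a in alleles)
        f = min(max(f, 0.0), 1.0)
        total += sqrt(2 * f)
    return (2 / (pi * L)) * total


def rarefied_richness_oracle(gene_list, g):
    """Exhaustive rarefaction: mean distinct alleles over all g-gene subsets."""
    n = len(gene_list)
    total = 0
    for subset in combinations(range(n), g):
        total += len({gene_list[i] for i in subset})
    return total / comb(n, g)


def holm_oracle(pvalues, alpha=0.05):
    """Step-down sequential Bonferroni: reject while p_(i) <= alpha/(m-i)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    reject = [False] * m
    for rank, i in enumerate(order):
        if pvalues[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def chapman_expectation(N, M, C):
    """Exact expectation of the Chapman estimator under hypergeometric R."""
    expect = 0.0
    for R in range(max(0, M + C - N), min(M, C) + 1):
        p = comb(M, R) * comb(N - M, C - R) / comb(N, C)
        expect += p * ((M + 1) * (C + 1) / (R + 1) - 1)
    return expect
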