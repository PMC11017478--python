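"""Diversity and differentiation statistics for multi-allelic diploid genotypes.

Implements the classical microsatellite toolbox: per-population diversity
(allele counts, rarefied allelic and private-allelic richness, observed and
unbiased expected heterozygosity, F_IS), Monte-Carlo Hardy–Weinberg exact-style
tests, Weir & Cockerham (1984) theta with bootstrap-over-loci confidence
intervals, Jost's D_est with Nei–Chesser bias correction, Cavalli-Sforza &
Edwards chord distances, and G-based allele-frequency heterogeneity tests with
Holm (sequential Bonferroni) correction.

Missing data are handled by genotype-wise deletion per locus throughout:
an individual untyped at a locus simply contributes nothing to that locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeTable

__all__ = [
    "allele_frequencies",
    "diversity_summary",
    "allelic_richness",
    "hwe_test",
    "weir_cockerham_theta",
    "pairwise_fst",
    "pairwise_dest",
    "chord_distance",
    "chord_distance_from_counts",
    "chord_distance_from_frequencies",
    "heterogeneity_test",
    "pairwise_heterogeneity",
    "sequential_bonferroni",
    "DiversitySummary",
    "FstResult",
]


# ---------------------------------------------------------------------------
# frequencies and diversity

def allele_frequencies(gt: GenotypeTable) -> pd.DataFrame:
    """Per-population, per-locus allele frequencies.

    Returns a long-format frame with columns ``population, locus, allele,
    frequency``.  A population x locus cell with zero typed individuals is
    reported as a single row with ``allele = NaN`` and ``frequency = NaN``
    (undefined, not zero).
    """
    counts, pops, n_typed = gt.counts()
    rows = []
    for p, pop in enumerate(pops):
        for l, locus in enumerate(gt.loci):
            total = 2 * n_typed[p, l]
            if total == 0:
                rows.append((pop, locus, np.nan, np.nan))
                continue
            for a in np.flatnonzero(counts[p, l]):
                rows.append((pop, locus, a + 1, counts[p, l, a] / total))
    return pd.DataFrame(rows, columns=["population", "locus", "allele", "frequency"])


def _wc_f_single_pop(counts_l: np.ndarray, het_l: np.ndarray, n: int):
    """Weir & Cockerham within-population f components for one pop x locus.

    Returns per-locus sums of the b and c variance components; ``f`` is
    ``1 - sum(c)/sum(b + c)`` accumulated across loci by the caller.
    """
    total = counts_l.sum()
    if total == 0 or n < 2:
        return np.nan, np.nan
    p = counts_l / total
    h = het_l / n
    b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
    c = h / 2.0
    return b.sum(), c.sum()


def _het_counts(gt: GenotypeTable):
    """Per pop x locus x allele counts of heterozygous carriers."""
    counts, pops, n_typed = gt.counts()
    a_max = counts.shape[2]
    het = np.zeros_like(counts)
    typed = gt.typed_mask()
    for p, pop in enumerate(pops):
        rows = gt.populations == pop
        sub = gt.alleles[rows]
        sub_typed = typed[rows]
        for l in range(gt.n_loci):
            calls = sub[sub_typed[:, l], l, :]
            is_het = calls[:, 0] != calls[:, 1]
            for col in (0, 1):
                np.add.at(het[p, l], calls[is_het, col] - 1, 1)
    del a_max
    return counts, het, pops, n_typed


@dataclass
class DiversitySummary:
    """Per-population diversity table plus per pop x locus HWE p-values."""

    table: pd.DataFrame
    hwe_pvalues: pd.DataFrame | None = None
    rarefaction_genes: int | None = None


def diversity_summary(gt: GenotypeTable, g: int = 16, hwe_permutations: int | None = None,
                      seed: int | None = None) -> DiversitySummary:
    """Standard per-population diversity statistics.

    ``Ho`` is the observed heterozygote fraction, ``He`` Nei's (1978)
    unbiased expected heterozygosity ``(2n/(2n-1)) (1 - sum p^2)``, ``Fis``
    the Weir & Cockerham (1984) within-population f.  Per-locus values are
    averaged across loci (monomorphic loci contribute He = 0 but are excluded
    from the Fis average, where f is undefined).  ``Ar``/``PAr`` are
    rarefied to ``g`` genes; populations with fewer typed genes at a locus
    are flagged with NaN there.
    """
    counts, het, pops, n_typed = _het_counts(gt)
    ar = allelic_richness(gt, g)
    records = []
    for p, pop in enumerate(pops):
        na_per_locus, ho_per_locus, he_per_locus = [], [], []
        b_sum, c_sum = 0.0, 0.0
        any_fis = False
        for l in range(gt.n_loci):
            n = n_typed[p, l]
            if n == 0:
                continue
            cl = counts[p, l]
            total = cl.sum()
            freqs = cl / total
            na_per_locus.append(int((cl > 0).sum()))
            n_het = het[p, l].sum() // 2  # each het counted for both alleles
            ho = n_het / n
            ho_per_locus.append(ho)
            he = (2 * n / (2 * n - 1.0)) * (1 - np.sum(freqs**2)) if n > 1 else np.nan
            he_per_locus.append(he)
            if (cl > 0).sum() >= 2 and n >= 2:
                b, c = _wc_f_single_pop(cl, het[p, l], n)
                b_sum += b
                c_sum += c
                any_fis = True
        fis = 1 - c_sum / (b_sum + c_sum) if any_fis and (b_sum + c_sum) != 0 else np.nan
        records.append({
            "population": pop,
            "N": int(np.sum(gt.populations == pop)),
            "NA_mean": float(np.mean(na_per_locus)) if na_per_locus else np.nan,
            "NA_sd": float(np.std(na_per_locus, ddof=1)) if len(na_per_locus) > 1 else np.nan,
            "Ar": ar.loc[pop, "Ar"],
            "PAr": ar.loc[pop, "PAr"],
            "Ho": float(np.nanmean(ho_per_locus)) if ho_per_locus else np.nan,
            "He": float(np.nanmean(he_per_locus)) if he_per_locus else np.nan,
            "Fis": fis,
        })
    table = pd.DataFrame.from_records(records).set_index("population")
    hwe = None
    if hwe_permutations is not None:
        hwe = hwe_test(gt, hwe_permutations, seed=seed)
    return DiversitySummary(table=table, hwe_pvalues=hwe, rarefaction_genes=g)


def _rarefied_richness(counts_l: np.ndarray, g: int) -> float:
    """Expected allele count in a draw of g genes (hypergeometric rarefaction)."""
    total = int(counts_l.sum())
    if g > total:
        return np.nan
    acc = 0.0
    denom = math.comb(total, g)
    for c in counts_l[counts_l > 0]:
        acc += 1.0 - math.comb(total - int(c), g) / denom
    return acc


def allelic_richness(gt: GenotypeTable, g: int = 16) -> pd.DataFrame:
    """Rarefied allelic richness ``Ar(g)`` and private allelic richness.

    ``Ar(g) = sum_a [1 - C(N - N_a, g) / C(N, g)]`` with ``N`` the typed
    genes at the locus and ``N_a`` copies of allele ``a``.  Private richness
    is the expected number of alleles present in a g-gene draw from the focal
    population *and absent* from independent g-gene draws from every other
    population (product of per-population absence probabilities).  Both are
    averaged over loci; loci with fewer than ``g`` typed genes in a
    population leave that population's value undefined (NaN) with a warning.
    """
    counts, pops, n_typed = gt.counts()
    ar = np.full((len(pops), gt.n_loci), np.nan)
    par = np.full((len(pops), gt.n_loci), np.nan)
    genes = 2 * n_typed
    for l in range(gt.n_loci):
        # absence probability of each allele in a g-draw from each population
        absent = np.ones((len(pops), counts.shape[2]))
        for p in range(len(pops)):
            total = int(genes[p, l])
            if total < g:
                continue
            denom = math.comb(total, g)
            for a in range(counts.shape[2]):
                c = int(counts[p, l, a])
                absent[p, a] = math.comb(total - c, g) / denom if c <= total else 0.0
        for p in range(len(pops)):
            total = int(genes[p, l])
            if total < g:
                continue
            present = 1.0 - absent[p]
            ar[p, l] = present.sum()
            others = [q for q in range(len(pops)) if q != p and genes[q, l] >= g]
            if others:
                par[p, l] = float(np.sum(present * np.prod(absent[others], axis=0)))
            else:
                par[p, l] = ar[p, l]
    short = [pops[p] for p in range(len(pops)) if np.isnan(ar[p]).any()]
    if short:
        warnings.warn(
            f"populations with < {g} typed genes at some locus excluded there: {short}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pd.DataFrame(
            {"Ar": np.nanmean(ar, axis=1), "PAr": np.nanmean(par, axis=1)},
            index=pd.Index(pops, name="population"),
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg

def _fis_plug(calls: np.ndarray) -> float:
    """W&C single-population f for an (n, 2) call array; NaN if undefined."""
    n = calls.shape[0]
    codes, inv = np.unique(calls.ravel(), return_inverse=True)
    if codes.size < 2 or n < 2:
        return np.nan
    cnt = np.bincount(inv, minlength=codes.size).astype(float)
    pairs = inv.reshape(n, 2)
    is_het = pairs[:, 0] != pairs[:, 1]
    het = np.zeros(codes.size)
    np.add.at(het, pairs[is_het, 0], 1)
    np.add.at(het, pairs[is_het, 1], 1)
    p = cnt / cnt.sum()
    h = het / n
    b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * h)
    c = h / 2.0
    denom = (b + c).sum()
    return 1 - c.sum() / denom if denom != 0 else np.nan


def hwe_test(gt: GenotypeTable, n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Monte-Carlo Hardy–Weinberg test per population x locus.

    Alleles are shuffled among the typed individuals of the cell and
    re-paired; the p-value is the add-one-corrected proportion of
    permutations with ``|f| >= |f_obs|``.  Cells with fewer than 5 typed
    individuals or a monomorphic allele pool are reported as NaN.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    typed = gt.typed_mask()
    pops = gt.population_names
    out = np.full((len(pops), gt.n_loci), np.nan)
    for p, pop in enumerate(pops):
        rows = gt.populations == pop
        sub = gt.alleles[rows]
        sub_typed = typed[rows]
        for l in range(gt.n_loci):
            calls = sub[sub_typed[:, l], l, :]
            n = calls.shape[0]
            if n < 5 or np.unique(calls).size < 2:
                continue
            obs = abs(_fis_plug(calls))
            if np.isnan(obs):
                continue
            pool = calls.ravel().copy()
            hits = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                f = _fis_plug(pool.reshape(n, 2))
                if not np.isnan(f) and abs(f) >= obs - 1e-12:
                    hits += 1
            out[p, l] = (hits + 1) / (n_perm + 1)
    return pd.DataFrame(out, index=pd.Index(pops, name="population"), columns=gt.loci)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta

def _wc_locus_components(counts_l: np.ndarray, het_l: np.ndarray, n_l: np.ndarray):
    """Per-locus W&C (1984) variance components a, b, c summed over alleles.

    ``counts_l``: (r, A) allele counts; ``het_l``: (r, A) heterozygous-carrier
    counts; ``n_l``: (r,) typed individuals.  Populations with no typed
    individuals are dropped.  Returns (a, a+b+c); (0, 0) if undefined.
    """
    keep = n_l > 0
    if keep.sum() < 2:
        return 0.0, 0.0
    cnt = counts_l[keep].astype(float)
    het = het_l[keep].astype(float)
    n = n_l[keep].astype(float)
    r = n.size
    totals = 2 * n
    if np.any(cnt.sum(axis=1) != totals):
        raise AssertionError("count bookkeeping error")
    p = cnt / totals[:, None]
    h = het / n[:, None]
    nbar = n.mean()
    nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1.0)
    pbar = (n[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)
    if nbar <= 1 or nc == 0:
        return 0.0, 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2 * nbar - 1) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    # skip alleles absent everywhere (0/0 terms)
    seen = cnt.sum(axis=0) > 0
    return float(a[seen].sum()), float((a + b + c)[seen].sum())


def weir_cockerham_theta(gt: GenotypeTable, populations=None):
    """Multilocus W&C theta across the given populations (default: all).

    Returns ``(theta, per_locus)`` where ``per_locus`` is an ``(L, 2)`` array
    of ``(a, a+b+c)`` sums; theta is the ratio of their column sums.
    """
    if populations is not None:
        gt = gt.subset_populations(populations)
    counts, het, _, n_typed = _het_counts(gt)
    per_locus = np.zeros((gt.n_loci, 2))
    for l in range(gt.n_loci):
        per_locus[l] = _wc_locus_components(counts[:, l], het[:, l], n_typed[:, l])
    denom = per_locus[:, 1].sum()
    theta = per_locus[:, 0].sum() / denom if denom != 0 else np.nan
    return theta, per_locus


@dataclass
class FstResult:
    """Pairwise theta matrix (floored at 0) plus the per-pair table."""

    matrix: DistanceMatrix
    pairs: pd.DataFrame


def pairwise_fst(gt: GenotypeTable, n_resample: int = 1000, seed: int | None = None,
                 ci: float = 0.95) -> FstResult:
    """Pairwise multilocus Weir & Cockerham theta with bootstrap CIs.

    The CI resamples loci with replacement ``n_resample`` times and takes
    percentile bounds of the recomputed multilocus ratio; a pair is flagged
    ``differentiated`` when its CI excludes 0.  Single-locus data leave the
    CI undefined (NaN) but keep the point estimate.
    """
    rng = np.random.default_rng(seed)
    pops = gt.population_names
    k = len(pops)
    mat = np.zeros((k, k))
    rows = []
    alpha = (1 - ci) / 2
    for i in range(k):
        for j in range(i + 1, k):
            theta, per_locus = weir_cockerham_theta(gt, [pops[i], pops[j]])
            usable = np.flatnonzero(per_locus[:, 1] != 0)
            lo = hi = np.nan
            if usable.size > 1:
                idx = rng.integers(0, usable.size, size=(n_resample, usable.size))
                comp = per_locus[usable]
                boot_num = comp[idx, 0].sum(axis=1)
                boot_den = comp[idx, 1].sum(axis=1)
                boots = boot_num / boot_den
                lo, hi = np.quantile(boots, [alpha, 1 - alpha])
            mat[i, j] = mat[j, i] = max(theta, 0.0)
            rows.append({
                "pop_a": pops[i], "pop_b": pops[j], "theta": theta,
                "ci_low": lo, "ci_high": hi,
                "differentiated": bool(lo > 0) if not np.isnan(lo) else None,
            })
    return FstResult(matrix=DistanceMatrix(mat, ids=[str(p) for p in pops]),
                     pairs=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Jost's D_est

def _dest_locus(counts_l: np.ndarray, n_l: np.ndarray) -> float:
    """Jost's D for one locus, two demes, Nei–Chesser corrected; NaN if undefined."""
    keep = n_l > 0
    if keep.sum() < 2:
        return np.nan
    cnt = counts_l[keep].astype(float)
    n = n_l[keep].astype(float)
    r = n.size
    p = cnt / (2 * n)[:, None]
    n_harm = r / np.sum(1.0 / n)
    hs_plug = 1 - np.mean(np.sum(p**2, axis=1))
    ht_plug = 1 - np.sum(np.mean(p, axis=0) ** 2)
    hs = (2 * n_harm / (2 * n_harm - 1)) * hs_plug
    ht = ht_plug + hs / (2 * n_harm * r)
    if 1 - hs == 0:
        return np.nan
    return (ht - hs) / (1 - hs) * r / (r - 1.0)


def pairwise_dest(gt: GenotypeTable) -> DistanceMatrix:
    """Pairwise multilocus Jost's D_est.

    Per-locus D values are floored at 0, then combined by the harmonic mean
    across usable loci (any zero-valued locus therefore drives the multilocus
    value to 0, the harmonic-mean limit).  A pair with all loci monomorphic
    has D_est = 0.
    """
    counts, pops, n_typed = gt.counts()
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals = []
            for l in range(gt.n_loci):
                d = _dest_locus(counts[[i, j], l], n_typed[[i, j], l])
                if not np.isnan(d):
                    vals.append(max(d, 0.0))
            if vals:
                vals = np.asarray(vals)
                mat[i, j] = mat[j, i] = (
                    0.0 if np.any(vals == 0) else vals.size / np.sum(1.0 / vals)
                )
    return DistanceMatrix(mat, ids=[str(p) for p in pops])


# ---------------------------------------------------------------------------
# chord distance

def chord_distance_from_frequencies(freqs: np.ndarray, usable: np.ndarray,
                                    pops) -> DistanceMatrix:
    """Cavalli-Sforza & Edwards chord distance from a frequency array.

    ``D_ce = (2 / (pi L)) * sum_l sqrt(2 f_l)`` with
    ``f_l = 1 - sum_a sqrt(p_la q_la)`` clipped to [0, 1]; ``L`` counts the
    loci usable in both populations.  ``freqs`` has shape
    ``(n_pops, n_loci, n_alleles)``; ``usable`` is a boolean
    ``(n_pops, n_loci)`` mask.  A pair with no shared usable locus raises.
    """
    k = len(pops)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            shared = usable[i] & usable[j]
            L = int(shared.sum())
            if L == 0:
                raise ValueError(f"populations {pops[i]} and {pops[j]} share no usable locus")
            f = 1.0 - np.sum(np.sqrt(freqs[i][shared] * freqs[j][shared]), axis=1)
            f = np.clip(f, 0.0, 1.0)
            mat[i, j] = mat[j, i] = (2.0 / (np.pi * L)) * np.sum(np.sqrt(2.0 * f))
    return DistanceMatrix(mat, ids=[str(p) for p in pops])


def chord_distance_from_counts(counts: np.ndarray, n_typed: np.ndarray, pops) -> DistanceMatrix:
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where((n_typed > 0)[:, :, None],
                         counts / np.maximum(2 * n_typed, 1)[:, :, None], 0.0)
    return chord_distance_from_frequencies(freqs, n_typed > 0, pops)


def chord_distance(gt: GenotypeTable) -> DistanceMatrix:
    counts, pops, n_typed = gt.counts()
    return chord_distance_from_counts(counts, n_typed, pops)


# ---------------------------------------------------------------------------
# heterogeneity tests

def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G on a 2 x A allele-count table (zero cells skipped)."""
    table = table[:, table.sum(axis=0) > 0].astype(float)
    if table.shape[1] < 2:
        return 0.0
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def heterogeneity_test(gt: GenotypeTable, pair, n_perm: int = 1000,
                       seed: int | None = None) -> float:
    """Allele-frequency heterogeneity between two populations.

    Per locus, a Monte-Carlo contingency test: the typed individuals' diploid
    genotypes are permuted between the two populations (sample sizes kept)
    and the G statistic on the 2 x alleles count table recomputed; per-locus
    p-values are add-one corrected and combined across loci by Fisher's
    method.  Loci untyped in either population are skipped.
    """
    rng = np.random.default_rng(seed)
    a, b = pair
    sub = gt.subset_populations([a, b])
    typed = sub.typed_mask()
    in_a = sub.populations == a
    pvals = []
    for l in range(sub.n_loci):
        calls = sub.alleles[typed[:, l], l, :]
        labels = in_a[typed[:, l]]
        n_a = int(labels.sum())
        if n_a == 0 or n_a == calls.shape[0]:
            continue
        codes = np.unique(calls)
        if codes.size < 2:
            continue
        idx = np.searchsorted(codes, calls)
        def table_for(lab):
            t = np.zeros((2, codes.size))
            np.add.at(t[0], idx[lab].ravel(), 1)
            np.add.at(t[1], idx[~lab].ravel(), 1)
            return t
        obs = _g_statistic(table_for(labels))
        hits = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if _g_statistic(table_for(lab)) >= obs - 1e-12:
                hits += 1
        pvals.append((hits + 1) / (n_perm + 1))
    if not pvals:
        return np.nan
    stat = -2.0 * np.sum(np.log(pvals))
    return float(stats.chi2.sf(stat, 2 * len(pvals)))


def pairwise_heterogeneity(gt: GenotypeTable, n_perm: int = 1000,
                           seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs heterogeneity tests with Holm step-down adjustment."""
    pops = gt.population_names
    rows = []
    rng = np.random.default_rng(seed)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            p = heterogeneity_test(gt, (pops[i], pops[j]), n_perm,
                                   seed=int(rng.integers(2**31)))
            rows.append({"pop_a": pops[i], "pop_b": pops[j], "p": p})
    df = pd.DataFrame(rows)
    reject, adjusted = sequential_bonferroni(df["p"].to_numpy(), alpha=alpha)
    df["p_holm"] = adjusted
    df["significant"] = reject
    return df


def sequential_bonferroni(pvalues, alpha: float = 0.05):
    """Holm step-down (sequential Bonferroni) adjustment.

    Returns ``(reject, adjusted_p)`` aligned with the input order; NaN
    p-values are left NaN and never rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    adjusted = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="holm")
        reject[ok] = rej
        adjusted[ok] = adj
    return reject, adjusted
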