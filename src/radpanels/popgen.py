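"""Population-genetic statistics computed from first principles.

Implements observed/unbiased-expected heterozygosity, a multi-locus
inbreeding coefficient with bootstrap confidence intervals, the
Weir & Cockerham (1984) multi-locus theta estimator of global FST,
rarefied allelic richness, and the biallelic conditional exact test of
Hardy-Weinberg proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .model import GenotypeMatrix, MISSING

__all__ = [
    "obs_exp_het",
    "fis",
    "fis_wc",
    "bootstrap_fis_ci",
    "global_fst_wc",
    "allelic_richness",
    "hwe_exact_test",
    "hwe_pvalues",
    "PopMetrics",
    "summarize_panel",
]


def _pop_calls(gm: GenotypeMatrix, pop: str) -> np.ndarray:
    rows = gm.pop_rows()
    if pop not in rows:
        raise ValueError(f"unknown population {pop!r}")
    return gm.calls[rows[pop]]


def _copy_counts(calls: np.ndarray) -> np.ndarray:
    """Allele-copy counts per SNP, shape (n_snps, 4), over non-missing calls."""
    counts = np.zeros((calls.shape[1], 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = ((calls[:, :, 0] == k).sum(axis=0) + (calls[:, :, 1] == k).sum(axis=0))
    return counts


def obs_exp_het(gm: GenotypeMatrix, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus observed and unbiased expected heterozygosity in one population.

    He uses the small-sample correction ``2n/(2n-1) * (1 - sum p_i^2)`` with
    ``n`` the number of genotyped individuals.  Loci with no genotyped
    individual are returned as NaN.
    """
    calls = _pop_calls(gm, pop)
    valid = calls[:, :, 0] >= 0
    n = valid.sum(axis=0).astype(float)
    het = (valid & (calls[:, :, 0] != calls[:, :, 1])).sum(axis=0)
    copies = _copy_counts(calls).astype(float)
    two_n = copies.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, het / n, np.nan)
        p = copies / two_n[:, None]
        gene_div = 1.0 - np.nansum(p * p, axis=1)
        he = np.where(two_n > 1, two_n / (two_n - 1.0) * gene_div, np.nan)
        he = np.where(n > 0, he, np.nan)
    return ho, he


def fis(gm: GenotypeMatrix, pop: str) -> float:
    """Multi-locus FIS = 1 - sum(Ho) / sum(He) (ratio of sums over loci)."""
    ho, he = obs_exp_het(gm, pop)
    ok = ~np.isnan(ho) & ~np.isnan(he)
    sum_he = float(he[ok].sum())
    if sum_he == 0.0:
        return float("nan")
    return 1.0 - float(ho[ok].sum()) / sum_he


def bootstrap_fis_ci(
    gm: GenotypeMatrix,
    pop: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for multi-locus FIS (resampling loci)."""
    ho, he = obs_exp_het(gm, pop)
    ok = ~np.isnan(ho) & ~np.isnan(he)
    ho, he = ho[ok], he[ok]
    if ho.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ho.size, size=(n_boot, ho.size))
    sum_he = he[idx].sum(axis=1)
    sum_ho = ho[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        reps = np.where(sum_he > 0, 1.0 - sum_ho / sum_he, np.nan)
    reps = reps[~np.isnan(reps)]
    if reps.size == 0:
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(reps, alpha)),
        float(np.quantile(reps, 1.0 - alpha)),
    )


def _wc_components(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c) for biallelic loci.

    The reference allele at each locus is the smallest nucleotide code
    observed; loci where fewer than two populations have genotyped
    individuals, or with mean sample size <= 1, get NaN components.
    """
    pops = gm.pops()
    r_max = len(pops)
    if r_max < 2:
        raise ValueError("global FST needs at least two populations")
    M = gm.n_snps
    n_i = np.zeros((r_max, M))
    p_i = np.zeros((r_max, M))
    h_i = np.zeros((r_max, M))
    # reference allele: smallest observed code over the whole matrix
    all_copies = _copy_counts(gm.calls)
    observed = all_copies > 0
    ref = np.where(observed.any(axis=1), observed.argmax(axis=1), 0)
    for k, pop in enumerate(pops):
        calls = _pop_calls(gm, pop)
        valid = calls[:, :, 0] >= 0
        n = valid.sum(axis=0).astype(float)
        ref_row = ref[None, :]
        copies_ref = ((calls[:, :, 0] == ref_row).sum(axis=0)
                      + (calls[:, :, 1] == ref_row).sum(axis=0)).astype(float)
        het = (valid & (calls[:, :, 0] != calls[:, :, 1])).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, copies_ref / (2.0 * n), np.nan)
            h_i[k] = np.where(n > 0, het / n, np.nan)
        n_i[k] = n
    present = n_i > 0
    r = present.sum(axis=0).astype(float)
    n_i = np.where(present, n_i, 0.0)
    p_i = np.where(present, np.nan_to_num(p_i), 0.0)
    h_i = np.where(present, np.nan_to_num(h_i), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n_i.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n_i * p_i).sum(axis=0) / n_tot
        s2 = (n_i * (p_i - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = (r < 2) | (nbar <= 1.0) | ~np.isfinite(nc) | (nc <= 0)
    a[bad] = np.nan
    b[bad] = np.nan
    c[bad] = np.nan
    return a, b, c


def global_fst_wc(gm: GenotypeMatrix) -> float:
    """Multi-locus Weir-Cockerham theta: sum(a) / sum(a + b + c) over loci."""
    a, b, c = _wc_components(gm)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = float((a[ok] + b[ok] + c[ok]).sum())
    if denom == 0.0:
        return float("nan")
    return float(a[ok].sum()) / denom


def fis_wc(gm: GenotypeMatrix) -> float:
    """Weir-Cockerham within-population small-f: 1 - sum(c) / sum(b + c)."""
    a, b, c = _wc_components(gm)
    ok = np.isfinite(b) & np.isfinite(c)
    denom = float((b[ok] + c[ok]).sum())
    if denom == 0.0:
        return float("nan")
    return 1.0 - float(c[ok].sum()) / denom


def allelic_richness(gm: GenotypeMatrix, pop: str, g: int) -> np.ndarray:
    """Per-locus rarefied allele count at a standardized sample of ``g`` gene copies.

    AR = sum over alleles of 1 - C(2n - N_a, g) / C(2n, g), where 2n is the
    number of genotyped gene copies and N_a the copies of allele a.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    calls = _pop_calls(gm, pop)
    copies = _copy_counts(calls)
    two_n = copies.sum(axis=1)
    out = np.full(gm.n_snps, np.nan)
    for j in range(gm.n_snps):
        tn = int(two_n[j])
        if tn == 0:
            continue
        if g > tn:
            raise ValueError(f"g={g} exceeds {tn} gene copies at locus {gm.snps[j].name}")
        denom = math.comb(tn, g)
        ar = 0.0
        for k in range(4):
            na = int(copies[j, k])
            if na > 0:
                ar += 1.0 - math.comb(tn - na, g) / denom
        out[j] = ar
    return out


@lru_cache(maxsize=None)
def _hwe_distribution(n: int, n_minor: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Conditional distribution of heterozygote count given allele counts.

    ``n`` diploid individuals, ``n_minor`` copies of the rarer allele.
    P(k hets) is proportional to n! / (n1! k! n2!) * 2^k with
    n1 = (n_minor - k)/2 minor homozygotes and n2 the rest.
    """
    ks = [k for k in range(n_minor % 2, n_minor + 1, 2) if (2 * n - n_minor - k) >= 0]
    logw = []
    for k in ks:
        n1 = (n_minor - k) // 2
        n2 = n - n1 - k
        logw.append(
            math.lgamma(n + 1)
            - math.lgamma(n1 + 1)
            - math.lgamma(k + 1)
            - math.lgamma(n2 + 1)
            + k * math.log(2.0)
        )
    mx = max(logw)
    w = [math.exp(x - mx) for x in logw]
    total = sum(w)
    return tuple(ks), tuple(x / total for x in w)


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Biallelic conditional exact test of Hardy-Weinberg proportions.

    P-value is the summed probability of all heterozygote counts no more
    probable than the observed one, conditional on the allele counts.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype counts")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    ks, probs = _hwe_distribution(n, n_minor)
    p_obs = probs[ks.index(n_het)]
    return float(min(1.0, sum(p for p in probs if p <= p_obs * (1.0 + 1e-12))))


def hwe_pvalues(gm: GenotypeMatrix, min_individuals: int = 2) -> np.ndarray:
    """Exact HWE P-values per (SNP, population); NaN where untestable.

    Populations with fewer than ``min_individuals`` genotyped individuals at
    a SNP are untestable, as are SNPs with more than two observed alleles in
    the whole matrix (caller is expected to filter to biallelic first).
    """
    pops = gm.pops()
    out = np.full((gm.n_snps, len(pops)), np.nan)
    all_copies = _copy_counts(gm.calls)
    n_alleles = (all_copies > 0).sum(axis=1)
    allele_pair = np.argsort(-all_copies, axis=1, kind="stable")[:, :2]
    for k, pop in enumerate(pops):
        calls = _pop_calls(gm, pop)
        valid = calls[:, :, 0] >= 0
        for j in range(gm.n_snps):
            if n_alleles[j] > 2 or n_alleles[j] == 0:
                continue
            col = calls[valid[:, j], j, :]
            n = col.shape[0]
            if n < min_individuals:
                continue
            a1, a2 = sorted(int(x) for x in allele_pair[j])
            hom1 = int(((col[:, 0] == a1) & (col[:, 1] == a1)).sum())
            hom2 = int(((col[:, 0] == a2) & (col[:, 1] == a2)).sum())
            n_het = n - hom1 - hom2
            out[j, k] = hwe_exact_test(hom1, n_het, hom2)
    return out


@dataclass
class PopMetrics:
    """Panel summary in the style of a per-panel metrics table."""

    panel: str
    per_pop: dict[str, dict[str, float]]
    global_fst: float
    fis_wc_global: float
    mean_ho: float = field(default=float("nan"))
    mean_he: float = field(default=float("nan"))
    mean_fis: float = field(default=float("nan"))
    mean_ar: float = field(default=float("nan"))


def _rarefaction_g(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus rarefaction size: 2 x smallest per-population genotyped n."""
    pops = gm.pops()
    mins = np.full(gm.n_snps, np.inf)
    for pop in pops:
        calls = _pop_calls(gm, pop)
        n = (calls[:, :, 0] >= 0).sum(axis=0)
        mins = np.minimum(mins, n)
    return (2 * mins).astype(int)


def summarize_panel(
    gm: GenotypeMatrix, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> PopMetrics:
    """Assemble the metric suite: Ho, He, FIS (+CI), AR per population; global theta.

    Allelic richness is rarefied per locus to twice the smallest genotyped
    sample size across populations at that locus (loci rarefiable to fewer
    than 2 gene copies are skipped).
    """
    pops = gm.pops()
    g_locus = _rarefaction_g(gm)
    per_pop: dict[str, dict[str, float]] = {}
    for pop in pops:
        ho, he = obs_exp_het(gm, pop)
        f = fis(gm, pop)
        ci = bootstrap_fis_ci(gm, pop, n_boot=n_boot, level=level, seed=seed)
        ars = []
        calls = _pop_calls(gm, pop)
        copies = _copy_counts(calls)
        two_n = copies.sum(axis=1)
        for j in range(gm.n_snps):
            g = int(g_locus[j])
            if g < 2 or two_n[j] < g:
                continue
            tn = int(two_n[j])
            denom = math.comb(tn, g)
            ar = 0.0
            for k in range(4):
                na = int(copies[j, k])
                if na > 0:
                    ar += 1.0 - math.comb(tn - na, g) / denom
            ars.append(ar)
        per_pop[pop] = {
            "Ho": float(np.nanmean(ho)) if np.isfinite(ho).any() else float("nan"),
            "He": float(np.nanmean(he)) if np.isfinite(he).any() else float("nan"),
            "FIS": f,
            "FIS_lo": ci[0],
            "FIS_hi": ci[1],
            "AR": float(np.mean(ars)) if ars else float("nan"),
        }
    theta = global_fst_wc(gm) if len(pops) >= 2 else float("nan")
    f_wc = fis_wc(gm) if len(pops) >= 2 else float("nan")
    return PopMetrics(
        panel=gm.label,
        per_pop=per_pop,
        global_fst=theta,
        fis_wc_global=f_wc,
        mean_ho=float(np.mean([v["Ho"] for v in per_pop.values()])),
        mean_he=float(np.mean([v["He"] for v in per_pop.values()])),
        mean_fis=float(np.mean([v["FIS"] for v in per_pop.values()])),
        mean_ar=float(np.mean([v["AR"] for v in per_pop.values()])),
    )
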