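"""Synthetic two-pipeline RAD datasets.

Generates structured populations (Balding-Nichols allele frequencies),
true diploid genotypes under within-population Hardy-Weinberg proportions,
well-separated tag catalogues, per-pipeline allele-depth matrices with
negative-binomial coverage and sequencing error, and two genotype callers:
a multinomial likelihood-ratio caller and a minor-allele-frequency
threshold caller.  Pipeline-specific perturbations (read loss, locus
dropout, oversplitting) let the generator reproduce realistic
between-pipeline mismatch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import chi2
from scipy.special import xlogy

from .model import (
    CODE,
    MISSING,
    NUCS,
    DepthMatrix,
    GenotypeMatrix,
    LocusCatalog,
    SNPSite,
    canonical_orientation,
)

__all__ = [
    "PipelineParams",
    "SimConfig",
    "TrueGenotypes",
    "SimResult",
    "simulate_allele_freqs",
    "simulate_true_genotypes",
    "simulate_tag_catalog",
    "simulate_depths",
    "call_genotypes_freq_threshold",
    "call_genotypes_lrt",
    "build_pipeline_outputs",
]

# fixed substream labels so each stage draws from its own deterministic stream
_STREAMS = {
    "tags": 1,
    "freqs": 2,
    "genotypes": 3,
    "reads": 4,
    "pipeline_a": 5,
    "pipeline_b": 6,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stage]]))


@dataclass
class PipelineParams:
    """Per-pipeline perturbations of the shared read process.

    ``read_loss`` thins every read count binomially; ``locus_dropout``
    removes whole loci from the pipeline's catalogue; ``oversplit`` strands
    minor-allele reads of heterozygotes on a spurious private locus;
    ``cell_dropout`` zeroes all reads of a (sample, locus) cell, emulating
    per-sample stacking/alignment failure, the mechanism behind
    one-pipeline-only missing genotypes at otherwise well-covered loci.
    """

    read_loss: float = 0.0
    locus_dropout: float = 0.0
    oversplit: float = 0.0
    cell_dropout: float = 0.0

    def __post_init__(self) -> None:
        for name in ("read_loss", "locus_dropout", "oversplit", "cell_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimConfig:
    n_pops: int = 2
    pop_sizes: list[int] = field(default_factory=lambda: [15, 15])
    n_loci: int = 200
    snps_per_locus_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.06, 5: 0.02}
    )
    tag_length: int = 36
    fst_sim: float = 0.05
    cov_mean: float = 20.0
    cov_dispersion: float = 3.0
    seq_error: float = 0.001
    triallelic_rate: float = 0.0
    min_pairwise_mismatch: int = 7
    pipeline_a: PipelineParams = field(default_factory=PipelineParams)
    pipeline_b: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.pipeline_a, dict):
            self.pipeline_a = PipelineParams(**self.pipeline_a)
        if isinstance(self.pipeline_b, dict):
            self.pipeline_b = PipelineParams(**self.pipeline_b)
        if self.n_pops < 1 or len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes must list one size per population")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be >= 1")
        if not 0.0 <= self.fst_sim < 1.0:
            raise ValueError("fst_sim must be in [0, 1)")
        if self.cov_mean <= 0:
            raise ValueError("cov_mean must be positive")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must be in [0, 1)")
        total = sum(self.snps_per_locus_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("snps_per_locus_dist probabilities must sum to 1")
        if any(k < 1 or k > 5 for k in self.snps_per_locus_dist):
            raise ValueError("snps_per_locus_dist supports 1..5 SNPs per locus")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "snps_per_locus_dist" in d:
            d["snps_per_locus_dist"] = {int(k): float(v) for k, v in d["snps_per_locus_dist"].items()}
        return cls(**d)


@dataclass
class TrueGenotypes:
    """Simulation ground truth: diploid genotypes plus per-pop frequencies."""

    samples: list[str]
    popmap: dict[str, str]
    snps: list[SNPSite]
    calls: np.ndarray  # (n_samples, n_snps, 2) nucleotide codes
    freqs: np.ndarray  # (n_pops, n_snps) frequency of the reference allele
    ref_alt: np.ndarray  # (n_snps, 2) codes of (reference, alternate) allele


def simulate_allele_freqs(
    fst_sim: float, n_snps: int, n_pops: int, seed: int = 0
) -> np.ndarray:
    """Balding-Nichols per-population allele frequencies, shape (n_pops, n_snps).

    Ancestral frequency ~ Uniform(0.05, 0.95); for F > 0 each population draws
    from Beta(p(1-F)/F, (1-p)(1-F)/F); F = 0 degenerates to the ancestral
    frequency in every population.
    """
    if not 0.0 <= fst_sim < 1.0:
        raise ValueError("fst_sim must be in [0, 1)")
    rng = _rng(seed, "freqs")
    p = rng.uniform(0.05, 0.95, size=n_snps)
    if fst_sim == 0.0:
        return np.tile(p, (n_pops, 1))
    shape1 = p * (1.0 - fst_sim) / fst_sim
    shape2 = (1.0 - p) * (1.0 - fst_sim) / fst_sim
    return rng.beta(shape1[None, :], shape2[None, :], size=(n_pops, n_snps))


def simulate_true_genotypes(
    freqs: np.ndarray,
    pop_sizes: list[int],
    snps: list[SNPSite],
    ref_alt: np.ndarray,
    seed: int = 0,
    triallelic_rate: float = 0.0,
) -> TrueGenotypes:
    """Draw diploid genotypes under HWE within each population.

    Each of an individual's two allele copies is the reference allele with its
    population's frequency, else the alternate.  A site marked triallelic
    replaces each allele copy with a third base with probability 0.15.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    n_pops, n_snps = freqs.shape
    if len(pop_sizes) != n_pops:
        raise ValueError("pop_sizes does not match frequency table")
    rng = _rng(seed, "genotypes")
    samples: list[str] = []
    popmap: dict[str, str] = {}
    blocks = []
    for k, size in enumerate(pop_sizes):
        pop = f"pop{k + 1}"
        for i in range(size):
            name = f"{pop}_s{i + 1:03d}"
            samples.append(name)
            popmap[name] = pop
        is_ref = rng.random((size, n_snps, 2)) < freqs[k][None, :, None]
        blocks.append(is_ref)
    is_ref = np.concatenate(blocks, axis=0)
    ref = ref_alt[:, 0][None, :, None]
    alt = ref_alt[:, 1][None, :, None]
    calls = np.where(is_ref, ref, alt).astype(np.int8)
    if triallelic_rate > 0:
        tri_sites = rng.random(n_snps) < triallelic_rate
        third = np.array(
            [_third_allele(int(a), int(b), rng) for a, b in ref_alt], dtype=np.int8
        )
        swap = (rng.random(calls.shape) < 0.15) & tri_sites[None, :, None]
        calls = np.where(swap, third[None, :, None], calls)
    calls = np.sort(calls, axis=2)
    return TrueGenotypes(samples, popmap, list(snps), calls, freqs, ref_alt)


def _third_allele(a: int, b: int, rng: np.random.Generator) -> int:
    others = [k for k in range(4) if k not in (a, b)]
    return int(rng.choice(others))


def simulate_tag_catalog(
    n_loci: int,
    tag_length: int = 36,
    min_pairwise_mismatch: int = 7,
    seed: int = 0,
    max_tries: int = 200,
) -> LocusCatalog:
    """Random canonical tags with all pairwise Hamming distances > threshold.

    Rejection sampling: candidate tags too close to an accepted tag (in
    canonical orientation) are re-drawn, so downstream clustering has an
    unambiguous ground truth.
    """
    rng = _rng(seed, "tags")
    accepted = np.empty((0, tag_length), dtype=np.uint8)
    tags: list[str] = []
    tries = 0
    while len(tags) < n_loci:
        if tries > max_tries * n_loci:
            raise RuntimeError(
                f"could not place {n_loci} tags with pairwise distance > "
                f"{min_pairwise_mismatch} within the retry budget"
            )
        tries += 1
        codes = rng.integers(0, 4, size=tag_length, dtype=np.uint8)
        tag = canonical_orientation("".join(NUCS[c] for c in codes))
        arr = np.frombuffer(tag.encode(), dtype=np.uint8)
        if accepted.size:
            if int((accepted != arr[None, :]).sum(axis=1).min()) <= min_pairwise_mismatch:
                continue
        accepted = np.vstack([accepted, arr]) if accepted.size else arr[None, :]
        tags.append(tag)
    tag_map = {f"L{i + 1:05d}": t for i, t in enumerate(tags)}
    return LocusCatalog("truth", tag_map, [])


def _attach_snps(cat: LocusCatalog, cfg: SimConfig, rng: np.random.Generator) -> tuple[list[SNPSite], np.ndarray]:
    """Choose SNP positions per locus; ref allele = tag base, alt random other."""
    ks = np.array(sorted(cfg.snps_per_locus_dist))
    probs = np.array([cfg.snps_per_locus_dist[int(k)] for k in ks])
    snps: list[SNPSite] = []
    ref_alt: list[tuple[int, int]] = []
    for lid in sorted(cat.tags):
        tag = cat.tags[lid]
        k = int(rng.choice(ks, p=probs))
        positions = np.sort(rng.choice(cfg.tag_length, size=k, replace=False))
        for pos in positions:
            ref = CODE[tag[int(pos)]]
            alt = int(rng.choice([c for c in range(4) if c != ref]))
            snps.append(
                SNPSite(lid, int(pos), (NUCS[ref], NUCS[alt]))
            )
            ref_alt.append((ref, alt))
    return snps, np.array(ref_alt, dtype=np.int8)


_OTHERS = np.array([[k for k in range(4) if k != a] for a in range(4)], dtype=np.int8)


def simulate_depths(
    truth: TrueGenotypes,
    cat: LocusCatalog,
    cov_mean: float,
    cov_dispersion: float,
    seq_error: float,
    pipeline_params: dict[str, PipelineParams],
    seed: int = 0,
) -> dict[str, tuple[DepthMatrix, LocusCatalog]]:
    """Per-pipeline allele-depth matrices and (perturbed) catalogues.

    The read process (negative-binomial per-locus totals, allele sampling,
    sequencing error) is drawn once from a shared substream, so pipelines
    with identity perturbations receive byte-identical depths.  Per pipeline:
    read loss thins every count binomially, locus dropout zeroes whole loci
    and removes them from that pipeline's catalogue, and oversplitting
    removes minor-allele reads at heterozygous sites of affected loci while
    adding a mutated private tag to the catalogue.
    """
    rng = _rng(seed, "reads")
    n_samples = len(truth.samples)
    snps = truth.snps
    n_snps = len(snps)
    locus_ids = sorted(cat.tags)
    locus_index = {lid: i for i, lid in enumerate(locus_ids)}
    snp_locus = np.array([locus_index[s.locus_id] for s in snps])

    # shared read process -------------------------------------------------
    k = float(cov_dispersion)
    p_nb = k / (k + float(cov_mean))
    locus_totals = rng.negative_binomial(k, p_nb, size=(n_samples, len(locus_ids)))
    totals = locus_totals[:, snp_locus]

    a = truth.calls[:, :, 0].astype(np.int64)
    b = truth.calls[:, :, 1].astype(np.int64)
    is_het = a != b
    n_b = np.where(is_het, rng.binomial(totals, 0.5), 0)
    n_a = totals - n_b

    counts = np.zeros((n_samples, n_snps, 4), dtype=np.int64)
    rows, cols = np.indices(a.shape)
    e_a = rng.binomial(n_a, seq_error) if seq_error > 0 else np.zeros_like(n_a)
    e_b = rng.binomial(n_b, seq_error) if seq_error > 0 else np.zeros_like(n_b)
    np.add.at(counts, (rows, cols, a), n_a - e_a)
    np.add.at(counts, (rows, cols, b), n_b - e_b)
    if seq_error > 0:
        third = np.full(3, 1.0 / 3.0)
        for err, allele in ((e_a, a), (e_b, b)):
            if err.sum() == 0:
                continue
            spread = rng.multinomial(err.ravel(), third).reshape(n_samples, n_snps, 3)
            for slot in range(3):
                target = _OTHERS[allele, slot]
                np.add.at(counts, (rows, cols, target), spread[:, :, slot])

    # per-pipeline perturbations ------------------------------------------
    out: dict[str, tuple[DepthMatrix, LocusCatalog]] = {}
    stream = {"A": "pipeline_a", "B": "pipeline_b"}
    for label, params in pipeline_params.items():
        prng = _rng(seed, stream.get(label, "pipeline_a"))
        pc = prng.binomial(counts, 1.0 - params.read_loss)
        cell_drop = prng.random((n_samples, len(locus_ids))) < params.cell_dropout
        if cell_drop.any():
            pc[cell_drop[:, snp_locus]] = 0
        drop = prng.random(len(locus_ids)) < params.locus_dropout
        split = prng.random(len(locus_ids)) < params.oversplit
        tags = dict(cat.tags)
        kept_snps = list(snps)
        if drop.any():
            dropped = {locus_ids[i] for i in np.flatnonzero(drop)}
            pc[:, np.isin(snp_locus, np.flatnonzero(drop)), :] = 0
            tags = {lid: t for lid, t in tags.items() if lid not in dropped}
            kept_snps = [s for s in snps if s.locus_id not in dropped]
        if split.any():
            split_idx = np.flatnonzero(split & ~drop)
            affected = np.isin(snp_locus, split_idx)
            # remove the alternate-allele reads of heterozygous individuals
            alt = truth.ref_alt[:, 1].astype(int)
            het_cells = is_het & affected[None, :]
            srows, scols = np.nonzero(het_cells)
            pc[srows, scols, alt[scols]] = 0
            for i in split_idx:
                lid = locus_ids[i]
                site = next((s for s in snps if s.locus_id == lid), None)
                if site is None:
                    continue
                tag = cat.tags[lid]
                alt_base = site.alleles[1] if tag[site.position] == site.alleles[0] else site.alleles[0]
                mutated = tag[: site.position] + alt_base + tag[site.position + 1 :]
                tags[f"{lid}x"] = canonical_orientation(mutated)
        keep_cols = np.array([s.locus_id in tags for s in snps])
        dm = DepthMatrix(
            samples=list(truth.samples),
            snps=[s for s in snps if s.locus_id in tags],
            counts=pc[:, keep_cols, :],
            label=label,
        )
        out[label] = (dm, LocusCatalog(label, tags, kept_snps))
    return out


def _rank_alleles(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Major and minor allele codes per cell; ties broken by A < C < G < T."""
    order = np.argsort(-counts, axis=-1, kind="stable")
    return order[..., 0], order[..., 1]


def call_genotypes_freq_threshold(
    dm: DepthMatrix,
    min_depth: int = 3,
    lo: float = 0.1,
    hi: float = 0.2,
    popmap: dict[str, str] | None = None,
    label: str = "",
) -> GenotypeMatrix:
    """Minor-allele-frequency threshold caller.

    total < min_depth -> missing; with f the second-highest base count over
    the total: f < lo -> homozygote for the major base, f > hi ->
    heterozygote major/minor, lo <= f <= hi -> uncertain (missing).
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    counts = dm.counts
    totals = counts.sum(axis=2)
    major, minor = _rank_alleles(counts)
    minor_count = np.take_along_axis(counts, minor[..., None], axis=2)[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(totals > 0, minor_count / totals, 0.0)
    calls = np.full((*totals.shape, 2), MISSING, dtype=np.int8)
    is_hom = (totals >= min_depth) & (f < lo)
    is_het = (totals >= min_depth) & (f > hi)
    calls[is_hom, 0] = major[is_hom]
    calls[is_hom, 1] = major[is_hom]
    pair = np.stack([major, minor], axis=-1)
    pair = np.sort(pair, axis=-1)
    calls[is_het] = pair[is_het]
    popmap = popmap or {s: "pop1" for s in dm.samples}
    return GenotypeMatrix(list(dm.samples), dict(popmap), list(dm.snps), calls, label=label)


def _loglik_tables(seq_error: float) -> tuple[np.ndarray, np.ndarray]:
    """Log emission probabilities.

    hom[a, x] = log P(read = x | genotype aa);
    het[a, b, x] = log P(read = x | genotype ab).
    """
    eps = float(seq_error)
    p_hom = np.full((4, 4), eps / 3.0)
    np.fill_diagonal(p_hom, 1.0 - eps)
    p_het = 0.5 * (p_hom[:, None, :] + p_hom[None, :, :])
    with np.errstate(divide="ignore"):
        return np.log(p_hom), np.log(p_het)


def call_genotypes_lrt(
    dm: DepthMatrix,
    min_depth: int = 3,
    alpha: float = 0.05,
    seq_error: float = 0.01,
    popmap: dict[str, str] | None = None,
    label: str = "",
) -> GenotypeMatrix:
    """Two-hypothesis multinomial likelihood-ratio caller.

    Compares homozygote-for-the-major-base against heterozygote
    major/minor under a per-read error model; the better model is called
    only when 2|dlnL| exceeds the chi-square(1) critical value at ``alpha``,
    otherwise the genotype is left missing.  total < min_depth -> missing.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    counts = dm.counts
    totals = counts.sum(axis=2)
    major, minor = _rank_alleles(counts)
    log_hom, log_het = _loglik_tables(seq_error)
    # 0 * log(0) counts as 0: a base with no reads contributes nothing even
    # when the model gives it probability zero (seq_error = 0)
    zero_mask = counts == 0
    with np.errstate(invalid="ignore"):
        ll_hom = np.where(zero_mask, 0.0, counts * log_hom[major]).sum(axis=2)
        ll_het = np.where(zero_mask, 0.0, counts * log_het[major, minor]).sum(axis=2)
    crit = chi2.ppf(1.0 - alpha, df=1)
    stat = 2.0 * np.abs(ll_het - ll_hom)
    decided = (totals >= min_depth) & (stat > crit)
    calls = np.full((*totals.shape, 2), MISSING, dtype=np.int8)
    hom_wins = decided & (ll_hom > ll_het)
    het_wins = decided & (ll_het > ll_hom)
    calls[hom_wins, 0] = major[hom_wins]
    calls[hom_wins, 1] = major[hom_wins]
    pair = np.sort(np.stack([major, minor], axis=-1), axis=-1)
    calls[het_wins] = pair[het_wins]
    popmap = popmap or {s: "pop1" for s in dm.samples}
    return GenotypeMatrix(list(dm.samples), dict(popmap), list(dm.snps), calls, label=label)


@dataclass
class SimResult:
    config: SimConfig
    truth: TrueGenotypes
    truth_catalog: LocusCatalog
    catalogs: dict[str, LocusCatalog]
    depths: dict[str, DepthMatrix]
    genotypes: dict[str, GenotypeMatrix]


def build_pipeline_outputs(config: SimConfig) -> SimResult:
    """Full simulation: truth, two perturbed catalogues, depths and calls.

    Pipeline ``A`` genotypes with the likelihood-ratio caller; pipeline ``B``
    with the frequency-threshold caller.  Everything is reproducible from
    ``config.seed``.
    """
    cat = simulate_tag_catalog(
        config.n_loci, config.tag_length, config.min_pairwise_mismatch, seed=config.seed
    )
    snp_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    snps, ref_alt = _attach_snps(cat, config, snp_rng)
    cat = LocusCatalog("truth", cat.tags, snps)
    freqs = simulate_allele_freqs(config.fst_sim, len(snps), config.n_pops, seed=config.seed)
    truth = simulate_true_genotypes(
        freqs,
        config.pop_sizes,
        snps,
        ref_alt,
        seed=config.seed,
        triallelic_rate=config.triallelic_rate,
    )
    per_pipe = simulate_depths(
        truth,
        cat,
        config.cov_mean,
        config.cov_dispersion,
        config.seq_error,
        {"A": config.pipeline_a, "B": config.pipeline_b},
        seed=config.seed,
    )
    dm_a, cat_a = per_pipe["A"]
    dm_b, cat_b = per_pipe["B"]
    gm_a = call_genotypes_lrt(
        dm_a, seq_error=max(config.seq_error, 1e-3), popmap=truth.popmap, label="STA"
    )
    gm_b = call_genotypes_freq_threshold(dm_b, popmap=truth.popmap, label="ALT")
    cat_a = LocusCatalog("STA", cat_a.tags, cat_a.snps)
    cat_b = LocusCatalog("ALT", cat_b.tags, cat_b.snps)
    return SimResult(
        config=config,
        truth=truth,
        truth_catalog=cat,
        catalogs={"STA": cat_a, "ALT": cat_b},
        depths={"STA": dm_a, "ALT": dm_b},
        genotypes={"STA": gm_a, "ALT": gm_b},
    )
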