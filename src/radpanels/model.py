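"""Core domain types: tags, SNP sites, catalogues, genotype and depth matrices.

Genotypes are stored as integer nucleotide codes (A=0, C=1, G=2, T=3) in a
``(n_samples, n_snps, 2)`` array of sorted allele pairs; a missing call is
``(-1, -1)``.  Depths are stored per nucleotide in a
``(n_samples, n_snps, 4)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

NUCS = "ACGT"
CODE = {c: i for i, c in enumerate(NUCS)}
_COMP = str.maketrans("ACGT", "TGCA")
MISSING = -1

__all__ = [
    "NUCS",
    "CODE",
    "MISSING",
    "revcomp",
    "canonical_orientation",
    "orient",
    "flip_position",
    "complement_base",
    "SNPSite",
    "LocusCatalog",
    "GenotypeMatrix",
    "DepthMatrix",
    "hom",
    "het",
    "missing_call",
    "validate_matrix",
]


def _check_tag(tag: str) -> None:
    if not tag:
        raise ValueError("empty tag sequence")
    if set(tag) - set(NUCS):
        bad = sorted(set(tag) - set(NUCS))
        raise ValueError(f"tag contains non-ACGT characters: {bad}")


def revcomp(tag: str) -> str:
    """Reverse complement of an ACGT string."""
    _check_tag(tag)
    return tag.translate(_COMP)[::-1]


def canonical_orientation(tag: str) -> str:
    """Lexicographic minimum of a tag and its reverse complement.

    Idempotent and independent of the orientation the tag arrived in, so two
    pipelines that emit the same locus in opposite orientations canonicalize
    to an identical string.
    """
    return min(tag, revcomp(tag))


def orient(tag: str) -> tuple[str, bool]:
    """Canonical tag plus a flag telling whether the input was flipped."""
    rc = revcomp(tag)
    return (tag, False) if tag <= rc else (rc, True)


def flip_position(position: int, length: int) -> int:
    """Remap a 0-based offset through a reverse-complement flip."""
    if not 0 <= position < length:
        raise ValueError(f"position {position} outside [0, {length})")
    return length - 1 - position


def complement_base(base: str) -> str:
    return base.translate(_COMP)


@dataclass(frozen=True, order=True)
class SNPSite:
    """A polymorphic position on a RAD tag.

    ``position`` is a 0-based offset within the (canonically oriented) tag;
    ``alleles`` is the sorted tuple of nucleotides segregating at the site.
    """

    locus_id: str
    position: int
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if self.position < 0:
            raise ValueError("SNP position must be non-negative")
        if not 1 <= len(self.alleles) <= 4:
            raise ValueError("a SNP site carries 1-4 alleles")
        for a in self.alleles:
            if a not in NUCS:
                raise ValueError(f"invalid allele {a!r}")

    @property
    def name(self) -> str:
        return f"{self.locus_id}_{self.position}"

    def flipped(self, length: int) -> "SNPSite":
        """The same site expressed in the opposite tag orientation."""
        return SNPSite(
            self.locus_id,
            flip_position(self.position, length),
            tuple(complement_base(a) for a in self.alleles),
        )


@dataclass
class LocusCatalog:
    """One pipeline's catalogue of fixed-length RAD tags with SNP sites."""

    label: str
    tags: dict[str, str]
    snps: list[SNPSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(t) for t in self.tags.values()}
        if len(lengths) > 1:
            raise ValueError(f"tags of mixed length in catalogue {self.label}: {sorted(lengths)}")
        for t in self.tags.values():
            _check_tag(t)
        for s in self.snps:
            if s.locus_id not in self.tags:
                raise ValueError(f"SNP {s.name} references unknown locus")
            if lengths and not s.position < next(iter(lengths)):
                raise ValueError(f"SNP {s.name} position outside tag")

    @property
    def tag_length(self) -> int:
        if not self.tags:
            raise ValueError("empty catalogue has no tag length")
        return len(next(iter(self.tags.values())))

    @property
    def n_loci(self) -> int:
        return len(self.tags)

    def snps_by_locus(self) -> dict[str, list[SNPSite]]:
        out: dict[str, list[SNPSite]] = {lid: [] for lid in self.tags}
        for s in self.snps:
            out[s.locus_id].append(s)
        for v in out.values():
            v.sort(key=lambda s: s.position)
        return out

    def canonicalized(self) -> "LocusCatalog":
        """Catalogue with every tag in canonical orientation, SNPs remapped."""
        L = self.tag_length if self.tags else 0
        tags = {}
        flips = {}
        for lid, t in self.tags.items():
            canon, flipped = orient(t)
            tags[lid] = canon
            flips[lid] = flipped
        snps = [s.flipped(L) if flips[s.locus_id] else s for s in self.snps]
        return LocusCatalog(self.label, tags, snps)


def hom(a: str) -> tuple[int, int]:
    return (CODE[a], CODE[a])


def het(a: str, b: str) -> tuple[int, int]:
    if a == b:
        raise ValueError("heterozygote needs two distinct alleles")
    i, j = sorted((CODE[a], CODE[b]))
    return (i, j)


def missing_call() -> tuple[int, int]:
    return (MISSING, MISSING)


def _as_calls(calls: np.ndarray) -> np.ndarray:
    arr = np.asarray(calls, dtype=np.int8)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("calls must have shape (n_samples, n_snps, 2)")
    return arr


@dataclass
class GenotypeMatrix:
    """Per-sample, per-SNP diploid calls for one panel."""

    samples: list[str]
    popmap: dict[str, str]
    snps: list[SNPSite]
    calls: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.calls = _as_calls(self.calls)
        if self.calls.shape[0] != len(self.samples):
            raise ValueError("calls row count != number of samples")
        if self.calls.shape[1] != len(self.snps):
            raise ValueError("calls column count != number of SNPs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")
        for s in self.samples:
            if s not in self.popmap:
                raise ValueError(f"sample {s!r} absent from popmap")
        # normalize: sorted allele pairs, missing = (-1, -1)
        lo = np.minimum(self.calls[:, :, 0], self.calls[:, :, 1])
        hi = np.maximum(self.calls[:, :, 0], self.calls[:, :, 1])
        miss = lo < 0
        lo[miss] = MISSING
        hi[miss] = MISSING
        self.calls = np.stack([lo, hi], axis=2)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def pops(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.popmap[s]
            if p not in seen:
                seen.append(p)
        return seen

    def pop_rows(self) -> dict[str, np.ndarray]:
        """Row indices per population, in sample order."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(self.popmap[s], []).append(i)
        return {p: np.array(v, dtype=int) for p, v in out.items()}

    def missing_mask(self) -> np.ndarray:
        return self.calls[:, :, 0] < 0

    def het_mask(self) -> np.ndarray:
        valid = ~self.missing_mask()
        return valid & (self.calls[:, :, 0] != self.calls[:, :, 1])

    def missing_fraction(self) -> float:
        if self.calls.size == 0:
            return 0.0
        return float(self.missing_mask().mean())

    def per_sample_missing(self) -> dict[str, float]:
        m = self.missing_mask()
        if self.n_snps == 0:
            return {s: 0.0 for s in self.samples}
        return {s: float(m[i].mean()) for i, s in enumerate(self.samples)}

    def snp_names(self) -> list[str]:
        return [s.name for s in self.snps]

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            popmap=dict(self.popmap),
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx, :].copy(),
            label=self.label,
        )

    def set_missing(self, mask: np.ndarray) -> None:
        """In-place: blank out calls where ``mask`` (samples x snps) is True."""
        self.calls[mask] = MISSING

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), dict(self.popmap), list(self.snps), self.calls.copy(), self.label
        )


@dataclass
class DepthMatrix:
    """Per-sample, per-SNP read counts for each nucleotide (A, C, G, T)."""

    samples: list[str]
    snps: list[SNPSite]
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (n_samples, n_snps, 4)")
        if self.counts.shape[0] != len(self.samples):
            raise ValueError("counts row count != number of samples")
        if self.counts.shape[1] != len(self.snps):
            raise ValueError("counts column count != number of SNPs")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    def take_snps(self, idx: Sequence[int] | np.ndarray) -> "DepthMatrix":
        idx = np.asarray(idx, dtype=int)
        return DepthMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            counts=self.counts[:, idx, :].copy(),
            label=self.label,
        )


def validate_matrix(
    gm: GenotypeMatrix, cat: LocusCatalog | None = None, dm: DepthMatrix | None = None
) -> list[str]:
    """Cross-check a genotype matrix against its catalogue and depths.

    Returns a list of human-readable violations; an empty list means every
    invariant holds.
    """
    report: list[str] = []
    for s in gm.samples:
        if s not in gm.popmap:
            report.append(f"sample {s!r} missing from popmap")
    if cat is not None:
        cat_snps = {(s.locus_id, s.position): set(s.alleles) for s in cat.snps}
        for j, snp in enumerate(gm.snps):
            key = (snp.locus_id, snp.position)
            if key not in cat_snps:
                report.append(f"SNP {snp.name} not present in catalogue {cat.label}")
                continue
            allowed = {CODE[a] for a in cat_snps[key]}
            col = gm.calls[:, j, :]
            observed = {int(c) for c in col.ravel() if c >= 0}
            extra = observed - allowed
            if extra:
                bases = sorted(NUCS[c] for c in extra)
                report.append(f"SNP {snp.name} has calls with alleles {bases} outside site alleles")
    if dm is not None:
        if dm.counts.shape[:2] != gm.calls.shape[:2]:
            report.append("depth matrix shape differs from genotype matrix")
        else:
            no_depth = (dm.totals() == 0) & ~gm.missing_mask()
            if no_depth.any():
                n = int(no_depth.sum())
                report.append(f"{n} non-missing call(s) with zero read depth")
    return report
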