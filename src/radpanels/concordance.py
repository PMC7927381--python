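"""Genotype-level comparison of two panels at matched SNPs.

Cross-tabulates every (sample, SNP) cell of two aligned genotype matrices
into concordant, both-missing and seven mismatch categories, and
attributes missing-data mismatches to their mechanistic source using the
underlying read depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .model import DepthMatrix, GenotypeMatrix

__all__ = [
    "Category",
    "MISMATCH_CATEGORIES",
    "ConcordanceTable",
    "MissingSourceTable",
    "classify_pair",
    "compare_panels",
    "attribute_missing",
]


class Category(str, Enum):
    CONCORDANT_HOM = "ConcordantHom"
    CONCORDANT_HET = "ConcordantHet"
    BOTH_MISSING = "BothMissing"
    HOM_HOM = "HomHom"  # different homozygotes
    HOM_MD = "HomMD"
    MD_HOM = "MDHom"
    HET_MD = "HetMD"
    MD_HET = "MDHet"
    HOM_HET = "HomHet"
    HET_HOM = "HetHom"


MISMATCH_CATEGORIES = (
    Category.HOM_HOM,
    Category.HOM_MD,
    Category.MD_HOM,
    Category.HET_MD,
    Category.MD_HET,
    Category.HOM_HET,
    Category.HET_HOM,
)

# state codes: 0 missing, 1 homozygous, 2 heterozygous
_STATE_TABLE = {
    (0, 0): Category.BOTH_MISSING,
    (1, 0): Category.HOM_MD,
    (0, 1): Category.MD_HOM,
    (2, 0): Category.HET_MD,
    (0, 2): Category.MD_HET,
    (1, 2): Category.HOM_HET,
    (2, 1): Category.HET_HOM,
}


def _state(call: tuple[int, int]) -> int:
    a, b = call
    if a < 0:
        return 0
    return 1 if a == b else 2


def classify_pair(call_a: tuple[int, int], call_b: tuple[int, int]) -> Category:
    """Table-2-style category for one (first-panel, second-panel) call pair."""
    sa, sb = _state(call_a), _state(call_b)
    if (sa, sb) in _STATE_TABLE:
        return _STATE_TABLE[(sa, sb)]
    if sa == 1 and sb == 1:
        return Category.CONCORDANT_HOM if call_a[0] == call_b[0] else Category.HOM_HOM
    # both heterozygous; matched SNPs share an allele pair, so discordant
    # het pairs indicate mis-matched inputs
    if tuple(call_a) != tuple(call_b):
        raise ValueError(
            f"heterozygotes with different allele pairs ({call_a} vs {call_b}); "
            "panels are not aligned on matched SNPs"
        )
    return Category.CONCORDANT_HET


@dataclass
class ConcordanceTable:
    total_genotypes: int
    counts: dict[Category, int]
    panel_a: str = ""
    panel_b: str = ""

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_genotypes:
            raise ValueError("category counts do not sum to the total genotype count")

    def frequencies(self) -> dict[Category, float]:
        if self.total_genotypes == 0:
            return {c: 0.0 for c in self.counts}
        return {c: n / self.total_genotypes for c, n in self.counts.items()}

    def mismatch_total(self) -> int:
        return sum(self.counts[c] for c in MISMATCH_CATEGORIES)


def compare_panels(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> ConcordanceTable:
    """Full cross-tabulation over aligned (sample, SNP) cells.

    Both matrices must carry the same samples in the same order and the
    same number of (matched) SNP columns.
    """
    if gm_a.samples != gm_b.samples:
        raise ValueError("sample sets differ between panels")
    if gm_a.n_snps != gm_b.n_snps:
        raise ValueError("panels have different numbers of matched SNPs")
    a, b = gm_a.calls, gm_b.calls
    sa = np.where(a[:, :, 0] < 0, 0, np.where(a[:, :, 0] == a[:, :, 1], 1, 2))
    sb = np.where(b[:, :, 0] < 0, 0, np.where(b[:, :, 0] == b[:, :, 1], 1, 2))
    same_geno = (a == b).all(axis=2)
    counts = {c: 0 for c in Category}
    counts[Category.BOTH_MISSING] = int(((sa == 0) & (sb == 0)).sum())
    counts[Category.HOM_MD] = int(((sa == 1) & (sb == 0)).sum())
    counts[Category.MD_HOM] = int(((sa == 0) & (sb == 1)).sum())
    counts[Category.HET_MD] = int(((sa == 2) & (sb == 0)).sum())
    counts[Category.MD_HET] = int(((sa == 0) & (sb == 2)).sum())
    counts[Category.HOM_HET] = int(((sa == 1) & (sb == 2)).sum())
    counts[Category.HET_HOM] = int(((sa == 2) & (sb == 1)).sum())
    counts[Category.CONCORDANT_HOM] = int(((sa == 1) & (sb == 1) & same_geno).sum())
    counts[Category.HOM_HOM] = int(((sa == 1) & (sb == 1) & ~same_geno).sum())
    counts[Category.CONCORDANT_HET] = int(((sa == 2) & (sb == 2) & same_geno).sum())
    het_discord = int(((sa == 2) & (sb == 2) & ~same_geno).sum())
    if het_discord:
        raise ValueError(
            f"{het_discord} heterozygote pair(s) with different alleles; "
            "panels are not aligned on matched SNPs"
        )
    return ConcordanceTable(
        total_genotypes=gm_a.n_samples * gm_a.n_snps,
        counts=counts,
        panel_a=gm_a.label,
        panel_b=gm_b.label,
    )


MISSING_SOURCES = ("below_call_floor", "coverage_filtered", "uncertain_call")


@dataclass
class MissingSourceTable:
    """Per MD-involving category: counts by missing-data mechanism.

    Sources: (i) ``below_call_floor`` - fewer reads than the caller's
    minimum (including loci absent from that pipeline's catalogue);
    (ii) ``coverage_filtered`` - called but blanked by the post-hoc
    minimum-coverage filter; (iii) ``uncertain_call`` - enough reads but
    the caller declined to decide.
    """

    sources: dict[Category, dict[str, int]] = field(default_factory=dict)

    def totals_by_source(self) -> dict[str, int]:
        out = {s: 0 for s in MISSING_SOURCES}
        for per_cat in self.sources.values():
            for s, n in per_cat.items():
                out[s] += n
        return out

    def total(self) -> int:
        return sum(self.totals_by_source().values())


def attribute_missing(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    dm_a: DepthMatrix,
    dm_b: DepthMatrix,
    call_floor: int = 3,
    cov_filter: int = 8,
) -> MissingSourceTable:
    """Assign each one-sided missing mismatch to a mechanistic source.

    Uses the missing side's read depth: depth < ``call_floor`` -> below the
    caller's floor (i); ``call_floor`` <= depth < ``cov_filter`` -> removed
    by the coverage filter (ii); depth >= ``cov_filter`` -> the caller saw
    enough reads but left the genotype undecided (iii).
    """
    if gm_a.samples != gm_b.samples:
        raise ValueError("sample sets differ between panels")
    tot_a, tot_b = dm_a.totals(), dm_b.totals()
    a, b = gm_a.calls, gm_b.calls
    sa = np.where(a[:, :, 0] < 0, 0, np.where(a[:, :, 0] == a[:, :, 1], 1, 2))
    sb = np.where(b[:, :, 0] < 0, 0, np.where(b[:, :, 0] == b[:, :, 1], 1, 2))

    def bucket(depths: np.ndarray, mask: np.ndarray) -> dict[str, int]:
        d = depths[mask]
        return {
            "below_call_floor": int((d < call_floor).sum()),
            "coverage_filtered": int(((d >= call_floor) & (d < cov_filter)).sum()),
            "uncertain_call": int((d >= cov_filter).sum()),
        }

    sources = {
        Category.HOM_MD: bucket(tot_b, (sa == 1) & (sb == 0)),
        Category.HET_MD: bucket(tot_b, (sa == 2) & (sb == 0)),
        Category.MD_HOM: bucket(tot_a, (sa == 0) & (sb == 1)),
        Category.MD_HET: bucket(tot_a, (sa == 0) & (sb == 2)),
    }
    return MissingSourceTable(sources)
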