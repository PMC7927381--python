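"""The seven ordered SNP filtering steps with a full audit trail.

Order (fixed): biallelic -> minimum coverage -> max SNPs per locus ->
minimum allele count -> per-population call rate -> Hardy-Weinberg ->
first SNP per locus.  Every step emits an audit record with SNP/locus
counts and missingness so per-step attrition can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .model import DepthMatrix, GenotypeMatrix, LocusCatalog, MISSING
from .popgen import hwe_pvalues

__all__ = [
    "AuditRecord",
    "FilterAudit",
    "CascadeParams",
    "filter_biallelic",
    "apply_min_coverage",
    "filter_max_snps_per_locus",
    "filter_mac",
    "filter_pop_callrate",
    "filter_hwe",
    "select_first_snp_per_locus",
    "run_cascade",
]

STEP_NAMES = [
    "biallelic",
    "min_coverage",
    "max_snps_per_locus",
    "mac",
    "pop_callrate",
    "hwe",
    "first_snp_per_locus",
]


@dataclass
class AuditRecord:
    step_name: str
    snps_before: int
    snps_after: int
    loci_before: int
    loci_after: int
    missing_fraction_after: float
    per_sample_missing: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterAudit:
    records: list[AuditRecord] = field(default_factory=list)

    def add(self, rec: AuditRecord) -> None:
        if self.records and rec.snps_before > self.records[-1].snps_after:
            raise ValueError("audit discontinuity: SNP count increased between steps")
        self.records.append(rec)

    def snp_trajectory(self) -> list[tuple[str, int, int]]:
        return [(r.step_name, r.snps_before, r.snps_after) for r in self.records]


@dataclass
class CascadeParams:
    min_coverage: int = 8
    max_snps_per_locus: int = 3
    mac: int = 3
    pop_max_missing: float = 0.40
    hwe_alpha: float = 0.01
    snps_per_locus_mode: str = "current"  # or "raw"

    def __post_init__(self) -> None:
        if self.snps_per_locus_mode not in ("current", "raw"):
            raise ValueError("snps_per_locus_mode must be 'current' or 'raw'")
        if not 0.0 < self.pop_max_missing <= 1.0:
            raise ValueError("pop_max_missing must be in (0, 1]")


def _n_loci(gm: GenotypeMatrix) -> int:
    return len({s.locus_id for s in gm.snps})


def _record(step: str, before: GenotypeMatrix, after: GenotypeMatrix) -> AuditRecord:
    return AuditRecord(
        step_name=step,
        snps_before=before.n_snps,
        snps_after=after.n_snps,
        loci_before=_n_loci(before),
        loci_after=_n_loci(after),
        missing_fraction_after=after.missing_fraction(),
        per_sample_missing=after.per_sample_missing(),
    )


def _observed_allele_count(gm: GenotypeMatrix) -> np.ndarray:
    counts = np.zeros((gm.n_snps, 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = (gm.calls[:, :, 0] == k).sum(axis=0) + (gm.calls[:, :, 1] == k).sum(axis=0)
    return (counts > 0).sum(axis=1)


def filter_biallelic(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Drop SNPs with more than two observed alleles.

    Monomorphic sites are retained here (the MAC step removes them); only
    sites exceeding two observed alleles are excluded.
    """
    n_obs = _observed_allele_count(gm)
    keep = np.flatnonzero(n_obs <= 2)
    out = gm.take_snps(keep)
    return out, keep, _record("biallelic", gm, out)


def apply_min_coverage(
    gm: GenotypeMatrix, dm: DepthMatrix, threshold: int = 8
) -> tuple[GenotypeMatrix, AuditRecord]:
    """Blank calls whose total read depth is below ``threshold``.

    The SNP set is unchanged; only missingness grows.  Raises when a
    non-missing call has no depth information at all.
    """
    if dm.counts.shape[:2] != gm.calls.shape[:2]:
        raise ValueError("depth matrix not aligned with genotype matrix")
    totals = dm.totals()
    if ((totals == 0) & ~gm.missing_mask()).any():
        raise ValueError("non-missing call without depth data")
    out = gm.copy()
    out.set_missing(totals < threshold)
    return out, _record("min_coverage", gm, out)


def filter_max_snps_per_locus(
    gm: GenotypeMatrix,
    cat: LocusCatalog | None = None,
    max_snps: int = 3,
    mode: str = "current",
) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Drop every SNP on a locus carrying more than ``max_snps`` SNPs.

    ``mode='current'`` counts SNPs surviving the preceding steps;
    ``mode='raw'`` counts the catalogue's full SNP complement per locus.
    """
    if mode == "raw":
        if cat is None:
            raise ValueError("raw mode needs the locus catalogue")
        per_locus: dict[str, int] = {}
        for s in cat.snps:
            per_locus[s.locus_id] = per_locus.get(s.locus_id, 0) + 1
    else:
        per_locus = {}
        for s in gm.snps:
            per_locus[s.locus_id] = per_locus.get(s.locus_id, 0) + 1
    keep = np.flatnonzero(
        np.array([per_locus.get(s.locus_id, 0) <= max_snps for s in gm.snps])
    )
    out = gm.take_snps(keep)
    return out, keep, _record("max_snps_per_locus", gm, out)


def _minor_allele_count(gm: GenotypeMatrix) -> np.ndarray:
    counts = np.zeros((gm.n_snps, 4), dtype=np.int64)
    for k in range(4):
        counts[:, k] = (gm.calls[:, :, 0] == k).sum(axis=0) + (gm.calls[:, :, 1] == k).sum(axis=0)
    order = np.sort(counts, axis=1)
    return order[:, -2]  # copies of the second-most-frequent allele


def filter_mac(gm: GenotypeMatrix, min_count: int = 3) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Keep SNPs whose minor allele is observed at least ``min_count`` times.

    Copies are counted over genotyped calls only (het = 1 copy, minor
    homozygote = 2); monomorphic sites have count 0 and are removed.
    """
    mac = _minor_allele_count(gm)
    keep = np.flatnonzero(mac >= min_count)
    out = gm.take_snps(keep)
    return out, keep, _record("mac", gm, out)


def filter_pop_callrate(
    gm: GenotypeMatrix, max_missing: float = 0.40
) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Keep SNPs with missing fraction strictly below ``max_missing`` in every population."""
    rows = gm.pop_rows()
    for pop, idx in rows.items():
        if idx.size == 0:
            raise ValueError(f"population {pop!r} has no samples")
    miss = gm.missing_mask()
    keep_mask = np.ones(gm.n_snps, dtype=bool)
    for pop, idx in rows.items():
        frac = miss[idx].mean(axis=0)
        keep_mask &= frac < max_missing
    keep = np.flatnonzero(keep_mask)
    out = gm.take_snps(keep)
    return out, keep, _record("pop_callrate", gm, out)


def filter_hwe(
    gm: GenotypeMatrix, p_threshold: float = 0.01
) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Drop SNPs out of Hardy-Weinberg (exact P < threshold) in more than half
    of the testable populations.

    Populations with fewer than two genotyped individuals at a SNP are
    skipped and excluded from the denominator.
    """
    pvals = hwe_pvalues(gm)
    testable = np.isfinite(pvals)
    n_sig = ((pvals < p_threshold) & testable).sum(axis=1)
    n_testable = testable.sum(axis=1)
    remove = n_sig > n_testable / 2.0
    remove &= n_testable > 0
    keep = np.flatnonzero(~remove)
    out = gm.take_snps(keep)
    return out, keep, _record("hwe", gm, out)


def select_first_snp_per_locus(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, np.ndarray, AuditRecord]:
    """Retain one SNP per locus: the smallest canonical-orientation position."""
    best: dict[str, int] = {}
    for j, s in enumerate(gm.snps):
        cur = best.get(s.locus_id)
        if cur is None or s.position < gm.snps[cur].position:
            best[s.locus_id] = j
    keep = np.array(sorted(best.values()), dtype=int)
    out = gm.take_snps(keep)
    return out, keep, _record("first_snp_per_locus", gm, out)


def run_cascade(
    gm: GenotypeMatrix,
    dm: DepthMatrix,
    cat: LocusCatalog | None = None,
    params: CascadeParams | None = None,
    stop_after_step: int = 7,
) -> tuple[GenotypeMatrix, DepthMatrix, FilterAudit]:
    """Apply filtering steps 1..``stop_after_step`` in the fixed order.

    Returns the filtered panel, the depth matrix subset to the surviving
    SNPs, and the audit trail.  ``stop_after_step=6`` yields the panels
    used for cross-catalogue SNP matching.
    """
    params = params or CascadeParams()
    if not 1 <= stop_after_step <= 7:
        raise ValueError("stop_after_step must be in 1..7")
    audit = FilterAudit()
    cur, cur_dm = gm, dm

    cur, keep, rec = filter_biallelic(cur)
    cur_dm = cur_dm.take_snps(keep)
    audit.add(rec)
    if stop_after_step >= 2:
        cur, rec = apply_min_coverage(cur, cur_dm, params.min_coverage)
        audit.add(rec)
    if stop_after_step >= 3:
        cur, keep, rec = filter_max_snps_per_locus(
            cur, cat, params.max_snps_per_locus, mode=params.snps_per_locus_mode
        )
        cur_dm = cur_dm.take_snps(keep)
        audit.add(rec)
    if stop_after_step >= 4:
        cur, keep, rec = filter_mac(cur, params.mac)
        cur_dm = cur_dm.take_snps(keep)
        audit.add(rec)
    if stop_after_step >= 5:
        cur, keep, rec = filter_pop_callrate(cur, params.pop_max_missing)
        cur_dm = cur_dm.take_snps(keep)
        audit.add(rec)
    if stop_after_step >= 6:
        cur, keep, rec = filter_hwe(cur, params.hwe_alpha)
        cur_dm = cur_dm.take_snps(keep)
        audit.add(rec)
    if stop_after_step >= 7:
        cur, keep, rec = select_first_snp_per_locus(cur)
        cur_dm = cur_dm.take_snps(keep)
        audit.add(rec)
    return cur, cur_dm, audit
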