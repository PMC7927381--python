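"""Hand-built fixtures shared across test modules.

``cascade_fixture`` is a 12-SNP, 3-population dataset designed so that
every cascade step removes a known, hand-enumerated subset of SNPs.
"""

from __future__ import annotations

import numpy as np

from radpanels.model import (
    DepthMatrix,
    GenotypeMatrix,
    LocusCatalog,
    SNPSite,
    het,
    hom,
    missing_call,
)

HOM_A = hom("A")
HOM_C = hom("C")
HOM_T = hom("T")
HET_AC = het("A", "C")
MISS = missing_call()

# depth vectors consistent with each call (A, C, G, T)
_DEPTH = {
    HOM_A: (10, 0, 0, 0),
    HOM_C: (0, 10, 0, 0),
    HOM_T: (0, 0, 0, 10),
    HET_AC: (6, 4, 0, 0),
}

# the standard per-population pattern: passes every filter
_PATTERN = [HOM_A] * 6 + [HET_AC] * 4


def _pop_block(pattern):
    """One population's worth (10 samples) of calls for a single SNP."""
    assert len(pattern) == 10
    return list(pattern)


def cascade_fixture():
    """Returns (gm, dm, cat, expected_trajectory, surviving_snp_names).

    30 samples (3 pops x 10), 8 loci, 12 SNPs.  Hand enumeration:

    step                 snps_before -> snps_after   removed
    biallelic                12 -> 11                S1 (observed A/C/T)
    min_coverage             11 -> 11                4 calls of S7 blanked (depth 7)
    max_snps_per_locus       11 -> 7                 S2..S5 (locus L2 has 4 SNPs)
    mac                       7 -> 6                 S6 (2 minor copies)
    pop_callrate              6 -> 5                 S7 (pop2 missing 4/10 = 0.40)
    hwe                       5 -> 4                 S8 (P < 0.01 in pops 1 and 2)
    first_snp_per_locus       4 -> 3                 S10 (L6 keeps position 5)

    Survivors: S9 (L6_5), S11 (L7_0), S12 (L8_0).
    """
    samples = [f"s{i:02d}" for i in range(30)]
    popmap = {s: f"pop{i // 10 + 1}" for i, s in enumerate(samples)}

    snps = [
        SNPSite("L1", 0, ("A", "C", "T")),  # S1: triallelic
        SNPSite("L2", 0, ("A", "C")),       # S2 \
        SNPSite("L2", 1, ("A", "C")),       # S3  | 4 SNPs on L2
        SNPSite("L2", 2, ("A", "C")),       # S4  |
        SNPSite("L2", 3, ("A", "C")),       # S5 /
        SNPSite("L3", 0, ("A", "C")),       # S6: MAC = 2
        SNPSite("L4", 0, ("A", "C")),       # S7: pop2 call-rate failure
        SNPSite("L5", 0, ("A", "C")),       # S8: HWE failure in 2/3 pops
        SNPSite("L6", 5, ("A", "C")),       # S9: survivor
        SNPSite("L6", 17, ("A", "C")),      # S10: dropped at step 7
        SNPSite("L7", 0, ("A", "C")),       # S11: survivor
        SNPSite("L8", 0, ("A", "C")),       # S12: survivor
    ]

    per_snp_calls = {
        # S1: pop1 5 hom A + 5 het AC; pop2 all hom T; pop3 all hom A
        0: [HOM_A] * 5 + [HET_AC] * 5 + [HOM_T] * 10 + [HOM_A] * 10,
        # S6: two hets only (minor count 2)
        5: [HET_AC] + [HOM_A] * 9 + [HET_AC] + [HOM_A] * 9 + [HOM_A] * 10,
        # S8: pops 1-2 fixed-split homozygotes (HWE reject); pop3 conforms
        7: ([HOM_A] * 5 + [HOM_C] * 5) * 2 + ([HOM_A] * 2 + [HET_AC] * 6 + [HOM_C] * 2),
    }
    calls = np.zeros((30, 12, 2), dtype=np.int8)
    for j in range(12):
        pattern = per_snp_calls.get(j, _pop_block(_PATTERN) * 3)
        for i, c in enumerate(pattern):
            calls[i, j] = c

    counts = np.zeros((30, 12, 4), dtype=np.int64)
    for i in range(30):
        for j in range(12):
            counts[i, j] = _DEPTH[tuple(int(x) for x in calls[i, j])]
    # S7 (column 6): first four pop2 samples sequenced at depth 7 -> blanked
    # by the 8x filter, giving pop2 a missing fraction of exactly 0.40
    for i in range(10, 14):
        counts[i, 6] = (7, 0, 0, 0)

    tags = {f"L{k}": "A" * 36 for k in range(1, 9)}
    cat = LocusCatalog("fixture", tags, snps)
    gm = GenotypeMatrix(samples, popmap, snps, calls, label="fixture")
    dm = DepthMatrix(samples, list(snps), counts, label="fixture")

    expected = [
        ("biallelic", 12, 11),
        ("min_coverage", 11, 11),
        ("max_snps_per_locus", 11, 7),
        ("mac", 7, 6),
        ("pop_callrate", 6, 5),
        ("hwe", 5, 4),
        ("first_snp_per_locus", 4, 3),
    ]
    survivors = ["L6_5", "L7_0", "L8_0"]
    return gm, dm, cat, expected, survivors


def random_matrix(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_snps: int = 10,
    n_pops: int = 2,
    missing_rate: float = 0.2,
    all_missing_cols: int = 0,
    label: str = "rand",
) -> GenotypeMatrix:
    """Random biallelic genotype matrix (optionally with all-missing columns)."""
    samples = [f"i{k:03d}" for k in range(n_samples)]
    popmap = {s: f"pop{(k % n_pops) + 1}" for k, s in enumerate(samples)}
    # keep samples grouped by population so GENEPOP blocks are contiguous
    samples.sort(key=lambda s: popmap[s])
    snps = []
    calls = np.zeros((n_samples, n_snps, 2), dtype=np.int8)
    for j in range(n_snps):
        pair = rng.choice(4, size=2, replace=False)
        a, b = int(pair.min()), int(pair.max())
        snps.append(SNPSite(f"L{j + 1:04d}", int(rng.integers(0, 36)), ("ACGT"[a], "ACGT"[b])))
        for i in range(n_samples):
            u = rng.random()
            if u < missing_rate:
                calls[i, j] = (-1, -1)
            elif u < missing_rate + 0.3:
                calls[i, j] = (a, b)
            elif u < missing_rate + 0.65:
                calls[i, j] = (a, a)
            else:
                calls[i, j] = (b, b)
    for j in range(all_missing_cols):
        calls[:, j % n_snps] = (-1, -1)
    return GenotypeMatrix(samples, popmap, snps, calls, label=label)
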