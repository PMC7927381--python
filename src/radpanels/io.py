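"""Readers and writers for the standard text formats.

GENEPOP (4-digit allele dialect, A=0001 .. T=0004, missing 0000),
catalogue FASTA plus a TSV sidecar of SNP sites, and per-call allele
depth TSVs.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CODE,
    MISSING,
    NUCS,
    DepthMatrix,
    GenotypeMatrix,
    LocusCatalog,
    SNPSite,
)

__all__ = [
    "read_genepop",
    "write_genepop",
    "read_catalog",
    "write_catalog",
    "read_depths",
    "write_depths",
]

_SNP_NAME = re.compile(r"^(?P<locus>.+)_(?P<pos>\d+)$")


class GenepopParseError(ValueError):
    pass


def _allele_to_code(tok: str, line_no: int) -> int:
    if tok == "00" or tok == "000":
        return MISSING
    v = int(tok)
    if not 1 <= v <= 4:
        raise GenepopParseError(f"line {line_no}: allele code {tok!r} outside 01..04")
    return v - 1


def read_genepop(path: str | Path) -> GenotypeMatrix:
    """Parse a GENEPOP file into a genotype matrix.

    Accepts 4-digit (2 digits per allele) and 6-digit (3 per allele)
    diploid genotypes; ``0000``/``000000`` is missing.  Allele codes 01..04
    map to A, C, G, T.  Populations are named pop1, pop2, ... in block
    order.  Locus names of the form ``<locus>_<pos>`` recover the SNP's
    locus id and tag position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty GENEPOP file")
    locus_names: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    samples: list[str] = []
    popmap: dict[str, str] = {}
    rows: list[list[int]] = []
    pop_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            pop_no += 1
            i += 1
            continue
        if not line:
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {i + 1}: expected 'name , genotypes'")
        name, geno_part = line.split(",", 1)
        name = name.strip()
        if name in popmap:
            raise GenepopParseError(f"line {i + 1}: duplicate sample name {name!r}")
        toks = geno_part.split()
        if len(toks) != len(locus_names):
            raise GenepopParseError(
                f"line {i + 1}: {len(toks)} genotypes for {len(locus_names)} loci"
            )
        row: list[int] = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(f"line {i + 1}: malformed genotype {tok!r}")
            half = len(tok) // 2
            a = _allele_to_code(tok[:half], i + 1)
            b = _allele_to_code(tok[half:], i + 1)
            if (a < 0) != (b < 0):
                raise GenepopParseError(f"line {i + 1}: half-missing genotype {tok!r}")
            row.extend((a, b))
        samples.append(name)
        popmap[name] = f"pop{pop_no}"
        rows.append(row)
        i += 1
    if pop_no == 0 and samples:
        raise GenepopParseError("genotype lines before any Pop block")
    calls = (
        np.array(rows, dtype=np.int8).reshape(len(samples), len(locus_names), 2)
        if samples
        else np.zeros((0, len(locus_names), 2), dtype=np.int8)
    )
    snps = []
    for j, n in enumerate(locus_names):
        m = _SNP_NAME.match(n)
        locus, pos = (m.group("locus"), int(m.group("pos"))) if m else (n, 0)
        observed = {NUCS[c] for c in calls[:, j, :].ravel() if c >= 0} if samples else set()
        snps.append(SNPSite(locus, pos, tuple(sorted(observed)) or ("A",)))
    return GenotypeMatrix(samples, popmap, snps, calls)


def write_genepop(gm: GenotypeMatrix, path: str | Path, title: str | None = None) -> None:
    """Write a 4-digit GENEPOP file (deterministic: popmap order, one locus per line)."""
    path = Path(path)
    out = [title or f"{gm.label or 'panel'} genotypes"]
    out.extend(gm.snp_names())
    rows = gm.pop_rows()
    for pop in gm.pops():
        out.append("Pop")
        for i in rows[pop]:
            cells = []
            for j in range(gm.n_snps):
                a, b = int(gm.calls[i, j, 0]), int(gm.calls[i, j, 1])
                if a < 0:
                    cells.append("0000")
                else:
                    cells.append(f"{a + 1:02d}{b + 1:02d}")
            out.append(f"{gm.samples[i]} ,  " + " ".join(cells))
    path.write_text("\n".join(out) + "\n")


def write_catalog(cat: LocusCatalog, fasta_path: str | Path, snps_path: str | Path) -> None:
    """Catalogue as FASTA (id = locus id) plus a TSV of SNP sites."""
    records = [
        SeqRecord(Seq(tag), id=lid, description="")
        for lid, tag in sorted(cat.tags.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    df = pd.DataFrame(
        [(s.locus_id, s.position, ",".join(s.alleles)) for s in cat.snps],
        columns=["locus_id", "position", "alleles"],
    )
    df.to_csv(snps_path, sep="\t", index=False)


def read_catalog(fasta_path: str | Path, snps_path: str | Path | None = None, label: str = "") -> LocusCatalog:
    tags = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    snps: list[SNPSite] = []
    if snps_path is not None:
        df = pd.read_csv(snps_path, sep="\t", dtype={"locus_id": str})
        for row in df.itertuples(index=False):
            snps.append(
                SNPSite(str(row.locus_id), int(row.position), tuple(str(row.alleles).split(",")))
            )
    return LocusCatalog(label, tags, snps)


def write_depths(dm: DepthMatrix, path: str | Path) -> None:
    """Depths as TSV: sample, locus_id, position, nA, nC, nG, nT."""
    rows = []
    for i, sample in enumerate(dm.samples):
        for j, snp in enumerate(dm.snps):
            c = dm.counts[i, j]
            rows.append((sample, snp.locus_id, snp.position, *(int(x) for x in c)))
    pd.DataFrame(
        rows, columns=["sample", "locus_id", "position", "nA", "nC", "nG", "nT"]
    ).to_csv(path, sep="\t", index=False)


def read_depths(path: str | Path, label: str = "") -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "sample": str})
    samples = list(dict.fromkeys(df["sample"]))
    site_keys = list(dict.fromkeys(zip(df["locus_id"], df["position"])))
    s_idx = {s: i for i, s in enumerate(samples)}
    k_idx = {k: j for j, k in enumerate(site_keys)}
    counts = np.zeros((len(samples), len(site_keys), 4), dtype=np.int64)
    for row in df.itertuples(index=False):
        i = s_idx[row.sample]
        j = k_idx[(row.locus_id, row.position)]
        counts[i, j] = (row.nA, row.nC, row.nG, row.nT)
    snps = []
    for locus, pos in site_keys:
        col = counts[:, k_idx[(locus, pos)], :]
        observed = tuple(sorted(NUCS[k] for k in range(4) if col[:, k].sum() > 0))
        snps.append(SNPSite(str(locus), int(pos), observed or ("A",)))
    return DepthMatrix(samples, snps, counts, label=label)
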