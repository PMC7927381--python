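"""Cross-catalogue RAD-locus clustering and COM/MER panel construction.

Equal-length, ungapped tags reduce identity-threshold clustering to greedy
Hamming clustering: tags (canonically oriented) are processed in a
deterministic order and each joins the best-matching existing
representative within the mismatch budget, else founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import select_first_snp_per_locus
from .model import (
    GenotypeMatrix,
    LocusCatalog,
    SNPSite,
    orient,
)

__all__ = [
    "hamming",
    "ClusterMember",
    "Cluster",
    "ClusterMap",
    "cluster_catalogs",
    "match_snps",
    "build_com_panel",
    "build_mer_panel",
]


def hamming(a: str, b: str) -> int:
    """Positional mismatch count between two equal-length tags."""
    if len(a) != len(b):
        raise ValueError(f"tag lengths differ: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ClusterMember:
    pipeline: str
    locus_id: str
    flipped: bool
    mismatches: int


@dataclass
class Cluster:
    representative_tag: str
    members: list[ClusterMember] = field(default_factory=list)

    def pipelines(self) -> set[str]:
        return {m.pipeline for m in self.members}


@dataclass
class ClusterMap:
    clusters: list[Cluster]
    max_mismatch: int

    def classification(self) -> dict[tuple[str, str], str]:
        """(pipeline, locus_id) -> 'shared' | 'private'."""
        out: dict[tuple[str, str], str] = {}
        for cl in self.clusters:
            status = "shared" if len(cl.pipelines()) >= 2 else "private"
            for m in cl.members:
                out[(m.pipeline, m.locus_id)] = status
        return out

    def shared_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if len(c.pipelines()) >= 2]

    def private_loci(self, pipeline: str) -> list[str]:
        out = []
        for c in self.clusters:
            if c.pipelines() == {pipeline}:
                out.extend(m.locus_id for m in c.members if m.pipeline == pipeline)
        return out


def cluster_catalogs(cat_a: LocusCatalog, cat_b: LocusCatalog, max_mismatch: int) -> ClusterMap:
    """Greedy best-match clustering of two catalogues' canonical tags.

    Tags are processed in (tag, pipeline label, locus id) lexicographic
    order; a tag joins the existing representative with the fewest
    mismatches when that minimum is <= ``max_mismatch`` (ties to the
    earliest representative), otherwise it becomes a new representative.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if cat_a.tags and cat_b.tags and cat_a.tag_length != cat_b.tag_length:
        raise ValueError("catalogues have different tag lengths")
    entries = []
    for cat in (cat_a, cat_b):
        for lid, tag in cat.tags.items():
            canon, flipped = orient(tag)
            entries.append((canon, cat.label, lid, flipped))
    entries.sort()
    clusters: list[Cluster] = []
    reps = np.empty((0, 0), dtype=np.uint8)
    for canon, label, lid, flipped in entries:
        arr = np.frombuffer(canon.encode(), dtype=np.uint8)
        if reps.size:
            dists = (reps != arr[None, :]).sum(axis=1)
            best = int(dists.argmin())
            if int(dists[best]) <= max_mismatch:
                clusters[best].members.append(
                    ClusterMember(label, lid, flipped, int(dists[best]))
                )
                continue
        clusters.append(
            Cluster(canon, [ClusterMember(label, lid, flipped, 0)])
        )
        reps = np.vstack([reps, arr[None, :]]) if reps.size else arr[None, :]
    return ClusterMap(clusters, max_mismatch)


def match_snps(
    clustermap: ClusterMap,
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix,
) -> list[tuple[int, int, str]]:
    """Matched SNP pairs at shared loci between two step-6 panels.

    Two SNPs match when they sit in the same shared cluster, at an equal
    canonical position, with equal unordered allele pairs.  Each SNP
    matches at most one partner.  Returns ``(col_a, col_b, cluster_locus)``
    triples, where ``cluster_locus`` is the representative's locus key used
    for downstream one-SNP-per-locus selection.
    """
    label_a, label_b = panel_a.label, panel_b.label
    cols_a: dict[str, list[int]] = {}
    for j, s in enumerate(panel_a.snps):
        cols_a.setdefault(s.locus_id, []).append(j)
    cols_b: dict[str, list[int]] = {}
    for j, s in enumerate(panel_b.snps):
        cols_b.setdefault(s.locus_id, []).append(j)

    def observed_alleles(gm: GenotypeMatrix, j: int) -> tuple[int, ...]:
        col = gm.calls[:, j, :]
        return tuple(sorted({int(c) for c in col.ravel() if c >= 0}))

    matches: list[tuple[int, int, str]] = []
    for ci, cl in enumerate(clustermap.clusters):
        pipes = cl.pipelines()
        if not (label_a in pipes and label_b in pipes):
            continue
        a_cols: list[int] = []
        b_cols: list[int] = []
        for m in cl.members:
            if m.pipeline == label_a:
                a_cols.extend(cols_a.get(m.locus_id, []))
            elif m.pipeline == label_b:
                b_cols.extend(cols_b.get(m.locus_id, []))
        used_b: set[int] = set()
        cluster_key = f"C{ci + 1:06d}"
        for ja in a_cols:
            sa = panel_a.snps[ja]
            for jb in b_cols:
                if jb in used_b:
                    continue
                sb = panel_b.snps[jb]
                if sa.position != sb.position:
                    continue
                if observed_alleles(panel_a, ja) != observed_alleles(panel_b, jb):
                    continue
                matches.append((ja, jb, cluster_key))
                used_b.add(jb)
                break
    return matches


def _relabel_snps(gm: GenotypeMatrix, new_ids: list[str]) -> GenotypeMatrix:
    snps = [
        SNPSite(new_id, s.position, s.alleles)
        for new_id, s in zip(new_ids, gm.snps)
    ]
    return GenotypeMatrix(list(gm.samples), dict(gm.popmap), snps, gm.calls.copy(), gm.label)


def build_com_panel(
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix,
    clustermap: ClusterMap,
    return_indices: bool = False,
):
    """COM panel: matched SNPs, then one SNP per (cluster) locus.

    Returns the same SNP set twice, once carrying each pipeline's calls
    (both are needed for genotype concordance).  SNPs are re-keyed by
    cluster so the per-locus selection treats reconciled loci as units.
    With ``return_indices=True`` also returns the source column indices
    into ``panel_a`` and ``panel_b`` for each COM column (e.g. to align
    depth matrices).
    """
    matches = match_snps(clustermap, panel_a, panel_b)
    if not matches:
        empty_a = panel_a.take_snps([])
        empty_b = panel_b.take_snps([])
        empty_a.label = f"COM({panel_a.label})"
        empty_b.label = f"COM({panel_b.label})"
        if return_indices:
            return empty_a, empty_b, np.array([], dtype=int), np.array([], dtype=int)
        return empty_a, empty_b
    ja = np.array([m[0] for m in matches], dtype=int)
    jb = np.array([m[1] for m in matches], dtype=int)
    keys = [m[2] for m in matches]
    com_a = _relabel_snps(panel_a.take_snps(ja), keys)
    com_b = _relabel_snps(panel_b.take_snps(jb), keys)
    com_a, keep, _ = select_first_snp_per_locus(com_a)
    com_b = com_b.take_snps(keep)
    com_a.label = f"COM({panel_a.label})"
    com_b.label = f"COM({panel_b.label})"
    if return_indices:
        return com_a, com_b, ja[keep], jb[keep]
    return com_a, com_b


def build_mer_panel(
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix,
    clustermap: ClusterMap,
    com: GenotypeMatrix,
) -> GenotypeMatrix:
    """MER panel: COM SNPs plus SNPs on loci private to either catalogue.

    Private SNPs keep their native pipeline's genotypes; a final
    one-SNP-per-locus pass runs over the union.
    """
    if panel_a.samples != panel_b.samples or com.samples != panel_a.samples:
        raise ValueError("panels must share an identical sample list")
    private_a = set(clustermap.private_loci(panel_a.label))
    private_b = set(clustermap.private_loci(panel_b.label))
    idx_a = [j for j, s in enumerate(panel_a.snps) if s.locus_id in private_a]
    idx_b = [j for j, s in enumerate(panel_b.snps) if s.locus_id in private_b]
    parts_snps: list[SNPSite] = list(com.snps)
    parts_calls = [com.calls]
    # namespace private loci by pipeline: the same locus id may survive in
    # both catalogues yet fail to share a cluster
    if idx_a:
        sub = _relabel_snps(
            panel_a.take_snps(idx_a),
            [f"{panel_a.label}:{panel_a.snps[j].locus_id}" for j in idx_a],
        )
        parts_snps.extend(sub.snps)
        parts_calls.append(sub.calls)
    if idx_b:
        sub = _relabel_snps(
            panel_b.take_snps(idx_b),
            [f"{panel_b.label}:{panel_b.snps[j].locus_id}" for j in idx_b],
        )
        parts_snps.extend(sub.snps)
        parts_calls.append(sub.calls)
    calls = np.concatenate(parts_calls, axis=1) if parts_calls else com.calls
    mer = GenotypeMatrix(
        list(com.samples), dict(com.popmap), parts_snps, calls, label="MER"
    )
    mer, _, _ = select_first_snp_per_locus(mer)
    return mer
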