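"""End-to-end orchestration: simulate -> filter -> reconcile -> compare -> metrics.

``run_full`` executes the whole two-pipeline workflow from a configuration
mapping and writes every artifact (panels, audits, cluster table,
concordance, missing-source attribution, metrics, manifest) into an output
directory as plain text.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .concordance import (
    MISMATCH_CATEGORIES,
    Category,
    attribute_missing,
    compare_panels,
)
from .filters import CascadeParams, FilterAudit, run_cascade
from .io import write_catalog, write_depths, write_genepop
from .model import GenotypeMatrix
from .popgen import summarize_panel
from .reconcile import build_com_panel, build_mer_panel, cluster_catalogs
from .simdata import SimConfig, build_pipeline_outputs

__all__ = ["run_full", "audit_to_frame", "concordance_to_frame", "metrics_to_frame"]


def audit_to_frame(audit: FilterAudit) -> pd.DataFrame:
    rows = []
    for rec in audit.records:
        d = rec.as_dict()
        d.pop("per_sample_missing")
        rows.append(d)
    return pd.DataFrame(rows)


def concordance_to_frame(table) -> pd.DataFrame:
    freqs = table.frequencies()
    rows = [
        {
            "category": cat.value,
            "count": table.counts[cat],
            "frequency": freqs[cat],
            "is_mismatch": cat in MISMATCH_CATEGORIES,
        }
        for cat in Category
    ]
    return pd.DataFrame(rows)


def metrics_to_frame(metrics_by_panel: dict[str, Any]) -> pd.DataFrame:
    rows = []
    for panel, pm in metrics_by_panel.items():
        for pop, vals in pm.per_pop.items():
            rows.append({"panel": panel, "population": pop, **vals, "global_fst": pm.global_fst})
    return pd.DataFrame(rows)


def run_full(config: dict[str, Any], out_dir: str | Path, seed: int | None = None) -> dict[str, Any]:
    """Run the complete workflow; returns the in-memory results bundle.

    ``config`` keys: ``simulate`` (SimConfig fields), ``filters``
    (CascadeParams fields), ``cluster_mismatch`` (int, default 2),
    ``bootstrap`` (int, default 200).  ``seed`` overrides the simulation
    seed.  All artifacts are written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig.from_dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg.seed = int(seed)
    params = CascadeParams(**config.get("filters", {}))
    m = int(config.get("cluster_mismatch", 2))
    n_boot = int(config.get("bootstrap", 200))

    sim = build_pipeline_outputs(sim_cfg)
    write_catalog(sim.catalogs["STA"], out / "catalog_STA.fasta", out / "catalog_STA.snps.tsv")
    write_catalog(sim.catalogs["ALT"], out / "catalog_ALT.fasta", out / "catalog_ALT.snps.tsv")

    panels: dict[str, GenotypeMatrix] = {}
    step6: dict[str, tuple] = {}
    audits: dict[str, FilterAudit] = {}
    for label in ("STA", "ALT"):
        gm, dm = sim.genotypes[label], sim.depths[label]
        full, full_dm, audit = run_cascade(gm, dm, sim.catalogs[label], params, stop_after_step=7)
        p6, p6_dm, _ = run_cascade(gm, dm, sim.catalogs[label], params, stop_after_step=6)
        full.label = label
        p6.label = label
        panels[label] = full
        step6[label] = (p6, p6_dm)
        audits[label] = audit
        audit_to_frame(audit).to_csv(out / f"audit_{label}.tsv", sep="\t", index=False)
        write_genepop(full, out / f"panel_{label}.genepop")

    cmap = cluster_catalogs(sim.catalogs["STA"], sim.catalogs["ALT"], m)
    cls = cmap.classification()
    cluster_rows = []
    for ci, cl in enumerate(cmap.clusters):
        for mem in cl.members:
            cluster_rows.append(
                {
                    "cluster_id": f"C{ci + 1:06d}",
                    "pipeline": mem.pipeline,
                    "locus_id": mem.locus_id,
                    "orientation_flipped": mem.flipped,
                    "mismatches": mem.mismatches,
                    "status": cls[(mem.pipeline, mem.locus_id)],
                }
            )
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)

    sta6, sta6_dm = step6["STA"]
    alt6, alt6_dm = step6["ALT"]
    com_sta, com_alt, idx_a, idx_b = build_com_panel(sta6, alt6, cmap, return_indices=True)
    mer = build_mer_panel(sta6, alt6, cmap, com_sta)
    write_genepop(com_sta, out / "panel_COM.genepop")
    write_genepop(mer, out / "panel_MER.genepop")

    table = compare_panels(com_sta, com_alt)
    concordance_to_frame(table).to_csv(out / "concordance_COM.tsv", sep="\t", index=False)
    sources = attribute_missing(
        com_sta,
        com_alt,
        sta6_dm.take_snps(idx_a),
        alt6_dm.take_snps(idx_b),
        call_floor=3,
        cov_filter=params.min_coverage,
    )
    src_rows = [
        {"category": cat.value, **per_cat}
        for cat, per_cat in sources.sources.items()
    ]
    pd.DataFrame(src_rows).to_csv(out / "missing_sources_COM.tsv", sep="\t", index=False)

    com_metric = com_sta.copy()
    com_metric.label = "COM"
    metric_panels = {"STA": panels["STA"], "ALT": panels["ALT"], "COM": com_metric, "MER": mer}
    metrics = {
        name: summarize_panel(gm, n_boot=n_boot, seed=sim_cfg.seed)
        for name, gm in metric_panels.items()
    }
    metrics_to_frame(metrics).to_csv(out / "metrics.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "simulate": asdict(sim_cfg),
        "filters": asdict(params),
        "cluster_mismatch": m,
        "bootstrap": n_boot,
        "comparison_direction": "category X->Y means X in STA (first panel), Y in ALT (second)",
        "n_snps": {name: gm.n_snps for name, gm in metric_panels.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    return {
        "sim": sim,
        "panels": metric_panels,
        "step6": {"STA": sta6, "ALT": alt6},
        "audits": audits,
        "clustermap": cmap,
        "com": (com_sta, com_alt),
        "mer": mer,
        "concordance": table,
        "missing_sources": sources,
        "metrics": metrics,
        "manifest": manifest,
    }
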