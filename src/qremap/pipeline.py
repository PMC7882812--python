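"""End-to-end orchestration: UTR extraction -> QRE scan -> miRNA filter ->
eCLIP validation -> proximity scan, with a JSON run manifest.

The manifest echoes every configuration value verbatim, records input file
checksums and per-stage feature counts, so a run is reproducible and
auditable from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .eclip import validate_qres, validated_to_frame
from .errors import InputError
from .io import (
    ExpressionTable,
    load_genome,
    load_peaks,
    load_site_table,
    load_transcripts,
    write_report,
)
from .mirna import SiteFilterConfig, filter_sites, site_filter_audit
from .proximity import (
    ProximityConfig,
    find_proximal_pairs,
    pairs_to_frame,
    summarize_genes,
    write_pairs_bed,
)
from .scanner import QreMotifConfig, hits_to_frame, scan_utr_qres
from .utr import build_all_utr3

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str
    annotation: str
    sites: str
    mirna_expression: str
    peaks: dict[str, str]  # replicate_id -> narrowPeak path
    outdir: str
    motif: QreMotifConfig = field(default_factory=QreMotifConfig)
    site_filter: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    min_replicates: int = 1


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; writes the report bundle and returns a summary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    logger.info("stage extract-utr: loading genome and annotation")
    genome = load_genome(cfg.genome)
    models = load_transcripts(cfg.annotation)
    utrs = build_all_utr3(models, genome)
    counts["transcripts"] = len(models)
    counts["utrs"] = len(utrs)

    logger.info("stage scan-qre: scanning %d UTR(s)", len(utrs))
    hits = [h for utr in utrs for h in scan_utr_qres(utr, cfg.motif)]
    counts["qre_hits"] = len(hits)
    write_report(hits_to_frame(hits), outdir / "qre_hits.tsv", _params(cfg))

    logger.info("stage filter-mirna")
    sites = load_site_table(cfg.sites)
    mirna_expr = ExpressionTable.read_tsv(cfg.mirna_expression)
    kept_sites = filter_sites(sites, mirna_expr, cfg.site_filter)
    counts["sites_total"] = len(sites)
    counts["sites_kept"] = len(kept_sites)
    write_report(
        site_filter_audit(sites, mirna_expr, cfg.site_filter),
        outdir / "site_filter_audit.tsv",
        _params(cfg),
    )

    logger.info("stage validate-eclip: %d replicate(s)", len(cfg.peaks))
    peaks_by_rep = {
        rep: load_peaks(path, rep) for rep, path in sorted(cfg.peaks.items())
    }
    validated = validate_qres(hits, peaks_by_rep, cfg.min_replicates)
    counts["qres_validated"] = len(validated)
    write_report(
        validated_to_frame(validated), outdir / "validated_qres.tsv", _params(cfg)
    )

    logger.info("stage scan-proximity")
    utr_by_tid = {u.region.transcript_id: u for u in utrs}
    pairs = find_proximal_pairs(validated, kept_sites, cfg.proximity, utr_by_tid)
    counts["proximal_pairs"] = len(pairs)
    gene_summary = summarize_genes(pairs)
    counts["proximal_genes"] = len(gene_summary)
    write_report(pairs_to_frame(pairs), outdir / "proximal_pairs.tsv", _params(cfg))
    write_report(gene_summary, outdir / "gene_summary.tsv", _params(cfg))
    write_pairs_bed(pairs, outdir / "proximal_pairs.bed")

    manifest = {
        "tool": "qremap",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": _params(cfg),
        "inputs": {
            "genome": {"path": cfg.genome, "sha256": _sha256(cfg.genome)},
            "annotation": {"path": cfg.annotation, "sha256": _sha256(cfg.annotation)},
            "sites": {"path": cfg.sites, "sha256": _sha256(cfg.sites)},
            "mirna_expression": {
                "path": cfg.mirna_expression,
                "sha256": _sha256(cfg.mirna_expression),
            },
            "peaks": {
                rep: {"path": path, "sha256": _sha256(path)}
                for rep, path in sorted(cfg.peaks.items())
            },
        },
        "stage_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for stage, count in counts.items():
        logger.info("count %s=%d", stage, count)
    return {
        "counts": counts,
        "pairs": pairs,
        "gene_summary": gene_summary,
        "validated": validated,
        "hits": hits,
        "kept_sites": kept_sites,
        "utrs": utrs,
    }


def _params(cfg: RunConfig) -> dict:
    return {
        "core": cfg.motif.core,
        "half_site_pattern": cfg.motif.half_site_pattern,
        "half_site_max_gap": cfg.motif.half_site_max_gap,
        "expression_top_fraction": cfg.site_filter.expression_top_fraction,
        "mirsvr_cutoff": cfg.site_filter.mirsvr_cutoff,
        "max_distance_nt": cfg.proximity.max_distance_nt,
        "coordinate_space": cfg.proximity.coordinate_space,
        "min_replicates": cfg.min_replicates,
    }
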