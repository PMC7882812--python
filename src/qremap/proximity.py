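"""The headline scan: QRE–miRNA-site pairs within the proximity threshold.

A validated QRE and a filtered miRNA target site form a proximal pair when
they are annotated to the same gene's 3'UTR and their distance is strictly
below the threshold (default: fewer than 20 intervening nucleotides;
overlap counts as distance 0).  Distance is measured on genomic
coordinates by default; a spliced-transcript mode is available and the two
agree whenever both features lie within one UTR exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .eclip import ValidatedQre
from .errors import ConfigError
from .intervals import interval_gap
from .mirna import MiRnaTargetSite
from .utr import Utr3

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProximityConfig:
    max_distance_nt: int = 20  # strict less-than
    coordinate_space: str = "genomic"  # or "spliced"

    def __post_init__(self) -> None:
        if self.max_distance_nt < 0:
            raise ConfigError("max_distance_nt must be >= 0")
        if self.coordinate_space not in ("genomic", "spliced"):
            raise ConfigError(
                f"coordinate_space must be genomic/spliced, got {self.coordinate_space!r}"
            )


@dataclass(frozen=True)
class ProximalPair:
    qre: ValidatedQre
    site: MiRnaTargetSite
    distance_nt: int
    gene_symbol: str
    transcript_id: str


def _genomic_distance(qre: ValidatedQre, site: MiRnaTargetSite) -> int | None:
    if site.interval.contig != qre.hit.contig:
        return None
    return min(
        interval_gap(block, site.interval) for block in qre.hit.genomic_blocks
    )


def _spliced_distance(
    qre: ValidatedQre, site: MiRnaTargetSite, utr: Utr3 | None
) -> int | None:
    if utr is None:
        logger.info(
            "spliced mode: no UTR model for transcript %s; pair skipped",
            qre.hit.transcript_id,
        )
        return None
    t_span = utr.region.map_interval_from_genome(site.interval)
    if t_span is None:
        logger.info(
            "spliced mode: site %s@%s outside 3'UTR of %s; pair skipped",
            site.mirna_id, site.interval, qre.hit.transcript_id,
        )
        return None
    s_start, s_end = t_span
    if s_start >= qre.hit.t_end:
        return s_start - qre.hit.t_end
    if qre.hit.t_start >= s_end:
        return qre.hit.t_start - s_end
    return 0


def find_proximal_pairs(
    validated: list[ValidatedQre],
    sites: list[MiRnaTargetSite],
    cfg: ProximityConfig | None = None,
    utrs: Mapping[str, Utr3] | None = None,
) -> list[ProximalPair]:
    """All same-gene (validated QRE, filtered site) pairs within threshold.

    ``utrs`` (transcript_id -> Utr3) is required for spliced mode only.
    """
    cfg = cfg or ProximityConfig()
    if cfg.coordinate_space == "spliced" and utrs is None:
        raise ConfigError("spliced coordinate mode needs the transcript UTR models")
    sites_by_gene: dict[str, list[MiRnaTargetSite]] = {}
    for s in sites:
        sites_by_gene.setdefault(s.gene_symbol, []).append(s)

    pairs: list[ProximalPair] = []
    for vq in validated:
        for site in sites_by_gene.get(vq.hit.gene_symbol, []):
            if cfg.coordinate_space == "genomic":
                distance = _genomic_distance(vq, site)
            else:
                distance = _spliced_distance(vq, site, utrs.get(vq.hit.transcript_id))
            if distance is not None and distance < cfg.max_distance_nt:
                pairs.append(
                    ProximalPair(
                        qre=vq,
                        site=site,
                        distance_nt=distance,
                        gene_symbol=vq.hit.gene_symbol,
                        transcript_id=vq.hit.transcript_id,
                    )
                )
    pairs.sort(
        key=lambda p: (
            p.gene_symbol, p.transcript_id, p.qre.hit.t_start,
            p.qre.hit.genomic_blocks[0].start,
            p.site.mirna_id, p.site.interval.start, p.site.interval.end,
        )
    )
    logger.info("proximity scan: %d pair(s) below %d nt", len(pairs), cfg.max_distance_nt)
    return pairs


def pairs_to_frame(pairs: list[ProximalPair]) -> pd.DataFrame:
    rows = [
        {
            "gene": p.gene_symbol,
            "transcript_id": p.transcript_id,
            "qre_t_start": p.qre.hit.t_start,
            "qre_blocks": ",".join(
                f"{b.start}-{b.end}" for b in p.qre.hit.genomic_blocks
            ),
            "qre_replicate_support": p.qre.replicate_support,
            "mirna_id": p.site.mirna_id,
            "site_start": p.site.interval.start,
            "site_end": p.site.interval.end,
            "mirsvr_score": p.site.mirsvr_score,
            "distance_nt": p.distance_nt,
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "transcript_id", "qre_t_start", "qre_blocks",
            "qre_replicate_support", "mirna_id", "site_start", "site_end",
            "mirsvr_score", "distance_nt",
        ],
    )


def summarize_genes(pairs: list[ProximalPair]) -> pd.DataFrame:
    """Per-gene summary of proximal pairs, gene symbol ascending."""
    per_gene: dict[str, list[ProximalPair]] = {}
    for p in pairs:
        per_gene.setdefault(p.gene_symbol, []).append(p)
    rows = []
    for gene in sorted(per_gene):
        gene_pairs = per_gene[gene]
        rows.append(
            {
                "gene": gene,
                "n_pairs": len(gene_pairs),
                "best_distance_nt": min(p.distance_nt for p in gene_pairs),
                "n_mirnas": len({p.site.mirna_id for p in gene_pairs}),
                "max_replicate_support": max(
                    p.qre.replicate_support for p in gene_pairs
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_pairs", "best_distance_nt", "n_mirnas", "max_replicate_support"],
    )


def write_pairs_bed(pairs: Iterable[ProximalPair], path: str | Path) -> None:
    """BED6 track of paired QREs and sites; the name field encodes pairing."""
    records = []
    for idx, p in enumerate(pairs):
        pair_id = f"pair{idx + 1}"
        for b in p.qre.hit.genomic_blocks:
            records.append(
                (b.contig, b.start, b.end,
                 f"{pair_id}|QRE|{p.gene_symbol}|{p.transcript_id}", 0, b.strand)
            )
        s = p.site.interval
        records.append(
            (s.contig, s.start, s.end,
             f"{pair_id}|site|{p.gene_symbol}|{p.site.mirna_id}", 0, s.strand)
        )
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
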