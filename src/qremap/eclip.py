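"""Cross-validation of QRE motif hits against eCLIP narrowPeak replicates.

A motif hit is supported by a replicate when any of its genomic blocks
overlaps (>= 1 bp, strand-ignorant) any peak of that replicate — relevant
for junction-spanning hits, where one covered block suffices.  By default
hits supported by at least one replicate are kept; the per-replicate
support pattern is always reported so a stricter both-duplicates view is
one flag away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError
from .io import Peak
from .scanner import MotifHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidatedQre:
    hit: MotifHit
    replicate_support: int
    supporting_peaks: tuple[str, ...]
    support_by_replicate: Mapping[str, bool]


def _peak_trees(peaks: list[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.contig, IntervalTree()).addi(
            p.interval.start, p.interval.end, p.name
        )
    return trees


def validate_qres(
    hits: list[MotifHit],
    peaks_by_replicate: Mapping[str, list[Peak]],
    min_replicates: int = 1,
) -> list[ValidatedQre]:
    """Hits overlapped by peaks in at least ``min_replicates`` replicates."""
    if not peaks_by_replicate:
        raise ConfigError("at least one eCLIP replicate is required")
    if not 1 <= min_replicates <= len(peaks_by_replicate):
        raise ConfigError(
            f"min_replicates={min_replicates} outside [1, {len(peaks_by_replicate)}]"
        )
    trees = {
        rep: _peak_trees(peaks) for rep, peaks in sorted(peaks_by_replicate.items())
    }
    validated: list[ValidatedQre] = []
    for hit in hits:
        support: dict[str, bool] = {}
        names: list[str] = []
        for rep, contig_trees in trees.items():
            tree = contig_trees.get(hit.contig)
            overlapping = set()
            if tree is not None:
                for block in hit.genomic_blocks:
                    for iv in tree.overlap(block.start, block.end):
                        overlapping.add(iv.data)
            support[rep] = bool(overlapping)
            names.extend(sorted(overlapping))
        n_support = sum(support.values())
        if n_support >= min_replicates:
            validated.append(
                ValidatedQre(
                    hit=hit,
                    replicate_support=n_support,
                    supporting_peaks=tuple(names),
                    support_by_replicate=support,
                )
            )
    logger.info(
        "eCLIP validation: %d/%d QRE hits supported by >=%d replicate(s)",
        len(validated), len(hits), min_replicates,
    )
    return validated


def validated_to_frame(validated: list[ValidatedQre]) -> pd.DataFrame:
    """Tabular view with one support flag column per replicate."""
    replicates = sorted(
        {rep for v in validated for rep in v.support_by_replicate}
    )
    rows = []
    for v in validated:
        row = {
            "transcript_id": v.hit.transcript_id,
            "gene": v.hit.gene_symbol,
            "t_start": v.hit.t_start,
            "contig": v.hit.contig,
            "genomic_blocks": ",".join(
                f"{b.start}-{b.end}" for b in v.hit.genomic_blocks
            ),
            "spans_junction": v.hit.spans_junction,
            "replicate_support": v.replicate_support,
            "supporting_peaks": ";".join(v.supporting_peaks),
        }
        for rep in replicates:
            row[f"support_{rep}"] = bool(v.support_by_replicate.get(rep, False))
        rows.append(row)
    columns = [
        "transcript_id", "gene", "t_start", "contig", "genomic_blocks",
        "spans_junction", "replicate_support", "supporting_peaks",
    ] + [f"support_{rep}" for rep in replicates]
    return pd.DataFrame(rows, columns=columns)
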