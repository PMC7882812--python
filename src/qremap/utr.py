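"""3'UTR models: genomic blocks plus the spliced, transcript-oriented RNA.

The 3'UTR is where both the QKI response element (QRE) and miRNA seed
matches live, so everything downstream operates on these objects.  When a
transcript annotates explicit three_prime_utr features they are used
verbatim; otherwise the UTR is the exonic territory strictly 3' of the
annotated CDS end in transcript orientation (on the minus strand that is
the genomic left of the CDS).  The CDS end is taken exactly as annotated —
no stop-codon adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .errors import AnnotationError, CoordinateError
from .intervals import GenomicInterval, SplicedRegion
from .io import TranscriptModel

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Utr3:
    """A 3'UTR: spliced region plus its 5'->3' RNA sequence."""

    region: SplicedRegion
    rna_sequence: str

    def __post_init__(self) -> None:
        if len(self.rna_sequence) != self.region.length:
            raise CoordinateError(
                f"sequence length {len(self.rna_sequence)} != region length "
                f"{self.region.length} for {self.region.transcript_id}"
            )


def derive_utr3_blocks(model: TranscriptModel) -> list[GenomicInterval] | None:
    """3'UTR genomic blocks of a transcript, or None when underivable.

    Preference order: explicit three_prime_utr features; else exon territory
    past the CDS end.  Transcripts with neither annotation are skipped with
    a warning (returns None), as are coding transcripts whose UTR is empty.
    """
    if model.utr3:
        return list(model.utr3)
    if not model.exons or not model.cds:
        logger.warning(
            "transcript %s has no three_prime_utr and no CDS; skipped",
            model.transcript_id,
        )
        return None

    exon_lo = min(b.start for b in model.exons)
    exon_hi = max(b.end for b in model.exons)
    cds_lo = min(b.start for b in model.cds)
    cds_hi = max(b.end for b in model.cds)
    if cds_lo < exon_lo or cds_hi > exon_hi:
        raise AnnotationError(
            f"CDS [{cds_lo},{cds_hi}) extends beyond exons of {model.transcript_id}"
        )

    blocks: list[GenomicInterval] = []
    if model.strand == "+":
        for b in model.exons:
            lo = max(b.start, cds_hi)
            if lo < b.end:
                blocks.append(GenomicInterval(b.contig, lo, b.end, b.strand))
    else:
        for b in model.exons:
            hi = min(b.end, cds_lo)
            if b.start < hi:
                blocks.append(GenomicInterval(b.contig, b.start, hi, b.strand))
    if not blocks:
        logger.warning("transcript %s has an empty 3'UTR; skipped", model.transcript_id)
        return None
    return blocks


def spliced_rna_sequence(region: SplicedRegion, genome: Mapping[str, str]) -> str:
    """Transcript-oriented (5'->3') RNA of a spliced region.

    Blocks are concatenated in genomic order, reverse-complemented for the
    minus strand, then transcribed T->U.  Bases outside A/C/G/T are kept
    as N.
    """
    contig_seq = genome.get(region.contig)
    if contig_seq is None:
        raise CoordinateError(f"contig {region.contig!r} absent from genome")
    parts = []
    for b in region.blocks:
        if b.end > len(contig_seq):
            raise CoordinateError(
                f"block {b} beyond contig {region.contig} length {len(contig_seq)}"
            )
        parts.append(contig_seq[b.start : b.end].upper())
    dna = "".join(parts)
    dna = "".join(base if base in _COMPLEMENT else "N" for base in dna)
    if region.strand == "-":
        dna = "".join(_COMPLEMENT[base] for base in reversed(dna))
    return dna.replace("T", "U")


def build_utr3(model: TranscriptModel, genome: Mapping[str, str]) -> Utr3 | None:
    """Derive and sequence the 3'UTR of one transcript (None if skipped)."""
    blocks = derive_utr3_blocks(model)
    if blocks is None:
        return None
    region = SplicedRegion(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        gene_symbol=model.gene_symbol,
        strand=model.strand,
        blocks=tuple(sorted(blocks, key=lambda b: b.start)),
    )
    return Utr3(region=region, rna_sequence=spliced_rna_sequence(region, genome))


def build_all_utr3(
    models: list[TranscriptModel], genome: Mapping[str, str]
) -> list[Utr3]:
    """Every transcript's 3'UTR; isoforms are kept independently."""
    utrs = []
    for model in models:
        utr = build_utr3(model, genome)
        if utr is not None:
            utrs.append(utr)
    return utrs
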