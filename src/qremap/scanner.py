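"""QRE motif scanning over spliced 3'UTR RNA.

The quaking response element is a bipartite motif: the core 5mer 'ACUAA'
and an optional downstream half-site 'UAAY' (Y = C or U).  Only the core
drives the validation/proximity pipeline; the half-site is annotated as
metadata.  Overlapping core occurrences are all reported, and a core that
spans an exon junction maps back to more than one genomic block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .intervals import GenomicInterval
from .utr import Utr3

_RNA_ALPHABET = set("ACGU")

# IUPAC degenerate RNA codes, for the half-site pattern
_IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


@dataclass(frozen=True)
class QreMotifConfig:
    core: str = "ACUAA"
    half_site_pattern: str = "UAAY"
    half_site_max_gap: int = 20

    def __post_init__(self) -> None:
        if not self.core:
            raise ConfigError("core motif must be non-empty")
        if set(self.core) - _RNA_ALPHABET:
            raise ConfigError(f"core motif {self.core!r} not over A/C/G/U")
        bad = set(self.half_site_pattern) - set(_IUPAC_RNA)
        if bad:
            raise ConfigError(f"half-site pattern has non-IUPAC symbols {bad}")
        if self.half_site_max_gap < 0:
            raise ConfigError("half_site_max_gap must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    """One QRE core occurrence in a 3'UTR, with its genomic placement."""

    transcript_id: str
    gene_symbol: str
    t_start: int
    t_end: int
    genomic_blocks: tuple[GenomicInterval, ...]
    core_seq: str
    half_site_t_start: int | None
    spans_junction: bool

    @property
    def contig(self) -> str:
        return self.genomic_blocks[0].contig


def scan_core_motif(seq: str, core: str = "ACUAA") -> list[int]:
    """All start positions of ``core`` in ``seq``, overlapping included.

    Exact matching over A/C/G/U: an N in the sequence never matches.
    """
    if not core:
        raise ConfigError("core motif must be non-empty")
    hits: list[int] = []
    pos = seq.find(core)
    while pos != -1:
        hits.append(pos)
        pos = seq.find(core, pos + 1)
    return hits


def annotate_half_site(seq: str, core_end: int, cfg: QreMotifConfig) -> int | None:
    """Nearest half-site start in [core_end, core_end + max_gap], or None."""
    if not 0 <= core_end <= len(seq):
        raise ConfigError(f"core_end {core_end} outside sequence of length {len(seq)}")
    pattern = re.compile("".join(_IUPAC_RNA[s] for s in cfg.half_site_pattern))
    plen = len(cfg.half_site_pattern)
    last_start = min(core_end + cfg.half_site_max_gap, len(seq) - plen)
    for start in range(core_end, last_start + 1):
        if pattern.fullmatch(seq, start, start + plen):
            return start
    return None


def scan_utr_qres(utr: Utr3, cfg: QreMotifConfig | None = None) -> list[MotifHit]:
    """One MotifHit per core occurrence in the UTR, genome-placed."""
    cfg = cfg or QreMotifConfig()
    hits = []
    core_len = len(cfg.core)
    for t_start in scan_core_motif(utr.rna_sequence, cfg.core):
        t_end = t_start + core_len
        blocks = tuple(utr.region.map_interval_to_genome(t_start, t_end))
        hits.append(
            MotifHit(
                transcript_id=utr.region.transcript_id,
                gene_symbol=utr.region.gene_symbol,
                t_start=t_start,
                t_end=t_end,
                genomic_blocks=blocks,
                core_seq=utr.rna_sequence[t_start:t_end],
                half_site_t_start=annotate_half_site(utr.rna_sequence, t_end, cfg),
                spans_junction=len(blocks) > 1,
            )
        )
    return hits


def count_qres(utr: Utr3, cfg: QreMotifConfig | None = None) -> int:
    """Number of QRE cores in one UTR (Fig-5-style per-gene count input)."""
    return len(scan_utr_qres(utr, cfg))


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """Tabular view of motif hits for TSV reports."""
    rows = [
        {
            "transcript_id": h.transcript_id,
            "gene": h.gene_symbol,
            "t_start": h.t_start,
            "t_end": h.t_end,
            "contig": h.contig,
            "genomic_blocks": ",".join(f"{b.start}-{b.end}" for b in h.genomic_blocks),
            "spans_junction": h.spans_junction,
            "half_site_t_start": "" if h.half_site_t_start is None else h.half_site_t_start,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene", "t_start", "t_end", "contig",
            "genomic_blocks", "spans_junction", "half_site_t_start",
        ],
    )
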