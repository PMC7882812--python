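"""Readers and writers for the standard formats the pipeline touches.

FASTA is read with Biopython, GTF with gffutils (in-memory database, no
inference of parent features), narrowPeak/TSV tables with pandas.  GTF spans
arrive 1-based closed and leave this module 0-based half-open; BED-family
coordinates pass through unchanged.

Output tables are TSV with '#'-prefixed metadata lines (tool version and
parameters) followed by a header row, so every report is self-describing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError
from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "contig", "start", "end", "name", "score",
    "strand", "signal_value", "p_value_log", "q_value_log", "summit_offset",
]

SITE_TABLE_COLUMNS = [
    "mirna_id", "contig", "start", "end", "strand", "gene", "mirsvr_score",
]


@dataclass(frozen=True)
class Peak:
    """One ENCODE narrowPeak record tagged with its replicate of origin."""

    interval: GenomicInterval
    name: str
    signal_value: float
    p_value_log: float
    q_value_log: float
    summit_offset: int
    replicate_id: str

    def __post_init__(self) -> None:
        if not self.replicate_id:
            raise FormatError("peak replicate_id must be non-empty")


@dataclass
class TranscriptModel:
    """Exon/CDS/3'UTR features of one transcript, 0-based half-open."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    contig: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)


class ExpressionTable:
    """Feature-by-sample table of non-negative expression values.

    Thin validation wrapper over a pandas DataFrame: unique feature keys,
    numeric non-negative values.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature keys: {dups}")
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            raise FormatError("non-numeric expression values")
        if (numeric < 0).any().any():
            raise InputError("negative expression values")
        self.frame = numeric

    @classmethod
    def read_tsv(cls, path: str | Path, index_col: int = 0) -> "ExpressionTable":
        frame = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
        if frame.empty and frame.columns.empty:
            raise FormatError(f"empty expression table: {path}")
        return cls(frame)

    @property
    def features(self) -> list[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.columns)

    def __contains__(self, feature: str) -> bool:
        return feature in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def values_for(self, feature: str) -> pd.Series:
        return self.frame.loc[feature]

    def write_tsv(self, path: str | Path, index_label: str = "feature") -> None:
        self.frame.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------------------
# FASTA

def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {contig: uppercase sequence}."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate contig name {record.id!r} in {path}")
        genome[record.id] = str(record.seq).upper()
    if not genome:
        raise FormatError(f"no FASTA records in {path}")
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

_FEATURE_SLOTS = {"exon": "exons", "CDS": "cds", "three_prime_utr": "utr3"}


def load_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Group exon/CDS/three_prime_utr GTF features per transcript_id.

    1-based closed GTF spans are converted to 0-based half-open; exons are
    sorted by genomic start.  Mixed strands or a feature lacking
    transcript_id are format errors.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc

    models: dict[str, TranscriptModel] = {}
    for feat in db.all_features():
        slot = _FEATURE_SLOTS.get(feat.featuretype)
        if slot is None:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{feat.featuretype} feature without transcript_id at "
                f"{feat.seqid}:{feat.start}-{feat.end}"
            ) from exc
        gene_id = feat.attributes.get("gene_id", [tid])[0]
        symbol = feat.attributes.get(
            "gene_name", feat.attributes.get("gene_symbol", [gene_id])
        )[0]
        model = models.setdefault(
            tid,
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                gene_symbol=symbol,
                contig=feat.seqid,
                strand=feat.strand,
            ),
        )
        if feat.strand != model.strand:
            raise FormatError(f"mixed strands within transcript {tid}")
        if feat.seqid != model.contig:
            raise FormatError(f"mixed contigs within transcript {tid}")
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        getattr(model, slot).append(interval)

    for model in models.values():
        model.exons.sort(key=lambda b: b.start)
        model.cds.sort(key=lambda b: b.start)
        model.utr3.sort(key=lambda b: b.start)
    return sorted(models.values(), key=lambda m: m.transcript_id)


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "qremap") -> None:
    """Write transcript models back to GTF (1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            for ftype, blocks in (("exon", m.exons), ("CDS", m.cds), ("three_prime_utr", m.utr3)):
                for b in blocks:
                    attrs = (
                        f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                        f'gene_name "{m.gene_symbol}";'
                    )
                    fh.write(
                        f"{m.contig}\t{source}\t{ftype}\t{b.start + 1}\t{b.end}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# narrowPeak

def load_peaks(path: str | Path, replicate_id: str) -> list[Peak]:
    """Read a 10-column ENCODE narrowPeak file (BED6+4)."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] != len(NARROWPEAK_COLUMNS):
        raise FormatError(
            f"narrowPeak needs 10 columns, found {frame.shape[1]} in {path}"
        )
    frame.columns = NARROWPEAK_COLUMNS
    peaks: list[Peak] = []
    for row in frame.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
            signal = float(row.signal_value)
            p_log = float(row.p_value_log)
            q_log = float(row.q_value_log)
            summit = int(row.summit_offset)
        except ValueError as exc:
            raise FormatError(f"non-numeric narrowPeak field in {path}: {exc}") from exc
        if start >= end:
            raise FormatError(f"narrowPeak start >= end ({start} >= {end}) in {path}")
        peaks.append(
            Peak(
                interval=GenomicInterval(row.contig, start, end, row.strand),
                name=row.name,
                signal_value=signal,
                p_value_log=p_log,
                q_value_log=q_log,
                summit_offset=summit,
                replicate_id=replicate_id,
            )
        )
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            i = p.interval
            fh.write(
                f"{i.contig}\t{i.start}\t{i.end}\t{p.name}\t0\t{i.strand}\t"
                f"{p.signal_value:g}\t{p.p_value_log:g}\t{p.q_value_log:g}\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# miRNA target-site table

def load_site_table(path: str | Path):
    """Read the project TSV of scored miRNA target sites.

    Required columns: mirna_id, contig, start, end, strand, gene,
    mirsvr_score; an optional transcript_id column is carried through.
    Returns a list of :class:`qremap.mirna.MiRnaTargetSite`.
    """
    from .mirna import MiRnaTargetSite  # local import avoids a cycle

    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"site table missing columns {missing} in {path}")
    sites = []
    for row in frame.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
            score = float(row.mirsvr_score)
        except ValueError as exc:
            raise FormatError(f"bad numeric field in site table {path}: {exc}") from exc
        sites.append(
            MiRnaTargetSite(
                mirna_id=row.mirna_id,
                gene_symbol=row.gene,
                interval=GenomicInterval(row.contig, start, end, row.strand),
                mirsvr_score=score,
                transcript_id=getattr(row, "transcript_id", None),
            )
        )
    return sites


def write_site_table(sites, path: str | Path) -> None:
    rows = [
        {
            "mirna_id": s.mirna_id,
            "contig": s.interval.contig,
            "start": s.interval.start,
            "end": s.interval.end,
            "strand": s.interval.strand,
            "gene": s.gene_symbol,
            "mirsvr_score": s.mirsvr_score,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic TSV report with provenance header

def write_report(frame: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a TSV report preceded by '#'-prefixed metadata lines."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# qremap {__version__}\n")
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
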