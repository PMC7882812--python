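"""Strand-aware genomic intervals and spliced-transcript coordinate mapping.

All coordinates are 0-based half-open throughout the package; conversion to
and from 1-based closed conventions (GTF) happens only at I/O boundaries.

A :class:`SplicedRegion` defines a transcript-local coordinate system over an
ordered set of exonic blocks.  Transcript position 0 is the 5'-most base of
the mature (spliced) RNA: the leftmost genomic base for a plus-strand region,
the rightmost for a minus-strand one.  Motifs found in spliced sequence are
placed back on the genome with :meth:`SplicedRegion.map_interval_to_genome`;
a hit spanning an exon junction maps to more than one genomic block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CoordinateError

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on one contig.

    Empty intervals are rejected: ``start < end`` always holds.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start}")
        if self.start >= self.end:
            raise CoordinateError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return interval_gap(self, other) == 0 and not (
            self.end <= other.start or other.end <= self.start
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases strictly between two intervals on the same contig.

    Overlapping or book-ended (adjacent) intervals have gap 0; "physical
    distance" is the count of intervening bases.  Different contigs are a
    domain error, not infinity.
    """
    if a.contig != b.contig:
        raise CoordinateError(
            f"cannot compute gap across contigs {a.contig!r} vs {b.contig!r}"
        )
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


@dataclass(frozen=True)
class SplicedRegion:
    """Ordered exonic blocks defining a transcript coordinate system.

    ``blocks`` are non-overlapping, on one contig, sorted by ascending
    genomic start regardless of strand; strand only affects which end is
    transcript position 0.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise CoordinateError(f"SplicedRegion strand must be +/-, got {self.strand!r}")
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks:
            raise CoordinateError("SplicedRegion needs at least one block")
        contigs = {b.contig for b in blocks}
        if len(contigs) != 1:
            raise CoordinateError(f"blocks span multiple contigs: {sorted(contigs)}")
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.start < prev.end:
                raise CoordinateError(
                    f"blocks overlap or are unsorted: {prev} then {cur}"
                )

    @property
    def contig(self) -> str:
        return self.blocks[0].contig

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def span(self) -> GenomicInterval:
        """Genomic envelope from first block start to last block end."""
        return GenomicInterval(
            self.contig, self.blocks[0].start, self.blocks[-1].end, self.strand
        )

    # -- transcript -> genome ------------------------------------------------

    def map_to_genome(self, t_pos: int) -> tuple[str, int]:
        """Genomic base holding transcript position ``t_pos`` (strand-aware)."""
        if not 0 <= t_pos < self.length:
            raise CoordinateError(
                f"transcript position {t_pos} outside [0, {self.length})"
            )
        if self.strand == "+":
            remaining = t_pos
            for b in self.blocks:
                if remaining < b.length:
                    return self.contig, b.start + remaining
                remaining -= b.length
        else:
            remaining = t_pos
            for b in reversed(self.blocks):
                if remaining < b.length:
                    return self.contig, b.end - 1 - remaining
                remaining -= b.length
        raise AssertionError("unreachable")

    def map_interval_to_genome(
        self, t_start: int, t_end: int
    ) -> list[GenomicInterval]:
        """Genomic blocks (ascending) covered by transcript span [t_start, t_end).

        Block lengths always sum to ``t_end - t_start``; a junction-spanning
        span yields more than one block.
        """
        if not (0 <= t_start < t_end <= self.length):
            raise CoordinateError(
                f"invalid transcript interval [{t_start}, {t_end}) for length {self.length}"
            )
        if self.strand == "-":
            # minus-strand transcript coords count from the genomic right;
            # flip to a left-anchored walk over the same blocks
            t_start, t_end = self.length - t_end, self.length - t_start
        out: list[GenomicInterval] = []
        offset = 0
        for b in self.blocks:
            lo = max(t_start, offset)
            hi = min(t_end, offset + b.length)
            if lo < hi:
                out.append(
                    GenomicInterval(
                        self.contig, b.start + lo - offset, b.start + hi - offset, self.strand
                    )
                )
            offset += b.length
        return out

    # -- genome -> transcript ------------------------------------------------

    def map_from_genome(self, g_pos: int) -> int:
        """Transcript position of genomic base ``g_pos``; error if intronic."""
        offset = 0
        for b in self.blocks:
            if b.start <= g_pos < b.end:
                t_plus = offset + (g_pos - b.start)
                return t_plus if self.strand == "+" else self.length - 1 - t_plus
            offset += b.length
        raise CoordinateError(
            f"genomic position {g_pos} not in any block of {self.transcript_id}"
        )

    def map_interval_from_genome(
        self, interval: GenomicInterval
    ) -> tuple[int, int] | None:
        """Transcript span of a fully exonic genomic interval, else None.

        Returns None when the interval lies (partly) outside the blocks or
        covers intronic bases, so callers can skip with a logged reason.
        """
        if interval.contig != self.contig:
            return None
        covered = 0
        for b in self.blocks:
            covered += max(0, min(interval.end, b.end) - max(interval.start, b.start))
        if covered != interval.length:
            return None
        t1 = self.map_from_genome(interval.start)
        t2 = self.map_from_genome(interval.end - 1)
        lo, hi = min(t1, t2), max(t1, t2)
        return lo, hi + 1
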