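"""Genomic coordinate model shared by every pipeline stage.

All coordinates are 0-based, half-open on the forward genome strand
(BED convention).  Transcript orientation is expressed through exon
*ordering*, never through coordinate flipping: a minus-strand transcript
lists its exons from high to low genomic coordinate so that the list is
always 5'->3' in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

#: Minimum intron length accepted when interpreting alignment gaps as
#: splicing; shorter N gaps are treated as micro-deletions and merged.
MIN_INTRON_LENGTH = 20

STRANDS = ("+", "-")


class Provenance(str, Enum):
    """Where a feature is supported: reference annotations or observation."""

    GENCODE = "GENCODE"
    REFSEQ = "REFSEQ"
    OBSERVED = "OBSERVED"
    NOVEL = "NOVEL"


class ExonRole(str, Enum):
    FIRST = "first"
    INTERNAL = "internal"
    LAST = "last"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    role: ExonRole = ExonRole.UNKNOWN
    provenance: frozenset = frozenset()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class SpliceJunction:
    """An intron: donor_end is the first intronic base (half-open end of the
    upstream exon in forward-genome coordinates), acceptor_start is one past
    the last intronic base.  Minus-strand introns are stored with the same
    left/right orientation; the strand field carries the biology.

    Provenance does not participate in equality/hashing so that the same
    coordinates observed by different sources collapse onto one key.
    """

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str
    provenance: frozenset = field(default=frozenset(), compare=False)

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"junction with non-positive intron: {self.key()}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def key(self) -> tuple:
        return (self.chrom, self.donor_end, self.acceptor_start, self.strand)

    @property
    def intron_length(self) -> int:
        return self.acceptor_start - self.donor_end

    def with_provenance(self, flags: Iterable[Provenance]) -> "SpliceJunction":
        return replace(self, provenance=frozenset(flags))

    def ends(self) -> tuple:
        """The two exon-end keys this junction supports.

        The left coordinate is an exon *end* (the upstream exon stops where
        the intron starts), the right one an exon *start*.
        """
        return (
            (self.chrom, self.donor_end, "end", self.strand),
            (self.chrom, self.acceptor_start, "start", self.strand),
        )


@dataclass
class Transcript:
    """An ordered exon chain; exons are 5'->3' in transcript orientation."""

    id: str
    exons: list
    source: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.id} spans chroms/strands")
        ordered = self.exons_genomic_order()
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or touch "
                    f"({a.start}-{a.end} vs {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    def exons_genomic_order(self) -> list:
        return sorted(self.exons, key=lambda e: e.start)

    def blocks(self) -> list:
        """Exon (start, end) pairs in forward-genome order."""
        return [(e.start, e.end) for e in self.exons_genomic_order()]

    def with_roles(self) -> "Transcript":
        """Return a copy whose exons carry first/internal/last roles."""
        n = len(self.exons)
        roles = [ExonRole.INTERNAL] * n
        if n == 1:
            roles = [ExonRole.FIRST]
        else:
            roles[0] = ExonRole.FIRST
            roles[-1] = ExonRole.LAST
        exons = [replace(e, role=r) for e, r in zip(self.exons, roles)]
        return Transcript(self.id, exons, self.source)


def junctions_of(transcript: Transcript) -> list:
    """The n-1 introns between consecutive exons of a transcript.

    Single-exon transcripts yield an empty list.
    """
    blocks = transcript.blocks()
    return [
        SpliceJunction(
            chrom=transcript.chrom,
            donor_end=left_end,
            acceptor_start=right_start,
            strand=transcript.strand,
        )
        for (_, left_end), (right_start, _) in zip(blocks, blocks[1:])
    ]


def order_exons_for_strand(
    exons: Sequence[Exon], strand: str
) -> list:
    """Sort exons into transcript (5'->3') orientation for the strand."""
    return sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
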