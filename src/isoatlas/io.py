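"""Readers and writers for GTF, FASTA, SAM text and BED12.

Readers transparently accept gzip-compressed input (by ``.gz`` suffix).
GTF coordinates are converted between the on-disk 1-based inclusive
convention and the internal 0-based half-open one at the boundary; the
round trip is exact.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    MIN_INTRON_LENGTH,
    Exon,
    GenomicInterval,
    Transcript,
    order_exons_for_strand,
)

log = logging.getLogger(__name__)


class GtfParseError(ValueError):
    pass


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path) -> list:
    """Parse exon features of a GTF into Transcripts.

    Exons are grouped by ``transcript_id`` and ordered 5'->3' in transcript
    orientation (reverse genomic order on the minus strand).
    """
    exons_by_tx: dict = {}
    source_by_tx: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9 or not (
                fields[3].isdigit() and fields[4].isdigit()
            ):
                raise GtfParseError(f"{path}: malformed GTF at line {lineno}")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfParseError(
                    f"{path}: malformed GTF at line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != "exon":
                continue
            tx_ids = feat.attributes.get("transcript_id")
            if not tx_ids:
                raise GtfParseError(
                    f"{path}: exon without transcript_id at line {lineno}"
                )
            interval = GenomicInterval(
                chrom=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
            )
            exon = Exon(interval=interval)
            for tx_id in tx_ids:
                exons_by_tx.setdefault(tx_id, []).append(exon)
                source_by_tx.setdefault(tx_id, feat.source)

    transcripts = []
    for tx_id, exons in exons_by_tx.items():
        strand = exons[0].strand
        ordered = order_exons_for_strand(exons, strand)
        transcripts.append(
            Transcript(id=tx_id, exons=ordered, source=source_by_tx[tx_id]).with_roles()
        )
    return transcripts


def write_gtf(transcripts: Iterable[Transcript], path, gene_id: str = "locus") -> None:
    """Write exon features, one block per transcript, genomic order."""
    with open(path, "wt") as fh:
        for tx in transcripts:
            source = tx.source or "isoatlas"
            for start, end in tx.blocks():
                attrs = f'gene_id "{gene_id}"; transcript_id "{tx.id}";'
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Contig name -> uppercase sequence string."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# SAM


@dataclass(frozen=True)
class ReadRecord:
    """A spliced alignment reduced to its reference-aligned blocks."""

    name: str
    chrom: str
    strand: str
    blocks: tuple  # ((start, end), ...) forward-genome order
    sample: str = ""


@dataclass
class SamReadStats:
    parsed: int = 0
    skipped_unmapped: int = 0
    errors: int = 0


# CIGAR op codes that consume the reference within an aligned block.
_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_INTRON_OP = 3  # N


def blocks_from_cigar(
    reference_start: int, cigartuples, min_intron: int = MIN_INTRON_LENGTH
) -> tuple:
    """Aligned (start, end) blocks; only N gaps >= min_intron split blocks.

    Deletions (D) and sub-threshold N gaps merge into the surrounding block:
    only a credible intron denotes splicing.
    """
    blocks = []
    pos = reference_start
    block_start = None
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _INTRON_OP:
            if length >= min_intron:
                if block_start is not None:
                    blocks.append((block_start, pos))
                    block_start = None
                pos += length
            else:
                # micro-deletion mis-encoded as N: keep the block open
                if block_start is None:
                    block_start = pos
                pos += length
        # I, S, H, P do not consume the reference
    if block_start is not None:
        blocks.append((block_start, pos))
    return tuple(blocks)


def read_spliced_sam(
    path,
    sample: str = "",
    min_intron: int = MIN_INTRON_LENGTH,
    stats: SamReadStats | None = None,
) -> Iterator[ReadRecord]:
    """Yield one ReadRecord per mapped alignment in a SAM file.

    Records with unusable CIGARs are counted and logged, never fatal.
    """
    if stats is None:
        stats = SamReadStats()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                stats.skipped_unmapped += 1
                continue
            try:
                blocks = blocks_from_cigar(
                    aln.reference_start, aln.cigartuples, min_intron
                )
            except Exception as exc:  # pragma: no cover - defensive
                stats.errors += 1
                log.warning("bad CIGAR for read %s: %s", aln.query_name, exc)
                continue
            if not blocks:
                stats.errors += 1
                continue
            stats.parsed += 1
            yield ReadRecord(
                name=aln.query_name,
                chrom=aln.reference_name,
                strand="-" if aln.is_reverse else "+",
                blocks=blocks,
                sample=sample,
            )


def write_sam(records: Iterable, path, contig_lengths: dict) -> None:
    """Write ReadRecord-like objects (name/chrom/strand/blocks) as SAM text."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": length} for name, length in contig_lengths.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = rec.name
            aln.reference_name = rec.chrom
            aln.reference_start = rec.blocks[0][0]
            aln.flag = 16 if rec.strand == "-" else 0
            aln.mapping_quality = 60
            cigar = []
            prev_end = None
            for start, end in rec.blocks:
                if prev_end is not None:
                    cigar.append((3, start - prev_end))  # N
                cigar.append((0, end - start))  # M
                prev_end = end
            aln.cigartuples = cigar
            # sequence-less alignment records (SEQ "*"): the pipeline only
            # consumes coordinates, and files stay small
            out.write(aln)


# ---------------------------------------------------------------------------
# BED


def write_bed12(chains: Iterable, path, name_of=lambda c: c.id, score_of=lambda c: 0):
    """Write objects exposing chrom/strand and blocks() as BED12 lines."""
    with open(path, "wt") as fh:
        for chain in chains:
            blocks = list(chain.blocks()) if callable(getattr(chain, "blocks", None)) else list(chain.blocks)
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, _ in blocks)
            fh.write(
                "\t".join(
                    [
                        chain.chrom,
                        str(start),
                        str(end),
                        str(name_of(chain)),
                        str(score_of(chain)),
                        chain.strand,
                        str(start),
                        str(end),
                        "0,0,0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
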