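"""Long-read amplicon isoform calling.

Full-length reads are assigned to primer pairs by their alignment ends,
their junctions snapped onto the atlas to absorb alignment jitter,
identical splice chains collapsed into isoforms, and each isoform tiered
by how well the atlas supports its internal exon ends:

  tier 1 — every internal exon end in the curated set;
  tier 2 — otherwise, every end at least in the unfiltered observed set;
  tier 3 — one or more ends unsupported anywhere.

Amplicon-terminal block ends are primer-defined, not splice-defined, and
are therefore exempt from tier judgement.  All orderings and tie-breaks
are deterministic so that reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .atlas import CuratedAtlas
from .model import GenomicInterval

log = logging.getLogger(__name__)

DEFAULT_END_TOL = 20
DEFAULT_SNAP_TOL = 10
DEFAULT_MIN_READS = 2


@dataclass(frozen=True)
class Amplicon:
    """A primer pair anchoring full-length reads from one first exon."""

    id: str
    forward_primer: GenomicInterval
    reverse_primer: GenomicInterval
    first_exon_label: str = ""

    def __post_init__(self) -> None:
        if self.forward_primer.chrom != self.reverse_primer.chrom:
            raise ValueError(f"amplicon {self.id}: primers on different chroms")
        if self.forward_primer.overlaps(self.reverse_primer):
            raise ValueError(f"amplicon {self.id}: primers overlap")

    @property
    def chrom(self) -> str:
        return self.forward_primer.chrom

    @property
    def strand(self) -> str:
        return self.forward_primer.strand

    def genomic_anchors(self):
        """(left, right) primer intervals in forward-genome orientation."""
        if self.strand == "+":
            return self.forward_primer, self.reverse_primer
        return self.reverse_primer, self.forward_primer


@dataclass
class IsoformChain:
    """A collapsed splice chain with per-sample support."""

    id: str
    amplicon: str
    chrom: str
    strand: str
    block_list: list  # (start, end) forward-genome order
    junctions: list  # junction keys, forward-genome order
    tier: int | None = None
    counts: dict = field(default_factory=dict)  # sample -> reads
    frequency: dict = field(default_factory=dict)  # sample -> fraction

    def blocks(self) -> list:
        return list(self.block_list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def chain_key(self) -> tuple:
        return tuple((d, a) for (_, d, a, _) in self.junctions)


def _distance_to_interval(pos: int, interval: GenomicInterval) -> int:
    if interval.start <= pos <= interval.end:
        return 0
    return min(abs(pos - interval.start), abs(pos - interval.end))


def assign_full_length(read, amplicons, end_tol: int = DEFAULT_END_TOL):
    """Amplicon id for a full-length read, or None when truncated.

    A read is full-length for an amplicon when its outer alignment start
    falls within end_tol of the left primer and its outer end within
    end_tol of the right primer (strand-aware).  Multi-amplicon matches go
    to the smallest combined end distance; exact ties break on amplicon id.
    """
    if end_tol < 0:
        raise ValueError("end_tol must be non-negative")
    read_start = read.blocks[0][0]
    read_end = read.blocks[-1][1]
    candidates = []
    for amp in sorted(amplicons, key=lambda a: a.id):
        if amp.chrom != read.chrom:
            continue
        left, right = amp.genomic_anchors()
        d_start = _distance_to_interval(read_start, left)
        d_end = _distance_to_interval(read_end, right)
        if d_start <= end_tol and d_end <= end_tol:
            candidates.append((d_start + d_end, amp.id))
    if not candidates:
        return None
    candidates.sort()
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        log.debug(
            "read %s matches multiple amplicons equally; taking %s",
            getattr(read, "name", "?"),
            candidates[0][1],
        )
    return candidates[0][1]


def _snap_junction(key, atlas_keys_by_chrom_strand, snap_tol: int):
    """Nearest atlas junction with both ends within snap_tol, else original."""
    chrom, donor, acceptor, strand = key
    best = None
    for cand_d, cand_a in atlas_keys_by_chrom_strand.get((chrom, strand), ()):
        dd = abs(cand_d - donor)
        da = abs(cand_a - acceptor)
        if dd <= snap_tol and da <= snap_tol:
            score = (dd + da, cand_d, cand_a)
            if best is None or score < best:
                best = score
    if best is None:
        return key
    return (chrom, best[1], best[2], strand)


def snap_and_collapse(
    reads,
    atlas: CuratedAtlas,
    amplicon: Amplicon,
    snap_tol: int = DEFAULT_SNAP_TOL,
    min_reads: int = DEFAULT_MIN_READS,
) -> list:
    """Snap read junctions onto the atlas and collapse identical chains.

    Reads whose snapped chains coincide merge into one IsoformChain with
    summed per-sample counts; chains supported by fewer than ``min_reads``
    total reads are discarded.  Outer block ends are primer-defined (the
    amplicon anchors), absorbing residual end wobble.  The result is
    sorted by total count descending, then lexicographic chain, so it is
    independent of input read order.
    """
    if snap_tol < 0:
        raise ValueError("snap_tol must be non-negative")
    by_cs: dict = {}
    for j in atlas.unfiltered_junctions:
        by_cs.setdefault((j.chrom, j.strand), []).append((j.donor_end, j.acceptor_start))
    for v in by_cs.values():
        v.sort()

    grouped: dict = {}
    for read in reads:
        snapped = []
        ok = True
        prev_acceptor = read.blocks[0][0]
        for (s0, e0), (s1, e1) in zip(read.blocks, read.blocks[1:]):
            key = _snap_junction((read.chrom, e0, s1, read.strand), by_cs, snap_tol)
            if key[1] <= prev_acceptor:  # snapping produced an inconsistent chain
                ok = False
                break
            prev_acceptor = key[2]
            snapped.append(key)
        if not ok:
            log.debug("read %s dropped: inconsistent snapped chain", read.name)
            continue
        chain = tuple(snapped)
        counts = grouped.setdefault(chain, {})
        sample = read.sample or "sample"
        counts[sample] = counts.get(sample, 0) + 1

    left, right = amplicon.genomic_anchors()
    chains = []
    for chain, counts in grouped.items():
        total = sum(counts.values())
        if total < min_reads:
            continue
        if chain and not (left.start < chain[0][1] and chain[-1][2] < right.end):
            log.debug("chain %s extends outside amplicon bounds; dropped", chain)
            continue
        blocks = []
        start = left.start
        for (_, donor, acceptor, _) in chain:
            blocks.append((start, donor))
            start = acceptor
        blocks.append((start, right.end))
        chains.append(
            IsoformChain(
                id="",
                amplicon=amplicon.id,
                chrom=amplicon.chrom,
                strand=amplicon.strand,
                block_list=blocks,
                junctions=list(chain),
                counts=dict(sorted(counts.items())),
            )
        )
    chains.sort(key=lambda c: (-c.total_count, c.chain_key()))
    for i, chain in enumerate(chains, start=1):
        chain.id = f"{amplicon.id}.iso{i}"
    return chains


def classify_tier(chain: IsoformChain, atlas: CuratedAtlas) -> int:
    """Support tier (1/2/3) of a chain's internal exon ends vs the atlas."""
    internal_ends = []
    for (chrom, donor, acceptor, strand) in chain.junctions:
        internal_ends.append((chrom, donor, "end", strand))
        internal_ends.append((chrom, acceptor, "start", strand))
    if all(e in atlas.exon_ends for e in internal_ends):
        return 1
    supported = atlas.exon_ends | atlas.unfiltered_exon_ends
    if all(e in supported for e in internal_ends):
        return 2
    return 3


def classify_tiers(chains, atlas: CuratedAtlas) -> None:
    for chain in chains:
        chain.tier = classify_tier(chain, atlas)


def top_isoforms(chains, fraction: float = 0.8) -> list:
    """Shortest count-sorted prefix covering >= fraction of the reads.

    Sorting is total count descending with lexicographic chain tie-break;
    an amplicon with zero reads yields an empty selection.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ordered = sorted(chains, key=lambda c: (-c.total_count, c.chain_key()))
    total = sum(c.total_count for c in ordered)
    if total == 0:
        return []
    selected = []
    cumulative = 0
    for chain in ordered:
        selected.append(chain)
        cumulative += chain.total_count
        if cumulative / total >= fraction:
            break
    return selected


def isoform_frequencies(chains) -> pd.DataFrame:
    """Within-amplicon relative expression per sample; also stored on chains.

    frequency(i, s) = count(i, s) / total counts of the amplicon in s; NaN
    where the sample contributed no reads.
    """
    samples = sorted({s for c in chains for s in c.counts})
    totals = {s: sum(c.counts.get(s, 0) for c in chains) for s in samples}
    rows = {}
    for chain in chains:
        freqs = {}
        for s in samples:
            if totals[s] > 0:
                freqs[s] = chain.counts.get(s, 0) / totals[s]
            else:
                freqs[s] = float("nan")
        chain.frequency = freqs
        rows[chain.id] = freqs
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


# ---------------------------------------------------------------------------
# Primer table interchange


def read_primer_table(path) -> list:
    """TSV: amplicon_id chrom strand fwd_start fwd_end rev_start rev_end [label]."""
    df = pd.read_csv(path, sep="\t")
    amplicons = []
    for row in df.itertuples():
        amplicons.append(
            Amplicon(
                id=str(row.amplicon_id),
                forward_primer=GenomicInterval(
                    row.chrom, int(row.fwd_start), int(row.fwd_end), row.strand
                ),
                reverse_primer=GenomicInterval(
                    row.chrom, int(row.rev_start), int(row.rev_end), row.strand
                ),
                first_exon_label=str(getattr(row, "first_exon_label", "")),
            )
        )
    return amplicons


def write_primer_table(amplicons, path) -> None:
    rows = [
        {
            "amplicon_id": a.id,
            "chrom": a.chrom,
            "strand": a.strand,
            "fwd_start": a.forward_primer.start,
            "fwd_end": a.forward_primer.end,
            "rev_start": a.reverse_primer.start,
            "rev_end": a.reverse_primer.end,
            "first_exon_label": a.first_exon_label,
        }
        for a in amplicons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def isoform_table(chains) -> pd.DataFrame:
    rows = []
    for c in chains:
        rows.append(
            {
                "isoform": c.id,
                "amplicon": c.amplicon,
                "chrom": c.chrom,
                "strand": c.strand,
                "tier": c.tier,
                "chain": ";".join(f"{d}-{a}" for d, a in c.chain_key()),
                "total_reads": c.total_count,
                **{f"count_{s}": n for s, n in sorted(c.counts.items())},
            }
        )
    return pd.DataFrame(rows)
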