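"""Curated junction atlas construction.

Short-read spliced alignments are reduced to a junction x sample count
matrix, expression-filtered (cpm-in-n-samples rule), merged with one or
more reference annotations, and flagged with provenance.  The curated
atlas is the yardstick against which long-read isoforms are later tiered,
so it deliberately keeps two layers: the filtered/curated junction set and
the unfiltered observed superset.

The study's manual-curation step is replaced here by the deterministic
filter rule plus optional allow/deny lists; reproducibility requires an
explicit procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    Exon,
    ExonRole,
    GenomicInterval,
    Provenance,
    SpliceJunction,
    Transcript,
    junctions_of,
)

log = logging.getLogger(__name__)


@dataclass
class JunctionCountMatrix:
    """Junction x sample read counts plus per-sample library sizes."""

    junctions: list
    samples: list
    counts: np.ndarray  # shape (n_junctions, n_samples), non-negative ints
    library_sizes: np.ndarray  # shape (n_samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.junctions), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.junctions)} junctions x {len(self.samples)} samples"
            )
        if self.library_sizes.shape != (len(self.samples),):
            raise ValueError("library_sizes length must equal sample count")
        if (self.counts < 0).any():
            raise ValueError("negative junction counts")

    @property
    def keys(self) -> list:
        return [j.key() for j in self.junctions]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            self.keys, names=["chrom", "donor_end", "acceptor_start", "strand"]
        )
        return pd.DataFrame(self.counts, index=idx, columns=self.samples)

    def subset(self, mask: np.ndarray) -> "JunctionCountMatrix":
        mask = np.asarray(mask, dtype=bool)
        return JunctionCountMatrix(
            junctions=[j for j, m in zip(self.junctions, mask) if m],
            samples=list(self.samples),
            counts=self.counts[mask],
            library_sizes=self.library_sizes.copy(),
        )


def count_junctions(
    reads: Iterable,
    region: GenomicInterval | None = None,
    samples: Sequence[str] | None = None,
    library_sizes: dict | None = None,
) -> JunctionCountMatrix:
    """Tally N-gap junctions per sample from exon-chain read records.

    Every gap between consecutive aligned blocks of a read increments the
    corresponding junction/sample cell.  Library sizes default to the total
    junction-read count per sample (the locus-level cpm base); pass genome-
    wide totals via ``library_sizes`` when available.
    """
    sample_order: list = list(samples) if samples is not None else []
    seen_samples = set(sample_order)
    tallies: dict = {}

    for read in reads:
        sample = read.sample or "sample"
        if sample not in seen_samples:
            seen_samples.add(sample)
            sample_order.append(sample)
        for (s0, e0), (s1, e1) in zip(read.blocks, read.blocks[1:]):
            if region is not None and not (
                region.chrom == read.chrom
                and region.start <= e0
                and s1 <= region.end
            ):
                continue
            key = (read.chrom, e0, s1, read.strand)
            tallies.setdefault(key, {}).setdefault(sample, 0)
            tallies[key][sample] += 1

    keys = sorted(tallies)
    counts = np.zeros((len(keys), len(sample_order)), dtype=np.int64)
    col = {s: i for i, s in enumerate(sample_order)}
    for i, key in enumerate(keys):
        for sample, n in tallies[key].items():
            counts[i, col[sample]] = n

    if library_sizes is not None:
        libs = np.array([library_sizes[s] for s in sample_order], dtype=np.int64)
    else:
        libs = counts.sum(axis=0)

    junctions = [
        SpliceJunction(chrom=c, donor_end=d, acceptor_start=a, strand=st)
        for (c, d, a, st) in keys
    ]
    return JunctionCountMatrix(junctions, sample_order, counts, libs)


def cpm(matrix: JunctionCountMatrix) -> np.ndarray:
    """Counts per million: count / library_size * 1e6, per cell."""
    libs = matrix.library_sizes.astype(float)
    zero = np.flatnonzero(libs == 0)
    if zero.size:
        bad = ", ".join(matrix.samples[i] for i in zero)
        raise ValueError(f"zero library size for sample(s): {bad}")
    return matrix.counts / libs[np.newaxis, :] * 1e6


def filter_junctions(
    matrix: JunctionCountMatrix,
    min_cpm: float = 2.0,
    min_samples: int = 2,
    keep_annotated: bool = False,
    annotated_keys: set | None = None,
) -> JunctionCountMatrix:
    """Keep junctions with cpm >= min_cpm in >= min_samples samples.

    With ``keep_annotated``, junctions whose keys appear in
    ``annotated_keys`` are exempt from removal regardless of expression.
    """
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    if len(matrix.junctions) == 0:
        return matrix
    if min_cpm == 0:  # every sample trivially passes; no cpm base needed
        passing = np.full(len(matrix.junctions), len(matrix.samples) >= min_samples)
    else:
        expr = cpm(matrix)
        passing = (expr >= min_cpm).sum(axis=1) >= min_samples
    if keep_annotated and annotated_keys:
        exempt = np.array([j.key() in annotated_keys for j in matrix.junctions])
        passing = passing | exempt
    return matrix.subset(passing)


@dataclass
class AnnotationSource:
    """Junctions and exon boundaries contributed by one reference annotation."""

    name: str  # e.g. "GENCODE", "REFSEQ"
    junction_keys: set
    exon_ends: set  # (chrom, offset, side, strand)
    first_exons: list = field(default_factory=list)
    last_exons: list = field(default_factory=list)

    @property
    def provenance(self) -> Provenance:
        return Provenance(self.name)


def annotation_source_from_transcripts(
    name: str, transcripts: Sequence[Transcript]
) -> AnnotationSource:
    """Collapse an annotation's transcripts to junction/exon-end sets."""
    junction_keys = set()
    exon_ends = set()
    first_exons: list = []
    last_exons: list = []
    seen_terminal = set()
    for tx in transcripts:
        tx = tx.with_roles()
        for j in junctions_of(tx):
            junction_keys.add(j.key())
        for exon in tx.exons:
            exon_ends.add((exon.chrom, exon.start, "start", exon.strand))
            exon_ends.add((exon.chrom, exon.end, "end", exon.strand))
            if exon.role in (ExonRole.FIRST, ExonRole.LAST):
                k = (exon.chrom, exon.start, exon.end, exon.strand, exon.role)
                if k not in seen_terminal:
                    seen_terminal.add(k)
                    (first_exons if exon.role is ExonRole.FIRST else last_exons).append(
                        exon
                    )
    return AnnotationSource(name, junction_keys, exon_ends, first_exons, last_exons)


@dataclass
class CuratedAtlas:
    """The merged, filtered junction/exon-end sets plus the unfiltered superset."""

    junctions: list  # curated SpliceJunctions carrying provenance
    unfiltered_junctions: list  # observed (pre-filter) union annotation junctions
    exon_ends: set  # curated exon-end keys
    unfiltered_exon_ends: set  # ends supported by the unfiltered superset
    first_exons: list = field(default_factory=list)
    last_exons: list = field(default_factory=list)

    @property
    def junction_keys(self) -> set:
        return {j.key() for j in self.junctions}

    @property
    def unfiltered_keys(self) -> set:
        return {j.key() for j in self.unfiltered_junctions}

    def provenance_of(self, key: tuple) -> frozenset:
        for j in self.junctions:
            if j.key() == key:
                return j.provenance
        return frozenset()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": j.chrom,
                "donor_end": j.donor_end,
                "acceptor_start": j.acceptor_start,
                "strand": j.strand,
                "provenance": ",".join(sorted(p.value for p in j.provenance)),
            }
            for j in self.junctions
        ]
        return pd.DataFrame(rows)


def build_atlas(
    observed: JunctionCountMatrix,
    annotations: Sequence[AnnotationSource],
    min_cpm: float = 2.0,
    min_samples: int = 2,
    keep_annotated: bool = True,
    allow_keys: set | None = None,
    deny_keys: set | None = None,
) -> CuratedAtlas:
    """Merge observed junctions with reference annotations into a curated atlas.

    Provenance flags: each annotation that contains the junction contributes
    its flag; observed junctions passing the expression filter get OBSERVED;
    junctions in no annotation get NOVEL.  ``allow_keys``/``deny_keys`` are
    the deterministic stand-in for manual curation: allow forces retention,
    deny forces removal (deny wins over everything except nothing).
    """
    if not annotations:
        raise ValueError("at least one annotation source is required")
    allow_keys = allow_keys or set()
    deny_keys = deny_keys or set()

    annotated_keys = set()
    for ann in annotations:
        annotated_keys |= ann.junction_keys

    passing = filter_junctions(
        observed,
        min_cpm=min_cpm,
        min_samples=min_samples,
        keep_annotated=keep_annotated,
        annotated_keys=annotated_keys,
    )
    passing_keys = {j.key() for j in passing.junctions} | (
        allow_keys & {j.key() for j in observed.junctions}
    )
    passing_keys -= deny_keys

    # strand-conflict check: identical coordinates on both strands
    coords = {}
    for j in observed.junctions:
        coords.setdefault((j.chrom, j.donor_end, j.acceptor_start), set()).add(j.strand)
    for (chrom, d, a), strands in coords.items():
        if len(strands) > 1:
            log.warning(
                "junction %s:%d-%d observed on both strands; keys kept distinct",
                chrom,
                d,
                a,
            )

    curated: dict = {}
    for j in observed.junctions:
        key = j.key()
        if key not in passing_keys:
            continue
        flags = {Provenance.OBSERVED}
        for ann in annotations:
            if key in ann.junction_keys:
                flags.add(ann.provenance)
        if not (flags - {Provenance.OBSERVED}):
            flags.add(Provenance.NOVEL)
        curated[key] = j.with_provenance(flags)

    observed_keys = {j.key() for j in observed.junctions}
    for ann in annotations:
        for key in ann.junction_keys:
            if key in deny_keys:
                continue
            if key in curated:
                continue
            flags = {
                a.provenance for a in annotations if key in a.junction_keys
            }
            if key in observed_keys and key in passing_keys:
                flags.add(Provenance.OBSERVED)
            curated[key] = SpliceJunction(*key).with_provenance(flags)

    unfiltered: dict = {j.key(): j for j in observed.junctions}
    for key in annotated_keys:
        unfiltered.setdefault(key, SpliceJunction(*key))

    exon_ends = set()
    for j in curated.values():
        exon_ends.update(j.ends())
    for ann in annotations:
        exon_ends |= ann.exon_ends

    unfiltered_ends = set(exon_ends)
    for j in unfiltered.values():
        unfiltered_ends.update(j.ends())

    first_exons: list = []
    last_exons: list = []
    seen = set()
    for ann in annotations:
        for exon in ann.first_exons + ann.last_exons:
            k = (exon.chrom, exon.start, exon.end, exon.strand, exon.role)
            if k in seen:
                continue
            seen.add(k)
            (first_exons if exon.role is ExonRole.FIRST else last_exons).append(exon)

    return CuratedAtlas(
        junctions=[curated[k] for k in sorted(curated)],
        unfiltered_junctions=[unfiltered[k] for k in sorted(unfiltered)],
        exon_ends=exon_ends,
        unfiltered_exon_ends=unfiltered_ends,
        first_exons=first_exons,
        last_exons=last_exons,
    )


# ---------------------------------------------------------------------------
# TSV interchange


def write_junction_counts(matrix: JunctionCountMatrix, path) -> None:
    df = matrix.to_frame().reset_index()
    df.insert(0, "library_size_row", "")
    df = df.drop(columns=["library_size_row"])
    df.to_csv(path, sep="\t", index=False)
    # library sizes travel in a sidecar header comment? keep simple: columns
    with open(path, "r+t") as fh:
        body = fh.read()
        fh.seek(0)
        libs = "\t".join(str(x) for x in matrix.library_sizes)
        fh.write(f"# library_sizes\t{libs}\n" + body)


def read_junction_counts(path) -> JunctionCountMatrix:
    libs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# library_sizes"):
            libs = np.array(
                [int(x) for x in first.rstrip("\n").split("\t")[1:]], dtype=np.int64
            )
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    key_cols = ["chrom", "donor_end", "acceptor_start", "strand"]
    samples = [c for c in df.columns if c not in key_cols]
    junctions = [
        SpliceJunction(r.chrom, int(r.donor_end), int(r.acceptor_start), r.strand)
        for r in df.itertuples()
    ]
    counts = df[samples].to_numpy(dtype=np.int64)
    if libs is None:
        libs = counts.sum(axis=0)
    return JunctionCountMatrix(junctions, samples, counts, libs)
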