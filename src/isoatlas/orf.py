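"""ORF prediction, HGVS p. alteration naming and epitope detectability.

An isoform's spliced sequence is scanned for an open reading frame, the
translation is compared with the reference protein by longest common
prefix/suffix decomposition, and the difference is named in HGVS protein
notation (del / ins / delins / fs).  Frameshift lengths follow the
convention in which ``fs*N`` counts the N novel residues appended after
the last reference residue (so Gly457Valfs*10 on a 595-residue reference
yields 456 + 10 = 466 aa); strict HGVS counting (Ter at new-frame
position N, i.e. N-1 novel residues) is available behind ``strict=True``.

Prefix/suffix decomposition prefers the maximal prefix when the two
overlap; 3'-most HGVS shifting is deliberately not applied.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq1, seq3

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_MIN_CODONS = 25


# ---------------------------------------------------------------------------
# Sequence plumbing


def spliced_sequence(genome, chain) -> str:
    """Concatenate a chain's exon blocks in transcript orientation.

    ``genome`` maps contig -> sequence.  Minus-strand chains are
    reverse-complemented so the result always reads 5'->3'.
    """
    if chain.chrom not in genome:
        raise KeyError(f"contig {chain.chrom!r} not in genome")
    contig = genome[chain.chrom]
    parts = []
    for start, end in chain.blocks():
        if start < 0 or end > len(contig):
            raise ValueError(
                f"block [{start},{end}) outside contig {chain.chrom} "
                f"(length {len(contig)})"
            )
        parts.append(contig[start:end])
    seq = "".join(parts)
    if chain.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(cds: str) -> str:
    """Peptide of a CDS, trailing stop stripped; N-codons become X."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    pep = str(Seq(cds).translate())
    return pep[:-1] if pep.endswith("*") else pep


# ---------------------------------------------------------------------------
# ORF finding


@dataclass(frozen=True)
class Orf:
    """Transcript-relative CDS coordinates (end one past the stop codon)."""

    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3:
            raise ValueError("ORF length not divisible by 3")
        if len(self.peptide) != (self.end - self.start) // 3 - 1:
            raise ValueError("peptide length inconsistent with ORF span")


def _frame_breaks(seq: str, frame: int):
    """Positions (codon starts) in a frame that stop the scan: true stop
    codons, and N-containing codons which invalidate the reading."""
    stops, breaks = [], []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            stops.append(i)
            breaks.append(i)
        elif "N" in codon:
            breaks.append(i)
    return stops, breaks


def find_orf(
    seq: str,
    policy: str = "longest",
    anchor_offset: int | None = None,
    min_codons: int = DEFAULT_MIN_CODONS,
):
    """The ORF of a transcript sequence under the given policy, or None.

    ``longest``: maximal ATG->stop ORF over all three frames, leftmost on
    ties.  ``anchored``: the ORF starting at ``anchor_offset`` (a known
    canonical start) when that ATG and its reading are intact, otherwise
    fall back to longest.  ORFs shorter than ``min_codons`` peptide
    residues are rejected.
    """
    seq = seq.upper()
    if policy not in ("longest", "anchored"):
        raise ValueError(f"unknown ORF policy {policy!r}")
    if policy == "anchored":
        if anchor_offset is None:
            raise ValueError("anchored policy requires anchor_offset")
        orf = _orf_at(seq, anchor_offset, min_codons)
        if orf is not None:
            return orf
        # canonical start destroyed: fall back
    best = None
    per_frame = {f: _frame_breaks(seq, f) for f in range(3)}
    for m in re.finditer("ATG", seq):
        i = m.start()
        frame = i % 3
        stops, breaks = per_frame[frame]
        k = bisect_left(breaks, i)
        if k == len(breaks):
            continue  # runs off the end without a stop
        brk = breaks[k]
        if brk not in set(stops):
            continue  # broken by an N codon before any stop
        end = brk + 3
        n_pep = (end - i) // 3 - 1
        if n_pep < min_codons:
            continue
        if best is None or n_pep > len(best.peptide):
            best = Orf(i, end, translate_cds(seq[i:end]))
    return best


def _orf_at(seq: str, start: int, min_codons: int):
    if seq[start : start + 3] != "ATG":
        return None
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            end = i + 3
            if (end - start) // 3 - 1 < min_codons:
                return None
            return Orf(start, end, translate_cds(seq[start:end]))
        if "N" in codon:
            return None
    return None


# ---------------------------------------------------------------------------
# HGVS protein alterations


@dataclass
class ProteinAlteration:
    """A typed protein-level difference against the reference.

    Residue positions are 1-based on the reference protein.  For
    insertions, ref_start/ref_end are the flanking residues (end =
    start + 1).  For frameshifts, ``inserted`` holds the novel tail and
    ``fs_new_residues`` its length (the novel-residue fs*N count).
    """

    kind: str  # identity | deletion | insertion | delins | frameshift
    ref_start: int = 0
    ref_end: int = 0
    inserted: str = ""  # 1-letter residues
    fs_new_residues: int = 0
    ref_first: str = ""  # reference residue at ref_start
    ref_last: str = ""  # reference residue at ref_end

    @property
    def hgvs(self) -> str:
        return render_hgvs(self)


def render_hgvs(alt: ProteinAlteration) -> str:
    if alt.kind == "identity":
        return "="
    a3 = seq3(alt.ref_first) if alt.ref_first else ""
    b3 = seq3(alt.ref_last) if alt.ref_last else ""
    if alt.kind == "deletion":
        if alt.ref_start == alt.ref_end:
            return f"{a3}{alt.ref_start}del"
        return f"{a3}{alt.ref_start}_{b3}{alt.ref_end}del"
    if alt.kind == "insertion":
        return f"{a3}{alt.ref_start}_{b3}{alt.ref_end}ins{seq3(alt.inserted)}"
    if alt.kind == "delins":
        if alt.ref_start == alt.ref_end:
            return f"{a3}{alt.ref_start}delins{seq3(alt.inserted)}"
        return f"{a3}{alt.ref_start}_{b3}{alt.ref_end}delins{seq3(alt.inserted)}"
    if alt.kind == "frameshift":
        new3 = seq3(alt.inserted[0]) if alt.inserted else "Ter"
        return f"{a3}{alt.ref_start}{new3}fs*{alt.fs_new_residues}"
    raise ValueError(f"unknown alteration kind {alt.kind!r}")


_AA3 = "(?:[A-Z][a-z]{2})"
_HGVS_PATTERNS = [
    (
        "frameshift",
        re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)(?P<new>{_AA3})fs\*(?P<n>\d+)$"),
    ),
    (
        "deletion_range",
        re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)_(?P<b>{_AA3})(?P<e>\d+)del$"),
    ),
    ("deletion_single", re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)del$")),
    (
        "delins_range",
        re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)_(?P<b>{_AA3})(?P<e>\d+)delins(?P<ins>{_AA3}+)$"),
    ),
    ("delins_single", re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)delins(?P<ins>{_AA3}+)$")),
    (
        "insertion",
        re.compile(rf"^(?P<a>{_AA3})(?P<s>\d+)_(?P<b>{_AA3})(?P<e>\d+)ins(?P<ins>{_AA3}+)$"),
    ),
]


def _aa1(three_letter_run: str) -> str:
    return seq1(three_letter_run)


def parse_hgvs_p(text: str) -> ProteinAlteration:
    """Parse an HGVS p. short description (del/ins/delins/fs) into fields."""
    text = text.strip()
    if text.startswith("p."):
        text = text[2:]
    if text in ("=", "(=)"):
        return ProteinAlteration(kind="identity")
    for name, pattern in _HGVS_PATTERNS:
        m = pattern.match(text)
        if not m:
            continue
        g = m.groupdict()
        start = int(g["s"])
        if name == "frameshift":
            return ProteinAlteration(
                kind="frameshift",
                ref_start=start,
                ref_end=start,
                inserted=_aa1(g["new"]),
                fs_new_residues=int(g["n"]),
                ref_first=_aa1(g["a"]),
                ref_last=_aa1(g["a"]),
            )
        if name == "deletion_single":
            return ProteinAlteration(
                kind="deletion",
                ref_start=start,
                ref_end=start,
                ref_first=_aa1(g["a"]),
                ref_last=_aa1(g["a"]),
            )
        if name == "deletion_range":
            return ProteinAlteration(
                kind="deletion",
                ref_start=start,
                ref_end=int(g["e"]),
                ref_first=_aa1(g["a"]),
                ref_last=_aa1(g["b"]),
            )
        if name == "insertion":
            end = int(g["e"])
            if end != start + 1:
                raise ValueError(f"insertion flanks must be adjacent: {text}")
            return ProteinAlteration(
                kind="insertion",
                ref_start=start,
                ref_end=end,
                inserted=_aa1(g["ins"]),
                ref_first=_aa1(g["a"]),
                ref_last=_aa1(g["b"]),
            )
        if name in ("delins_single", "delins_range"):
            return ProteinAlteration(
                kind="delins",
                ref_start=start,
                ref_end=int(g.get("e") or start),
                inserted=_aa1(g["ins"]),
                ref_first=_aa1(g["a"]),
                ref_last=_aa1(g.get("b") or g["a"]),
            )
    raise ValueError(f"unrecognised HGVS p. description: {text!r}")


def name_alteration(
    ref_peptide: str, alt_peptide: str, ref_nt: str = "", alt_nt: str = ""
) -> ProteinAlteration:
    """Describe alt vs ref peptide as a typed HGVS p. alteration.

    Longest-common-prefix/suffix decomposition isolates the differing
    middle.  ``ref_nt``/``alt_nt`` are the nucleotide sequences carrying
    the event (the spliced transcripts, or any pair of sequences whose
    length difference equals the event's): when their lengths differ by a
    non-multiple of three the reading frame shifts and the alteration is
    a frameshift anchored at the first changed residue.  Note that
    ATG->stop ORF sequences cannot carry this signal (any ORF is a
    multiple of three); pass transcript-level sequences.
    """
    if ref_peptide == alt_peptide:
        return ProteinAlteration(kind="identity")

    p = 0
    limit = min(len(ref_peptide), len(alt_peptide))
    while p < limit and ref_peptide[p] == alt_peptide[p]:
        p += 1

    if ref_nt and alt_nt and (len(ref_nt) - len(alt_nt)) % 3 != 0:
        tail = alt_peptide[p:]
        return ProteinAlteration(
            kind="frameshift",
            ref_start=p + 1,
            ref_end=p + 1,
            inserted=tail,
            fs_new_residues=len(tail),
            ref_first=ref_peptide[p] if p < len(ref_peptide) else "",
            ref_last=ref_peptide[p] if p < len(ref_peptide) else "",
        )

    s = 0
    while (
        s < limit - p
        and ref_peptide[len(ref_peptide) - 1 - s] == alt_peptide[len(alt_peptide) - 1 - s]
    ):
        s += 1

    ref_mid = ref_peptide[p : len(ref_peptide) - s]
    alt_mid = alt_peptide[p : len(alt_peptide) - s]

    if not alt_mid:  # deletion of ref_mid
        start, end = p + 1, len(ref_peptide) - s
        return ProteinAlteration(
            kind="deletion",
            ref_start=start,
            ref_end=end,
            ref_first=ref_peptide[start - 1],
            ref_last=ref_peptide[end - 1],
        )
    if not ref_mid:  # insertion between residues p and p+1
        return ProteinAlteration(
            kind="insertion",
            ref_start=p,
            ref_end=p + 1,
            inserted=alt_mid,
            ref_first=ref_peptide[p - 1],
            ref_last=ref_peptide[p],
        )
    start, end = p + 1, len(ref_peptide) - s
    return ProteinAlteration(
        kind="delins",
        ref_start=start,
        ref_end=end,
        inserted=alt_mid,
        ref_first=ref_peptide[start - 1],
        ref_last=ref_peptide[end - 1],
    )


def apply_alteration(ref_peptide: str, alt: ProteinAlteration) -> str:
    """Reconstruct the alternative peptide from the reference + alteration."""
    n = len(ref_peptide)
    if alt.kind == "identity":
        return ref_peptide
    if alt.kind != "insertion" and not (1 <= alt.ref_start <= alt.ref_end <= n):
        raise ValueError(f"alteration positions outside reference (length {n})")
    if alt.kind == "deletion":
        return ref_peptide[: alt.ref_start - 1] + ref_peptide[alt.ref_end :]
    if alt.kind == "insertion":
        if not (1 <= alt.ref_start < n):
            raise ValueError("insertion flank outside reference")
        return ref_peptide[: alt.ref_start] + alt.inserted + ref_peptide[alt.ref_start :]
    if alt.kind == "delins":
        return (
            ref_peptide[: alt.ref_start - 1] + alt.inserted + ref_peptide[alt.ref_end :]
        )
    if alt.kind == "frameshift":
        return ref_peptide[: alt.ref_start - 1] + alt.inserted
    raise ValueError(f"unknown alteration kind {alt.kind!r}")


def apply_alteration_length(
    ref_length: int, alteration: ProteinAlteration, strict: bool = False
) -> int:
    """Residue count of the altered protein, from the reference length alone.

    Frameshift counting defaults to length = (ref_start - 1) + fs*N
    (fs*N read as the number of novel residues); ``strict`` switches to
    standard HGVS semantics where Ter sits at new-frame position N, giving
    one residue fewer.
    """
    alt = alteration
    if alt.kind == "identity":
        return ref_length
    if not (1 <= alt.ref_start <= ref_length) or (
        alt.kind != "insertion" and alt.ref_end > ref_length
    ):
        raise ValueError(
            f"alteration {alt.hgvs} outside reference of length {ref_length}"
        )
    if alt.kind == "deletion":
        return ref_length - (alt.ref_end - alt.ref_start + 1)
    if alt.kind == "insertion":
        return ref_length + len(alt.inserted)
    if alt.kind == "delins":
        return ref_length - (alt.ref_end - alt.ref_start + 1) + len(alt.inserted)
    if alt.kind == "frameshift":
        new = alt.fs_new_residues - 1 if strict else alt.fs_new_residues
        return (alt.ref_start - 1) + new
    raise ValueError(f"unknown alteration kind {alt.kind!r}")


# ---------------------------------------------------------------------------
# Annotation matching and antibody epitopes


def match_isoform(alt_peptide: str, annotation_peptides: dict) -> list:
    """Transcript ids whose annotated peptide equals alt exactly; [] = novel."""
    return sorted(
        tx_id for tx_id, pep in annotation_peptides.items() if pep == alt_peptide
    )


@dataclass(frozen=True)
class Epitope:
    """An antibody's binding interval on the reference protein (1-based,
    inclusive residue positions)."""

    antibody: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid epitope interval [{self.start},{self.end}]")


def epitope_detectable(
    alteration: ProteinAlteration, epitope: Epitope, ref_length: int
) -> bool:
    """Whether every epitope residue survives unchanged in the isoform.

    Deletions and delins must not intersect the interval; a frameshift
    destroys everything from its anchor onward; an insertion strictly
    inside the interval disrupts it, while flanking insertions do not.
    """
    if epitope.end > ref_length:
        raise ValueError(
            f"epitope [{epitope.start},{epitope.end}] exceeds reference length"
        )
    alt = alteration
    if alt.kind == "identity":
        return True
    if alt.kind in ("deletion", "delins"):
        return not (alt.ref_start <= epitope.end and epitope.start <= alt.ref_end)
    if alt.kind == "insertion":
        # inserted between residues ref_start and ref_start+1
        strictly_inside = epitope.start <= alt.ref_start < epitope.end
        return not strictly_inside
    if alt.kind == "frameshift":
        return epitope.end < alt.ref_start
    raise ValueError(f"unknown alteration kind {alt.kind!r}")


def detectability_fraction(
    alterations, epitope: Epitope, ref_length: int
) -> float:
    """Fraction of isoforms the antibody can theoretically detect."""
    alterations = list(alterations)
    if not alterations:
        raise ValueError("empty isoform set")
    hits = sum(
        epitope_detectable(a, epitope, ref_length) for a in alterations
    )
    return hits / len(alterations)
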