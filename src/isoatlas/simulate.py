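"""Ground-truthed synthetic loci, junction counts and long reads.

The generator builds a multi-exon gene on a synthetic contig whose
canonical transcript carries a clean ATG->stop ORF, plus one alternative
isoform per requested splicing event (cassette skips, in-frame and
frame-shifting, alternative donors/acceptors, a novel first exon).  Every
splice site is a genuine GT..AG pair on the transcribed strand, so all
emitted artefacts survive the package's own readers and validators.

Short-read junction counts are drawn negative-binomially around
isoform-mixture expectations (dispersion 0 reduces to Poisson); long
reads are sampled multinomially from per-amplicon isoform frequencies
with Gaussian end wobble, optional 5'-truncation (amplicon degradation;
3' ends are anchored by the reverse primer) and junction jitter to
exercise snapping.  Everything is deterministic per seed via numpy's
PCG64 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import JunctionCountMatrix
from .io import ReadRecord
from .longread import Amplicon
from .model import Exon, GenomicInterval, SpliceJunction, Transcript, junctions_of

CHROM = "chrSyn"
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event relative to the canonical transcript.

    kind: skip | skip_fs | alt_donor | alt_acceptor | novel_first_exon.
    ``exons`` are 1-based canonical exon indices; ``shift`` moves the
    donor/acceptor in nt (positive = into the intron for donors, into the
    exon for acceptors).
    """

    kind: str
    exons: tuple = ()
    shift: int = 0

    @property
    def id(self) -> str:
        if self.kind in ("skip", "skip_fs"):
            tag = "-".join(str(e) for e in self.exons)
            return f"{'skipfs' if self.kind == 'skip_fs' else 'skip'}_ex{tag}"
        if self.kind == "alt_donor":
            return f"altdonor_ex{self.exons[0]}{self.shift:+d}"
        if self.kind == "alt_acceptor":
            return f"altacceptor_ex{self.exons[0]}{self.shift:+d}"
        return "novelfirst"


def default_events() -> list:
    """The six event classes the pipeline is designed around: an in-frame
    alternative donor insertion, single/large cassette deletions, a 1-aa
    alternative donor deletion, and a frame-shifting skip."""
    return [
        SpliceEvent("skip_fs", (7,)),
        SpliceEvent("alt_donor", (2,), 6),
        SpliceEvent("skip", (3,)),
        SpliceEvent("alt_donor", (3,), -3),
        SpliceEvent("skip", (2, 3, 4, 5)),
        SpliceEvent("skip", (4,)),
    ]


@dataclass
class SyntheticLocus:
    genome: dict  # contig -> sequence
    chrom: str
    strand: str
    exon_coords: list  # canonical (start, end) pairs, genomic order
    catalog: list  # Transcript objects, canonical first
    events: list  # SpliceEvent per non-canonical catalog entry (same order)
    isoform_weights: dict  # transcript id -> mixture weight (sums to 1)
    true_psi: dict  # event id -> inclusion PSI implied by the weights
    amplicons: list
    true_frequencies: dict  # amplicon id -> {transcript id: frequency}
    cds_anchor: int  # transcript-relative ATG offset of the canonical ORF
    seed: int

    @property
    def canonical(self) -> Transcript:
        return self.catalog[0]

    def transcript(self, tx_id: str) -> Transcript:
        for tx in self.catalog:
            if tx.id == tx_id:
                return tx
        raise KeyError(tx_id)


def _random_codons(rng, n: int) -> str:
    return "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n))


def _scrub_atg(seq: str) -> str:
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[:i] + "ACG" + seq[i + 3 :]
    return seq


def make_locus(
    n_exons: int = 8,
    exon_len_range: tuple = (90, 180),
    intron_len_range: tuple = (400, 900),
    events: list | None = None,
    seed: int = 0,
    weights: dict | None = None,
) -> SyntheticLocus:
    """Build a deterministic synthetic locus with one isoform per event.

    The canonical transcript is 5'UTR + ATG + CDS + stop + 3'UTR spread
    over ``n_exons`` exons; internal exon lengths are multiples of three
    (codon-aligned boundaries) except exons skipped by ``skip_fs`` events,
    whose length is made ≡1 mod 3 so skipping them shifts the frame.
    """
    if n_exons < 3:
        raise ValueError("need at least 3 exons")
    if events is None:
        events = default_events()
    rng = np.random.default_rng(seed)

    fs_exons = set()
    for ev in events:
        if ev.kind not in (
            "skip",
            "skip_fs",
            "alt_donor",
            "alt_acceptor",
            "novel_first_exon",
        ):
            raise ValueError(f"unknown event kind {ev.kind!r}")
        if ev.kind in ("skip", "skip_fs", "alt_donor", "alt_acceptor"):
            if not all(2 <= e <= n_exons - 1 for e in ev.exons):
                raise ValueError(f"event {ev.id} touches a terminal exon")
        if ev.kind == "skip_fs":
            if len(ev.exons) != 1:
                raise ValueError("skip_fs takes a single exon")
            fs_exons.add(ev.exons[0])
        if ev.kind == "alt_donor" and not (ev.shift >= 3 or ev.shift == -3):
            raise ValueError("alt_donor supports shift >= +3 or exactly -3")
        if ev.kind == "alt_acceptor" and (ev.shift < 3 or ev.shift % 3):
            raise ValueError("alt_acceptor supports positive multiples of 3")

    # --- canonical geometry -------------------------------------------------
    utr5_len, utr3_tail = 30, 60
    lengths = {}
    for k in range(2, n_exons):
        ln = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
        ln -= ln % 3
        if k in fs_exons:
            ln += 1
        lengths[k] = max(ln, 9)
    body1 = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
    body1 -= body1 % 3
    lengths[1] = utr5_len + 3 + body1
    pre = 3 + body1 + sum(lengths[k] for k in range(2, n_exons))
    tail = 24 + (-pre) % 3  # CDS nt in the last exon, closing the frame
    lengths[n_exons] = tail + 3 + utr3_tail

    introns = [
        int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        for _ in range(n_exons - 1)
    ]
    spacer = 150
    exon_coords = []
    pos = spacer
    for k in range(1, n_exons + 1):
        exon_coords.append((pos, pos + lengths[k]))
        pos += lengths[k]
        if k < n_exons:
            pos += introns[k - 1]
    genome_len = pos + spacer

    # --- canonical mRNA -----------------------------------------------------
    n_codons = (pre + tail) // 3
    cds = "ATG" + _random_codons(rng, n_codons - 1)
    cds_list = list(cds)

    def cds_offset_of_exon_start(k: int) -> int:
        # CDS nt consumed before canonical exon k starts (k >= 2)
        return 3 + body1 + sum(lengths[j] for j in range(2, k))

    for ev in events:
        if ev.kind == "alt_donor" and ev.shift == -3:
            off = cds_offset_of_exon_start(ev.exons[0] + 1) - 3
            cds_list[off : off + 3] = "GTG"  # alt intron must open with GT
        if ev.kind == "alt_acceptor":
            off = cds_offset_of_exon_start(ev.exons[0]) + ev.shift - 3
            cds_list[off : off + 3] = "CAG"  # alt intron must close with AG
    cds = "".join(cds_list)

    utr5 = _scrub_atg("".join(rng.choice(list("ACGT")) for _ in range(utr5_len)))
    utr3 = ("TAAA" * 5) + "".join(
        rng.choice(list("ACGT")) for _ in range(utr3_tail - 20)
    )
    mrna = utr5 + cds + "TAA" + utr3

    # --- genome assembly ----------------------------------------------------
    genome = np.array(list("".join(rng.choice(list("ACGT")) for _ in range(genome_len))))
    cursor = 0
    for (s, e) in exon_coords:
        genome[s:e] = list(mrna[cursor : cursor + (e - s)])
        cursor += e - s
    for (s0, e0), (s1, e1) in zip(exon_coords, exon_coords[1:]):
        genome[e0 : e0 + 2] = list("GT")
        genome[s1 - 2 : s1] = list("AG")

    novel_first_coord = None
    for ev in events:
        if ev.kind == "alt_donor" and ev.shift > 0:
            e0 = exon_coords[ev.exons[0] - 1][1]
            genome[e0 + 2 : e0 + ev.shift] = list("C" * (ev.shift - 2))
            genome[e0 + ev.shift : e0 + ev.shift + 2] = list("GT")
        elif ev.kind == "novel_first_exon":
            i1s = exon_coords[0][1]  # intron 1 interior
            ns = i1s + 60
            ne = ns + 90
            if ne + 20 > exon_coords[1][0]:
                raise ValueError("intron 1 too short for a novel first exon")
            novel_first_coord = (ns, ne)
            genome[ns:ne] = list(
                _scrub_atg("".join(rng.choice(list("ACGT")) for _ in range(90)))
            )
            genome[ne : ne + 2] = list("GT")
    genome_seq = "".join(genome)

    # --- catalog ------------------------------------------------------------
    def tx_from_coords(tx_id: str, coords) -> Transcript:
        exons = [
            Exon(GenomicInterval(CHROM, s, e, "+")) for s, e in coords
        ]
        return Transcript(tx_id, exons, source="synthetic").with_roles()

    catalog = [tx_from_coords("canonical", exon_coords)]
    event_list = []
    for ev in events:
        coords = list(exon_coords)
        if ev.kind in ("skip", "skip_fs"):
            drop = {e - 1 for e in ev.exons}
            coords = [c for i, c in enumerate(coords) if i not in drop]
        elif ev.kind == "alt_donor":
            k = ev.exons[0] - 1
            s, e = coords[k]
            coords[k] = (s, e + ev.shift)
        elif ev.kind == "alt_acceptor":
            k = ev.exons[0] - 1
            s, e = coords[k]
            coords[k] = (s + ev.shift, e)
        elif ev.kind == "novel_first_exon":
            coords = [novel_first_coord] + coords[1:]
        catalog.append(tx_from_coords(ev.id, coords))
        event_list.append(ev)

    # --- mixture weights and implied PSI ------------------------------------
    if weights is None:
        alt = 0.6 / len(event_list) if event_list else 0.0
        weights = {"canonical": 1.0 - alt * len(event_list)}
        weights.update({ev.id: alt for ev in event_list})
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("isoform weights must sum to 1")

    locus = SyntheticLocus(
        genome={CHROM: genome_seq},
        chrom=CHROM,
        strand="+",
        exon_coords=exon_coords,
        catalog=catalog,
        events=event_list,
        isoform_weights=dict(weights),
        true_psi={},
        amplicons=[],
        true_frequencies={},
        cds_anchor=utr5_len,
        seed=seed,
    )
    locus.true_psi = {ev.id: _implied_psi(locus, ev) for ev in event_list}

    # --- amplicons ----------------------------------------------------------
    first_s, first_e = exon_coords[0]
    last_s, last_e = exon_coords[-1]
    amplicons = [
        Amplicon(
            "amp1",
            GenomicInterval(CHROM, first_s, first_s + 20, "+"),
            GenomicInterval(CHROM, last_e - 20, last_e, "+"),
            first_exon_label="exon1",
        )
    ]
    if novel_first_coord is not None:
        ns, ne = novel_first_coord
        amplicons.append(
            Amplicon(
                "amp2",
                GenomicInterval(CHROM, ns, ns + 20, "+"),
                GenomicInterval(CHROM, last_e - 20, last_e, "+"),
                first_exon_label="novelfirst",
            )
        )
    locus.amplicons = amplicons
    for amp in amplicons:
        reach = [
            tx.id
            for tx in catalog
            if tx.blocks()[0][0] <= amp.forward_primer.end
            and tx.blocks()[-1][1] >= amp.reverse_primer.start
        ]
        total = sum(weights[t] for t in reach)
        locus.true_frequencies[amp.id] = {t: weights[t] / total for t in reach}

    validate_splice_sites(locus)
    return locus


def _implied_psi(locus: SyntheticLocus, event: SpliceEvent) -> float:
    """Inclusion PSI of an event under the locus mixture weights: weight of
    transcripts spanning the event region without the alternative junction,
    over all spanning transcripts."""
    alt_tx = locus.transcript(event.id)
    alt_keys = {j.key() for j in junctions_of(alt_tx)} - {
        j.key() for j in junctions_of(locus.canonical)
    }
    if not alt_keys:
        return float("nan")
    key = sorted(alt_keys)[0]
    lo, hi = key[1], key[2]
    spanning = incl = 0.0
    for tx in locus.catalog:
        w = locus.isoform_weights[tx.id]
        if tx.start <= lo and tx.end >= hi:
            spanning += w
            if key not in {j.key() for j in junctions_of(tx)}:
                incl += w
    return incl / spanning if spanning else float("nan")


def validate_splice_sites(locus: SyntheticLocus) -> None:
    """Assert every catalog intron is GT..AG on the transcribed strand."""
    seq = locus.genome[locus.chrom]
    for tx in locus.catalog:
        for j in junctions_of(tx):
            donor = seq[j.donor_end : j.donor_end + 2]
            acceptor = seq[j.acceptor_start - 2 : j.acceptor_start]
            if (donor, acceptor) != ("GT", "AG"):
                raise AssertionError(
                    f"{tx.id}: intron {j.key()} is {donor}..{acceptor}, not GT..AG"
                )


# ---------------------------------------------------------------------------
# Short-read junction counts


def simulate_junction_counts(
    locus: SyntheticLocus,
    n_samples: int = 20,
    groups: dict | None = None,
    group_psi_shift: float = 0.0,
    shift_event: str | None = None,
    libsize_range: tuple = (20_000, 50_000),
    dispersion: float = 0.05,
    seed: int = 0,
):
    """Draw a junction x sample count matrix from the isoform mixture.

    Reads are junction observations: a sample's library size is split over
    junction instances in proportion to isoform weights, then each cell is
    drawn NB(mean, dispersion).  ``group_psi_shift`` moves mixture mass
    between the ``shift_event`` isoform and the canonical one, +shift/2 of
    inclusion in the first group and -shift/2 in the second.  Returns
    (JunctionCountMatrix, truth DataFrame of per-sample expected counts).
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i + 1}" for i in range(n_samples)]
    if groups is None:
        groups = {s: "A" for s in samples}
    else:
        missing = [s for s in samples if s not in groups]
        if missing:
            raise ValueError(f"group labels missing for samples: {missing}")
    group_labels = sorted(set(groups.values()))
    if shift_event is None and group_psi_shift:
        skips = [ev.id for ev in locus.events if ev.kind in ("skip", "skip_fs")]
        if not skips:
            raise ValueError("no cassette event available for group_psi_shift")
        shift_event = skips[0]

    tx_junctions = {
        tx.id: [j.key() for j in junctions_of(tx)] for tx in locus.catalog
    }
    all_keys = sorted({k for keys in tx_junctions.values() for k in keys})
    key_idx = {k: i for i, k in enumerate(all_keys)}

    expected = np.zeros((len(all_keys), n_samples))
    counts = np.zeros((len(all_keys), n_samples), dtype=np.int64)
    libs = rng.integers(libsize_range[0], libsize_range[1] + 1, size=n_samples)

    for si, s in enumerate(samples):
        w = dict(locus.isoform_weights)
        if group_psi_shift and shift_event:
            sign = +1 if groups[s] == group_labels[0] else -1
            delta = sign * group_psi_shift / 2.0
            moved = min(w[shift_event], max(-w["canonical"], delta))
            if moved != delta:
                import logging

                logging.getLogger(__name__).warning(
                    "psi shift clipped for sample %s", s
                )
            w[shift_event] -= moved
            w["canonical"] += moved
        denom = sum(w[t] * len(tx_junctions[t]) for t in w)
        for t, keys in tx_junctions.items():
            for k in keys:
                expected[key_idx[k], si] += libs[si] * w[t] / denom
        mu = expected[:, si]
        if dispersion <= 1e-12:
            counts[:, si] = rng.poisson(mu)
        else:
            n = 1.0 / dispersion
            p = n / (n + np.maximum(mu, 1e-12))
            counts[:, si] = np.where(mu > 0, rng.negative_binomial(n, p), 0)

    junctions = [SpliceJunction(*k) for k in all_keys]
    matrix = JunctionCountMatrix(junctions, samples, counts, counts.sum(axis=0))
    truth = pd.DataFrame(
        expected,
        index=pd.Index(all_keys, tupleize_cols=False, name="junction"),
        columns=samples,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Event-level PSI simulation (differential-splicing power/size studies)


def simulate_psi_events(
    n_events: int,
    n_per_group: int = 20,
    planted_delta: float = 0.0,
    depth_range: tuple = (200, 2000),
    seed: int = 0,
):
    """Binomial PSI observations for null events plus one optional planted
    differential event.

    Each null event has a true inclusion rate drawn once from U(0.2, 0.8)
    shared by both groups; per sample the observed PSI is a binomial
    fraction at a random read depth.  When ``planted_delta`` > 0 an extra
    event named 'planted' sits at 0.5 ± delta/2 between the groups.
    Returns (PsiTable, groups dict, planted event id or None).
    """
    from .quant import PsiTable

    rng = np.random.default_rng(seed)
    samples = [f"a{i + 1}" for i in range(n_per_group)] + [
        f"b{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    n_total = n_events + (1 if planted_delta > 0 else 0)
    depths = rng.integers(depth_range[0], depth_range[1] + 1, size=(n_total, len(samples)))
    p = np.empty((n_total, len(samples)))
    p[:n_events, :] = rng.uniform(0.2, 0.8, size=n_events)[:, None]
    names = [f"null{i + 1}" for i in range(n_events)]
    planted = None
    if planted_delta > 0:
        planted = "planted"
        names.append(planted)
        pa = 0.5 + planted_delta / 2.0
        pb = 0.5 - planted_delta / 2.0
        p[-1, :] = [pa if groups[s] == "A" else pb for s in samples]
    psi = rng.binomial(depths, p) / depths
    index = pd.Index(names, name="event")
    table = PsiTable(
        psi=pd.DataFrame(psi, index=index, columns=samples),
        denominator=pd.DataFrame(depths, index=index, columns=samples),
        event_kind=pd.Series("junction", index=index),
    )
    return table, groups, planted


# ---------------------------------------------------------------------------
# The packaged demo scenario: locus + atlas inputs with known tier truth


def make_demo_scenario(seed: int = 0):
    """A six-isoform locus with planned atlas support per isoform.

    Mixture: canonical 0.35, alt-donor exon 2 (+6) 0.25, skip exon 3 0.15,
    alt-donor exon 3 (-3) 0.10, frame-shifting skip exon 7 0.10,
    alt-acceptor exon 5 (+15) 0.05.  Annotation A carries the canonical and
    alt-donor-2 transcripts, annotation B the canonical and exon-7 skip;
    the short-read matrix supports everything except: the alt-donor-3
    junction appears in a single sample (below the 2-cpm-in-2 filter, so
    unfiltered-only) and the alt-acceptor-5 junction is never observed (and lies beyond snap range of any known junction).
    Expected tiers are therefore 1/1/1/2/1/3.

    Returns a dict with the locus, atlas, observed matrix, annotation
    sources, expected tiers and expected splice chains per isoform.
    """
    from .atlas import annotation_source_from_transcripts, build_atlas

    events = [
        SpliceEvent("alt_donor", (2,), 6),
        SpliceEvent("skip", (3,)),
        SpliceEvent("alt_donor", (3,), -3),
        SpliceEvent("skip_fs", (7,)),
        SpliceEvent("alt_acceptor", (5,), 15),
    ]
    weights = {
        "canonical": 0.35,
        "altdonor_ex2+6": 0.25,
        "skip_ex3": 0.15,
        "altdonor_ex3-3": 0.10,
        "skipfs_ex7": 0.10,
        "altacceptor_ex5+15": 0.05,
    }
    locus = make_locus(n_exons=8, events=events, seed=seed, weights=weights)

    gencode = annotation_source_from_transcripts(
        "GENCODE", [locus.canonical, locus.transcript("altdonor_ex2+6")]
    )
    refseq = annotation_source_from_transcripts(
        "REFSEQ", [locus.canonical, locus.transcript("skipfs_ex7")]
    )

    well_supported = ["canonical", "altdonor_ex2+6", "skip_ex3", "skipfs_ex7"]
    strong_keys = sorted(
        {
            j.key()
            for tx_id in well_supported
            for j in junctions_of(locus.transcript(tx_id))
        }
    )
    weak_keys = sorted(
        {j.key() for j in junctions_of(locus.transcript("altdonor_ex3-3"))}
        - set(strong_keys)
    )
    samples = ["t1", "t2", "t3", "t4"]
    keys = strong_keys + weak_keys
    counts = np.zeros((len(keys), len(samples)), dtype=np.int64)
    counts[: len(strong_keys), :] = 40
    counts[len(strong_keys) :, 0] = 1  # single-sample support: unfiltered only
    observed = JunctionCountMatrix(
        [SpliceJunction(*k) for k in keys], samples, counts, counts.sum(axis=0)
    )

    atlas = build_atlas(observed, [gencode, refseq], min_cpm=2, min_samples=2)

    expected_tiers = {
        "canonical": 1,
        "altdonor_ex2+6": 1,
        "skip_ex3": 1,
        "altdonor_ex3-3": 2,
        "skipfs_ex7": 1,
        "altacceptor_ex5+15": 3,
    }
    expected_chains = {
        tx.id: tuple(
            (j.donor_end, j.acceptor_start) for j in junctions_of(tx)
        )
        for tx in locus.catalog
    }
    return {
        "locus": locus,
        "atlas": atlas,
        "observed": observed,
        "annotations": [gencode, refseq],
        "expected_tiers": expected_tiers,
        "expected_chains": expected_chains,
    }


# ---------------------------------------------------------------------------
# Long reads


def simulate_long_reads(
    locus: SyntheticLocus,
    amplicons: list | None = None,
    n_reads: int = 2000,
    end_wobble_sd: float = 5.0,
    truncation_prob: float = 0.05,
    junction_jitter_sd: float = 0.0,
    frequencies: dict | None = None,
    sample: str = "lr1",
    seed: int = 0,
):
    """Sample amplicon long reads from the per-amplicon isoform frequencies.

    Outer alignment ends get rounded Normal(0, end_wobble_sd) wobble; with
    ``truncation_prob`` the start instead moves >=100 nt into the
    transcript (5' degradation; the reverse primer anchors the 3' end);
    junction coordinates are jittered by a rounded normal clamped to
    ±2·junction_jitter_sd.  Returns (reads, truth DataFrame with the
    source isoform and truncation flag per read).
    """
    rng = np.random.default_rng(seed)
    if amplicons is None:
        amplicons = locus.amplicons
    reads, truth_rows = [], []
    for amp in amplicons:
        freqs = (frequencies or locus.true_frequencies)[amp.id]
        iso_ids = sorted(freqs)
        probs = np.array([freqs[i] for i in iso_ids], dtype=float)
        probs = probs / probs.sum()
        choices = rng.choice(len(iso_ids), size=n_reads, p=probs)
        left, right = amp.genomic_anchors()
        for ri, ci in enumerate(choices):
            tx = locus.transcript(iso_ids[ci])
            blocks = [
                [max(s, left.start), e] for s, e in tx.blocks() if e > left.start
            ]
            blocks = [[s, min(e, right.end)] for s, e in blocks if s < right.end]

            if junction_jitter_sd > 0:
                lim = int(round(2 * junction_jitter_sd))
                for bi in range(len(blocks) - 1):
                    j1 = int(np.clip(round(rng.normal(0, junction_jitter_sd)), -lim, lim))
                    j2 = int(np.clip(round(rng.normal(0, junction_jitter_sd)), -lim, lim))
                    new_end = blocks[bi][1] + j1
                    new_start = blocks[bi + 1][0] + j2
                    if blocks[bi][0] < new_end < new_start < blocks[bi + 1][1]:
                        blocks[bi][1] = new_end
                        blocks[bi + 1][0] = new_start

            truncated = bool(rng.random() < truncation_prob)
            if truncated:
                shift = 100 + int(rng.integers(0, 200))
                new_start = blocks[0][0] + shift
                while len(blocks) > 1 and new_start >= blocks[0][1]:
                    overshoot = new_start - blocks[0][1]
                    blocks.pop(0)
                    new_start = blocks[0][0] + overshoot
                blocks[0][0] = min(new_start, blocks[0][1] - 1)
            else:
                wob = int(round(rng.normal(0, end_wobble_sd)))
                blocks[0][0] = max(0, min(blocks[0][0] + wob, blocks[0][1] - 1))
            wob = int(round(rng.normal(0, end_wobble_sd)))
            contig_len = len(locus.genome[locus.chrom])
            blocks[-1][1] = min(
                contig_len, max(blocks[-1][1] + wob, blocks[-1][0] + 1)
            )

            name = f"{amp.id}_read{ri + 1}"
            reads.append(
                ReadRecord(
                    name=name,
                    chrom=locus.chrom,
                    strand=locus.strand,
                    blocks=tuple(tuple(b) for b in blocks),
                    sample=sample,
                )
            )
            truth_rows.append(
                {
                    "read": name,
                    "amplicon": amp.id,
                    "isoform": iso_ids[ci],
                    "truncated": truncated,
                }
            )
    return reads, pd.DataFrame(truth_rows)
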