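"""End-to-end orchestration: atlas -> quant -> longread -> orf.

Every stage is a pure function of (inputs, config, seed); the manifest
records a checksum per output so a rerun with identical inputs can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import io, longread, orf, quant, simulate
from .model import junctions_of

log = logging.getLogger(__name__)


class _TranscriptChain:
    """Adapter presenting a Transcript with the block-chain interface."""

    def __init__(self, tx):
        self.chrom = tx.chrom
        self.strand = tx.strand
        self._blocks = tx.blocks()

    def blocks(self):
        return self._blocks


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs plus every threshold the stages consume.

    ``annotations`` maps source name (GENCODE/REFSEQ) to a GTF path;
    ``short_sams`` maps sample id to a spliced short-read SAM;
    ``long_sams`` maps sample id to a long-read amplicon SAM.
    """

    outdir: str
    genome: str = ""
    annotations: dict = field(default_factory=dict)
    short_sams: dict = field(default_factory=dict)
    junction_counts: str = ""
    long_sams: dict = field(default_factory=dict)
    primers: str = ""
    groups: dict = field(default_factory=dict)
    epitopes: str = ""
    reference_transcript: str = ""  # annotation transcript whose ORF is the reference protein
    min_cpm: float = 2.0
    min_samples: int = 2
    end_tol: int = longread.DEFAULT_END_TOL
    snap_tol: int = longread.DEFAULT_SNAP_TOL
    min_reads: int = longread.DEFAULT_MIN_READS
    fraction: float = 0.8
    min_codons: int = orf.DEFAULT_MIN_CODONS
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        for name, value in [
            ("min_cpm", self.min_cpm),
            ("min_samples", self.min_samples),
            ("end_tol", self.end_tol),
            ("snap_tol", self.snap_tol),
            ("min_reads", self.min_reads),
            ("min_codons", self.min_codons),
        ]:
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        for path in self._input_paths():
            if not Path(path).exists():
                raise FileNotFoundError(f"input does not exist: {path}")

    def _input_paths(self):
        paths = []
        if self.genome:
            paths.append(self.genome)
        paths += list(self.annotations.values())
        paths += list(self.short_sams.values())
        if self.junction_counts:
            paths.append(self.junction_counts)
        paths += list(self.long_sams.values())
        if self.primers:
            paths.append(self.primers)
        if self.epitopes:
            paths.append(self.epitopes)
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage; returns the output manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list = []

    # --- atlas --------------------------------------------------------------
    try:
        sources = []
        for name, path in config.annotations.items():
            transcripts = io.read_gtf(path)
            sources.append(
                atlas_mod.annotation_source_from_transcripts(name.upper(), transcripts)
            )
        if config.junction_counts:
            observed = atlas_mod.read_junction_counts(config.junction_counts)
        else:
            reads = []
            for sample, path in sorted(config.short_sams.items()):
                reads.extend(io.read_spliced_sam(path, sample=sample))
            observed = atlas_mod.count_junctions(reads)
        curated = atlas_mod.build_atlas(
            observed,
            sources,
            min_cpm=config.min_cpm,
            min_samples=config.min_samples,
        )
        atlas_tsv = outdir / "atlas.tsv"
        curated.to_frame().to_csv(atlas_tsv, sep="\t", index=False)
        outputs.append(atlas_tsv)
    except Exception as exc:
        raise StageError("atlas", exc) from exc

    # --- quant --------------------------------------------------------------
    try:
        psi = quant.psi_junction(observed)
        psi_tsv = outdir / "psi_junctions.tsv"
        psi.psi.to_csv(psi_tsv, sep="\t")
        outputs.append(psi_tsv)
        if config.groups:
            events = quant.differential_events(psi, config.groups)
            diff_tsv = outdir / "differential.tsv"
            quant.differential_frame(events).to_csv(diff_tsv, sep="\t", index=False)
            outputs.append(diff_tsv)
    except Exception as exc:
        raise StageError("quant", exc) from exc

    # --- longread -----------------------------------------------------------
    top_chains: list = []
    try:
        if config.primers and config.long_sams:
            amplicons = longread.read_primer_table(config.primers)
            reads = []
            for sample, path in sorted(config.long_sams.items()):
                reads.extend(io.read_spliced_sam(path, sample=sample))
            all_chains = []
            for amp in amplicons:
                assigned = [
                    r
                    for r in reads
                    if longread.assign_full_length(r, amplicons, config.end_tol)
                    == amp.id
                ]
                chains = longread.snap_and_collapse(
                    assigned,
                    curated,
                    amp,
                    snap_tol=config.snap_tol,
                    min_reads=config.min_reads,
                )
                longread.classify_tiers(chains, curated)
                longread.isoform_frequencies(chains)
                all_chains.extend(chains)
                top_chains.extend(longread.top_isoforms(chains, config.fraction))
            iso_tsv = outdir / "isoforms.tsv"
            longread.isoform_table(all_chains).to_csv(iso_tsv, sep="\t", index=False)
            iso_bed = outdir / "isoforms.bed12"
            io.write_bed12(
                all_chains, iso_bed, score_of=lambda c: c.tier or 0
            )
            outputs += [iso_tsv, iso_bed]
    except Exception as exc:
        raise StageError("longread", exc) from exc

    # --- orf ----------------------------------------------------------------
    try:
        if config.genome and top_chains:
            genome = io.read_fasta(config.genome)
            annotation_peptides = {}
            reference_peptide = ""
            reference_nt = ""
            for name, path in config.annotations.items():
                for tx in io.read_gtf(path):
                    seq = orf.spliced_sequence(genome, _TranscriptChain(tx))
                    found = orf.find_orf(seq, min_codons=config.min_codons)
                    if found:
                        annotation_peptides[tx.id] = found.peptide
                        is_ref = (
                            tx.id == config.reference_transcript
                            if config.reference_transcript
                            else (
                                not reference_peptide
                                or len(found.peptide) > len(reference_peptide)
                            )
                        )
                        if is_ref:
                            reference_peptide = found.peptide
                            reference_nt = seq
            epitopes = []
            if config.epitopes:
                edf = pd.read_csv(config.epitopes, sep="\t")
                epitopes = [
                    orf.Epitope(str(r.antibody), int(r.start), int(r.end))
                    for r in edf.itertuples()
                ]
            rows = []
            peptides = {}
            for chain in top_chains:
                seq = orf.spliced_sequence(genome, chain)
                found = orf.find_orf(seq, min_codons=config.min_codons)
                if found is None:
                    rows.append({"isoform": chain.id, "orf": "none"})
                    continue
                peptides[chain.id] = found.peptide
                alteration = (
                    orf.name_alteration(
                        reference_peptide, found.peptide, reference_nt, seq
                    )
                    if reference_peptide
                    else orf.ProteinAlteration(kind="identity")
                )
                row = {
                    "isoform": chain.id,
                    "orf": f"{found.start}-{found.end}",
                    "peptide_length": len(found.peptide),
                    "hgvs": alteration.hgvs,
                    "matched_transcripts": ",".join(
                        orf.match_isoform(found.peptide, annotation_peptides)
                    ),
                }
                for ep in epitopes:
                    row[f"detectable_{ep.antibody}"] = orf.epitope_detectable(
                        alteration, ep, len(reference_peptide)
                    )
                rows.append(row)
            prot_tsv = outdir / "proteins.tsv"
            pd.DataFrame(rows).to_csv(prot_tsv, sep="\t", index=False)
            pep_fa = outdir / "peptides.fasta"
            io.write_fasta(peptides, pep_fa)
            outputs += [prot_tsv, pep_fa]
    except StageError:
        raise
    except Exception as exc:
        raise StageError("orf", exc) from exc

    manifest = {
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        }
        | {k: dict(v) for k, v in asdict(config).items() if isinstance(v, dict)},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_demo_inputs(outdir, seed: int = 0, n_long_reads: int = 2000) -> RunConfig:
    """Materialise the packaged synthetic scenario as on-disk inputs and
    return a RunConfig pointing at them (the one-command demo)."""
    outdir = Path(outdir)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    scen = simulate.make_demo_scenario(seed=seed)
    locus = scen["locus"]

    genome_fa = indir / "genome.fa"
    io.write_fasta(locus.genome, genome_fa)
    ann_paths = {}
    for src in scen["annotations"]:
        tx_ids = set()
        if src.name == "GENCODE":
            tx_ids = {"canonical", "altdonor_ex2+6"}
        else:
            tx_ids = {"canonical", "skipfs_ex7"}
        path = indir / f"{src.name.lower()}.gtf"
        io.write_gtf([t for t in locus.catalog if t.id in tx_ids], path)
        ann_paths[src.name] = str(path)

    counts_tsv = indir / "junction_counts.tsv"
    atlas_mod.write_junction_counts(scen["observed"], counts_tsv)

    primers_tsv = indir / "primers.tsv"
    longread.write_primer_table(locus.amplicons, primers_tsv)

    reads, _truth = simulate.simulate_long_reads(
        locus, n_reads=n_long_reads, seed=seed + 1
    )
    long_sam = indir / "longreads.sam"
    io.write_sam(
        reads, long_sam, {locus.chrom: len(locus.genome[locus.chrom])}
    )

    return RunConfig(
        outdir=str(outdir / "results"),
        genome=str(genome_fa),
        annotations=ann_paths,
        junction_counts=str(counts_tsv),
        long_sams={"lr1": str(long_sam)},
        primers=str(primers_tsv),
        reference_transcript="canonical",
        seed=seed,
    )
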