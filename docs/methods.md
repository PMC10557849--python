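# Methods

## Coordinate model

All internal coordinates are 0-based, half-open on the forward genome
strand (BED convention); GTF input/output converts at the boundary and
round-trips exactly. Transcript orientation is expressed by exon ordering
(a minus-strand transcript lists exons from high to low coordinate), never
by coordinate flipping. Splice junctions are keyed by
`(chrom, donor_end, acceptor_start, strand)` with the donor stored as the
left coordinate even on the minus strand, so identical coordinates from
different sources collapse onto one key. When reducing alignments to
blocks, only CIGAR `N` operations of at least 20 nt (configurable
`min_intron`) split a block; deletions (`D`) and sub-threshold gaps merge
into the surrounding block, because only a credible intron denotes
splicing.

## Atlas curation

The observed junction × sample count matrix is cpm-normalised
(count / library size × 10⁶; the library size defaults to the per-sample
total of junction reads in the analysed region, since a locus-level
analysis has no genome-wide total) and filtered with the
*≥ 2 cpm in ≥ 2 samples* rule. Reference-annotation junctions are retained
regardless of expression (`keep_annotated`, default on). Manual curation
is replaced by this deterministic rule set plus optional allow/deny lists:
a reproducible pipeline needs an explicit procedure, so the rules here are
a stated stand-in, not a reconstruction of any particular curator's
choices. Provenance flags per curated junction: one flag per annotation
containing it, OBSERVED for expression-supported junctions, and NOVEL
exactly when no annotation contains it. The atlas keeps two layers — the
curated junction/exon-end sets and the unfiltered observed superset —
because isoform tiering needs both.

## PSI and differential events

Junction PSI uses Leafcutter-style clusters: connected components of the
share-a-donor-or-acceptor graph define the denominator, so per cluster
and sample the defined PSI values sum to 1. Cassette-exon PSI is
mean(upstream, downstream inclusion) / (mean inclusion + exclusion),
where exclusion junctions are introns strictly containing the exon.
Terminal-exon usage proxies a first (last) exon's expression by the
junction reads leaving (entering) it, keeping the whole pipeline
junction-based and therefore simulator-verifiable. A zero denominator is
encoded as NaN, never 0 — 0/0 is absence of evidence, not evidence of
exclusion. Differential testing is a per-event two-sided Wilcoxon
rank-sum on per-sample PSI with Benjamini–Hochberg correction across
tested events; groups whose values are all identical get p = 1 explicitly
(the asymptotic statistic is undefined there). A rank test was chosen
because PSI is a bounded proportion with no credible parametric model at
cohort scale.

## Long-read isoform calling

A read is full-length for an amplicon when its outer alignment start and
end fall within `end_tol` (default 20 nt) of the strand-appropriate
primer intervals; ambiguous matches resolve to the smallest combined end
distance, exact ties to amplicon-id order. Read junctions within
`snap_tol` (default 10 nt, both ends) of an atlas junction are replaced
by it — exact matches always win because distance is minimised — and
reads with identical snapped chains collapse into one isoform with summed
per-sample counts; chains with fewer than `min_reads` (default 2) reads
are discarded. The defaults reflect typical nanopore end and junction
jitter and are recorded in output metadata. Outer block ends are set to
the amplicon primer boundaries: they are primer-defined, not
splice-defined, which both removes residual end wobble from the reported
models and is why terminal ends are exempt from tier judgement. Tiers
check every junction-derived exon end against the curated set (tier 1),
else the unfiltered observed set (tier 2), else unsupported (tier 3);
growing either set can only lower a tier. All orderings break ties
deterministically (count descending, then lexicographic chain), so
outputs are byte-identical across reruns and input orderings. Because
amplicons are pooled RT-PCR products, within-amplicon frequencies are
relative expression only; absolute abundances across amplicons are not
quantitative.

## ORF prediction and HGVS naming

`find_orf` returns the maximal ATG→stop ORF over the three forward
frames (leftmost on ties), or the ORF anchored at a known canonical start
when intact, falling back to longest otherwise; ORFs shorter than
`min_codons` (default 25 residues) are rejected and a codon containing N
invalidates the reading through it. Alterations are named by longest
common prefix/suffix decomposition of the reference and alternative
peptides, preferring the maximal prefix when the two overlap; standard
3'-most HGVS shifting is deliberately not applied (a simplicity choice,
flagged here). A frameshift is recognised when the nucleotide sequences
carrying the event differ in length by a non-multiple of three — the
sequences compared must be transcript-level, since any ATG→stop ORF is
trivially a multiple of three and carries no frame signal.

Frameshift length convention: `fs*N` is read as *N novel residues after
the last reference residue*, so the altered length is
(ref_start − 1) + N; this matches the published residue counts
(e.g. Gly457Valfs*10 on 595 → 466). Strict HGVS semantics (Ter at
new-frame position N, one residue fewer) are available via `strict=True`.
The 595-residue reference is supplied as configuration (sequence or
length); 595 is forced by the insertion arithmetic of the published
table (597 = 595 + 2).

Epitope detectability: an antibody detects an isoform iff every residue
of its reference-interval epitope is retained unchanged — deletions and
delins must not intersect the interval, a frameshift destroys everything
from its anchor onward, and insertions strictly inside the interval
disrupt it while flanking insertions do not. Epitope coordinates are
user-supplied configuration.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not raw sequencing: a ~10 kb locus with 8 exons (default), canonical
transcript 5'UTR + ATG + CDS + stop + poly-stop 3'UTR, internal exon
boundaries codon-aligned so event classes have controlled protein
consequences, and every splice site a genuine GT..AG pair. Event classes
mirror the published table: in-frame alternative-donor insertion (+6),
single and multi-exon cassette deletions, a 1-residue alternative-donor
deletion (−3), an alternative acceptor, and a frame-shifting skip (exon
length ≡ 1 mod 3). Short-read counts are negative-binomial around
isoform-mixture expectations (dispersion 0.05 by default, typical
RNA-seq over-dispersion; 0 reduces to Poisson), with library sizes of
20–50k junction reads. Long reads are multinomial over per-amplicon
isoform frequencies with rounded-Gaussian end wobble, 5'-truncation
(≥ 100 nt internal; only starts truncate because the reverse primer
anchors the 3' end) and clamped junction jitter. Everything is
deterministic per seed (numpy PCG64).

What the generator does **not** emulate — base-level nanopore error
profiles, amplicon PCR bias, genome-wide junction background,
cohort-scale sample numbers — bounds what passing tests show: they
validate the pipeline's logic and statistical calibration under the
stated noise model, not its behaviour on raw sequencer output.

The packaged demonstration scenario mixes six isoforms at
0.35/0.25/0.15/0.10/0.10/0.05 and plans their atlas support so all three
tiers occur: one alternative junction is observed in a single sample only
(below the 2-cpm-in-2 filter → tier 2) and one is never observed and lies
beyond snap range of any known junction (→ tier 3). Problem sizes in the
analysis scripts and tests — 2000 long reads, 40-sample cohorts, 200-event
differential panels, 1000-replicate calibration loops — were chosen so the
full chain runs in seconds to a few minutes on one CPU while keeping
binomial/multinomial sampling error well inside the asserted tolerances.

## Known limitations

- PSI denominators and the differential test are stated stand-ins chosen
  for robustness and testability; other definitions (e.g. exon-body
  coverage for terminal exons) are legitimate and would differ in detail.
- Junction snapping erases genuinely novel junctions closer than
  `snap_tol` to a known junction; the tolerance trades alignment-jitter
  robustness against sensitivity to near-canonical novelty.
- Minus-strand loci are fully supported by the coordinate model and
  readers, but the synthetic generator emits plus-strand loci only.
- IRES-mediated alternative starts, molecular-weight estimation and
  chimera detection are out of scope.
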