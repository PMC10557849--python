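# isoatlas

Locus-level discovery and characterisation of transcript isoforms, built
around the oestrogen receptor alpha (*ESR1*) use case: a gene whose public
annotation is incomplete and inconsistent, whose alternative isoforms differ
functionally, and whose protein products are variably visible to the
antibodies used in clinical immunohistochemistry.

The package implements the full computational chain as a tested library
plus a set of narrative analysis scripts:

1. **Junction atlas** — splice junctions are extracted from spliced
   short-read alignments (CIGAR `N` operations), counted per sample,
   normalised to counts per million (cpm), filtered with the
   *≥ 2 cpm in ≥ 2 samples* rule, merged with reference annotations
   (GENCODE/RefSeq-style GTFs) and flagged by provenance
   (GENCODE / REFSEQ / OBSERVED / NOVEL).
2. **Splicing quantification** — percent spliced-in (PSI) scores
   ψ(j, s) = n(j, s) / Σ_{k∈C(j)} n(k, s) over Leafcutter-style clusters
   C(j) of junctions sharing a donor or acceptor; cassette-exon PSI from
   flanking inclusion and spanning exclusion junctions; first/last-exon
   usage as each terminal exon's fraction of all terminal-exon expression;
   group-wise differential events via Wilcoxon rank-sum with
   Benjamini–Hochberg correction.
3. **Long-read isoform calling** — full-length amplicon reads are assigned
   to primer pairs by their outer alignment coordinates, junctions are
   snapped onto the atlas to absorb alignment jitter, identical splice
   chains are collapsed and classified into support tiers
   (1: all internal exon ends curated; 2: some ends only in the unfiltered
   observed set; 3: some ends unsupported), and the minimal isoform set
   covering 80% of each amplicon's reads is reported.
4. **Protein prediction** — spliced sequences are scanned for open reading
   frames, translations are compared with the reference protein by longest
   common prefix/suffix decomposition and named in HGVS p. notation
   (`Gly254del`, `Gly215_His216insAsnArg`, `Gly457Valfs*10`, …), and
   antibody-epitope detectability is evaluated per isoform.

A first-class synthetic-data module generates ground-truthed loci (genuine
GT..AG splice sites, clean canonical ORF, one isoform per event class),
group-structured junction counts (negative-binomial noise) and long reads
with end wobble, 5'-truncation and junction jitter, so every stage is
testable without external data.

## Worked example

The numbered scripts under `analysis/` run the whole chain on the packaged
synthetic locus (six isoforms mixed at 0.35/0.25/0.15/0.10/0.10/0.05):

```sh
python analysis/01_simulate_locus.py   --seed 1   # write inputs
python analysis/02_build_atlas.py      --seed 1   # curate the atlas
python analysis/03_quantify_splicing.py --seed 1  # PSI + differential test
python analysis/04_call_isoforms.py    --seed 1   # tiers + frequencies
python analysis/05_predict_proteins.py --seed 1   # ORFs, HGVS, epitopes
```

`04_call_isoforms.py` prints (seed 1):

```
1909/2000 reads full-length (91 truncated); 6 isoforms -> results/isoforms.tsv
  amp1.iso1: canonical            tier 1 freq 0.351 (true 0.35)
  amp1.iso2: altdonor_ex2+6       tier 1 freq 0.263 (true 0.25)
  amp1.iso3: skip_ex3             tier 1 freq 0.145 (true 0.15)
  amp1.iso4: skipfs_ex7           tier 1 freq 0.106 (true 0.10)
  amp1.iso5: altdonor_ex3-3       tier 2 freq 0.087 (true 0.10)
  amp1.iso6: altacceptor_ex5+15   tier 3 freq 0.046 (true 0.05)
80%-coverage set: ['amp1.iso1', 'amp1.iso2', 'amp1.iso3', 'amp1.iso4']
```

All six planted isoforms are recovered with the tiers their atlas support
implies and frequencies within sampling error of the truth; the 5%
truncated reads fail full-length assignment as designed.
`05_predict_proteins.py` then names each isoform's protein change — the
in-frame donor extension becomes a two-residue insertion
(`Thr99_Ile100insValPro`), the frame-shifting exon skip a truncating
frameshift (`Trp286Aspfs*5`) that a C-terminal epitope can no longer
detect — and reproduces the residue counts of the six published receptor
isoforms from their HGVS descriptions alone (e.g. `Gly457Valfs*10` on the
595-residue receptor → 466 aa).

The same pipeline is available as a CLI
(`isoatlas atlas|quant|longread|simulate|run-all`);
`isoatlas run-all --outdir out --seed 1` runs the demo end to end and
writes a checksummed manifest, byte-identical on rerun.

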