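"""ORF finding, HGVS naming round trips, epitope detectability."""

import numpy as np
import pytest

from isoatlas.longread import IsoformChain
from isoatlas.orf import (
    Epitope,
    apply_alteration,
    apply_alteration_length,
    detectability_fraction,
    epitope_detectable,
    find_orf,
    match_isoform,
    name_alteration,
    parse_hgvs_p,
    render_hgvs,
    spliced_sequence,
    translate_cds,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _chain(blocks, strand="+", chrom="c"):
    return IsoformChain(
        id="x", amplicon="a", chrom=chrom, strand=strand,
        block_list=list(blocks), junctions=[],
    )


class TestSplicedSequence:
    GENOME = {"c": "ATGCCCGGG"}

    def test_plus_strand_concatenation(self):
        assert spliced_sequence(self.GENOME, _chain([(0, 3), (6, 9)])) == "ATGGGG"

    def test_minus_strand_reverse_complement(self):
        assert spliced_sequence(self.GENOME, _chain([(0, 3), (6, 9)], "-")) == "CCCCAT"

    def test_length_is_sum_of_blocks(self, locus):
        for tx in locus.catalog:
            chain = _chain(tx.blocks(), chrom=locus.chrom)
            seq = spliced_sequence(locus.genome, chain)
            assert len(seq) == sum(e - s for s, e in tx.blocks())

    def test_out_of_bounds_block_rejected(self):
        with pytest.raises(ValueError):
            spliced_sequence(self.GENOME, _chain([(5, 50)]))


def _brute_force_orf(seq, min_codons):
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i, len(seq) - 2, 3):
            codon = seq[j : j + 3]
            if "N" in codon:
                break
            if codon in stops:
                if (j + 3 - i) // 3 - 1 >= min_codons and (
                    best is None or j + 3 - i > best[1] - best[0]
                ):
                    best = (i, j + 3)
                break
    return best


class TestFindOrf:
    def test_worked_example(self):
        orf = find_orf("AAATGGCCTAGAA", min_codons=2)
        assert (orf.start, orf.end, orf.peptide) == (2, 11, "MA")

    def test_no_start_codon_gives_none(self):
        assert find_orf("CCCCCCCCCCCC", min_codons=1) is None

    def test_anchored_policy_uses_canonical_start(self):
        seq = "ATGAAAATGGCCGCCGCCTAA"
        anchored = find_orf(seq, policy="anchored", anchor_offset=0, min_codons=2)
        assert anchored.start == 0
        # destroyed anchor falls back to the longest ORF
        fallback = find_orf("CCG" + seq[3:], policy="anchored", anchor_offset=0, min_codons=2)
        assert fallback.start == 6

    def test_matches_three_frame_brute_force(self):
        rng = np.random.default_rng(20)
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=120))
            got = find_orf(seq, min_codons=2)
            want = _brute_force_orf(seq, 2)
            if want is None:
                assert got is None
            else:
                assert (got.start, got.end) == want

    def test_peptide_length_invariant(self, locus):
        seq = spliced_sequence(
            locus.genome, _chain(locus.canonical.blocks(), chrom=locus.chrom)
        )
        orf = find_orf(seq)
        assert len(orf.peptide) == (orf.end - orf.start) // 3 - 1


class TestNameAlteration:
    def test_single_deletion_by_hand(self):
        alt = name_alteration("MKTGHWL", "MKTHWL")
        assert (alt.kind, alt.hgvs) == ("deletion", "Gly4del")

    def test_insertion_by_hand(self):
        alt = name_alteration("MKTGHWL", "MKTGNRHWL")
        assert (alt.kind, alt.hgvs) == ("insertion", "Gly4_His5insAsnArg")

    def test_identity(self):
        assert name_alteration("MKT", "MKT").kind == "identity"

    def test_frameshift_flagged_by_transcript_length_difference(self):
        ref, alt = "MKTGHWL", "MKTGRS"
        named = name_alteration(ref, alt, "x" * 30, "x" * 26)  # 4 nt lost
        assert named.kind == "frameshift"
        assert named.hgvs == "His5Argfs*2"
        assert apply_alteration(ref, named) == alt

    def test_random_deletion_round_trips(self):
        rng = np.random.default_rng(21)
        for _ in range(300):
            ref = "M" + "".join(rng.choice(list(AA), size=40))
            i = int(rng.integers(1, 35))
            j = int(rng.integers(i + 1, 41))
            alt_pep = ref[:i] + ref[j:]
            named = name_alteration(ref, alt_pep)
            assert named.kind in ("deletion", "delins")
            assert apply_alteration(ref, named) == alt_pep
            assert apply_alteration_length(len(ref), named) == len(alt_pep)

    def test_random_insertion_round_trips(self):
        rng = np.random.default_rng(22)
        for _ in range(300):
            ref = "M" + "".join(rng.choice(list(AA), size=30))
            i = int(rng.integers(1, 30))
            ins = "".join(rng.choice(list(AA), size=rng.integers(1, 6)))
            alt_pep = ref[:i] + ins + ref[i:]
            named = name_alteration(ref, alt_pep)
            assert named.kind in ("insertion", "delins")
            assert apply_alteration(ref, named) == alt_pep
            assert apply_alteration_length(len(ref), named) == len(alt_pep)

    def test_hgvs_parse_render_round_trip(self):
        for text in [
            "Gly457Valfs*10",
            "Gly215_His216insAsnArg",
            "His216_Gly254del",
            "Gly254del",
            "Pro152_Arg412del",
            "Gly254_Pro365del",
            "Ala10delinsTrpTrp",
        ]:
            assert render_hgvs(parse_hgvs_p(text)) == text


class TestApplyAlterationLength:
    @pytest.mark.parametrize(
        "hgvs,expected",
        [
            ("Gly215_His216insAsnArg", 597),
            ("Gly254del", 594),
            ("Gly457Valfs*10", 466),
        ],
    )
    def test_reference_protein_arithmetic(self, hgvs, expected):
        assert apply_alteration_length(595, parse_hgvs_p(hgvs)) == expected

    def test_strict_frameshift_counting_one_shorter(self):
        alt = parse_hgvs_p("Gly457Valfs*10")
        assert apply_alteration_length(595, alt, strict=True) == 465

    def test_out_of_range_positions_rejected(self):
        with pytest.raises(ValueError):
            apply_alteration_length(100, parse_hgvs_p("Gly254del"))


class TestTranslate:
    def test_trailing_stop_stripped(self):
        assert translate_cds("ATGGCCTAG") == "MA"

    def test_n_codon_becomes_x(self):
        assert translate_cds("ATGGNCTAA") == "MX"


class TestMatchIsoform:
    CATALOG = {"tx1": "MKT", "tx2": "MKTG", "tx3": "MKT"}

    def test_exact_matches_returned(self):
        assert match_isoform("MKT", self.CATALOG) == ["tx1", "tx3"]

    def test_near_miss_is_novel(self):
        assert match_isoform("MKA", self.CATALOG) == []


class TestEpitopes:
    def test_c_terminal_epitope_lost_to_frameshift(self):
        fs = parse_hgvs_p("Gly457Valfs*10")
        assert not epitope_detectable(fs, Epitope("SP1", 560, 595), 595)

    def test_n_terminal_epitope_survives_internal_deletion(self):
        dele = parse_hgvs_p("Gly254del")
        assert epitope_detectable(dele, Epitope("EP1", 1, 100), 595)

    def test_identity_always_detectable(self):
        from isoatlas.orf import ProteinAlteration

        ident = ProteinAlteration(kind="identity")
        assert epitope_detectable(ident, Epitope("x", 1, 595), 595)

    def test_insertion_inside_disrupts_flanking_does_not(self):
        ins = parse_hgvs_p("Gly215_His216insAsnArg")
        assert not epitope_detectable(ins, Epitope("x", 200, 230), 595)
        assert epitope_detectable(ins, Epitope("x", 216, 230), 595)
        assert epitope_detectable(ins, Epitope("x", 200, 215), 595)

    def test_fraction_matches_brute_force_count(self):
        alterations = [
            parse_hgvs_p(t)
            for t in [
                "Gly457Valfs*10",
                "Gly215_His216insAsnArg",
                "His216_Gly254del",
                "Gly254del",
                "Pro152_Arg412del",
                "Gly254_Pro365del",
            ]
        ]
        n_term = Epitope("EP1", 1, 100)
        c_term = Epitope("SP1", 560, 595)
        expected_n = sum(
            epitope_detectable(a, n_term, 595) for a in alterations
        ) / len(alterations)
        assert detectability_fraction(alterations, n_term, 595) == expected_n
        # all six events leave the N-terminus intact; the C-terminal
        # antibody misses only the frameshift-truncated isoform
        assert detectability_fraction(alterations, n_term, 595) == 1.0
        assert detectability_fraction(alterations, c_term, 595) == pytest.approx(5 / 6)
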