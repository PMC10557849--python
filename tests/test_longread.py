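"""Full-length assignment, snap/collapse, tier classification, 80% sets."""

import dataclasses
import random

import numpy as np
import pytest

from isoatlas.io import ReadRecord
from isoatlas.longread import (
    Amplicon,
    IsoformChain,
    assign_full_length,
    classify_tier,
    classify_tiers,
    isoform_frequencies,
    snap_and_collapse,
    top_isoforms,
)
from isoatlas.model import GenomicInterval
from isoatlas.simulate import simulate_long_reads


def _amp(amp_id="amp1", fwd=(100, 120), rev=(5000, 5020)):
    return Amplicon(
        amp_id,
        GenomicInterval("chrSyn", *fwd, "+"),
        GenomicInterval("chrSyn", *rev, "+"),
    )


def _read(start, end, name="r", sample="s1"):
    return ReadRecord(name, "chrSyn", "+", ((start, end),), sample)


class TestAssignFullLength:
    def test_read_near_both_primers_assigned(self):
        amp = _amp()
        assert assign_full_length(_read(98, 5021), [amp], end_tol=20) == "amp1"

    def test_truncated_read_unassigned(self):
        amp = _amp()
        assert assign_full_length(_read(600, 5020), [amp], end_tol=20) is None

    def test_closest_amplicon_wins(self):
        a = _amp("a", fwd=(100, 120))
        b = _amp("b", fwd=(140, 160))
        assert assign_full_length(_read(95, 5010), [a, b], end_tol=50) == "a"

    def test_exact_tie_breaks_on_amplicon_id(self):
        a = _amp("a", fwd=(200, 220))
        b = _amp("b", fwd=(100, 120))
        # read start 160 is 40 from either primer interval
        assert assign_full_length(_read(160, 5010), [a, b], end_tol=50) == "a"

    def test_truncation_rate_reflected_in_assignment(self, locus):
        reads, truth = simulate_long_reads(
            locus, n_reads=600, end_wobble_sd=0, truncation_prob=0.1, seed=13
        )
        assigned = [
            assign_full_length(r, locus.amplicons, end_tol=20) for r in reads
        ]
        n_none = sum(a is None for a in assigned)
        assert n_none == truth.truncated.sum()
        # binomial 99.9% band around 10%
        assert 0.1 * 600 - 3.3 * np.sqrt(600 * 0.09) <= n_none <= 0.1 * 600 + 3.3 * np.sqrt(600 * 0.09)


class TestSnapAndCollapse:
    def test_jittered_junctions_snap_onto_atlas_and_merge(self, scenario):
        locus, atlas = scenario["locus"], scenario["atlas"]
        amp = locus.amplicons[0]
        (j0,) = [scenario["expected_chains"]["canonical"][0]]
        blocks_a = ((amp.forward_primer.start, j0[0] - 3), (j0[1] + 2, amp.reverse_primer.end))
        blocks_b = ((amp.forward_primer.start, j0[0] + 3), (j0[1] - 1, amp.reverse_primer.end))
        reads = [
            ReadRecord("a", locus.chrom, "+", blocks_a, "s1"),
            ReadRecord("b", locus.chrom, "+", blocks_b, "s1"),
        ]
        chains = snap_and_collapse(reads, atlas, amp, snap_tol=10, min_reads=1)
        assert len(chains) == 1
        assert chains[0].chain_key() == (j0,)
        assert chains[0].total_count == 2

    def test_exact_duplicates_sum_with_zero_tolerance(self, scenario):
        locus, atlas = scenario["locus"], scenario["atlas"]
        amp = locus.amplicons[0]
        reads, _ = simulate_long_reads(
            locus, n_reads=40, end_wobble_sd=0, truncation_prob=0, seed=14
        )
        chains = snap_and_collapse(reads, atlas, amp, snap_tol=0, min_reads=1)
        assert sum(c.total_count for c in chains) == 40

    def test_collapse_is_order_independent(self, scenario):
        locus, atlas = scenario["locus"], scenario["atlas"]
        amp = locus.amplicons[0]
        reads, _ = simulate_long_reads(
            locus, n_reads=300, end_wobble_sd=5, truncation_prob=0, seed=15
        )
        shuffled = list(reads)
        random.Random(0).shuffle(shuffled)
        a = snap_and_collapse(reads, atlas, amp)
        b = snap_and_collapse(shuffled, atlas, amp)
        assert [(c.chain_key(), c.counts) for c in a] == [
            (c.chain_key(), c.counts) for c in b
        ]

    def test_min_reads_filters_singletons(self, scenario):
        locus, atlas = scenario["locus"], scenario["atlas"]
        amp = locus.amplicons[0]
        reads, truth = simulate_long_reads(
            locus, n_reads=500, end_wobble_sd=0, truncation_prob=0, seed=16
        )
        chains = snap_and_collapse(reads, atlas, amp, min_reads=2)
        assert all(c.total_count >= 2 for c in chains)


class TestClassifyTier:
    def _chain(self, junctions):
        return IsoformChain(
            id="c", amplicon="amp1", chrom="chrSyn", strand="+",
            block_list=[], junctions=list(junctions),
        )

    def test_three_definitional_cases(self, scenario, atlas):
        locus = scenario["locus"]
        chains = {
            tx_id: self._chain(
                [("chrSyn", d, a, "+") for d, a in chain]
            )
            for tx_id, chain in scenario["expected_chains"].items()
        }
        assert classify_tier(chains["canonical"], atlas) == 1
        assert classify_tier(chains["altdonor_ex3-3"], atlas) == 2
        assert classify_tier(chains["altacceptor_ex5+15"], atlas) == 3

    def test_tier_monotone_under_atlas_growth(self, atlas):
        rng = np.random.default_rng(17)
        curated = sorted(atlas.exon_ends)
        unfiltered = sorted(atlas.unfiltered_exon_ends - atlas.exon_ends)
        for _ in range(300):
            junctions = []
            pos = 0
            for _ in range(rng.integers(1, 5)):
                d = pos + int(rng.integers(1, 50))
                a = d + int(rng.integers(25, 100))
                junctions.append(("chrSyn", d, a, "+"))
                pos = a
            chain = self._chain(junctions)
            # enrich the chain with some genuinely supported ends
            tier_before = classify_tier(chain, atlas)
            grown_curated = atlas.exon_ends | {
                e for j in junctions for e in [
                    (j[0], j[1], "end", j[3]), (j[0], j[2], "start", j[3])
                ][: rng.integers(0, 3)]
            }
            grown = dataclasses.replace(
                atlas,
                exon_ends=grown_curated,
                unfiltered_exon_ends=atlas.unfiltered_exon_ends | grown_curated,
            )
            assert classify_tier(chain, grown) <= tier_before

    def test_adding_missing_end_to_curated_lowers_tier(self, scenario, atlas):
        chain = self._chain(
            [("chrSyn", d, a, "+") for d, a in scenario["expected_chains"]["altacceptor_ex5+15"]]
        )
        assert classify_tier(chain, atlas) == 3
        missing = {
            e
            for j in chain.junctions
            for e in [(j[0], j[1], "end", j[3]), (j[0], j[2], "start", j[3])]
        }
        grown = dataclasses.replace(
            atlas,
            unfiltered_exon_ends=atlas.unfiltered_exon_ends | missing,
        )
        assert classify_tier(chain, grown) == 2
        fully = dataclasses.replace(atlas, exon_ends=atlas.exon_ends | missing)
        assert classify_tier(chain, fully) == 1


def _iso(counts_total, chain_tag):
    return IsoformChain(
        id=chain_tag, amplicon="amp1", chrom="chrSyn", strand="+",
        block_list=[], junctions=[("chrSyn", ord(chain_tag[0]) * 10, ord(chain_tag[0]) * 10 + 50, "+")],
        counts={"s1": counts_total},
    )


def _brute_force_top(chains, fraction):
    ordered = sorted(chains, key=lambda c: (-c.total_count, c.chain_key()))
    total = sum(c.total_count for c in ordered)
    if total == 0:
        return []
    best = None
    for k in range(1, len(ordered) + 1):
        if sum(c.total_count for c in ordered[:k]) / total >= fraction:
            best = ordered[:k]
            break
    return best


class TestTopIsoforms:
    def test_exact_80_percent_boundary(self):
        chains = [_iso(n, t) for n, t in zip([50, 30, 15, 5], "abcd")]
        assert [c.id for c in top_isoforms(chains, 0.8)] == ["a", "b"]

    def test_fraction_one_returns_everything(self):
        chains = [_iso(n, t) for n, t in zip([5, 3, 2], "abc")]
        assert len(top_isoforms(chains, 1.0)) == 3

    def test_zero_reads_gives_empty_selection(self):
        assert top_isoforms([_iso(0, "a")], 0.8) == []

    def test_matches_brute_force_on_random_counts(self):
        rng = np.random.default_rng(18)
        for _ in range(300):
            chains = [
                _iso(int(n), t)
                for n, t in zip(rng.integers(0, 100, size=6), "abcdef")
            ]
            frac = float(rng.uniform(0.05, 1.0))
            got = [c.id for c in top_isoforms(chains, frac)]
            want = [c.id for c in _brute_force_top(chains, frac)]
            assert got == want


class TestIsoformFrequencies:
    def test_simple_split(self):
        chains = [_iso(80, "a"), _iso(20, "b")]
        table = isoform_frequencies(chains)
        assert table.loc["a", "s1"] == pytest.approx(0.8)
        assert table.loc["b", "s1"] == pytest.approx(0.2)

    def test_frequencies_sum_to_one_per_sample(self, scenario):
        locus, atlas = scenario["locus"], scenario["atlas"]
        amp = locus.amplicons[0]
        reads, _ = simulate_long_reads(locus, n_reads=400, seed=19)
        assigned = [
            r for r in reads if assign_full_length(r, locus.amplicons) == amp.id
        ]
        chains = snap_and_collapse(assigned, atlas, amp)
        table = isoform_frequencies(chains)
        assert np.allclose(table.sum(axis=0), 1.0)
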