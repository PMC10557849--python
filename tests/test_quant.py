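"""PSI quantification and group-wise differential splicing."""

import numpy as np
import pytest

from isoatlas.atlas import (
    JunctionCountMatrix,
    annotation_source_from_transcripts,
    build_atlas,
)
from isoatlas.model import Exon, GenomicInterval, SpliceJunction
from isoatlas.quant import (
    differential_events,
    junction_clusters,
    psi_exon,
    psi_junction,
    terminal_exon_usage,
)
from isoatlas.simulate import (
    SpliceEvent,
    make_locus,
    simulate_junction_counts,
    simulate_psi_events,
)


def _j(donor, acceptor, strand="+"):
    return SpliceJunction("chr1", donor, acceptor, strand)


def _brute_force_components(junctions):
    """Independent union-find over the share-an-end relation."""
    keys = [j.key() for j in junctions]
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            k = parent[k]
        return k

    for a in keys:
        for b in keys:
            if a[0] != b[0] or a[3] != b[3]:
                continue
            if a[1] == b[1] or a[2] == b[2]:
                parent[find(a)] = find(b)
    comps = {}
    for k in keys:
        comps.setdefault(find(k), set()).add(k)
    return {frozenset(c) for c in comps.values()}


class TestJunctionClusters:
    def test_shared_donor_merges(self):
        clusters = junction_clusters([_j(10, 100), _j(10, 200)])
        assert len(clusters) == 1

    def test_disjoint_junctions_stay_apart(self):
        clusters = junction_clusters([_j(10, 100), _j(300, 400)])
        assert len(clusters) == 2

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ends = rng.integers(0, 12, size=(12, 2))
            junctions = list(
                { _j(int(min(d, a) * 10), int(max(d, a) * 10 + 105)) for d, a in ends }
            )
            got = {frozenset(c) for c in junction_clusters(junctions)}
            assert got == _brute_force_components(junctions)


class TestPsiJunction:
    def test_cluster_fraction(self):
        m = JunctionCountMatrix(
            [_j(10, 100), _j(10, 200)], ["s1"], np.array([[30], [10]]), np.array([40])
        )
        table = psi_junction(m)
        assert table.psi.iloc[0, 0] == pytest.approx(0.75)
        assert table.psi.iloc[1, 0] == pytest.approx(0.25)

    def test_singleton_cluster_is_one(self):
        m = JunctionCountMatrix([_j(10, 100)], ["s1"], np.array([[7]]), np.array([7]))
        assert psi_junction(m).psi.iloc[0, 0] == 1.0

    def test_zero_denominator_is_undefined_not_zero(self):
        m = JunctionCountMatrix(
            [_j(10, 100)], ["s1", "s2"], np.array([[5, 0]]), np.array([5, 1])
        )
        table = psi_junction(m)
        assert np.isnan(table.psi.iloc[0, 1])

    def test_cluster_psi_sums_to_one_per_sample(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 40, size=(6, 5))
        junctions = [_j(10, 100 + 30 * i) for i in range(3)] + [
            _j(500 + 40 * i, 900) for i in range(3)
        ]
        m = JunctionCountMatrix(junctions, [f"s{i}" for i in range(5)], counts, counts.sum(axis=0))
        table = psi_junction(m)
        for cluster in junction_clusters(junctions):
            rows = table.psi.loc[list(cluster)]
            sums = rows.sum(axis=0, skipna=False)
            for total in sums[~sums.isna()]:
                assert total == pytest.approx(1.0)

    def test_invariant_to_uniform_count_scaling(self):
        counts = np.array([[30, 4], [10, 6]])
        junctions = [_j(10, 100), _j(10, 200)]
        m1 = JunctionCountMatrix(junctions, ["a", "b"], counts, counts.sum(axis=0))
        m2 = JunctionCountMatrix(junctions, ["a", "b"], counts * 7, (counts * 7).sum(axis=0))
        assert np.allclose(psi_junction(m1).psi, psi_junction(m2).psi)


class TestPsiExon:
    @pytest.fixture()
    def cassette(self):
        """Inclusion junctions 30/50, exclusion 20 around exon [200, 300)."""
        junctions = [_j(100, 200), _j(300, 400), _j(100, 400)]
        counts = np.array([[30], [50], [20]])
        m = JunctionCountMatrix(junctions, ["s1"], counts, counts.sum(axis=0))
        exon = Exon(GenomicInterval("chr1", 200, 300, "+"))
        return m, exon

    def _atlas_for(self, matrix):
        from isoatlas.model import Transcript

        tx = Transcript(
            "t",
            [
                Exon(GenomicInterval("chr1", 50, 100, "+")),
                Exon(GenomicInterval("chr1", 200, 300, "+")),
                Exon(GenomicInterval("chr1", 400, 450, "+")),
            ],
        )
        return build_atlas(
            matrix,
            [annotation_source_from_transcripts("GENCODE", [tx])],
            min_samples=1,
        )

    def test_formula_by_hand(self, cassette):
        m, exon = cassette
        table = psi_exon(m, exon, self._atlas_for(m))
        # mean(30, 50) / (mean + 20) = 40/60
        assert table.psi.iloc[0, 0] == pytest.approx(40 / 60)

    def test_no_exclusion_gives_one(self, cassette):
        m, exon = cassette
        m.counts[2, 0] = 0
        table = psi_exon(m, exon, self._atlas_for(m))
        assert table.psi.iloc[0, 0] == pytest.approx(1.0)

    def test_simulated_cassette_recovers_true_inclusion(self):
        locus = make_locus(
            events=[SpliceEvent("skip", (3,))],
            weights={"canonical": 0.7, "skip_ex3": 0.3},
            seed=5,
        )
        matrix, _ = simulate_junction_counts(
            locus, n_samples=1, dispersion=0.0, libsize_range=(20000, 20000), seed=6
        )
        atlas = build_atlas(
            matrix, [annotation_source_from_transcripts("GENCODE", locus.catalog)]
        )
        exon = locus.canonical.exons[2]
        psi = psi_exon(matrix, exon, atlas).psi.iloc[0, 0]
        # denominator is in the thousands: 99% CI is a few points wide
        n = psi_exon(matrix, exon, atlas).denominator.iloc[0, 0]
        half_width = 2.58 * np.sqrt(0.7 * 0.3 / n)
        assert abs(psi - 0.7) < max(half_width, 0.02)


class TestTerminalExonUsage:
    def test_two_first_exons_split_80_20(self):
        locus = make_locus(
            events=[SpliceEvent("novel_first_exon")],
            weights={"canonical": 0.8, "novelfirst": 0.2},
            seed=7,
        )
        matrix, _ = simulate_junction_counts(
            locus, n_samples=2, dispersion=0.0, libsize_range=(30000, 30000), seed=8
        )
        atlas = build_atlas(
            matrix, [annotation_source_from_transcripts("GENCODE", locus.catalog)]
        )
        table = terminal_exon_usage(matrix, atlas, side="first")
        assert len(table.psi) == 2
        sums = table.psi.sum(axis=0)
        assert np.allclose(sums, 1.0)
        canon_first = (
            locus.chrom,
            locus.canonical.exons[0].start,
            locus.canonical.exons[0].end,
            "+",
        )
        assert abs(table.psi.loc[[canon_first]].iloc[0, 0] - 0.8) < 0.05

    def test_single_last_exon_usage_is_one(self, locus, atlas, scenario):
        matrix = scenario["observed"]
        table = terminal_exon_usage(matrix, atlas, side="last")
        assert np.allclose(table.psi.to_numpy(), 1.0)

    def test_missing_terminal_exons_is_an_error(self, scenario):
        import dataclasses

        bare = dataclasses.replace(scenario["atlas"], first_exons=[])
        with pytest.raises(ValueError, match="first"):
            terminal_exon_usage(scenario["observed"], bare, side="first")


def _brute_force_bh(pvals):
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


class TestDifferentialEvents:
    def test_identical_groups_are_null(self):
        table, groups, _ = simulate_psi_events(5, n_per_group=4, seed=9)
        # make both groups literally identical
        for s in [c for c in table.psi.columns if c.startswith("b")]:
            table.psi[s] = table.psi["a" + s[1:]].to_numpy()
        events = differential_events(table, groups)
        for e in events:
            assert e.delta_psi == pytest.approx(0.0)
            assert e.p_value > 0.9

    def test_q_values_match_brute_force_bh(self):
        table, groups, _ = simulate_psi_events(40, n_per_group=6, seed=10)
        events = differential_events(table, groups)
        p = np.array([e.p_value for e in events])
        q = np.array([e.q_value for e in events])
        assert np.allclose(q, _brute_force_bh(p))

    def test_planted_event_detected_and_top_ranked(self):
        table, groups, planted = simulate_psi_events(
            200, n_per_group=20, planted_delta=0.4, seed=11
        )
        events = differential_events(table, groups)
        best = min(events, key=lambda e: (e.q_value, e.p_value))
        assert best.event == planted
        assert abs(best.delta_psi) == pytest.approx(0.4, abs=0.08)

    def test_small_groups_rejected(self):
        table, groups, _ = simulate_psi_events(3, n_per_group=1, seed=12)
        with pytest.raises(ValueError):
            differential_events(table, groups)
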