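"""Scaffolder: pair mapping, insert estimation, links, ordering, emission."""

import numpy as np
import pytest

from dbgasm.kmer import revcomp_seq
from dbgasm.scaffold import (
    LibraryStats,
    PairMapping,
    ScaffoldError,
    ScaffoldLink,
    build_links,
    estimate_insert_stats,
    map_pairs,
    order_and_emit,
    read_pair_db,
    write_pair_db,
)
from dbgasm.stats import split_scaffolds


def random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


K = 15


class TestMapPairs:
    def test_same_contig_pair(self):
        c = random_seq(51, 500)
        r1 = c[100:136]
        r2 = revcomp_seq(c[264:300])
        db = map_pairs([c], [(("p/1", r1), ("p/2", r2))], K)
        assert len(db) == 1
        m = db[0]
        assert m.contig_a == m.contig_b == 0
        assert (m.strand_a, m.offset_a) == (True, 100)
        assert (m.strand_b, m.offset_b) == (False, 264)

    def test_cross_contig_pair(self):
        g = random_seq(52, 1000)
        a, b = g[:400], g[500:]
        r1 = g[300:336]                    # inside A
        r2 = revcomp_seq(g[700:736])       # inside B
        db = map_pairs([a, b], [(("p/1", r1), ("p/2", r2))], K)
        assert len(db) == 1
        m = db[0]
        assert (m.contig_a, m.contig_b) == (0, 1)
        assert m.offset_a == 300 and m.offset_b == 200

    def test_ambiguous_mate_dropped(self):
        c = random_seq(53, 300)
        r1 = c[50:86]
        r2 = revcomp_seq(c[200:236])
        db = map_pairs([c, c], [(("p/1", r1), ("p/2", r2))], K)
        assert db == []

    def test_half_mapped_pair_not_stored(self):
        c = random_seq(54, 300)
        r1 = c[50:86]
        db = map_pairs([c], [(("p/1", r1), ("p/2", "G" * 36))], K)
        assert db == []

    def test_db_round_trip(self, tmp_path):
        c = random_seq(55, 500)
        pairs = [((f"{i}/1", c[i:i + 36]),
                  (f"{i}/2", revcomp_seq(c[i + 164:i + 200])))
                 for i in range(0, 200, 7)]
        db = map_pairs([c], pairs, K)
        path = tmp_path / "pairs.tsv"
        write_pair_db(db, str(path))
        assert sorted(m.to_row() for m in db) == \
            [m.to_row() for m in read_pair_db(str(path))]


def synthetic_same_contig_db(spans, library="lib0"):
    return [PairMapping(library, 0, True, 0, 36, 0, False,
                        int(s) - 36, 36) for s in spans]


class TestInsertStats:
    def test_degenerate_spans(self):
        db = synthetic_same_contig_db([200] * 150)
        st = estimate_insert_stats(db, "lib0")
        assert st.median_insert == 200 and st.insert_sd == 0

    def test_normal_spans_recovered(self):
        rng = np.random.default_rng(56)
        spans = np.rint(rng.normal(200, 20, size=10_000))
        st = estimate_insert_stats(synthetic_same_contig_db(spans), "lib0")
        assert 198 <= st.median_insert <= 202
        assert 18 <= st.insert_sd <= 22

    def test_too_few_pairs_is_error_naming_library(self):
        db = synthetic_same_contig_db([200] * 99)
        with pytest.raises(ScaffoldError, match="lib0"):
            estimate_insert_stats(db, "lib0")


def cross_pair(offset_a, strand_a, offset_b, strand_b, library="lib0"):
    return PairMapping(library, 0, strand_a, offset_a, 36,
                       1, strand_b, offset_b, 36)


STATS = {"lib0": LibraryStats("lib0", 200.0, 20.0, 1000)}
LENS = [400, 500]


class TestBuildLinks:
    def test_three_pairs_make_a_link_two_do_not(self):
        pairs = [cross_pair(300 + i, True, 50 - i, False) for i in range(3)]
        assert len(build_links(pairs[:2], STATS, LENS)) == 0
        links = build_links(pairs, STATS, LENS)
        assert len(links) == 1
        assert links[0].n_pairs == 3

    def test_gap_arithmetic(self):
        # tails: (400 - 300) and (50 + 36); gap = 200 - 100 - 86 = 14
        links = build_links([cross_pair(300, True, 50, False)] * 3,
                            STATS, LENS)
        assert links[0].gap_estimate == pytest.approx(14.0)
        assert links[0].orientation_class == "FF"

    def test_contradictory_orientations_stay_separate(self):
        pairs = [cross_pair(300 + i, True, 50 - i, False) for i in range(3)]
        pairs += [cross_pair(300 + i, True, 50 - i, True) for i in range(3)]
        links = build_links(pairs, STATS, LENS)
        assert len(links) == 2
        assert {l.orientation_class for l in links} == {"FF", "FR"}

    def test_min_pairs_monotonicity(self):
        rng = np.random.default_rng(57)
        pairs = []
        for group in range(6):
            n = int(rng.integers(1, 7))
            pairs += [cross_pair(300, True, 40, False,
                                 library="lib0")] * n
            pairs += [cross_pair(10, False, 450, True)] * (6 - n)
        keys = lambda ls: {(l.contig_a, l.orient_a, l.contig_b, l.orient_b)
                           for l in ls}
        k2 = keys(build_links(pairs, STATS, LENS, min_pairs=2))
        k3 = keys(build_links(pairs, STATS, LENS, min_pairs=3))
        k4 = keys(build_links(pairs, STATS, LENS, min_pairs=4))
        assert k4 <= k3 <= k2


def simulate_scaffold_case(seed, gap=150, insert=500, sd=25, cov=30):
    """Genome cut into two contigs around an unassembled middle region."""
    from dbgasm.simulate import SimConfig, simulate_pairs
    g = random_seq(seed, 8000)
    a, b = g[:3900], g[3900 + gap:]
    cfg = SimConfig(genome_length=8000, coverage=cov, insert_mean=insert,
                    insert_sd=sd, seed=seed)
    sim = simulate_pairs(g, cfg)
    pairs = [((f"{i}/1", r1), (f"{i}/2", r2))
             for i, (r1, r2) in enumerate(zip(sim.reads_1, sim.reads_2))]
    return g, a, b, pairs


class TestOrderAndEmit:
    def test_two_contig_truth(self):
        """Known 150-base gap: one scaffold, right order and orientation,
        rendered gap close to truth, split inverts emission."""
        g, a, b, pairs = simulate_scaffold_case(58)
        db = map_pairs([a, b], pairs, K)
        stats = {"lib0": estimate_insert_stats(db, "lib0")}
        links = build_links(db, stats, [len(a), len(b)])
        assert len(links) == 1
        recs, rejected = order_and_emit(links, [a, b])
        assert len(recs) == 1 and rejected == []
        seq = recs[0][1]
        assert abs(seq.count("N") - 150) <= 15
        parts = [p for _n, p in split_scaffolds(recs)]
        assert parts in ([a, b], [revcomp_seq(b), revcomp_seq(a)])

    def test_three_contigs_one_scaffold(self):
        a = random_seq(59, 300)
        b = random_seq(60, 300)
        c = random_seq(61, 300)
        links = [
            ScaffoldLink(0, True, 1, True, 10, 50.0, 5.0),
            ScaffoldLink(1, True, 2, True, 8, 30.0, 5.0),
        ]
        recs, rejected = order_and_emit(links, [a, b, c])
        assert len(recs) == 1 and rejected == []
        parts = [p for _n, p in split_scaffolds(recs)]
        assert parts in ([a, b, c],
                         [revcomp_seq(c), revcomp_seq(b), revcomp_seq(a)])

    def test_negative_gap_rendered_as_single_N(self):
        a = random_seq(62, 200)
        b = random_seq(63, 200)
        links = [ScaffoldLink(0, True, 1, True, 5, -12.0, 4.0)]
        recs, _ = order_and_emit(links, [a, b])
        assert recs[0][1].count("N") == 1

    def test_every_contig_once(self):
        contigs = [random_seq(64 + i, 250) for i in range(5)]
        links = [
            ScaffoldLink(0, True, 1, True, 9, 20.0, 3.0),
            ScaffoldLink(3, False, 2, True, 7, 10.0, 3.0),
        ]
        recs, _ = order_and_emit(links, contigs)
        parts = [p for _n, p in split_scaffolds(recs)]
        canon = sorted(min(p, revcomp_seq(p)) for p in parts)
        assert canon == sorted(min(p, revcomp_seq(p)) for p in contigs)

    def test_cycle_closing_link_rejected(self):
        a = random_seq(70, 200)
        b = random_seq(71, 200)
        links = [
            ScaffoldLink(0, True, 1, True, 9, 20.0, 3.0),
            ScaffoldLink(1, True, 0, True, 4, 25.0, 3.0),  # closes a cycle
        ]
        recs, rejected = order_and_emit(links, [a, b])
        assert len(recs) == 1
        assert len(rejected) == 1 and rejected[0].n_pairs == 4

    def test_scaffold_length_accounting(self):
        a = random_seq(72, 300)
        b = random_seq(73, 300)
        links = [ScaffoldLink(0, True, 1, True, 6, 40.0, 4.0)]
        recs, _ = order_and_emit(links, [a, b])
        assert len(recs[0][1]) == 600 + 40
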