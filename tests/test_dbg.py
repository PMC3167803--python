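"""de Bruijn graph: linkage construction, simplification, chain extraction."""

import numpy as np
import pytest

from dbgasm.dbg import (
    add_read_linkages,
    build_linkages,
    check_edge_symmetry,
    estimate_M,
    extract_chains,
    remove_low_frequency_dead_ends,
    remove_tips,
    right_neighbors,
    simplify_and_extract,
)
from dbgasm.kmer import canonical, encode, revcomp_seq
from dbgasm.store import count_kmers


def build_graph(reads, k, n_parts=1):
    store = count_kmers(reads, k, n_parts=n_parts)
    build_linkages(store, reads)
    return store


def random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def sliding_reads(seq, length, copies=1):
    reads = [seq[i:i + length] for i in range(len(seq) - length + 1)]
    return reads * copies


def neighbor_oracle(store, reads, k):
    """Brute-force: the set of adjacent k-molecule pairs found in reads."""
    pairs = set()
    for read in reads:
        for i in range(len(read) - k):
            a = canonical(encode(read[i:i + k]), k)
            b = canonical(encode(read[i + 1:i + 1 + k]), k)
            pairs.add(frozenset((a, b)) if a != b else frozenset((a,)))
    return pairs


def graph_pairs(store):
    pairs = set()
    for rec in store.iter_records():
        for orient in (True, False):
            for (nbr, _o), _b in right_neighbors(store,
                                                 (rec.canonical, orient)):
                a, b = rec.canonical, nbr
                pairs.add(frozenset((a, b)) if a != b else frozenset((a,)))
    return pairs


class TestLinkages:
    def test_read_adjacency_matches_brute_force(self):
        reads = ["ACGTT"]
        store = build_graph(reads, 3)
        assert graph_pairs(store) == neighbor_oracle(store, reads, 3)
        assert check_edge_symmetry(store)

    def test_random_reads_match_brute_force(self):
        rng = np.random.default_rng(21)
        reads = [random_seq(rng, 30) for _ in range(25)]
        store = build_graph(reads, 7, n_parts=3)
        assert graph_pairs(store) == neighbor_oracle(store, reads, 7)
        assert check_edge_symmetry(store)

    def test_read_of_length_k_sets_no_bits(self):
        store = build_graph(["ACGTA"], 5)
        rec = next(store.iter_records())
        assert rec.adjacency == 0

    def test_strand_symmetric(self):
        """A read and its reverse complement give identical adjacency."""
        rng = np.random.default_rng(22)
        reads = [random_seq(rng, 40) for _ in range(10)]
        fwd = build_graph(reads, 7)
        rev = build_graph([revcomp_seq(r) for r in reads], 7)
        a = {(r.canonical, r.multiplicity, r.adjacency)
             for r in fwd.iter_records()}
        b = {(r.canonical, r.multiplicity, r.adjacency)
             for r in rev.iter_records()}
        assert a == b

    def test_absent_kmer_is_consistency_error(self):
        store = count_kmers(["ACGTA"], 3)
        from dbgasm.kmer import KmerError
        with pytest.raises(KmerError):
            add_read_linkages(store, "GGGGG")


class TestEstimateM:
    def test_bimodal_valley(self):
        """Error mode at 1, coverage mode at 30, smoothed valley at 4."""
        hist = {1: 1000, 2: 300, 3: 100, 4: 20, 5: 60, 6: 150}
        for m in range(7, 31):
            hist[m] = 150 + 15 * m  # rises to the coverage mode at 30
        assert estimate_M(hist) == 4

    def test_strictly_decreasing_falls_back(self):
        hist = {m: 1000 >> m for m in range(1, 10)}
        assert estimate_M(hist) == 2

    def test_clean_spectrum_threshold_below_all_kmers(self):
        """30x error-free: mode ~ coverage, no error mass, M <= min mult."""
        rng = np.random.default_rng(23)
        genome = random_seq(rng, 3000)
        store = build_graph(sliding_reads(genome, 36), 15)
        M = estimate_M(store.multiplicity_histogram())
        min_mult = min(r.multiplicity for r in store.iter_records())
        assert M <= max(2, min_mult)

    def test_empty_histogram(self):
        assert estimate_M({}) == 2


class TestLowFrequencyDeadEnds:
    def test_error_tip_removed_and_path_repaired(self):
        """One erroneous read end: its novel k-mers go, the clean graph
        is restored exactly."""
        rng = np.random.default_rng(24)
        genome = random_seq(rng, 200)
        clean = sliding_reads(genome, 36, copies=2)  # all true mult >= 2
        err_read = genome[:11] + "".join(
            "ACGT"[(("ACGT".index(c)) + 1) % 4] for c in genome[11:14])
        store = build_graph(clean + [err_read], 11)
        clean_store = build_graph(clean, 11)
        removed = remove_low_frequency_dead_ends(store, M=2)
        assert removed == 3  # the chain of three novel k-mers
        a = {(r.canonical, r.adjacency) for r in store.iter_records()}
        b = {(r.canonical, r.adjacency) for r in clean_store.iter_records()}
        assert a == b
        assert check_edge_symmetry(store)

    def test_clean_graph_unchanged(self):
        rng = np.random.default_rng(25)
        genome = random_seq(rng, 200)
        store = build_graph(sliding_reads(genome, 36, copies=2), 11)
        assert remove_low_frequency_dead_ends(store, M=2) == 0


class TestTips:
    k = 9

    def _with_branch(self, rng, novel):
        # branch hangs off the middle of the path, so the path's own
        # dead-end stubs on either side of the junction are >= 2k long
        genome = random_seq(rng, 160)
        reads = sliding_reads(genome, 30, copies=2)
        branch_read = genome[70:80] + novel
        clean = build_graph(reads, self.k)
        # fixture sanity: clean graph is one unbranched path and the
        # branch k-mers are genuinely novel (no canonical collisions)
        assert len(extract_chains(clean, min_coverage=0.0)) == 1
        n_novel = sum(
            1 for i in range(len(branch_read) - self.k + 1)
            if canonical(encode(branch_read[i:i + self.k]),
                         self.k) not in clean)
        assert n_novel == len(novel)
        reads += [branch_read, branch_read]  # mult 2: survives M pass
        return build_graph(reads, self.k), genome

    def test_short_branch_removed(self):
        """A (2k-1)-base dead-end branch off the path is clipped."""
        rng = np.random.default_rng(26)
        # 9 novel bases -> branch chain of 9 k-mers = 2k-1 = 17 bases
        store, genome = self._with_branch(rng, "GTGCATGAC")
        n_before = store.n_records
        removed = remove_tips(store)
        assert removed == 9
        assert store.n_records == n_before - 9
        assert check_edge_symmetry(store)

    def test_2k_branch_released(self):
        """A 2k-base dead-end branch is kept (boundary of the rule)."""
        rng = np.random.default_rng(26)
        # 10 novel bases -> chain of 10 k-mers = 2k = 18 bases
        store, _ = self._with_branch(rng, "GTGCATGACT")
        assert remove_tips(store) == 0

    def test_isolated_chain_is_not_a_tip(self):
        rng = np.random.default_rng(27)
        seq = random_seq(rng, 16)  # a lone 16-base chain, < 2k bases
        store = build_graph([seq], self.k)
        assert remove_tips(store) == 0
        assert store.n_records == 8


class TestExtractChains:
    def test_single_sequence_losslessly_compacted(self):
        rng = np.random.default_rng(28)
        seq = random_seq(rng, 500)
        store = build_graph([seq], 15)
        chains = extract_chains(store, min_coverage=0.0)
        assert len(chains) == 1
        assert chains[0].sequence in (seq, revcomp_seq(seq))
        assert chains[0].kmer_count == store.n_records

    def test_cycle_emitted_once_as_linear_chain(self):
        k = 7
        s = None
        for seed in range(100):  # need 40 distinct k-molecules on the cycle
            cand = random_seq(np.random.default_rng(seed), 40)
            wrapped = cand + cand[:k - 1]
            mols = {min(wrapped[i:i + k], revcomp_seq(wrapped[i:i + k]))
                    for i in range(40)}
            if len(mols) == 40:
                s = cand
                break
        assert s is not None
        store = build_graph([s + s[:k]], k)  # circular coverage + wrap edge
        assert store.n_records == 40
        chains = extract_chains(store, min_coverage=0.0)
        assert len(chains) == 1
        assert chains[0].kmer_count == 40
        assert len(chains[0].sequence) == 40 + k - 1

    def test_chain_partition_property(self):
        """Every surviving k-mer lands in exactly one extracted chain."""
        rng = np.random.default_rng(30)
        reads = [random_seq(rng, 30) for _ in range(40)]
        store = build_graph(reads, 9, n_parts=2)
        n = store.n_records
        chains = extract_chains(store, min_coverage=0.0)
        assert sum(c.kmer_count for c in chains) == n

    @pytest.mark.parametrize("n_parts", [2, 4])
    def test_partition_invariance(self, n_parts):
        rng = np.random.default_rng(31)
        genome = random_seq(rng, 1500)
        reads = sliding_reads(genome, 36)[::2]
        base = [(c.sequence, c.kmer_count, c.multiplicity_sum)
                for c in extract_chains(build_graph(reads, 13, 1), 0.0)]
        other = [(c.sequence, c.kmer_count, c.multiplicity_sum)
                 for c in extract_chains(build_graph(reads, 13, n_parts),
                                         0.0)]
        assert base == other

    def test_coverage_filter_discards(self):
        rng = np.random.default_rng(32)
        seq = random_seq(rng, 100)
        store = build_graph([seq], 15)  # every k-mer multiplicity 1
        assert extract_chains(store, min_coverage=2.0) == []


def test_full_stage_commutes_with_read_reverse_complement():
    rng = np.random.default_rng(33)
    genome = random_seq(rng, 800)
    reads = sliding_reads(genome, 36)[::3]
    fwd_store = build_graph(reads, 13)
    rev_store = build_graph([revcomp_seq(r) for r in reads], 13)
    a, _ = simplify_and_extract(fwd_store, min_coverage=0.0)
    b, _ = simplify_and_extract(rev_store, min_coverage=0.0)
    assert [c.sequence for c in a] == [c.sequence for c in b]


def test_pipeline_unitigs_match_naive_oracle(naive_compactor):
    """Partitioned compaction equals single-table string compaction."""
    rng = np.random.default_rng(34)
    for _ in range(5):
        genome = random_seq(rng, 900)
        reads = sliding_reads(genome, 36)[:: int(rng.integers(1, 4))]
        store = build_graph(reads, 13, n_parts=3)
        chains = sorted(c.sequence
                        for c in extract_chains(store, min_coverage=0.0))
        assert chains == naive_compactor(reads, 13)
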