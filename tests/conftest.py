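"""Shared fixtures: simulated datasets and a naive de Bruijn oracle.

The naive oracle compacts a single-table string de Bruijn graph with no
bit packing, no partitioning and no canonical-code arithmetic; it is the
independent reference the partitioned pipeline is checked against.
"""

from collections import defaultdict

import pytest

from dbgasm.kmer import revcomp_seq
from dbgasm.simulate import SimConfig, simulate_genome, simulate_pairs


def naive_unitigs(reads, k):
    """String-space de Bruijn compaction: maximal unambiguous paths.

    Works on raw k-mer strings with both strands materialized; returns
    the sorted list of canonical (lexicographically smaller strand)
    unitig sequences.
    """
    out_edges = defaultdict(set)
    in_edges = defaultdict(set)
    kmers = set()
    for read in reads:
        for strand in (read, revcomp_seq(read)):
            prev = None
            for i in range(len(strand) - k + 1):
                cur = strand[i:i + k]
                kmers.add(cur)
                if prev is not None:
                    out_edges[prev].add(cur)
                    in_edges[cur].add(prev)
                prev = cur

    def is_start(x):
        if len(in_edges[x]) != 1:
            return True
        (parent,) = in_edges[x]
        return len(out_edges[parent]) != 1

    visited = set()  # raw k-mers; each unitig is walked on both strands
    unitigs = set()

    def walk(start):
        path = [start]
        visited.add(start)
        while True:
            cur = path[-1]
            if len(out_edges[cur]) != 1:
                break
            (nxt,) = out_edges[cur]
            if not (len(in_edges[nxt]) == 1 and nxt not in visited):
                break
            path.append(nxt)
            visited.add(nxt)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        unitigs.add(min(seq, revcomp_seq(seq)))

    for x in sorted(kmers):
        if x not in visited and is_start(x):
            walk(x)
    for x in sorted(kmers):  # leftovers are cycles
        if x not in visited:
            walk(x)
    return sorted(unitigs)


@pytest.fixture(scope="session")
def naive_compactor():
    return naive_unitigs


@pytest.fixture(scope="session")
def clean_sim():
    """Repeat-free 20 kb genome with error-free 36 bp pairs at 30x."""
    genome = simulate_genome(20_000, seed=123, repeat_free_k=21)
    cfg = SimConfig(genome_length=20_000, coverage=30.0, seed=123)
    sim = simulate_pairs(genome, cfg)
    return genome, sim


@pytest.fixture(scope="session")
def clean_reads(clean_sim):
    _genome, sim = clean_sim
    return sim.reads_1 + sim.reads_2
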