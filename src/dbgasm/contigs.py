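"""Sequence graph over unitigs: read threading, bubble merging, contigs.

Every unitig becomes a node together with its twin (the reverse
complement); a signed identifier addresses the pair, ``-n`` being the twin
of ``n``. Edges are created only by threading the original reads back
through the unitigs: two adjacent k-mers of a read falling in different
nodes create (or re-support) a directed edge, mirrored on the twins, so no
mapping information about individual reads is retained.

Bubbles — pairs of short parallel paths sharing a source and sink, caused
by heterozygous SNPs or internal read errors — are found by a Tour-bus
style shortest-path sweep from each branching node, with nodes visited in
order of cumulative path length in bases. A detected pair is merged iff
the parallel path sequences differ by at most ``max_len_diff`` bases in
length and align with at least ``min_identity`` identity; the
lower-coverage branch is folded onto the higher-coverage one.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align

from .dbg import LinearChain
from .kmer import enumerate_kmers, revcomp_seq, sanitize_read

MAX_LEN_DIFF = 2       # merge criterion: <= 2 bp path length difference
MIN_IDENTITY = 0.90    # merge criterion: >= 90% alignment identity


@dataclass
class MergeEvent:
    source: int
    sink: int
    kept_path: Tuple[int, ...]
    dropped_path: Tuple[int, ...]
    dropped_bases: int


class SequenceGraph:
    """Bidirected unitig graph with twin-symmetric edges."""

    def __init__(self, k: int):
        self.k = k
        self.seqs: Dict[int, str] = {}      # node_id (> 0) -> forward seq
        self.cov: Dict[int, float] = {}     # node_id -> chain coverage
        self._out: Dict[int, Set[int]] = {}  # signed id -> signed neighbors
        self._support: Dict[Tuple[int, int], int] = {}

    # -- construction -------------------------------------------------------

    def add_node(self, node_id: int, seq: str, coverage: float) -> None:
        assert node_id > 0
        self.seqs[node_id] = seq
        self.cov[node_id] = coverage

    def seq(self, signed_id: int) -> str:
        s = self.seqs[abs(signed_id)]
        return s if signed_id > 0 else revcomp_seq(s)

    def _edge_key(self, u: int, v: int) -> Tuple[int, int]:
        return min((u, v), (-v, -u))

    def add_edge(self, u: int, v: int, support: int = 1) -> None:
        key = self._edge_key(u, v)
        if key not in self._support:
            self._support[key] = 0
            self._out.setdefault(u, set()).add(v)
            self._out.setdefault(-v, set()).add(-u)
        self._support[key] += support

    def remove_edge(self, u: int, v: int) -> None:
        key = self._edge_key(u, v)
        if key in self._support:
            del self._support[key]
            self._out[u].discard(v)
            self._out[-v].discard(-u)

    def support(self, u: int, v: int) -> int:
        return self._support.get(self._edge_key(u, v), 0)

    def out_neighbors(self, u: int) -> List[int]:
        return sorted(self._out.get(u, ()))

    def in_neighbors(self, u: int) -> List[int]:
        return [-v for v in self.out_neighbors(-u)]

    def out_degree(self, u: int) -> int:
        return len(self._out.get(u, ()))

    def in_degree(self, u: int) -> int:
        return self.out_degree(-u)

    def remove_node(self, node_id: int) -> None:
        nid = abs(node_id)
        for u in (nid, -nid):
            for v in list(self._out.get(u, ())):
                self.remove_edge(u, v)
            for v in list(self.in_neighbors(u)):
                self.remove_edge(v, u)
        self._out.pop(nid, None)
        self._out.pop(-nid, None)
        del self.seqs[nid]
        del self.cov[nid]

    @property
    def node_ids(self) -> List[int]:
        return sorted(self.seqs)

    def check_twin_symmetry(self) -> bool:
        for u, vs in self._out.items():
            for v in vs:
                if -u not in self._out.get(-v, ()):
                    return False
        return True


def build_sequence_graph(unitigs: Sequence[Tuple[str, float]],
                         reads: Iterable[str], k: int) -> SequenceGraph:
    """Nodes from unitigs; edges from adjacent read k-mers in distinct nodes.

    ``unitigs`` is a sequence of (sequence, coverage) pairs. A read k-mer
    absent from every node (it was filtered upstream) silently breaks the
    adjacency at that position.
    """
    graph = SequenceGraph(k)
    index: Dict[int, Tuple[int, bool]] = {}  # canon code -> (node_id, canon?)
    for i, (seq, coverage) in enumerate(unitigs, start=1):
        graph.add_node(i, seq, coverage)
        for _pos, canon, is_canon in enumerate_kmers(seq, k):
            index[canon] = (i, is_canon)
    for read in reads:
        read = sanitize_read(read)
        prev: Optional[int] = None  # signed node of previous k-mer
        prev_pos = -2
        for pos, canon, is_canon in enumerate_kmers(read, k):
            hit = index.get(canon)
            if hit is None:
                prev = None
                continue
            nid, node_canon = hit
            signed = nid if (is_canon == node_canon) else -nid
            if prev is not None and pos == prev_pos + 1 and signed != prev:
                graph.add_edge(prev, signed)
            prev, prev_pos = signed, pos
    return graph


def sequence_graph_from_chains(chains: Sequence[LinearChain],
                               reads: Iterable[str], k: int
                               ) -> SequenceGraph:
    # node coverage is mean k-mer multiplicity: unlike the chain-emission
    # coverage (multiplicity / sequence length) it is not diluted by the
    # k-1 overlap on short nodes, so bubble arms compare fairly
    return build_sequence_graph(
        [(c.sequence, c.multiplicity_sum / c.kmer_count) for c in chains],
        reads, k)


# ---------------------------------------------------------------------------
# Bubble detection and merging (Tour-bus style)

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def alignment_identity(a: str, b: str) -> float:
    """Matches over alignment length for a unit-cost global alignment."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length if length else 1.0


def _path_interior_seq(graph: SequenceGraph, path: Sequence[int]) -> str:
    """Bases contributed strictly between source and sink of a path."""
    k = graph.k
    return "".join(graph.seq(v)[k - 1:] for v in path[1:-1])


def _path_cov(graph: SequenceGraph, path: Sequence[int]) -> float:
    interior = path[1:-1]
    if not interior:
        return float("inf")  # a direct edge outranks any detour
    w = [len(graph.seq(v)) for v in interior]
    c = [graph.cov[abs(v)] for v in interior]
    return float(np.average(c, weights=w))


def _find_bubble(graph: SequenceGraph, source: int, max_depth: int
                 ) -> Optional[Tuple[List[int], List[int]]]:
    """Tour-bus sweep from ``source``: first reconvergent path pair.

    Nodes are visited in order of cumulative path length in bases from the
    source; when a node is reached a second time along a different parent,
    the two source-rooted paths form the candidate bubble.
    """
    k = graph.k
    # distance = interior bases between the source's end and a node's start
    dist: Dict[int, int] = {source: 0}
    parent: Dict[int, Optional[int]] = {source: None}
    heap: List[Tuple[int, int, Optional[int]]] = []
    for v in graph.out_neighbors(source):
        heapq.heappush(heap, (0, v, source))
    while heap:
        d, v, par = heapq.heappop(heap)
        if d > max_depth:
            continue
        if v in dist:
            # second arrival: reconstruct both paths back to the source
            path_a = _trace(parent, v)
            path_b = _trace(parent, par) + [v]
            if path_a[0] == source and path_b[0] == source:
                return path_a, path_b
            continue
        dist[v] = d
        parent[v] = par
        step = d + len(graph.seq(v)) - (k - 1)
        for w in graph.out_neighbors(v):
            if w == source or w == -source or w == -v:
                continue
            heapq.heappush(heap, (step, w, v))
    return None


def _trace(parent: Dict[int, Optional[int]], v: int) -> List[int]:
    path = [v]
    while parent.get(path[-1]) is not None:
        path.append(parent[path[-1]])
    return path[::-1]


def _mergeable(graph: SequenceGraph, path_a: List[int], path_b: List[int],
               max_len_diff: int, min_identity: float) -> bool:
    seq_a = _path_interior_seq(graph, path_a)
    seq_b = _path_interior_seq(graph, path_b)
    if abs(len(seq_a) - len(seq_b)) > max_len_diff:
        return False
    return alignment_identity(seq_a, seq_b) >= min_identity


def _interior_is_private(graph: SequenceGraph, path: Sequence[int]) -> bool:
    """Interior nodes must connect only along the path (clean bubble arm)."""
    for i, v in enumerate(path[1:-1], start=1):
        if graph.in_neighbors(v) != sorted([path[i - 1]]):
            return False
        if graph.out_neighbors(v) != sorted([path[i + 1]]):
            return False
    return True


def merge_bubbles(graph: SequenceGraph,
                  max_len_diff: int = MAX_LEN_DIFF,
                  min_identity: float = MIN_IDENTITY,
                  max_depth_factor: int = 5) -> List[MergeEvent]:
    """Detect and merge bubbles until no mergeable bubble remains.

    The lower-coverage arm is removed and its coverage mass folded onto
    the higher-coverage arm; edge support is transferred. Returns the log
    of merge events (sequence content discarded is accounted there).
    """
    max_depth = max_depth_factor * graph.k
    events: List[MergeEvent] = []
    changed = True
    while changed:
        changed = False
        for source in list(graph.node_ids):
            if source not in graph.seqs:
                continue
            for s in (source, -source):
                if graph.out_degree(s) < 2:
                    continue
                found = _find_bubble(graph, s, max_depth)
                if found is None:
                    continue
                path_a, path_b = found
                if path_a[-1] != path_b[-1]:
                    continue
                interior_a = set(map(abs, path_a[1:-1]))
                interior_b = set(map(abs, path_b[1:-1]))
                if interior_a & interior_b:
                    continue  # not internally disjoint
                if not (_interior_is_private(graph, path_a)
                        and _interior_is_private(graph, path_b)):
                    continue
                if not _mergeable(graph, path_a, path_b,
                                  max_len_diff, min_identity):
                    continue
                keep, drop = path_a, path_b
                if _path_cov(graph, path_b) > _path_cov(graph, path_a):
                    keep, drop = path_b, path_a
                events.append(_apply_merge(graph, keep, drop))
                changed = True
                break  # adjacency changed; rescan this source
    return events


def _apply_merge(graph: SequenceGraph, keep: List[int], drop: List[int]
                 ) -> MergeEvent:
    dropped_seq = _path_interior_seq(graph, drop)
    drop_mass = sum(
        graph.cov[abs(v)] * len(graph.seq(v)) for v in drop[1:-1])
    keep_len = sum(len(graph.seq(v)) for v in keep[1:-1])
    # fold coverage of the dropped arm onto the kept arm
    for v in keep[1:-1]:
        graph.cov[abs(v)] += drop_mass / keep_len if keep_len else 0.0
    # transfer entry/exit edge support onto the kept arm
    if len(keep) >= 2:
        graph.add_edge(keep[0], keep[1],
                       support=graph.support(drop[0], drop[1]))
        graph.add_edge(keep[-2], keep[-1],
                       support=graph.support(drop[-2], drop[-1]))
    for v in drop[1:-1]:
        graph.remove_node(v)
    if len(drop) == 2:  # direct parallel edge
        graph.remove_edge(drop[0], drop[1])
    return MergeEvent(keep[0], keep[-1], tuple(keep), tuple(drop),
                      len(dropped_seq))


# ---------------------------------------------------------------------------
# Cleanup and contig emission

def remove_node_tips(graph: SequenceGraph, min_keep_len: Optional[int] = None
                     ) -> int:
    """Remove dead-ended nodes shorter than 2k attached at a branch."""
    if min_keep_len is None:
        min_keep_len = 2 * graph.k
    removed = 0
    changed = True
    while changed:
        changed = False
        for nid in list(graph.node_ids):
            if nid not in graph.seqs or len(graph.seqs[nid]) >= min_keep_len:
                continue
            for s in (nid, -nid):
                if graph.in_degree(s) == 0 and graph.out_degree(s) > 0:
                    # dead-ended on the left; tip iff it meets a branch
                    nexts = graph.out_neighbors(s)
                    if any(graph.in_degree(v) > 1 or graph.out_degree(v) > 1
                           for v in nexts):
                        graph.remove_node(nid)
                        removed += 1
                        changed = True
                        break
    return removed


def remove_low_coverage_nodes(graph: SequenceGraph,
                              cutoff: Optional[float] = None,
                              rel_cutoff: float = 0.5) -> int:
    """Drop nodes below the coverage cutoff (default 0.5 x median)."""
    if not graph.seqs:
        return 0
    if cutoff is None:
        cutoff = rel_cutoff * float(np.median(list(graph.cov.values())))
    doomed = [nid for nid in graph.node_ids if graph.cov[nid] < cutoff]
    for nid in doomed:
        graph.remove_node(nid)
    return len(doomed)


def _linear_runs(graph: SequenceGraph) -> List[List[int]]:
    """Maximal unbranched signed-node runs, each twin pair used once."""
    runs: List[List[int]] = []
    seen: Set[int] = set()
    for nid in graph.node_ids:
        if nid in seen:
            continue
        run = [nid]
        # extend right
        while True:
            cur = run[-1]
            outs = graph.out_neighbors(cur)
            if len(outs) != 1:
                break
            nxt = outs[0]
            if graph.in_degree(nxt) != 1 or abs(nxt) in seen \
                    or abs(nxt) in {abs(x) for x in run}:
                break
            run.append(nxt)
        # extend left
        while True:
            cur = run[0]
            ins = graph.in_neighbors(cur)
            if len(ins) != 1:
                break
            prv = ins[0]
            if graph.out_degree(prv) != 1 or abs(prv) in seen \
                    or abs(prv) in {abs(x) for x in run}:
                break
            run.insert(0, prv)
        seen.update(abs(x) for x in run)
        runs.append(run)
    return runs


def run_sequence(graph: SequenceGraph, run: Sequence[int]) -> str:
    k = graph.k
    seq = graph.seq(run[0])
    for v in run[1:]:
        seq += graph.seq(v)[k - 1:]
    return seq


def finalize_contigs(graph: SequenceGraph, min_len: int = 100,
                     low_cov_cutoff: Optional[float] = None,
                     rel_cutoff: float = 0.5,
                     ) -> List[Tuple[str, float]]:
    """Cleanup and contig emission after bubble merging.

    Node-level tips and low-coverage nodes are removed, remaining linear
    node runs concatenated (k-1 overlaps collapsed), and contigs of at
    least ``min_len`` bases emitted as (sequence, coverage) in canonical
    sorted order, one strand per twin pair.
    """
    remove_node_tips(graph)
    remove_low_coverage_nodes(graph, cutoff=low_cov_cutoff,
                              rel_cutoff=rel_cutoff)
    contigs: List[Tuple[str, float]] = []
    for run in _linear_runs(graph):
        seq = run_sequence(graph, run)
        if len(seq) < min_len:
            continue
        w = [len(graph.seq(v)) for v in run]
        c = [graph.cov[abs(v)] for v in run]
        coverage = float(np.average(c, weights=w))
        rc = revcomp_seq(seq)
        contigs.append((min(seq, rc), coverage))
    contigs.sort()
    return contigs
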