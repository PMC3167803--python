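"""Preliminary de Bruijn graph: read-derived linkages and simplification.

Nodes are canonical k-mers held in a :class:`~dbgasm.store.PartitionedStore`;
edges live in each record's 8-bit adjacency mask. The low nibble holds the
right-extensions of the canonical strand (bit index = 2-bit code of the
extension base) and the high nibble holds the right-extensions of the
reverse-complement strand — equivalently, the left-extensions of the
canonical strand indexed by the *complement* of the left base. An edge is
created if and only if the two k-mers are adjacent in at least one input
read; neighbours are never inferred by probing all possible extensions, so
no spurious edges connecting k-mers that co-occur in no read can arise.

Simplification proceeds in three passes: (1) round-by-round removal of
low-multiplicity dead-end k-mers below an automatically estimated
threshold M, (2) clipping of tips (dead-end chains attached to a branching
node) shorter than 2k bases, and (3) extraction of maximal linear chains
(unitigs) with a chain-coverage filter.

An *oriented node* is the pair ``(code, orient)`` where ``orient`` True
means the canonical strand read left-to-right. Walking "right" from an
oriented node follows the extensions recorded in that orientation's
nibble; walking left is walking right on the opposite orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .kmer import (
    BASE_TO_CODE,
    CODE_TO_BASE,
    canonical,
    decode,
    revcomp,
    revcomp_seq,
    partition_of,
    sanitize_read,
)
from .store import PartitionedStore

OrientedNode = Tuple[int, bool]  # (canonical code, True = canonical strand)

_POPCOUNT4 = [bin(i).count("1") for i in range(16)]


# ---------------------------------------------------------------------------
# Oriented-node primitives

def fwd_code(code: int, orient: bool, k: int) -> int:
    """Packed code of the oriented strand read left-to-right."""
    return code if orient else revcomp(code, k)


def right_nibble(adj: int, orient: bool) -> int:
    return adj & 0xF if orient else (adj >> 4) & 0xF


def right_bit(orient: bool, base: int) -> int:
    """Adjacency bit for a right-extension by ``base`` in ``orient``."""
    return (1 << base) if orient else (1 << (4 + base))


def right_degree(store: PartitionedStore, node: OrientedNode) -> int:
    code, orient = node
    return _POPCOUNT4[right_nibble(store.adjacency(code), orient)]


def left_degree(store: PartitionedStore, node: OrientedNode) -> int:
    return right_degree(store, (node[0], not node[1]))


def step_right(code: int, orient: bool, base: int, k: int) -> OrientedNode:
    """Follow a right-extension edge; returns the neighbour oriented node."""
    mask2 = (1 << (2 * k)) - 1
    raw = ((fwd_code(code, orient, k) << 2) | base) & mask2
    canon = canonical(raw, k)
    return canon, raw == canon


def right_neighbors(store: PartitionedStore,
                    node: OrientedNode) -> List[Tuple[OrientedNode, int]]:
    """All (neighbour oriented node, extension base) to the right."""
    code, orient = node
    nib = right_nibble(store.adjacency(code), orient)
    k = store.k
    return [(step_right(code, orient, b, k), b)
            for b in range(4) if nib & (1 << b)]


def back_bit(node: OrientedNode, neighbor: OrientedNode, k: int) -> int:
    """The neighbour's adjacency bit that points back (left) at ``node``.

    A left-extension of the neighbour's arrival orientation is stored as a
    right-extension of its opposite orientation, indexed by the complement
    of the left base — which is the first base of ``node``'s oriented form.
    """
    first = (fwd_code(node[0], node[1], k) >> (2 * (k - 1))) & 3
    return right_bit(not neighbor[1], first ^ 3)


def clear_edges_of(store: PartitionedStore, code: int,
                   doomed: Set[int]) -> None:
    """Clear every surviving neighbour's bit that points at ``code``."""
    k = store.k
    for orient in (True, False):
        for nbr, _base in right_neighbors(store, (code, orient)):
            if nbr[0] in doomed:
                continue
            store.clear_adjacency(nbr[0], back_bit((code, orient), nbr, k))


# ---------------------------------------------------------------------------
# Linkage construction (stage ii, part 1)

def add_read_linkages(store: PartitionedStore, read: str) -> None:
    """Set adjacency bits for every pair of adjacent k-mers in ``read``.

    For the k-mer at position i the extension bases are S[i-1] (left) and
    S[i+k] (right); at the read boundary the extension base is absent and
    no bit is set in that direction. Bits are recorded on the canonical
    record with nibble and base complement-swapped when the occurrence is
    on the non-canonical strand.
    """
    read = sanitize_read(read)
    k = store.k
    n = len(read)
    if n < k:
        return
    mask2 = (1 << (2 * k)) - 1
    shift_hi = 2 * (k - 1)
    code = 0
    for ch in read[:k]:
        code = (code << 2) | BASE_TO_CODE[ch]
    rc = revcomp(code, k)
    for i in range(n - k + 1):
        if i > 0:
            b = BASE_TO_CODE[read[i + k - 1]]
            code = ((code << 2) | b) & mask2
            rc = (rc >> 2) | ((b ^ 3) << shift_hi)
        is_canon = code <= rc
        canon = code if is_canon else rc
        bits = 0
        if i + k < n:  # right extension exists
            r = BASE_TO_CODE[read[i + k]]
            bits |= right_bit(is_canon, r)
        if i > 0:  # left extension exists
            l = BASE_TO_CODE[read[i - 1]]
            bits |= right_bit(not is_canon, l ^ 3)
        if bits:
            store.or_adjacency(canon, bits)


def build_linkages(store: PartitionedStore, reads: Iterable[str]) -> None:
    for read in reads:
        add_read_linkages(store, read)


def check_edge_symmetry(store: PartitionedStore) -> bool:
    """Every recorded edge has its reciprocal bit set (full scan)."""
    k = store.k
    for rec in store.iter_records():
        for orient in (True, False):
            node = (rec.canonical, orient)
            for nbr, _b in right_neighbors(store, node):
                adj = store.adjacency(nbr[0])
                if nbr[0] not in store:
                    return False
                if not adj & back_bit(node, nbr, k):
                    return False
    return True


# ---------------------------------------------------------------------------
# Multiplicity threshold estimation

def estimate_M(histogram: Dict[int, int]) -> int:
    """Estimate the minimum-multiplicity threshold from the k-mer spectrum.

    The spectrum of a shotgun dataset with errors is bimodal: an error mode
    at multiplicity ~1 and a coverage mode near the sequencing depth. M is
    the multiplicity at the first local minimum of the smoothed spectrum
    (moving average, window 3) between the two modes; when no interior
    minimum exists (e.g. a strictly decreasing spectrum) the conservative
    fallback is M = 2.
    """
    if not histogram:
        return 2
    max_mult = max(histogram)
    counts = np.zeros(max_mult + 2, dtype=float)
    for m, c in histogram.items():
        counts[m] = c
    # window-3 moving average over multiplicities 1..max
    sm = counts.copy()
    for m in range(1, max_mult + 1):
        lo, hi = max(1, m - 1), min(max_mult, m + 1)
        sm[m] = counts[lo:hi + 1].mean()
    if max_mult < 4:
        return 2
    # coverage mode: spectrum peak beyond the error slope at 1-2
    mode = 3 + int(np.argmax(sm[3:max_mult + 1]))
    for m in range(2, mode):
        if sm[m] <= sm[m - 1] and sm[m] <= sm[m + 1]:
            return m
    return 2


# ---------------------------------------------------------------------------
# Simplification pass 1: low-frequency dead-end k-mers

def is_dead_end(store: PartitionedStore, code: int) -> bool:
    adj = store.adjacency(code)
    return (adj & 0xF) == 0 or (adj >> 4) == 0


def remove_low_frequency_dead_ends(store: PartitionedStore, M: int) -> int:
    """Round-by-round removal of dead-end k-mers with multiplicity < M.

    Each round snapshots the candidate set, removes it, and repairs the
    neighbours' adjacency bits; removal exposes new dead ends, so rounds
    repeat until one removes nothing. Returns total k-mers removed.
    """
    total = 0
    while True:
        doomed: Set[int] = set()
        for part in store.partitions:
            cand = ~part.dead & (part.mult < M) & (
                ((part.adj & 0xF) == 0) | ((part.adj >> 4) == 0))
            doomed.update(int(c) for c in part.codes[cand])
        if not doomed:
            break
        for code in doomed:
            clear_edges_of(store, code, doomed)
        for code in doomed:
            store.remove_record(code)
        total += len(doomed)
    store.compact()
    return total


# ---------------------------------------------------------------------------
# Simplification pass 2: tip clipping

def _walk_chain(store: PartitionedStore, start: OrientedNode,
                stop_at: Optional[OrientedNode] = None,
                visited: Optional[Set[int]] = None,
                ) -> Tuple[List[OrientedNode], str]:
    """Extend a chain rightward from ``start`` until it stops.

    Returns (chain, reason); reason is one of:
      'dead'   — last node has no right extension
      'branch' — last node has >1 right extensions (it stays in the chain)
      'merge'  — the unique next node has left-degree != 1, or is visited
      'cycle'  — the unique next node closes the walk onto ``stop_at`` or
                 onto a node already in the chain, in the SAME orientation
    A k-molecule may legitimately appear twice in one chain in opposite
    orientations (the two raw k-mers of an inverted repeat); only a
    repeat of the same oriented node is a cycle.
    """
    chain = [start]
    in_chain = {start}
    while True:
        cur = chain[-1]
        nbrs = right_neighbors(store, cur)
        if len(nbrs) == 0:
            return chain, "dead"
        if len(nbrs) > 1:
            return chain, "branch"
        nxt, _base = nbrs[0]
        if stop_at is not None and nxt == stop_at:
            return chain, "cycle"
        if nxt in in_chain:
            return chain, "cycle"
        if visited is not None and nxt[0] in visited:
            return chain, "merge"
        if left_degree(store, nxt) != 1:
            return chain, "merge"
        chain.append(nxt)
        in_chain.add(nxt)


def remove_tips(store: PartitionedStore, k: int | None = None) -> int:
    """Clip dead-end chains shorter than 2k bases off branching nodes.

    A tip starts at a dead-end k-mer and terminates where the chain meets
    a branching node; chains of >= 2k bases are released (kept), and an
    isolated chain that dead-ends on both sides is a candidate contig, not
    a tip, and is never clipped. Applied iteratively to a fixed point.
    Returns the number of k-mers removed.
    """
    if k is None:
        k = store.k
    total = 0
    while True:
        removed_this_round = 0
        starts: List[int] = []
        for part in store.partitions:
            rd = (part.adj & 0xF) == 0
            ld = (part.adj >> 4) == 0
            # one-sided dead ends only: both-dead is isolated, not a tip
            cand = ~part.dead & (rd ^ ld)
            starts.extend(int(c) for c in part.codes[cand])
        for code in starts:
            if code not in store:
                continue  # removed earlier this round
            adj = store.adjacency(code)
            right_dead = (adj & 0xF) == 0
            left_dead = (adj >> 4) == 0
            if right_dead == left_dead:
                continue  # adjacency changed earlier this round
            # walk away from the dead side
            orient = not right_dead
            chain, reason = _walk_chain(store, (code, orient))
            if reason == "dead":
                continue  # isolated linear chain: keep
            if reason == "branch":
                # last node branches forward: it is the junction, keep it
                tip = chain[:-1]
            else:  # 'merge' / 'cycle': junction lies beyond the chain
                tip = chain
            if not tip:
                continue
            seq_len = len(tip) + k - 1
            if seq_len >= 2 * k:
                continue  # released
            doomed = {c for c, _o in tip}
            for c in doomed:
                clear_edges_of(store, c, doomed)
            for c in doomed:
                store.remove_record(c)
            removed_this_round += len(doomed)
        if removed_this_round == 0:
            break
        total += removed_this_round
        store.compact()
    return total


# ---------------------------------------------------------------------------
# Linear-chain (unitig) extraction

@dataclass
class LinearChain:
    sequence: str
    kmer_count: int
    multiplicity_sum: int

    @property
    def coverage(self) -> float:
        return self.multiplicity_sum / len(self.sequence)


def chain_sequence(store: PartitionedStore, chain: Sequence[OrientedNode]
                   ) -> str:
    k = store.k
    first = decode(fwd_code(chain[0][0], chain[0][1], k), k)
    tail = "".join(
        CODE_TO_BASE[fwd_code(c, o, k) & 3] for c, o in chain[1:]
    )
    return first + tail


def _emit(store: PartitionedStore, chain: Sequence[OrientedNode]
          ) -> LinearChain:
    seq = chain_sequence(store, chain)
    rc = revcomp_seq(seq)
    if rc < seq:
        seq = rc
    mult = sum(store.multiplicity(c) for c, _o in chain)
    return LinearChain(seq, len(chain), mult)


def extract_chains(store: PartitionedStore, min_coverage: float = 1.0,
                   ) -> List[LinearChain]:
    """Decompose the simplified graph into maximal linear chains.

    Step 1 walks one direction from each dead-end k-mer; when both chain
    terminals are dead ends the chain is kept by the walk starting in the
    lower-indexed partition (ties broken by the smaller terminal code), so
    every such chain is emitted exactly once. Step 2 walks both directions
    from each remaining k-mer, breaking loops at the start point. Chains
    with coverage (multiplicity sum / sequence length) below
    ``min_coverage`` are discarded as likely spurious connections. Kept
    chains are returned sorted by canonical sequence, so output is
    identical across runs and partition counts.
    """
    visited: Set[int] = set()
    chains: List[LinearChain] = []
    n_parts = store.n_parts
    k = store.k

    # Step 1: chains anchored at dead ends.
    for p_i, part in enumerate(store.partitions):
        for idx in np.nonzero(~part.dead)[0]:
            code = int(part.codes[idx])
            if code in visited:
                continue
            adj = int(part.adj[idx])
            right_dead = (adj & 0xF) == 0
            left_dead = (adj >> 4) == 0
            if not (right_dead or left_dead):
                continue
            # walk right on the strand whose left side is the dead side
            orient = left_dead  # both dead -> isolated, walk canonical
            chain, reason = _walk_chain(store, (code, orient),
                                        visited=visited)
            end = chain[-1]
            if reason == "dead":
                # dead-to-dead chain: duplicate-avoidance rule
                p_j = partition_of(end[0], k, n_parts)
                if p_i > p_j or (p_i == p_j and code > end[0]):
                    continue  # released; regenerated from the other end
            visited.update(c for c, _o in chain)
            chains.append(_emit(store, chain))

    # Step 2: remaining k-mers (cycles, inter-branch segments).
    for part in store.partitions:
        for idx in np.nonzero(~part.dead)[0]:
            code = int(part.codes[idx])
            if code in visited:
                continue
            fwd, f_reason = _walk_chain(store, (code, True),
                                        stop_at=(code, True),
                                        visited=visited)
            if f_reason == "cycle":
                chain = fwd  # loop broken at the start point
            else:
                back, _ = _walk_chain(store, (code, False),
                                      stop_at=(code, False),
                                      visited=visited)
                rev = [(c, not o) for c, o in reversed(back[1:])]
                chain = rev + fwd
            visited.update(c for c, _o in chain)
            chains.append(_emit(store, chain))

    kept = [ch for ch in chains if ch.coverage >= min_coverage]
    kept.sort(key=lambda ch: ch.sequence)
    return kept


def simplify_and_extract(store: PartitionedStore,
                         min_coverage: float = 1.0,
                         M: int | None = None,
                         ) -> Tuple[List[LinearChain], Dict[str, int]]:
    """Run the full simplification pipeline; returns (unitigs, counters)."""
    if M is None:
        M = estimate_M(store.multiplicity_histogram())
    n_low = remove_low_frequency_dead_ends(store, M)
    n_tip = remove_tips(store)
    chains = extract_chains(store, min_coverage=min_coverage)
    counters = {
        "M": M,
        "kmers_removed_low_freq": n_low,
        "kmers_removed_tips": n_tip,
        "chains_kept": len(chains),
    }
    return chains, counters
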