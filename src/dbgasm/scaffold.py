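"""Paired-end scaffolding: pair mapping, insert estimation, contig joining.

Only read-*pair* evidence is used to link contigs (single reads spanning
several nodes are never used), and a link is considered reliable only when
at least three pairs support it. Mates are mapped to contigs by k-mer
voting: a mate maps iff at least 80% of its k-mers agree on one
(contig, strand, offset) and no second contig ties. Per-library insert
statistics (median and standard deviation of the outer-end-to-outer-end
span) come from pairs whose mates map onto the same contig. Accepted
links order and orient contigs greedily by support into simple paths,
emitted as scaffolds with gaps rendered as runs of 'N'.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .kmer import enumerate_kmers, revcomp_seq, sanitize_read

MIN_LINK_PAIRS = 3      # "reliable" link support threshold
MIN_STATS_PAIRS = 100   # same-contig pairs needed for insert estimation
MIN_MAP_FRACTION = 0.8  # fraction of a mate's k-mers that must agree


class ScaffoldError(ValueError):
    pass


@dataclass
class PairMapping:
    library_id: str
    contig_a: int
    strand_a: bool   # True = mate forward on the contig
    offset_a: int    # 0-based leftmost mapped coordinate
    len_a: int
    contig_b: int
    strand_b: bool
    offset_b: int
    len_b: int

    def to_row(self) -> str:
        return "\t".join(str(x) for x in (
            self.library_id, self.contig_a, int(self.strand_a),
            self.offset_a, self.len_a, self.contig_b, int(self.strand_b),
            self.offset_b, self.len_b))

    @classmethod
    def from_row(cls, row: str) -> "PairMapping":
        f = row.rstrip("\n").split("\t")
        return cls(f[0], int(f[1]), bool(int(f[2])), int(f[3]), int(f[4]),
                   int(f[5]), bool(int(f[6])), int(f[7]), int(f[8]))


@dataclass
class LibraryStats:
    library_id: str
    median_insert: float
    insert_sd: float
    n_pairs: int


@dataclass
class ScaffoldLink:
    """Oriented link: contig_a (orient_a) precedes contig_b (orient_b)."""
    contig_a: int
    orient_a: bool   # True = forward in the scaffold direction
    contig_b: int
    orient_b: bool
    n_pairs: int
    gap_estimate: float
    gap_sd: float

    @property
    def orientation_class(self) -> str:
        return ("F" if self.orient_a else "R") + \
               ("F" if self.orient_b else "R")


# ---------------------------------------------------------------------------
# Read-pair mapping

class ContigIndex:
    """k-mer lookup over contigs; k-mers present in >1 contig are ambiguous."""

    def __init__(self, contigs: Sequence[str], k: int):
        self.k = k
        self.contigs = list(contigs)
        self.index: Dict[int, Optional[Tuple[int, int, bool]]] = {}
        for ci, seq in enumerate(self.contigs):
            for pos, canon, is_canon in enumerate_kmers(seq, k):
                if canon in self.index:
                    self.index[canon] = None  # ambiguous: present twice
                else:
                    self.index[canon] = (ci, pos, is_canon)

    def map_read(self, read: str) -> Optional[Tuple[int, bool, int]]:
        """Map one mate; returns (contig, strand, leftmost offset) or None.

        Votes are cast per (contig, strand, implied read-start offset);
        the winner needs >= 80% of the read's k-mers and must not tie
        with a hit on a different contig.
        """
        read = sanitize_read(read)
        n_kmers = len(read) - self.k + 1
        if n_kmers < 1:
            return None
        votes: Dict[Tuple[int, bool, int], int] = defaultdict(int)
        for rpos, canon, r_canon in enumerate_kmers(read, self.k):
            hit = self.index.get(canon)
            if hit is None:
                continue
            ci, cpos, c_canon = hit
            if r_canon == c_canon:  # read forward along contig
                votes[(ci, True, cpos - rpos)] += 1
            else:  # read maps reverse complemented
                start = cpos - (len(read) - self.k - rpos)
                votes[(ci, False, start)] += 1
        if not votes:
            return None
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        (ci, strand, offset), best = ranked[0]
        if best < MIN_MAP_FRACTION * n_kmers:
            return None
        for (ci2, _s2, _o2), v2 in ranked[1:]:
            if v2 == best and ci2 != ci:
                return None  # ambiguous across contigs
            if v2 < best:
                break
        return ci, strand, offset


def map_pairs(contigs: Sequence[str],
              pairs: Iterable[Tuple[Tuple[str, str], Tuple[str, str]]],
              k: int, library_id: str = "lib0") -> List[PairMapping]:
    """Map read pairs; only pairs with both mates mapped are recorded."""
    idx = ContigIndex(contigs, k)
    db: List[PairMapping] = []
    for (_id1, r1), (_id2, r2) in pairs:
        m1 = idx.map_read(r1)
        m2 = idx.map_read(r2)
        if m1 is None or m2 is None:
            continue
        db.append(PairMapping(
            library_id, m1[0], m1[1], m1[2], len(r1),
            m2[0], m2[1], m2[2], len(r2)))
    return db


def write_pair_db(db: Sequence[PairMapping], path: str) -> None:
    """Persist the mapping database as a sorted tab-delimited file."""
    rows = sorted(m.to_row() for m in db)
    with open(path, "wt") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


def read_pair_db(path: str) -> List[PairMapping]:
    with open(path, "rt") as fh:
        return [PairMapping.from_row(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Insert-size estimation

def estimate_insert_stats(db: Sequence[PairMapping], library_id: str,
                          min_pairs: int = MIN_STATS_PAIRS) -> LibraryStats:
    """Median and sd of spans of same-contig pairs for one library."""
    spans = []
    for m in db:
        if m.library_id != library_id or m.contig_a != m.contig_b:
            continue
        left = min(m.offset_a, m.offset_b)
        right = max(m.offset_a + m.len_a, m.offset_b + m.len_b)
        spans.append(right - left)
    if len(spans) < min_pairs:
        raise ScaffoldError(
            f"library {library_id!r}: only {len(spans)} same-contig pairs "
            f"(need >= {min_pairs}) for insert estimation")
    arr = np.asarray(spans, dtype=float)
    return LibraryStats(library_id, float(np.median(arr)),
                        float(arr.std()), len(spans))


# ---------------------------------------------------------------------------
# Link construction

def _pair_link(m: PairMapping, contig_lens: Sequence[int],
               median_insert: float
               ) -> Tuple[Tuple[int, bool, int, bool], float]:
    """One cross-contig pair -> (canonical link key, gap estimate).

    Mate A's strand orients contig A along the fragment; mate B, being
    the inward-facing far mate, orients contig B *against* its mapped
    strand. tail_x is the distance from the mate's outer end to the
    gap-facing end of its contig.
    """
    a, b = m.contig_a, m.contig_b
    oa = m.strand_a          # scaffold orientation of contig A
    ob = not m.strand_b      # scaffold orientation of contig B
    tail_a = contig_lens[a] - m.offset_a if m.strand_a \
        else m.offset_a + m.len_a
    tail_b = contig_lens[b] - m.offset_b if m.strand_b \
        else m.offset_b + m.len_b
    gap = median_insert - tail_a - tail_b
    # canonical direction: smaller contig id first (mirror flips orients)
    if a <= b:
        key = (a, oa, b, ob)
    else:
        key = (b, not ob, a, not oa)
    return key, gap


def build_links(db: Sequence[PairMapping], stats: Dict[str, LibraryStats],
                contig_lens: Sequence[int],
                min_pairs: int = MIN_LINK_PAIRS) -> List[ScaffoldLink]:
    """Group cross-contig pair evidence into reliable scaffold links.

    Pairs are grouped by (contig pair, orientation class); groups with
    fewer than ``min_pairs`` supporting pairs are discarded. Contradictory
    orientation classes form separate groups, never one link.
    """
    groups: Dict[Tuple[int, bool, int, bool], List[float]] = defaultdict(list)
    for m in db:
        if m.contig_a == m.contig_b:
            continue
        lib = stats[m.library_id]
        key, gap = _pair_link(m, contig_lens, lib.median_insert)
        groups[key].append(gap)
    links = []
    for (a, oa, b, ob), gaps in sorted(groups.items()):
        if len(gaps) < min_pairs:
            continue
        arr = np.asarray(gaps, dtype=float)
        links.append(ScaffoldLink(a, oa, b, ob, len(gaps),
                                  float(arr.mean()), float(arr.std())))
    return links


# ---------------------------------------------------------------------------
# Ordering and emission

def order_and_emit(links: Sequence[ScaffoldLink], contigs: Sequence[str],
                   min_len: int = 100,
                   ) -> Tuple[List[Tuple[str, str]], List[ScaffoldLink]]:
    """Greedy path construction and N-gapped scaffold emission.

    Links are accepted in decreasing support order if both contig ends
    they join are free and joining them does not close a cycle (the
    lower-support closing link is rejected and logged). Each path becomes
    one scaffold; gaps are rendered as max(1, round(gap)) 'N's, so a
    slightly negative (overlapping) estimate still yields a gap that
    ``split_scaffolds`` can invert exactly. Returns (records, rejected).
    """
    n = len(contigs)
    # end occupancy: (contig, 'L'/'R') -> (other contig, its end, gap)
    joins: Dict[Tuple[int, str], Tuple[int, str, float]] = {}
    comp = list(range(n))  # union-find over contigs

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    rejected: List[ScaffoldLink] = []
    for link in sorted(links, key=lambda l: (-l.n_pairs, l.contig_a,
                                             l.contig_b)):
        end_a = (link.contig_a, "R" if link.orient_a else "L")
        end_b = (link.contig_b, "L" if link.orient_b else "R")
        if end_a in joins or end_b in joins:
            rejected.append(link)
            continue
        if find(link.contig_a) == find(link.contig_b):
            rejected.append(link)  # would close a cycle
            continue
        joins[end_a] = (*end_b, link.gap_estimate)
        joins[end_b] = (*end_a, link.gap_estimate)
        comp[find(link.contig_a)] = find(link.contig_b)

    # walk each path once, starting from a free end
    emitted: List[Tuple[str, str]] = []
    seen = [False] * n
    for start in range(n):
        if seen[start]:
            continue
        # locate a terminal end of this path
        cur, cur_in = start, "L"
        while (cur, cur_in) in joins:
            prev, prev_end, _g = joins[(cur, cur_in)]
            cur, cur_in = prev, "L" if prev_end == "R" else "R"
            if cur == start:
                break  # safety: should not happen (cycles rejected)
        parts: List[str] = []
        while True:
            seen[cur] = True
            seq = contigs[cur]
            parts.append(seq if cur_in == "L" else revcomp_seq(seq))
            out_end = "R" if cur_in == "L" else "L"
            nxt = joins.get((cur, out_end))
            if nxt is None:
                break
            nxt_c, nxt_end, gap = nxt
            parts.append("N" * max(1, round(gap)))
            cur, cur_in = nxt_c, nxt_end
        seq = "".join(parts)
        rc = revcomp_seq(seq)
        emitted.append(min(seq, rc))
    emitted = sorted(s for s in emitted if len(s) >= min_len)
    records = [(f"scaffold_{i} len={len(s)}", s)
               for i, s in enumerate(emitted, start=1)]
    return records, rejected


def link_report(links: Sequence[ScaffoldLink]) -> str:
    lines = ["contig_a\torient_a\tcontig_b\torient_b\tclass\tn_pairs"
             "\tgap\tgap_sd"]
    for l in links:
        lines.append(
            f"{l.contig_a}\t{'+' if l.orient_a else '-'}\t{l.contig_b}\t"
            f"{'+' if l.orient_b else '-'}\t{l.orientation_class}\t"
            f"{l.n_pairs}\t{l.gap_estimate:.1f}\t{l.gap_sd:.1f}")
    return "\n".join(lines)
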