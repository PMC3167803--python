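"""Partitioned sorted-vector k-mer container with prefix acceleration tables.

Each distinct canonical k-mer (k-molecule representative) is one record:
a 64-bit packed code, a saturating 16-bit multiplicity, and an 8-bit
adjacency mask. Records are distributed over partitions by an LCG hash of
the canonical code, and each partition keeps its records in a strictly
sorted numpy vector. A per-partition acceleration table maps the most
significant ``r`` bits of a code (default r=24, clamped to 2k) to the
contiguous index range of records sharing that prefix, narrowing the
binary search from log N to log(N / 2^r).

Removal tombstones records (a dead flag) so the sorted vector and its
acceleration table stay valid between simplification rounds; ``compact()``
rebuilds both. All externally visible results are identical to sequential
processing in partition order.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .kmer import (
    BASE_TO_CODE,
    KmerError,
    lcg_hash,
    partition_of,
    revcomp,
    sanitize_read,
    validate_k,
)

MULT_MAX = 0xFFFF  # two-byte multiplicity, saturating
DEFAULT_R = 24

_MAGIC = b"PSHK"
_VERSION = 1
_HEADER = struct.Struct("<4sBBBQ")  # magic, version, k, r, record count
_RECORD = struct.Struct("<QHB")  # code, multiplicity, adjacency


class FormatError(ValueError):
    """Malformed on-disk k-mer partition file."""


@dataclass
class KmerRecord:
    canonical: int
    multiplicity: int
    adjacency: int


class Partition:
    """One partition: parallel sorted arrays plus the prefix table."""

    def __init__(self, codes: np.ndarray, mult: np.ndarray, adj: np.ndarray,
                 k: int, r: int):
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order].astype(np.uint64)
        if self.codes.size > 1 and not np.all(np.diff(self.codes) > 0):
            raise ValueError("duplicate canonical codes in partition")
        self.mult = mult[order].astype(np.uint16)
        self.adj = adj[order].astype(np.uint8)
        self.dead = np.zeros(self.codes.size, dtype=bool)
        self.k = k
        self.r_eff = min(r, 2 * k)
        self._build_accel()

    def _build_accel(self) -> None:
        shift = np.uint64(2 * self.k - self.r_eff)
        prefixes = self.codes >> shift
        uniq, starts = np.unique(prefixes, return_index=True)
        ends = np.append(starts[1:], self.codes.size)
        self._accel: Dict[int, Tuple[int, int]] = {
            int(p): (int(s), int(e)) for p, s, e in zip(uniq, starts, ends)
        }
        self._shift = shift

    def find(self, code: int) -> int:
        """Index of ``code`` or -1; accelerated binary search."""
        lo, hi = self._accel.get(int(code) >> int(self._shift), (0, 0))
        i = lo + int(np.searchsorted(self.codes[lo:hi], np.uint64(code)))
        if i < hi and self.codes[i] == code and not self.dead[i]:
            return i
        return -1

    def find_linear(self, code: int) -> int:
        """Full linear scan; the oracle ``find`` must agree with."""
        hits = np.nonzero((self.codes == np.uint64(code)) & ~self.dead)[0]
        return int(hits[0]) if hits.size else -1

    @property
    def n_alive(self) -> int:
        return int(self.codes.size - self.dead.sum())

    def compact(self) -> None:
        keep = ~self.dead
        self.codes = self.codes[keep]
        self.mult = self.mult[keep]
        self.adj = self.adj[keep]
        self.dead = np.zeros(self.codes.size, dtype=bool)
        self._build_accel()


class PartitionedStore:
    """The k-mer graph node table, split over ``n_parts`` partitions."""

    def __init__(self, partitions: List[Partition], k: int, n_parts: int,
                 r: int = DEFAULT_R):
        self.partitions = partitions
        self.k = k
        self.n_parts = n_parts
        self.r = r

    # -- addressing ---------------------------------------------------------

    def _locate(self, code: int) -> Tuple[Optional[Partition], int]:
        # stored codes are canonical, so hashing the code directly equals
        # partition_of; a non-canonical probe is absent from every partition
        part = self.partitions[lcg_hash(code) % self.n_parts]
        i = part.find(code)
        return (part, i) if i >= 0 else (None, -1)

    def lookup(self, code: int) -> Optional[KmerRecord]:
        part, i = self._locate(code)
        if part is None:
            return None
        return KmerRecord(int(part.codes[i]), int(part.mult[i]),
                          int(part.adj[i]))

    def __contains__(self, code: int) -> bool:
        return self._locate(code)[0] is not None

    def multiplicity(self, code: int) -> int:
        part, i = self._locate(code)
        return int(part.mult[i]) if part is not None else 0

    def adjacency(self, code: int) -> int:
        part, i = self._locate(code)
        return int(part.adj[i]) if part is not None else 0

    def or_adjacency(self, code: int, bits: int) -> None:
        part, i = self._locate(code)
        if part is None:
            raise KmerError(
                f"k-mer code {code} absent from store during linkage update"
            )
        part.adj[i] |= np.uint8(bits)

    def clear_adjacency(self, code: int, bits: int) -> None:
        part, i = self._locate(code)
        if part is not None:
            part.adj[i] &= np.uint8(0xFF ^ bits)

    def remove_record(self, code: int) -> None:
        """Tombstone a record; removing an absent code is a no-op."""
        part, i = self._locate(code)
        if part is not None:
            part.dead[i] = True

    def compact(self) -> None:
        for part in self.partitions:
            part.compact()

    # -- iteration ----------------------------------------------------------

    @property
    def n_records(self) -> int:
        return sum(p.n_alive for p in self.partitions)

    def iter_codes(self) -> Iterator[int]:
        """All alive canonical codes, partition order then sorted order."""
        for part in self.partitions:
            alive = np.nonzero(~part.dead)[0]
            for i in alive:
                yield int(part.codes[i])

    def iter_records(self) -> Iterator[KmerRecord]:
        for part in self.partitions:
            alive = np.nonzero(~part.dead)[0]
            for i in alive:
                yield KmerRecord(int(part.codes[i]), int(part.mult[i]),
                                 int(part.adj[i]))

    def multiplicity_histogram(self) -> Dict[int, int]:
        hist: Dict[int, int] = {}
        for part in self.partitions:
            vals, counts = np.unique(part.mult[~part.dead],
                                     return_counts=True)
            for v, c in zip(vals, counts):
                hist[int(v)] = hist.get(int(v), 0) + int(c)
        return hist


def count_kmers(reads: Iterable[str], k: int, n_parts: int = 1,
                r: int = DEFAULT_R) -> PartitionedStore:
    """Count canonical k-mers over a read stream into a partitioned store.

    Both strands of an occurrence count as one k-molecule; multiplicities
    saturate at 65535. Reads are sanitized (non-ACGT -> 'A') on the way in.
    """
    validate_k(k)
    if n_parts < 1:
        raise KmerError(f"n_parts must be >= 1, got {n_parts}")
    counts: Dict[int, int] = {}
    mask2 = (1 << (2 * k)) - 1
    shift_hi = 2 * (k - 1)
    for read in reads:
        read = sanitize_read(read)
        n = len(read)
        if n < k:
            continue
        code = 0
        for ch in read[:k]:
            code = (code << 2) | BASE_TO_CODE[ch]
        rc = revcomp(code, k)
        canon = code if code <= rc else rc
        counts[canon] = counts.get(canon, 0) + 1
        for i in range(k, n):
            b = BASE_TO_CODE[read[i]]
            code = ((code << 2) | b) & mask2
            rc = (rc >> 2) | ((b ^ 3) << shift_hi)
            canon = code if code <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    return _store_from_counts(counts, k, n_parts, r)


def _store_from_counts(counts: Dict[int, int], k: int, n_parts: int,
                       r: int) -> PartitionedStore:
    codes = np.fromiter(counts.keys(), dtype=np.uint64, count=len(counts))
    mult = np.fromiter(
        (min(c, MULT_MAX) for c in counts.values()),
        dtype=np.uint16, count=len(counts),
    )
    adj = np.zeros(codes.size, dtype=np.uint8)
    if n_parts == 1:
        pids = np.zeros(codes.size, dtype=np.int64)
    else:
        from .kmer import lcg_hash_array
        pids = (lcg_hash_array(codes) % np.uint64(n_parts)).astype(np.int64)
    parts = []
    for p in range(n_parts):
        sel = pids == p
        parts.append(Partition(codes[sel], mult[sel], adj[sel], k, r))
    return PartitionedStore(parts, k, n_parts, r)


# ---------------------------------------------------------------------------
# On-disk partition files (".pshk"): stage (i) output.

def write_kmer_file(part: Partition, path: str) -> None:
    alive = ~part.dead
    codes = part.codes[alive]
    mult = part.mult[alive]
    adj = part.adj[alive]
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, _VERSION, part.k, part.r_eff,
                              codes.size))
        for c, m, a in zip(codes, mult, adj):
            fh.write(_RECORD.pack(int(c), int(m), int(a)))


def read_kmer_file(path: str) -> Partition:
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise FormatError(f"{path}: truncated header at offset {len(head)}")
        magic, version, k, r, count = _HEADER.unpack(head)
        if magic != _MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r} at offset 0")
        if version != _VERSION:
            raise FormatError(f"{path}: unsupported version {version} "
                              f"at offset 4")
        payload = fh.read()
    expected = count * _RECORD.size
    if len(payload) != expected:
        raise FormatError(
            f"{path}: expected {expected} record bytes, got {len(payload)} "
            f"(truncation at offset {_HEADER.size + len(payload)})"
        )
    codes = np.zeros(count, dtype=np.uint64)
    mult = np.zeros(count, dtype=np.uint16)
    adj = np.zeros(count, dtype=np.uint8)
    for i, (c, m, a) in enumerate(_RECORD.iter_unpack(payload)):
        codes[i], mult[i], adj[i] = c, m, a
    return Partition(codes, mult, adj, k, r)


def write_store(store: PartitionedStore, prefix: str) -> List[str]:
    paths = []
    for i, part in enumerate(store.partitions):
        path = f"{prefix}.part{i}.pshk"
        write_kmer_file(part, path)
        paths.append(path)
    return paths


def read_store(paths: List[str], n_parts: int | None = None,
               r: int = DEFAULT_R) -> PartitionedStore:
    parts = [read_kmer_file(p) for p in paths]
    if not parts:
        raise FormatError("no partition files given")
    k = parts[0].k
    if any(p.k != k for p in parts):
        raise FormatError("partition files disagree on k")
    return PartitionedStore(parts, k, n_parts or len(parts), r)
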