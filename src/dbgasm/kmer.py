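"""Bit-packed k-mer codec: encoding, canonicalization, deterministic partitioning.

A k-mer (k <= 31, odd) is packed two bits per base into a 64-bit integer
with the base map A=0, C=1, G=2, T=3 and the *first* base most significant.
Under this packing, integer order on codes coincides with lexicographic
order on the strings, so the canonical form of a k-molecule (the
lexicographically smaller of a k-mer and its reverse complement) is simply
``min(code, revcomp(code))``.

Odd k is required throughout: an even k admits palindromic k-mers that are
their own reverse complement, which makes the canonical representative of a
double-stranded k-molecule ambiguous.
"""

from __future__ import annotations

from typing import Iterator, Tuple

import numpy as np

BASES = "ACGT"
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_TO_BASE = {0: "A", 1: "C", 2: "G", 3: "T"}

_SANITIZE = str.maketrans(
    {c: "A" for c in map(chr, range(256)) if c.upper() not in "ACGT"}
)

# Fixed 64-bit linear congruential hash: h(x) = ((a*x + c) mod 2^64) >> 33.
# The constants are a well-mixed LCG choice (Knuth MMIX multiplier); they are
# a constant of this implementation -- any fixed, well-mixed choice gives the
# near-uniform partition balance the distribution scheme needs.
_LCG_A = 6364136223846793005
_LCG_C = 1442695040888963407
_U64 = (1 << 64) - 1


class KmerError(ValueError):
    """Invalid k-mer parameters or sequence content."""


def validate_k(k: int, require_odd: bool = True) -> None:
    if not (1 <= k <= 31):
        raise KmerError(f"k must be in [1, 31], got {k}")
    if require_odd and k % 2 == 0:
        raise KmerError(
            f"k must be odd (even k admits palindromic self-reverse-complement "
            f"k-mers), got {k}"
        )


def sanitize_read(seq: str) -> str:
    """Uppercase ``seq`` and convert every non-A/C/G/T character to 'A'.

    The whole read is always retained; ambiguous bases are never grounds
    for discarding it.
    """
    return seq.upper().translate(_SANITIZE)


def encode(seq: str, k: int | None = None) -> int:
    """Pack a clean A/C/G/T string into its base-4 code."""
    if k is None:
        k = len(seq)
    if len(seq) != k:
        raise KmerError(f"sequence length {len(seq)} != k={k}")
    validate_k(k, require_odd=False)
    code = 0
    try:
        for ch in seq:
            code = (code << 2) | BASE_TO_CODE[ch]
    except KeyError as exc:
        raise KmerError(f"invalid base {exc.args[0]!r} in k-mer") from None
    return code


def decode(code: int, k: int) -> str:
    """Unpack a base-4 code into its A/C/G/T string."""
    validate_k(k, require_odd=False)
    if not (0 <= code < (1 << (2 * k))):
        raise KmerError(f"code {code} out of range for k={k}")
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(CODE_TO_BASE[(code >> shift) & 3])
    return "".join(out)


def revcomp(code: int, k: int) -> int:
    """Code of the reverse complement (an involution)."""
    mask2 = (1 << (2 * k)) - 1
    comp = code ^ mask2  # A<->T, C<->G: complement is bitwise NOT on 2 bits
    out = 0
    for _ in range(k):
        out = (out << 2) | (comp & 3)
        comp >>= 2
    return out


def revcomp_seq(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def canonical(code: int, k: int) -> int:
    """The smaller of a code and its reverse complement (canonical strand)."""
    rc = revcomp(code, k)
    return code if code <= rc else rc


def lcg_hash(code: int) -> int:
    return ((_LCG_A * code + _LCG_C) & _U64) >> 33


def partition_of(code: int, k: int, n_parts: int) -> int:
    """Deterministic owning partition of a k-molecule.

    Canonicalization precedes hashing, so a k-mer and its reverse
    complement always land in the same partition.
    """
    if n_parts < 1:
        raise KmerError(f"n_parts must be >= 1, got {n_parts}")
    return lcg_hash(canonical(code, k)) % n_parts


def enumerate_kmers(read: str, k: int) -> Iterator[Tuple[int, int, bool]]:
    """Yield ``(position, canonical_code, is_canonical)`` for every k-mer.

    ``position`` is the 0-based start of the k-mer in the read;
    ``is_canonical`` is True when the observed strand equals the canonical
    strand (needed downstream to orient adjacency bits). Reads shorter than
    k yield nothing. The read must already be sanitized.
    """
    validate_k(k, require_odd=False)
    n = len(read)
    if n < k:
        return
    mask2 = (1 << (2 * k)) - 1
    code = encode(read[:k], k)
    rc = revcomp(code, k)
    shift_hi = 2 * (k - 1)
    for i in range(n - k + 1):
        if i > 0:
            b = BASE_TO_CODE[read[i + k - 1]]
            code = ((code << 2) | b) & mask2
            rc = (rc >> 2) | ((b ^ 3) << shift_hi)
        if code <= rc:
            yield i, code, True
        else:
            yield i, rc, False


# ---------------------------------------------------------------------------
# Vectorized variants used by the counting hot path.

def encode_array(codes_2bit: np.ndarray, k: int) -> np.ndarray:
    """Pack a (n, k) array of 2-bit base codes into uint64 k-mer codes."""
    out = np.zeros(codes_2bit.shape[0], dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes_2bit[:, j].astype(np.uint64)
    return out


def revcomp_array(codes: np.ndarray, k: int) -> np.ndarray:
    comp = codes ^ np.uint64((1 << (2 * k)) - 1)
    out = np.zeros_like(codes)
    for _ in range(k):
        out = (out << np.uint64(2)) | (comp & np.uint64(3))
        comp = comp >> np.uint64(2)
    return out


def lcg_hash_array(codes: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return (
            codes * np.uint64(_LCG_A) + np.uint64(_LCG_C)
        ) >> np.uint64(33)
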