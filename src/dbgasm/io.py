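"""Streaming FASTA/FASTQ readers and FASTA writing, gzip-aware.

Parsing is delegated to Bio.SeqIO; records stream through constant memory
as ``(identifier, sequence)`` pairs. FASTQ quality strings are parsed and
discarded — the assembler is quality-blind by design. Malformed input is
reported as :class:`ReadFormatError` carrying the record index.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple

from Bio import SeqIO

ReadPair = Tuple[str, str]  # (identifier, sequence)


class ReadFormatError(ValueError):
    """Malformed FASTA/FASTQ input."""


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: str | Path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ReadFormatError(
                f"{path}: unrecognized leading character {line[0]!r}; "
                f"expected FASTA '>' or FASTQ '@'"
            )
    raise ReadFormatError(f"{path}: empty file")


def read_sequences(path: str | Path, fmt: str | None = None
                   ) -> Iterator[ReadPair]:
    """Stream records from a FASTA or FASTQ file (format auto-detected)."""
    if fmt is None:
        fmt = _sniff_format(path)
    fh = _open_text(path)
    index = 0
    try:
        for rec in SeqIO.parse(fh, fmt):
            # full header (description), not the whitespace-truncated id:
            # downstream stages carry cov=/len=/k= annotations there
            yield rec.description or rec.id, str(rec.seq)
            index += 1
    except ValueError as exc:
        raise ReadFormatError(
            f"{path}: malformed {fmt} at record index {index}: {exc}"
        ) from exc
    finally:
        fh.close()


def read_fasta(path: str | Path) -> Iterator[ReadPair]:
    return read_sequences(path, "fasta")


def read_fastq(path: str | Path) -> Iterator[ReadPair]:
    return read_sequences(path, "fastq")


def read_paired(path_1: str | Path, path_2: str | Path
                ) -> Iterator[Tuple[ReadPair, ReadPair]]:
    """Zip two mate files; mismatched lengths are an input-format error."""
    it1 = read_sequences(path_1)
    it2 = read_sequences(path_2)
    sentinel = object()
    i = 0
    while True:
        a = next(it1, sentinel)
        b = next(it2, sentinel)
        if a is sentinel and b is sentinel:
            return
        if a is sentinel or b is sentinel:
            raise ReadFormatError(
                f"unpaired input: mate files diverge at pair index {i}"
            )
        yield a, b
        i += 1


def read_interleaved(path: str | Path
                     ) -> Iterator[Tuple[ReadPair, ReadPair]]:
    it = read_sequences(path)
    i = 0
    while True:
        a = next(it, None)
        if a is None:
            return
        b = next(it, None)
        if b is None:
            raise ReadFormatError(
                f"interleaved input has an odd mate count (pair index {i})"
            )
        yield a, b
        i += 1


def write_fasta(records: Iterable[ReadPair], path: str | Path,
                width: int = 70) -> int:
    """Write ``(id, seq)`` records as wrapped FASTA; returns record count."""
    n = 0
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
            n += 1
    return n


def sequences_of(path: str | Path) -> Iterator[str]:
    for _name, seq in read_sequences(path):
        yield seq


def load_fasta(path: str | Path) -> List[ReadPair]:
    return list(read_fasta(path))
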