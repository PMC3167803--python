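"""Assembly summary statistics: NGx, scaffold splitting, report tables.

NG50/NG80 are computed against the *reference* genome size, not the
assembly total: sequences are ordered longest first and lengths summed
until the running total strictly exceeds x% of the genome size; the length
of the sequence that crosses the threshold is the NGx. Scaffolds are split
into constituent contigs at runs of 'N' before contig-level statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

MIN_REPORT_LEN = 100  # sequences shorter than this are not reported

_N_RUN = re.compile(r"N+")


@dataclass
class AssemblySummary:
    n_sequences: int
    ng50: Optional[int]
    ng80: Optional[int]
    max: int
    mean: float
    median: float
    total: int


def ngx(lengths: Sequence[int], genome_size: int, x: float) -> Optional[int]:
    """Length at which the sorted-descending cumulative total first
    strictly exceeds x% of ``genome_size``; None if it never does."""
    if not (0 < x < 100):
        raise ValueError(f"x must be in (0, 100), got {x}")
    if genome_size <= 0:
        raise ValueError(f"genome_size must be positive, got {genome_size}")
    if not lengths:
        raise ValueError("lengths must be non-empty")
    threshold = genome_size * x / 100.0
    running = 0
    for length in sorted(lengths, reverse=True):
        running += length
        if running > threshold:
            return length
    return None


def split_scaffolds(records: Iterable[Tuple[str, str]]
                    ) -> List[Tuple[str, str]]:
    """Split each scaffold at N-gaps into its constituent contigs."""
    out = []
    for name, seq in records:
        pieces = [p for p in _N_RUN.split(seq) if p]
        if len(pieces) == 1:
            out.append((name, pieces[0]))
        else:
            for i, p in enumerate(pieces):
                out.append((f"{name}/{i}", p))
    return out


def assembly_summary(lengths: Sequence[int], genome_size: int,
                     min_len: int = MIN_REPORT_LEN) -> AssemblySummary:
    kept = [l for l in lengths if l >= min_len]
    if not kept:
        return AssemblySummary(0, None, None, 0, 0.0, 0.0, 0)
    arr = np.asarray(kept)
    return AssemblySummary(
        n_sequences=len(kept),
        ng50=ngx(kept, genome_size, 50),
        ng80=ngx(kept, genome_size, 80),
        max=int(arr.max()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        total=int(arr.sum()),
    )


def format_summary(summary: AssemblySummary, label: str = "scaffolds") -> str:
    rows = [
        (f"no. of {label}", summary.n_sequences),
        ("NG50", summary.ng50 if summary.ng50 is not None else "NA"),
        ("NG80", summary.ng80 if summary.ng80 is not None else "NA"),
        ("max", summary.max),
        ("mean", round(summary.mean, 1)),
        ("median", round(summary.median, 1)),
        ("total", summary.total),
    ]
    return "\n".join(f"{name}\t{value}" for name, value in rows)
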