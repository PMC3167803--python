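"""Simulation of genomes and paired short reads for assembler validation.

The generator emulates the short-read regime the assembler targets:
36 bp paired-end reads from ~200 bp insert libraries, uniform fragment
starts, i.i.d. per-base substitution errors, and optionally two haplotypes
differing at planted heterozygous SNP sites (the source of bubbles in the
graph). Insert sizes are normal(insert_mean, insert_sd) rounded and
clamped; mates are drawn from opposite strands facing inward. Everything
is reproducible bit-exactly from the seed, and truth tables (fragment
coordinates, SNP positions) are returned alongside the reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .kmer import BASES, revcomp_seq


@dataclass
class SimConfig:
    genome_length: int = 20_000
    read_length: int = 36       # Table-1-style short reads
    insert_mean: float = 200.0  # outer-end-to-outer-end fragment span
    insert_sd: float = 20.0
    coverage: float = 30.0
    error_rate: float = 0.0     # per-base substitution probability
    het_snp_rate: float = 0.0   # per-base heterozygous SNP probability
    snp_positions: Optional[Tuple[int, ...]] = None  # explicit het sites
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "het_snp_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class PairTruth:
    """Ground truth for one simulated fragment."""
    start: int        # 0-based leftmost genome coordinate of the fragment
    insert: int       # fragment span in bases
    haplotype: int    # 0 or 1


@dataclass
class SimOutput:
    reads_1: List[str]
    reads_2: List[str]
    truth: List[PairTruth]
    snp_positions: List[int] = field(default_factory=list)
    snp_alleles: List[Tuple[str, str]] = field(default_factory=list)


def simulate_genome(length: int, seed: int = 0,
                    repeat_free_k: Optional[int] = None,
                    max_tries: int = 50) -> str:
    """Uniform random genome; optionally reject until no exact repeat of
    length >= repeat_free_k - 1 exists (feasible for <= ~100 kb genomes)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
        if repeat_free_k is None:
            return seq
        if _is_repeat_free(seq, repeat_free_k - 1):
            return seq
    raise ValueError(
        f"could not draw a genome of length {length} free of repeats of "
        f"length >= {repeat_free_k - 1} in {max_tries} tries; try a larger k"
    )


def _is_repeat_free(seq: str, m: int) -> bool:
    """True iff no m-mer occurs twice across the sequence and its
    reverse complement (brute-force hash scan)."""
    seen = set()
    rc = revcomp_seq(seq)
    for s in (seq, rc):
        for i in range(len(s) - m + 1):
            w = s[i:i + m]
            if w in seen:
                return False
            seen.add(w)
    return True


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = base_bytes[base_bytes != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def plant_snps(genome: str, rate: float, rng: np.random.Generator,
               positions: Optional[Tuple[int, ...]] = None,
               ) -> Tuple[str, List[int], List[Tuple[str, str]]]:
    """Second haplotype differing from ``genome`` at heterozygous sites.

    Sites are Bernoulli(rate) draws unless ``positions`` pins them."""
    if positions is not None:
        positions = sorted(positions)
    elif rate > 0:
        positions = sorted(
            np.nonzero(rng.random(len(genome)) < rate)[0].tolist())
    else:
        return genome, [], []
    hap = list(genome)
    alleles = []
    for p in positions:
        alt = BASES[(BASES.index(hap[p]) + rng.integers(1, 4)) % 4]
        alleles.append((hap[p], alt))
        hap[p] = alt
    return "".join(hap), positions, alleles


def simulate_pairs(genome: str, cfg: SimConfig) -> SimOutput:
    """Draw inward-facing read pairs from ``genome`` (and, with
    het_snp_rate > 0, from a second planted haplotype at 50% balance)."""
    rng = np.random.default_rng(cfg.seed)
    L = len(genome)
    rl = cfg.read_length
    if cfg.insert_mean + 3 * cfg.insert_sd >= L:
        raise ValueError("genome too short for the configured insert size")
    hap2, snp_pos, snp_alleles = plant_snps(
        genome, cfg.het_snp_rate, rng, positions=cfg.snp_positions)
    haplotypes = (genome, hap2)
    n_pairs = int(round(cfg.coverage * L / (2 * rl)))
    inserts = np.clip(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)),
        2 * rl, L,
    ).astype(int)
    # Fragments are sampled on an interval padded by (insert - read_length)
    # on each side and the mates clipped at the genome boundary, so
    # per-base read coverage is uniform across the whole genome, ends
    # included; a fully interior fragment is never clipped.
    pads = inserts - rl
    starts = rng.integers(-pads, L - inserts + pads + 1)
    diploid = cfg.het_snp_rate > 0 or cfg.snp_positions is not None
    haps = (rng.random(n_pairs) < 0.5).astype(int) if diploid \
        else np.zeros(n_pairs, dtype=int)
    reads_1, reads_2, truth = [], [], []
    for s, ins, h in zip(starts, inserts, haps):
        hap = haplotypes[h]
        r1 = hap[max(0, s):max(0, min(L, s + rl))]
        r2 = hap[max(0, min(L, s + ins - rl)):max(0, min(L, s + ins))]
        r1 = _mutate(r1, rng, cfg.error_rate)
        r2 = _mutate(revcomp_seq(r2), rng, cfg.error_rate)
        reads_1.append(r1)
        reads_2.append(r2)
        truth.append(PairTruth(int(s), int(ins), int(h)))
    return SimOutput(reads_1, reads_2, truth, snp_pos, snp_alleles)


def write_truth_tsv(out: SimOutput, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("pair_index\tstart\tinsert\thaplotype\n")
        for i, t in enumerate(out.truth):
            fh.write(f"{i}\t{t.start}\t{t.insert}\t{t.haplotype}\n")


def write_snp_tsv(out: SimOutput, path: str) -> None:
    with open(path, "wt") as fh:
        fh.write("position\tref\talt\n")
        for p, (ref, alt) in zip(out.snp_positions, out.snp_alleles):
            fh.write(f"{p}\t{ref}\t{alt}\n")
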