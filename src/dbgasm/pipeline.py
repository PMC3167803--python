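"""Staged assembly pipeline over on-disk artifacts.

Four stages, each consuming the previous stage's files:
(i)   ``kmers``    reads -> partitioned k-mer files (``kmers.part*.pshk``)
(ii)  ``graph``    k-mer files + reads -> unitig FASTA
(iii) ``contigs``  unitig FASTA + reads -> contig FASTA
(iv)  ``scaffold`` contig FASTA + read pairs -> scaffold FASTA + link table

Stages are runnable individually or end-to-end; a missing upstream
artifact raises :class:`StageError` naming the required file. FASTA
headers carry k so stage-order violations are detected rather than
silently mis-parsed. Per-stage counters are logged to standard error as
machine-parsable ``key=value`` lines.
"""

from __future__ import annotations

import glob as _glob
import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from . import contigs as _contigs
from . import dbg as _dbg
from . import io as _io
from . import scaffold as _scaffold
from . import stats as _stats
from . import store as _store
from .kmer import validate_k


class StageError(RuntimeError):
    """A stage dependency is missing or inconsistent."""


@dataclass
class PipelineConfig:
    k: int = 21
    n_parts: int = 1
    r: int = _store.DEFAULT_R
    min_coverage: float = 1.0
    min_pairs: int = _scaffold.MIN_LINK_PAIRS
    min_len: int = 100
    seed: int = 0
    out_dir: str = "."
    reads_1: Optional[str] = None
    reads_2: Optional[str] = None   # None: single-end or interleaved
    interleaved: bool = False

    def __post_init__(self):
        validate_k(self.k)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def _log(stage: str, **counts) -> None:
    msg = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[{stage}] {msg}", file=sys.stderr)


def _read_stream(cfg: PipelineConfig) -> Iterable[str]:
    """All read sequences, both mates included."""
    if cfg.reads_1 is None:
        raise StageError("no input reads configured")
    for seq in _io.sequences_of(cfg.reads_1):
        yield seq
    if cfg.reads_2 is not None:
        for seq in _io.sequences_of(cfg.reads_2):
            yield seq


def _pair_stream(cfg: PipelineConfig):
    if cfg.reads_2 is not None:
        return _io.read_paired(cfg.reads_1, cfg.reads_2)
    if cfg.interleaved:
        return _io.read_interleaved(cfg.reads_1)
    raise StageError(
        "scaffolding needs paired input (two mate files or --interleaved)")


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage {stage!r} requires {path} (produced by stage "
            f"{produced_by!r}); run that stage first")
    return path


# ---------------------------------------------------------------------------

def stage_kmers(cfg: PipelineConfig) -> List[str]:
    cfg.out.mkdir(parents=True, exist_ok=True)
    store = _store.count_kmers(_read_stream(cfg), cfg.k, cfg.n_parts, cfg.r)
    paths = _store.write_store(store, str(cfg.out / "kmers"))
    _log("kmers", k=cfg.k, n_parts=cfg.n_parts, distinct=store.n_records)
    return paths


def _load_store(cfg: PipelineConfig) -> _store.PartitionedStore:
    paths = sorted(
        _glob.glob(str(cfg.out / "kmers.part*.pshk")),
        key=lambda p: int(re.search(r"part(\d+)", p).group(1)),
    )
    if not paths:
        raise StageError(
            f"stage 'graph' requires {cfg.out / 'kmers.part*.pshk'} "
            f"(produced by stage 'kmers'); run that stage first")
    store = _store.read_store(paths, r=cfg.r)
    if store.k != cfg.k:
        raise StageError(
            f"k-mer files were built with k={store.k}, pipeline has "
            f"k={cfg.k}")
    return store


def stage_graph(cfg: PipelineConfig) -> Path:
    store = _load_store(cfg)
    _dbg.build_linkages(store, _read_stream(cfg))
    chains, counters = _dbg.simplify_and_extract(
        store, min_coverage=cfg.min_coverage)
    out_path = cfg.out / "unitigs.fasta"
    _io.write_fasta(
        ((f"unitig_{i} cov={c.coverage:.1f} len={len(c.sequence)} k={cfg.k}",
          c.sequence) for i, c in enumerate(chains, start=1)),
        out_path)
    _log("graph", **counters)
    return out_path


_HEADER_K = re.compile(r"\bk=(\d+)\b")
_HEADER_COV = re.compile(r"\bcov=([0-9.]+)\b")


def _load_annotated_fasta(path: Path, cfg: PipelineConfig, stage: str,
                          produced_by: str) -> List[Tuple[str, float]]:
    _require(path, stage, produced_by)
    out = []
    for name, seq in _io.read_fasta(path):
        m = _HEADER_K.search(name)
        if m and int(m.group(1)) != cfg.k:
            raise StageError(
                f"{path} was built with k={m.group(1)}, pipeline has "
                f"k={cfg.k}")
        c = _HEADER_COV.search(name)
        out.append((seq, float(c.group(1)) if c else 1.0))
    return out


def stage_contigs(cfg: PipelineConfig) -> Path:
    unitigs = _load_annotated_fasta(cfg.out / "unitigs.fasta", cfg,
                                    "contigs", "graph")
    graph = _contigs.build_sequence_graph(unitigs, _read_stream(cfg), cfg.k)
    events = _contigs.merge_bubbles(graph)
    recs = _contigs.finalize_contigs(graph, min_len=cfg.min_len)
    out_path = cfg.out / "contigs.fasta"
    _io.write_fasta(
        ((f"contig_{i} cov={cov:.1f} len={len(seq)} k={cfg.k}", seq)
         for i, (seq, cov) in enumerate(recs, start=1)),
        out_path)
    _log("contigs", unitigs=len(unitigs), merged_bubbles=len(events),
         contigs=len(recs))
    return out_path


def stage_scaffold(cfg: PipelineConfig) -> Path:
    contig_recs = _load_annotated_fasta(cfg.out / "contigs.fasta", cfg,
                                        "scaffold", "contigs")
    seqs = [seq for seq, _cov in contig_recs]
    db = _scaffold.map_pairs(seqs, _pair_stream(cfg), cfg.k)
    _scaffold.write_pair_db(db, str(cfg.out / "pairs.tsv"))
    try:
        lib = _scaffold.estimate_insert_stats(db, "lib0")
        stats = {"lib0": lib}
        links = _scaffold.build_links(db, stats, [len(s) for s in seqs],
                                      min_pairs=cfg.min_pairs)
    except _scaffold.ScaffoldError:
        lib = None
        links = []
    recs, rejected = _scaffold.order_and_emit(links, seqs,
                                              min_len=cfg.min_len)
    out_path = cfg.out / "scaffolds.fasta"
    _io.write_fasta(((f"{name} k={cfg.k}", seq) for name, seq in recs),
                    out_path)
    (cfg.out / "links.tsv").write_text(_scaffold.link_report(links) + "\n")
    _log("scaffold", mapped_pairs=len(db), links=len(links),
         rejected_links=len(rejected), scaffolds=len(recs),
         median_insert=f"{lib.median_insert:.1f}" if lib else "NA")
    return out_path


def stage_stats(cfg: PipelineConfig, genome_size: int,
                which: str = "scaffolds") -> _stats.AssemblySummary:
    path = _require(cfg.out / f"{which}.fasta", "stats", which)
    lengths = [len(seq) for _n, seq in _io.read_fasta(path)]
    summary = _stats.assembly_summary(lengths, genome_size,
                                      min_len=cfg.min_len)
    report = _stats.format_summary(summary, label=which)
    (cfg.out / f"stats_{which}.tsv").write_text(report + "\n")
    _log("stats", which=which, n=summary.n_sequences, ng50=summary.ng50)
    return summary


def run_pipeline(cfg: PipelineConfig,
                 genome_size: Optional[int] = None) -> Dict[str, Path]:
    """Run stages (i)-(iv) end to end; returns the artifact paths."""
    stage_kmers(cfg)
    unitigs = stage_graph(cfg)
    contig_fa = stage_contigs(cfg)
    paired = cfg.reads_2 is not None or cfg.interleaved
    artifacts = {"unitigs": unitigs, "contigs": contig_fa}
    if paired:
        artifacts["scaffolds"] = stage_scaffold(cfg)
    if genome_size is not None:
        stage_stats(cfg, genome_size,
                    which="scaffolds" if paired else "contigs")
    return artifacts
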