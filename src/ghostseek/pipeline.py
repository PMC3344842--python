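"""Search orchestration: translate, seed, align, merge, sort, write.

Results are merged per read across database chunks, deduplicated per
(read, frame, subject), sorted by bit score (ties by smallest subject then
query coordinate), and truncated to the top N hits plus ties within a bit
tolerance.  Output is deterministic and independent of chunking, batching
and worker count.
"""

from __future__ import annotations

import multiprocessing
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from . import seq_io
from .db_index import IndexChunk, SearchParams, load_chunks
from .local_align import KCONST_DEFAULT, LAMBDA_DEFAULT, Hit, align_candidate
from .seed_search import find_candidates, query_keys
from .seq_io import DnaRead
from .translate import FRAMES, six_frame_translate

__all__ = ["RunConfig", "process_read", "search_reads", "search_all", "sniff_format"]

_FRAME_ORDER = {f: i for i, f in enumerate(FRAMES)}


@dataclass
class RunConfig:
    """Everything needed for one `aln` run."""

    params: SearchParams = field(default_factory=SearchParams)
    index_path: Union[str, Path] = ""
    query_path: Union[str, Path] = ""
    output_path: Union[str, Path] = ""
    top_n: int = 1
    tie_bits: float = 1.0
    batch_size: int = 500
    min_bit: float = 20.0
    threads: int = 1
    seed: int = 0
    quality_filter: bool = False
    lenient: bool = False
    compute_evalue: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")


def _hit_sort_key(hit: Hit) -> Tuple:
    # bit score is strictly increasing in raw score, so raw sorts identically;
    # deterministic tie-break: smallest subject coord, then query, then ids
    return (-hit.raw_score, hit.s_start, hit.q_start, hit.db_seq_id, _FRAME_ORDER[hit.frame])


def process_read(
    read: DnaRead,
    chunks: Sequence[IndexChunk],
    params: SearchParams,
    min_bit: float = 20.0,
    top_n: int = 1,
    tie_bits: float = 1.0,
    lenient: bool = False,
    lambda_: float = LAMBDA_DEFAULT,
    k_const: float = KCONST_DEFAULT,
    compute_evalue: bool = False,
) -> List[Hit]:
    """All reported hits for one read, merged across chunks and sorted."""
    frames = six_frame_translate(read, lenient=lenient) if len(read.bases) >= 3 else []
    best: Dict[Tuple[int, str], Hit] = {}
    db_residues = sum(c.residue_count() for c in chunks) if compute_evalue else None
    for frame in frames:
        if len(frame.residues) < params.k:
            continue
        keys = query_keys(frame, params.k, params.s)
        if not keys:
            continue
        for chunk in chunks:
            for cand in find_candidates(keys, chunk, params.r, params.t, frame.frame):
                hit = align_candidate(
                    frame,
                    cand,
                    chunk,
                    params,
                    min_bit=min_bit,
                    lambda_=lambda_,
                    k_const=k_const,
                    db_residues=db_residues,
                )
                if hit is None:
                    continue
                key = (frame.frame, hit.db_seq_id)
                prev = best.get(key)
                if prev is None or _hit_sort_key(hit) < _hit_sort_key(prev):
                    best[key] = hit
    hits = sorted(best.values(), key=_hit_sort_key)
    if len(hits) > top_n:
        cutoff = hits[top_n - 1].bit_score - tie_bits
        kept = hits[:top_n]
        for hit in hits[top_n:]:
            if hit.bit_score >= cutoff:
                kept.append(hit)
            else:
                break
        hits = kept
    return hits


def search_reads(
    reads: Iterable[DnaRead],
    chunks: Sequence[IndexChunk],
    params: SearchParams,
    **kwargs,
) -> Dict[str, List[Hit]]:
    """Convenience in-memory search returning hits keyed by read id."""
    return {read.id: process_read(read, chunks, params, **kwargs) for read in reads}


def sniff_format(path: Union[str, Path]) -> str:
    """'fasta' or 'fastq' from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise seq_io.ParseError(
                f"{path}: first record starts with {line[0]!r}; expected FASTA or FASTQ"
            )
    return "empty"


def _read_queries(config: RunConfig) -> List[DnaRead]:
    fmt = sniff_format(config.query_path)
    if fmt == "empty":
        return []
    if fmt == "fasta":
        if config.quality_filter:
            raise ValueError("quality filtering requires FASTQ input with qualities")
        return list(_read_dna_fasta(config.query_path))
    reads = list(seq_io.read_fastq(config.query_path))
    if config.quality_filter:
        kept = []
        for read in reads:
            filtered = seq_io.quality_filter(read)
            if filtered is not None:
                kept.append(filtered)
        return kept
    return reads


def _read_dna_fasta(path: Union[str, Path]) -> Iterable[DnaRead]:
    # reuse the FASTA line scanner but keep DNA letters verbatim
    with open(path) as fh:
        header: Optional[str] = None
        parts: List[str] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield DnaRead(id=header, bases="".join(parts).upper())
                header = line[1:].split()[0] if line[1:].split() else ""
                parts = []
            else:
                if header is None:
                    raise seq_io.ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                parts.append(line)
        if header is not None:
            yield DnaRead(id=header, bases="".join(parts).upper())


# -- worker-pool plumbing (fork start method keeps the index shared) --------

_POOL_STATE: dict = {}


def _pool_init(chunks, params, opts) -> None:
    _POOL_STATE["chunks"] = chunks
    _POOL_STATE["params"] = params
    _POOL_STATE["opts"] = opts


def _pool_batch(batch: List[DnaRead]) -> List[List[Hit]]:
    chunks = _POOL_STATE["chunks"]
    params = _POOL_STATE["params"]
    opts = _POOL_STATE["opts"]
    return [process_read(read, chunks, params, **opts) for read in batch]


def search_all(config: RunConfig) -> int:
    """Run the full search and write tabular output; returns the hit count."""
    chunks, meta = load_chunks(config.index_path, expect_k=config.params.k)
    reads = _read_queries(config)
    opts = dict(
        min_bit=config.min_bit,
        top_n=config.top_n,
        tie_bits=config.tie_bits,
        lenient=config.lenient,
        compute_evalue=config.compute_evalue,
    )
    batches = [
        reads[i : i + config.batch_size] for i in range(0, len(reads), config.batch_size)
    ]
    results: List[List[Hit]] = []
    if config.threads > 1 and len(batches) > 1 and hasattr(os, "fork"):
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(
            processes=config.threads,
            initializer=_pool_init,
            initargs=(chunks, config.params, opts),
        ) as pool:
            for batch_hits in pool.map(_pool_batch, batches):
                results.extend(batch_hits)
    else:
        for batch in batches:
            for read in batch:
                results.append(process_read(read, chunks, config.params, **opts))
    n_hits = 0
    with open(config.output_path, "w") as fh:
        for hits in results:  # read input order; per-read order from process_read
            seq_io.write_tabular(hits, fh)
            n_hits += len(hits)
    return n_hits
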