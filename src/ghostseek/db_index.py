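"""Chunked k-mer inverted index over a protein database.

Database sequences are concatenated with a delimiter sentinel and greedily
packed into chunks under a residue limit; each chunk carries an exact-match
map from every k-mer (not containing the delimiter, X or a stop) to its
start positions in order of appearance.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .seq_io import ProteinRecord

__all__ = [
    "DELIMITER",
    "SearchParams",
    "IndexChunk",
    "ParamError",
    "ChunkSizeError",
    "KeyLengthError",
    "IndexFormatError",
    "KMismatchError",
    "plan_chunks",
    "build_chunks",
    "index_chunk",
    "lookup",
    "save_chunks",
    "load_chunks",
]

#: sentinel inserted between concatenated sequences; outside the amino-acid alphabet
DELIMITER = "|"

INDEX_FORMAT = "ghostseek-index"
INDEX_VERSION = 1


class ParamError(ValueError):
    """Search parameter outside its valid range."""


class ChunkSizeError(ValueError):
    """A single sequence exceeds the chunk residue limit."""


class KeyLengthError(ValueError):
    """Lookup key length differs from the index k."""


class IndexFormatError(ValueError):
    """Unreadable, truncated or wrong-version index file."""


class KMismatchError(ValueError):
    """Index was built with a different seed length than requested."""


@dataclass(frozen=True)
class SearchParams:
    """All tunables of the search.

    ``k`` seed length (residues), ``s`` query-key skip, ``r`` region size,
    ``e`` extension size, ``t`` required seed matches, ``chunk_limit`` max
    residues per database chunk, plus affine gap penalties and the
    substitution matrix name.
    """

    k: int = 4
    s: int = 2
    r: int = 4
    e: int = 2
    t: int = 2
    chunk_limit: int = 128_000_000
    gap_open: int = 11
    gap_extend: int = 1
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParamError(f"k must be >= 1, got {self.k}")
        if self.s < 1:
            raise ParamError(f"s must be >= 1, got {self.s}")
        if self.r < 1:
            raise ParamError(f"r must be >= 1, got {self.r}")
        if self.e < 0:
            raise ParamError(f"e must be >= 0, got {self.e}")
        if self.t < 1:
            raise ParamError(f"t must be >= 1, got {self.t}")
        if self.chunk_limit < 1:
            raise ParamError(f"chunk_limit must be >= 1, got {self.chunk_limit}")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ParamError("gap penalties must be positive")


@dataclass
class IndexChunk:
    """A concatenated database segment with its inverted k-mer index."""

    chunk_id: int
    concat: str
    seq_table: List[Tuple[str, int, int]]  # (seq_id, start_offset, length)
    index: Dict[str, List[int]]
    k: int

    def __post_init__(self) -> None:
        self._starts = [start for _, start, _ in self.seq_table]
        self._by_id = {sid: (start, length) for sid, start, length in self.seq_table}

    def seq_entry_at(self, pos: int) -> Tuple[str, int, int]:
        """The (seq_id, start, length) entry containing concat position ``pos``."""
        i = bisect_right(self._starts, pos) - 1
        if i < 0:
            raise IndexError(f"position {pos} before first sequence")
        sid, start, length = self.seq_table[i]
        if pos >= start + length:
            raise IndexError(f"position {pos} falls on a delimiter")
        return sid, start, length

    def bounds(self, seq_id: str) -> Tuple[int, int]:
        """Half-open concat bounds of a sequence."""
        start, length = self._by_id[seq_id]
        return start, start + length

    def residue_count(self) -> int:
        return sum(length for _, _, length in self.seq_table)


def plan_chunks(lengths: Iterable[int], chunk_limit: int) -> List[Tuple[int, int]]:
    """Greedy partition of sequence lengths under a per-chunk residue limit.

    Returns half-open index ranges; a new chunk starts exactly when adding
    the next sequence would exceed ``chunk_limit``, which is the minimal
    chunk count achievable without reordering.
    """
    ranges: List[Tuple[int, int]] = []
    start = 0
    acc = 0
    n = 0
    for i, length in enumerate(lengths):
        n = i + 1
        if length > chunk_limit:
            raise ChunkSizeError(
                f"sequence #{i} has {length} residues, exceeding the chunk limit "
                f"{chunk_limit}; rebuild with a larger -l"
            )
        if acc and acc + length > chunk_limit:
            ranges.append((start, i))
            start = i
            acc = 0
        acc += length
    if n > start:
        ranges.append((start, n))
    return ranges


def index_chunk(concat: str, seq_table: Sequence[Tuple[str, int, int]], k: int) -> Dict[str, List[int]]:
    """Inverted index of every valid k-mer offset in ``concat``.

    Valid offsets lie entirely within one sequence; k-mers containing the
    delimiter, X or a stop are excluded.  Position lists come out in
    ascending (order-of-appearance) order.
    """
    if k < 1:
        raise ParamError(f"k must be >= 1, got {k}")
    index: Dict[str, List[int]] = {}
    for _, start, length in seq_table:
        for off in range(start, start + length - k + 1):
            kmer = concat[off : off + k]
            if "X" in kmer or "*" in kmer or DELIMITER in kmer:
                continue
            index.setdefault(kmer, []).append(off)
    return index


def build_chunks(db: Iterable[ProteinRecord], params: SearchParams) -> List[IndexChunk]:
    """Pack the database into chunks (greedy, input order) and index each."""
    records = list(db)
    ranges = plan_chunks((len(r.residues) for r in records), params.chunk_limit)
    chunks: List[IndexChunk] = []
    for cid, (a, b) in enumerate(ranges):
        group = records[a:b]
        concat = DELIMITER.join(rec.residues for rec in group)
        seq_table: List[Tuple[str, int, int]] = []
        pos = 0
        for rec in group:
            seq_table.append((rec.id, pos, len(rec.residues)))
            pos += len(rec.residues) + 1  # +1 for the delimiter
        chunks.append(
            IndexChunk(
                chunk_id=cid,
                concat=concat,
                seq_table=seq_table,
                index=index_chunk(concat, seq_table, params.k),
                k=params.k,
            )
        )
    return chunks


def lookup(chunk: IndexChunk, key: str) -> List[int]:
    """Exact-match positions of ``key`` in the chunk, ascending."""
    if len(key) != chunk.k:
        raise KeyLengthError(f"key {key!r} has length {len(key)}, index k is {chunk.k}")
    return chunk.index.get(key, [])


def save_chunks(
    chunks: Sequence[IndexChunk], path: Union[str, Path], params: Optional[SearchParams] = None
) -> None:
    """Serialize chunks with a self-describing header (format, version, k)."""
    k = chunks[0].k if chunks else (params.k if params else None)
    doc = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "k": k,
        "chunk_limit": params.chunk_limit if params else None,
        "n_chunks": len(chunks),
        "chunks": [
            {
                "chunk_id": c.chunk_id,
                "concat": c.concat,
                "seq_table": [list(row) for row in c.seq_table],
                "index": c.index,
            }
            for c in chunks
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_chunks(path: Union[str, Path], expect_k: Optional[int] = None):
    """Load a saved index; returns ``(chunks, meta)``.

    Raises :class:`IndexFormatError` on truncated/foreign files and
    :class:`KMismatchError` when ``expect_k`` differs from the stored k.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise IndexFormatError(f"{path}: truncated or corrupt index file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != INDEX_FORMAT:
        raise IndexFormatError(f"{path}: not a {INDEX_FORMAT} file")
    if doc.get("version") != INDEX_VERSION:
        raise IndexFormatError(
            f"{path}: index version {doc.get('version')!r}, expected {INDEX_VERSION}"
        )
    k = doc["k"]
    if expect_k is not None and k is not None and expect_k != k:
        raise KMismatchError(
            f"index was built with k={k} but k={expect_k} was requested; "
            "rebuild the index or drop the conflicting -k"
        )
    chunks = [
        IndexChunk(
            chunk_id=c["chunk_id"],
            concat=c["concat"],
            seq_table=[tuple(row) for row in c["seq_table"]],
            index={key: list(v) for key, v in c["index"].items()},
            k=k,
        )
        for c in doc["chunks"]
    ]
    meta = {"k": k, "chunk_limit": doc.get("chunk_limit"), "n_chunks": doc.get("n_chunks")}
    return chunks, meta
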