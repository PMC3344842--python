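"""Candidate alignment detection by region-bucketed seed-match counting.

Each exact k-mer match between a translated query frame (sampled every
``s`` residues) and a database sequence predicts an alignment start
``d = p - q`` (database position minus query offset).  Starts are bucketed
into regions of size ``r`` relative to the start of the database sequence;
whenever a region and its right neighbour together hold at least ``t``
matches, a candidate is emitted.  Runs of overlapping qualifying region
pairs are merged into a single candidate anchored at the smallest
contributing start, so the same stretch is never aligned twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .db_index import IndexChunk, ParamError, SearchParams, lookup
from .seq_io import DnaRead
from .translate import TranslatedFrame, six_frame_translate

__all__ = [
    "Candidate",
    "query_keys",
    "group_matches",
    "find_candidates",
    "count_candidates",
]


@dataclass(frozen=True)
class Candidate:
    """A putative alignment start on a database chunk.

    ``align_start`` is in concatenated-chunk coordinates and may precede its
    sequence start (query overhang); it is clipped into the sequence when
    the alignment window is formed.
    """

    chunk_id: int
    frame: int
    db_seq_id: str
    align_start: int
    support: int


def query_keys(frame: TranslatedFrame, k: int, s: int) -> List[Tuple[int, str]]:
    """Skip-sampled query k-mer keys at offsets 0, s, 2s, ...

    Keys containing X or a stop are omitted; a frame shorter than ``k``
    yields no keys.
    """
    if k < 1:
        raise ParamError(f"k must be >= 1, got {k}")
    if s < 1:
        raise ParamError(f"s must be >= 1, got {s}")
    res = frame.residues
    out: List[Tuple[int, str]] = []
    for q in range(0, len(res) - k + 1, s):
        key = res[q : q + k]
        if "X" in key or "*" in key:
            continue
        out.append((q, key))
    return out


def group_matches(starts: Sequence[int], r: int, t: int) -> List[Tuple[int, int]]:
    """Bucket predicted starts into regions of size ``r`` and apply the
    region + right-adjacent-region threshold ``t``.

    Returns one ``(anchor, support)`` per emitted region pair ``(b, b+1)``
    with ``count(b) + count(b+1) >= t``.  The anchor is the boundary
    ``(b+1) * r`` between the two regions, which makes the alignment window
    of size ``m + 2r + 2e`` centred on it cover every supporting match with
    ``e`` residues of gap slack on each side.  A pair whose matches are
    wholly contained in an emitted adjacent pair is suppressed.
    """
    if r <= 0:
        raise ParamError(f"r must be >= 1, got {r}")
    if not starts:
        return []
    count: Dict[int, int] = {}
    for d in starts:
        b = d // r  # floor division handles negative overhangs
        count[b] = count.get(b, 0) + 1

    def qualifies(b: int) -> bool:
        return count.get(b, 0) + count.get(b + 1, 0) >= t

    out: List[Tuple[int, int]] = []
    for b in sorted(set(count) | {b - 1 for b in count}):
        if not qualifies(b):
            continue
        # matches all in the right region and covered by the pair to the right
        if count.get(b, 0) == 0 and qualifies(b + 1):
            continue
        # matches all in the left region and covered by the emitted pair to the left
        if count.get(b + 1, 0) == 0 and qualifies(b - 1) and count.get(b - 1, 0) > 0:
            continue
        out.append(((b + 1) * r, count.get(b, 0) + count.get(b + 1, 0)))
    return out


def find_candidates(
    keys: Sequence[Tuple[int, str]],
    chunk: IndexChunk,
    r: int,
    t: int,
    frame: int = 0,
) -> List[Candidate]:
    """Candidates supported by >= t seed matches in a region pair.

    Matches are grouped per database sequence (so no candidate's support
    spans a delimiter) and bucketed on sequence-relative starts, making the
    result independent of how the database was packed into chunks.
    """
    if r <= 0:
        raise ParamError(f"r must be >= 1, got {r}")
    if t < 1:
        raise ParamError(f"t must be >= 1, got {t}")
    per_seq: Dict[Tuple[int, str], List[int]] = {}
    for q, key in keys:
        for p in lookup(chunk, key):
            sid, seq_start, _ = chunk.seq_entry_at(p)
            per_seq.setdefault((seq_start, sid), []).append((p - seq_start) - q)
    out: List[Candidate] = []
    for (seq_start, sid) in sorted(per_seq):
        for rel_start, support in group_matches(per_seq[(seq_start, sid)], r, t):
            out.append(
                Candidate(
                    chunk_id=chunk.chunk_id,
                    frame=frame,
                    db_seq_id=sid,
                    align_start=seq_start + rel_start,
                    support=support,
                )
            )
    return out


def count_candidates(
    queries: Iterable[DnaRead],
    chunks: Sequence[IndexChunk],
    params: SearchParams,
    lenient: bool = True,
) -> Dict[Tuple[str, int], int]:
    """Per (read, frame) candidate counts across all chunks.

    Batching hook: callers can use these counts to split query batches
    under a memory budget before running alignments.
    """
    counts: Dict[Tuple[str, int], int] = {}
    for read in queries:
        for frame in six_frame_translate(read, lenient=lenient):
            n = 0
            for chunk in chunks:
                keys = query_keys(frame, params.k, params.s)
                n += len(find_candidates(keys, chunk, params.r, params.t, frame.frame))
            counts[(read.id, frame.frame)] = n
    return counts
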