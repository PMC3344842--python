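"""Window-restricted Smith-Waterman scoring of candidates.

Each candidate is aligned with affine-gap Smith-Waterman (a gap of length L
costs ``gap_open + L * gap_extend``) against a database window of size
``m + 2r + 2e`` around its predicted start, where ``m`` is the translated
query length.  Raw scores convert to bit scores with the standard
Karlin-Altschul rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit

from .db_index import IndexChunk, SearchParams
from .seed_search import Candidate
from .translate import TranslatedFrame, back_map

__all__ = [
    "Hit",
    "SWResult",
    "load_matrix",
    "encode",
    "window_bounds",
    "smith_waterman",
    "align_candidate",
    "bit_score",
    "LAMBDA_DEFAULT",
    "KCONST_DEFAULT",
]

# Karlin-Altschul parameters for gapped BLOSUM62 with gap open 11 / extend 1
LAMBDA_DEFAULT = 0.267
KCONST_DEFAULT = 0.041

_NEG = -(10**7)

_MATRIX_CACHE: Dict[str, Tuple[str, np.ndarray, np.ndarray]] = {}


def load_matrix(name: str = "BLOSUM62") -> Tuple[str, np.ndarray, np.ndarray]:
    """Load a substitution matrix by name or from an NCBI-format text file.

    Returns ``(alphabet, matrix, encoder)`` where ``encoder`` maps ASCII
    codes to matrix indices (-1 for unknown characters).  The stop symbol
    ``*`` is rescored to the matrix minimum against every residue so that
    alignments never extend through stops.
    """
    if name in _MATRIX_CACHE:
        return _MATRIX_CACHE[name]
    from Bio.Align import substitution_matrices

    if Path(name).is_file():
        mat = substitution_matrices.read(name)
    else:
        mat = substitution_matrices.load(name)
    alphabet = "".join(mat.alphabet)
    arr = np.array(mat, dtype=np.int32)
    if "*" in alphabet:
        stop = alphabet.index("*")
        floor = int(arr.min())
        arr[stop, :] = floor
        arr[:, stop] = floor
    encoder = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(alphabet):
        encoder[ord(ch)] = i
    _MATRIX_CACHE[name] = (alphabet, arr, encoder)
    return _MATRIX_CACHE[name]


def encode(residues: str, encoder: np.ndarray) -> np.ndarray:
    """Encode residues to matrix indices; unknown residues are an error."""
    codes = encoder[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = residues[int(np.argmax(codes < 0))]
        raise ValueError(f"residue {bad!r} not in substitution matrix alphabet")
    return codes.astype(np.int64)


@njit(cache=True)
def _sw_kernel(q, t, sub, gap_open, gap_ext):  # pragma: no cover - compiled
    m = q.shape[0]
    n = t.shape[0]
    goe = gap_open + gap_ext
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - goe
            if E[i, j - 1] - gap_ext > e:
                e = E[i, j - 1] - gap_ext
            f = H[i - 1, j] - goe
            if F[i - 1, j] - gap_ext > f:
                f = F[i - 1, j] - gap_ext
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback; prefers diagonal moves and shortest gaps on score ties
    i = bi
    j = bj
    state = 0  # 0 = match state, 1 = gap in target dim (E), 2 = gap in query dim (F)
    matches = 0
    mism = 0
    gap_opens = 0
    alen = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = sub[q[i - 1], t[j - 1]]
            if H[i, j] == H[i - 1, j - 1] + s:
                alen += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                else:
                    mism += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            alen += 1
            if E[i, j] == H[i, j - 1] - goe:
                gap_opens += 1
                state = 0
            j -= 1
        else:
            alen += 1
            if F[i, j] == H[i - 1, j] - goe:
                gap_opens += 1
                state = 0
            i -= 1
    return best, i, bi, j, bj, alen, matches, mism, gap_opens


@dataclass(frozen=True)
class SWResult:
    """Optimal local alignment of two protein strings."""

    score: int
    q_start: int  # 0-based half-open, on the query protein
    q_end: int
    t_start: int  # 0-based half-open, on the target protein
    t_end: int
    align_len: int
    matches: int
    mismatches: int
    gap_openings: int


def smith_waterman(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> SWResult:
    """Affine-gap Smith-Waterman local alignment of two protein strings.

    A score-0 result has empty intervals.
    """
    if not query or not target:
        raise ValueError("smith_waterman requires non-empty sequences")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    _, sub, enc = load_matrix(matrix)
    q = encode(query, enc)
    t = encode(target, enc)
    score, qs, qe, ts, te, alen, matches, mism, gaps = _sw_kernel(
        q, t, sub, np.int32(gap_open), np.int32(gap_extend)
    )
    return SWResult(
        score=int(score),
        q_start=int(qs),
        q_end=int(qe),
        t_start=int(ts),
        t_end=int(te),
        align_len=int(alen),
        matches=int(matches),
        mismatches=int(mism),
        gap_openings=int(gaps),
    )


def bit_score(raw: float, lambda_: float = LAMBDA_DEFAULT, k_const: float = KCONST_DEFAULT) -> float:
    """Karlin-Altschul bit score: ``(lambda * raw - ln k) / ln 2``."""
    if lambda_ <= 0 or k_const <= 0:
        raise ValueError("lambda and k must be positive")
    if raw < 0:
        raise ValueError(f"raw score must be >= 0, got {raw}")
    return (lambda_ * raw - math.log(k_const)) / math.log(2)


def window_bounds(
    candidate: Candidate,
    m: int,
    r: int,
    e: int,
    seq_start: int,
    seq_end: int,
) -> Tuple[int, int]:
    """Alignment window of size <= m + 2r + 2e around a candidate start.

    The window is clipped to the candidate's source-sequence bounds so it
    never crosses a delimiter.
    """
    if m < 1:
        raise ValueError(f"query frame length must be >= 1, got {m}")
    lo = max(seq_start, candidate.align_start - (r + e))
    hi = min(seq_end, candidate.align_start + m + r + e)
    return lo, hi


@dataclass(frozen=True)
class Hit:
    """A scored local alignment of a read frame against a database sequence.

    Query coordinates are 0-based half-open DNA positions on the forward
    strand of the original read; subject coordinates are 0-based half-open
    protein positions.
    """

    read_id: str
    frame: int
    db_seq_id: str
    raw_score: int
    bit_score: float
    identity_pct: float
    align_len: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: Optional[float] = None


def align_candidate(
    frame: TranslatedFrame,
    candidate: Candidate,
    chunk: IndexChunk,
    params: SearchParams,
    min_bit: float = 20.0,
    lambda_: float = LAMBDA_DEFAULT,
    k_const: float = KCONST_DEFAULT,
    db_residues: Optional[int] = None,
) -> Optional[Hit]:
    """Score one candidate with window-restricted Smith-Waterman.

    Returns a :class:`Hit` when the alignment reaches ``min_bit`` bits,
    otherwise ``None``.  When ``db_residues`` is given, an e-value
    ``E = k * m * n * exp(-lambda * S)`` is attached.
    """
    m = len(frame.residues)
    if m == 0:
        return None
    seq_start, seq_end = chunk.bounds(candidate.db_seq_id)
    lo, hi = window_bounds(candidate, m, params.r, params.e, seq_start, seq_end)
    if hi - lo < 1:
        return None
    res = smith_waterman(
        frame.residues, chunk.concat[lo:hi], params.matrix, params.gap_open, params.gap_extend
    )
    if res.score <= 0:
        return None
    bits = bit_score(res.score, lambda_, k_const)
    if bits < min_bit:
        return None
    q_dna_start, q_dna_end = back_map(frame, res.q_start, res.q_end - res.q_start)
    evalue = None
    if db_residues is not None:
        evalue = k_const * m * db_residues * math.exp(-lambda_ * res.score)
    return Hit(
        read_id=frame.read_id,
        frame=frame.frame,
        db_seq_id=candidate.db_seq_id,
        raw_score=res.score,
        bit_score=bits,
        identity_pct=100.0 * res.matches / res.align_len,
        align_len=res.align_len,
        mismatches=res.mismatches,
        gap_openings=res.gap_openings,
        q_start=q_dna_start,
        q_end=q_dna_end,
        s_start=lo + res.t_start - seq_start,
        s_end=lo + res.t_end - seq_start,
        evalue=evalue,
    )
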