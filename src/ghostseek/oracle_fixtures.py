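"""Synthetic database/read generation, the exhaustive Smith-Waterman oracle,
and recall-vs-bit-score evaluation.

The oracle is a separate, score-only, linear-memory Smith-Waterman scan over
the whole database (all six frames, no window restriction); it plays the
role an exhaustive aligner plays when benchmarking heuristic search
sensitivity, and is implemented independently of the windowed aligner it
is used to judge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .db_index import SearchParams
from .local_align import KCONST_DEFAULT, LAMBDA_DEFAULT, Hit, bit_score, encode, load_matrix
from .seq_io import DnaRead, ProteinRecord
from .translate import CODON_TO_AA, revcomp, six_frame_translate

__all__ = [
    "SyntheticSpec",
    "TruthRow",
    "OracleBest",
    "BACKGROUND_FREQS",
    "generate_db",
    "generate_reads",
    "full_sw_search",
    "sensitivity_curve",
    "recall_ge",
    "best_subjects",
    "save_oracle",
    "load_oracle",
    "write_truth",
    "read_truth",
]

#: Robinson & Robinson amino-acid background frequencies (the BLOSUM62 /
#: BLAST background composition)
BACKGROUND_FREQS: Dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_AA20 = "".join(BACKGROUND_FREQS)

#: ungapped Karlin-Altschul lambda for BLOSUM62, used only by the mutation model
_LAMBDA_UNGAPPED = 0.3176

_NEG = -(10**7)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic database/read fixture.

    ``target_identity`` may be a single fraction or an inclusive (low, high)
    range sampled per read.  Everything is deterministic for a fixed seed.
    """

    n_db_seqs: int = 2000
    db_len_range: Tuple[int, int] = (100, 500)
    n_reads: int = 2000
    read_len_range: Tuple[int, int] = (60, 75)
    target_identity: Union[float, Tuple[float, float]] = 0.8
    indel_rate: float = 0.01
    quality_profile: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        ids = self.target_identity
        lo, hi = (ids, ids) if isinstance(ids, (int, float)) else ids
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"target_identity must lie in (0, 1], got {ids}")
        if self.read_len_range[0] < 3:
            raise ValueError("reads must be at least one codon long")


@dataclass(frozen=True)
class TruthRow:
    """Provenance of one synthetic read."""

    read_id: str
    subject_id: str
    frame: int
    subject_start: int  # 0-based half-open protein interval on the source
    subject_end: int
    realized_identity: float


def generate_db(spec: SyntheticSpec) -> List[ProteinRecord]:
    """i.i.d. protein sequences drawn from the BLOSUM62 background composition."""
    rng = np.random.default_rng(spec.seed)
    freqs = np.array(list(BACKGROUND_FREQS.values()))
    freqs = freqs / freqs.sum()
    letters = np.array(list(_AA20))
    records = []
    lo, hi = spec.db_len_range
    for i in range(spec.n_db_seqs):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(letters[rng.choice(len(letters), size=length, p=freqs)])
        records.append(ProteinRecord(id=f"db{i:05d}", residues=residues))
    return records


def _conditional_substitutions() -> np.ndarray:
    """P(b | a, b != a) proportional to BLOSUM62 target frequencies."""
    _, sub, enc = load_matrix("BLOSUM62")
    idx = encode(_AA20, enc)
    p = np.array(list(BACKGROUND_FREQS.values()))
    p = p / p.sum()
    scores = sub[np.ix_(idx, idx)].astype(float)
    q = np.outer(p, p) * np.exp(_LAMBDA_UNGAPPED * scores)
    np.fill_diagonal(q, 0.0)
    return q / q.sum(axis=1, keepdims=True)


_AA_TO_CODONS: Dict[str, List[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _codons in _AA_TO_CODONS.values():
    _codons.sort()


def generate_reads(
    db: Sequence[ProteinRecord], spec: SyntheticSpec
) -> Tuple[List[DnaRead], List[TruthRow]]:
    """Reads reverse-translated from database fragments at controlled divergence.

    Per read: sample a source fragment, substitute residues to the target
    identity (substitutions drawn from BLOSUM62 conditional probabilities),
    apply single-residue indels at ``indel_rate``, reverse-translate with
    uniformly random synonymous codons, place on a random strand at a random
    codon phase, and pad with random bases into the read length range.
    """
    if not db:
        raise ValueError("database is empty")
    rng = np.random.default_rng(spec.seed + 1)
    cond = _conditional_substitutions()
    aa_index = {aa: i for i, aa in enumerate(_AA20)}
    ids = spec.target_identity
    id_lo, id_hi = (ids, ids) if isinstance(ids, (int, float)) else ids
    len_lo, len_hi = spec.read_len_range
    reads: List[DnaRead] = []
    truth: List[TruthRow] = []
    bases = "ACGT"
    for i in range(spec.n_reads):
        read_len = int(rng.integers(len_lo, len_hi + 1))
        n_aa = read_len // 3
        while True:
            src = db[int(rng.integers(len(db)))]
            if len(src.residues) >= n_aa:
                break
        start = int(rng.integers(0, len(src.residues) - n_aa + 1))
        fragment = list(src.residues[start : start + n_aa])
        identity_target = float(rng.uniform(id_lo, id_hi))
        conserved = 0
        mutated: List[str] = []
        for aa in fragment:
            if aa in aa_index and rng.random() > identity_target:
                mutated.append(_AA20[rng.choice(len(_AA20), p=cond[aa_index[aa]])])
            else:
                mutated.append(aa)
                conserved += 1
        realized = conserved / len(fragment)
        # single-residue indels
        with_indels: List[str] = []
        for aa in mutated:
            u = rng.random()
            if u < spec.indel_rate / 2:
                continue  # deletion
            with_indels.append(aa)
            if u > 1 - spec.indel_rate / 2:
                with_indels.append(_AA20[int(rng.integers(len(_AA20)))])
        if not with_indels:
            with_indels = mutated[:1]
        lead = int(rng.integers(0, 3))
        # trim codons that would push the read past the length range
        max_aa = (len_hi - lead) // 3
        with_indels = with_indels[:max_aa]
        codons = "".join(
            _AA_TO_CODONS[aa][int(rng.integers(len(_AA_TO_CODONS[aa])))]
            if aa in _AA_TO_CODONS
            else "NNN"
            for aa in with_indels
        )
        coding = "".join(bases[int(rng.integers(4))] for _ in range(lead)) + codons
        if len(coding) < len_lo:
            coding += "".join(
                bases[int(rng.integers(4))] for _ in range(len_lo - len(coding))
            )
        forward = rng.random() < 0.5
        frame = (lead % 3) + 1
        if forward:
            seq = coding
        else:
            seq = revcomp(coding)
            frame = -frame
        read_id = f"read{i:05d}"
        reads.append(
            DnaRead(id=read_id, bases=seq, quals=[spec.quality_profile] * len(seq))
        )
        truth.append(
            TruthRow(
                read_id=read_id,
                subject_id=src.id,
                frame=frame,
                subject_start=start,
                subject_end=start + n_aa,
                realized_identity=realized,
            )
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Exhaustive Smith-Waterman oracle
# ---------------------------------------------------------------------------


@njit(cache=True)
def _scan_best(prof, db, starts, lens, goe, ge, out):  # pragma: no cover - compiled
    """Score-only affine SW of one query profile against every db sequence."""
    m = prof.shape[1]
    H = np.zeros(m + 1, np.int32)
    E = np.full(m + 1, _NEG, np.int32)
    for k in range(starts.shape[0]):
        best = 0
        for i in range(m + 1):
            H[i] = 0
            E[i] = _NEG
        for j in range(starts[k], starts[k] + lens[k]):
            row = prof[db[j]]
            f = _NEG
            diag = 0
            for i in range(1, m + 1):
                hold = H[i]
                e = hold - goe
                if E[i] - ge > e:
                    e = E[i] - ge
                fcand = H[i - 1] - goe
                if f - ge > fcand:
                    f = f - ge
                else:
                    f = fcand
                h = diag + row[i - 1]
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                diag = hold
                H[i] = h
                E[i] = e
                if h > best:
                    best = h
        out[k] = best


@dataclass(frozen=True)
class OracleBest:
    """Best exhaustive-SW hit of a read, with its score tie set."""

    read_id: str
    raw_score: int
    bit: float
    subjects: FrozenSet[str]


def full_sw_search(
    reads: Iterable[DnaRead],
    db: Sequence[ProteinRecord],
    params: Optional[SearchParams] = None,
    lambda_: float = LAMBDA_DEFAULT,
    k_const: float = KCONST_DEFAULT,
) -> Dict[str, OracleBest]:
    """Per-read best full Smith-Waterman hit over all six frames and sequences.

    Uses the same matrix, gap penalties and bit conversion as the windowed
    aligner; reads with no positive-scoring alignment are omitted.
    """
    params = params or SearchParams()
    _, sub, enc = load_matrix(params.matrix)
    sub = np.ascontiguousarray(sub, dtype=np.int32)
    starts = np.empty(len(db), np.int64)
    lens = np.empty(len(db), np.int64)
    pos = 0
    codes_parts = []
    for i, rec in enumerate(db):
        starts[i] = pos
        lens[i] = len(rec.residues)
        codes_parts.append(encode(rec.residues, enc))
        pos += len(rec.residues)
    db_codes = (
        np.concatenate(codes_parts) if codes_parts else np.empty(0, np.int64)
    )
    goe = np.int32(params.gap_open + params.gap_extend)
    ge = np.int32(params.gap_extend)
    ids = [rec.id for rec in db]
    out: Dict[str, OracleBest] = {}
    scores = np.empty(len(db), np.int32)
    for read in reads:
        if len(read.bases) < 3:
            continue
        best_score = 0
        best_subjects: set = set()
        for frame in six_frame_translate(read, lenient=True):
            if not frame.residues:
                continue
            q = encode(frame.residues, enc)
            prof = np.ascontiguousarray(sub[:, q])
            _scan_best(prof, db_codes, starts, lens, goe, ge, scores)
            frame_max = int(scores.max()) if len(db) else 0
            if frame_max > best_score:
                best_score = frame_max
                best_subjects = {ids[j] for j in np.flatnonzero(scores == frame_max)}
            elif frame_max == best_score and frame_max > 0:
                best_subjects.update(ids[j] for j in np.flatnonzero(scores == frame_max))
        if best_score > 0:
            out[read.id] = OracleBest(
                read_id=read.id,
                raw_score=best_score,
                bit=bit_score(best_score, lambda_, k_const),
                subjects=frozenset(best_subjects),
            )
    return out


# ---------------------------------------------------------------------------
# Sensitivity evaluation
# ---------------------------------------------------------------------------


def best_subjects(hits: Sequence[Hit]) -> FrozenSet[str]:
    """Subjects of the top-raw-score hits of one read (tie set)."""
    if not hits:
        return frozenset()
    top = max(h.raw_score for h in hits)
    return frozenset(h.db_seq_id for h in hits if h.raw_score == top)


def _recovered(tool_hits: Sequence[Hit], oracle: OracleBest) -> bool:
    return bool(best_subjects(tool_hits) & oracle.subjects)


def sensitivity_curve(
    tool_hits: Dict[str, Sequence[Hit]],
    oracle_hits: Dict[str, OracleBest],
    bins: Optional[Sequence[float]] = None,
) -> List[Tuple[float, float, int, int, float]]:
    """Fraction of oracle best hits recovered per oracle-bit-score bin.

    ``bins`` are ascending lower bin edges (default 20, 30, ... 100); the
    last bin is open-ended.  Returns rows of
    ``(bin_lo, bin_hi, n_oracle, n_recovered, fraction)``; ``fraction`` is
    NaN for empty bins.
    """
    if bins is None:
        bins = [20.0 + 10.0 * i for i in range(9)]
    bins = list(bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError(f"bin edges must be strictly increasing, got {bins}")
    edges = bins + [math.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = 0
        hit = 0
        for read_id, oracle in oracle_hits.items():
            if lo <= oracle.bit < hi:
                n += 1
                if _recovered(tool_hits.get(read_id, []), oracle):
                    hit += 1
        rows.append((lo, hi, n, hit, hit / n if n else math.nan))
    return rows


def recall_ge(
    tool_hits: Dict[str, Sequence[Hit]],
    oracle_hits: Dict[str, OracleBest],
    min_bit: float = 50.0,
) -> Tuple[float, int]:
    """Overall fraction of oracle hits with bit >= ``min_bit`` recovered."""
    n = 0
    hit = 0
    for read_id, oracle in oracle_hits.items():
        if oracle.bit >= min_bit:
            n += 1
            if _recovered(tool_hits.get(read_id, []), oracle):
                hit += 1
    return (hit / n if n else math.nan), n


# ---------------------------------------------------------------------------
# Plain-text table round-trips
# ---------------------------------------------------------------------------


def save_oracle(oracle_hits: Dict[str, OracleBest], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\traw_score\tbit\tsubjects\n")
        for read_id in sorted(oracle_hits):
            ob = oracle_hits[read_id]
            fh.write(
                f"{ob.read_id}\t{ob.raw_score}\t{ob.bit:.6f}\t"
                + ",".join(sorted(ob.subjects))
                + "\n"
            )


def load_oracle(path: Union[str, Path]) -> Dict[str, OracleBest]:
    out: Dict[str, OracleBest] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            read_id, raw, bit, subjects = line.rstrip("\n").split("\t")
            out[read_id] = OracleBest(
                read_id=read_id,
                raw_score=int(raw),
                bit=float(bit),
                subjects=frozenset(subjects.split(",")) if subjects else frozenset(),
            )
    return out


def write_truth(truth: Sequence[TruthRow], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsubject_id\tframe\tsubject_start\tsubject_end\trealized_identity\n")
        for row in truth:
            fh.write(
                f"{row.read_id}\t{row.subject_id}\t{row.frame}\t"
                f"{row.subject_start}\t{row.subject_end}\t{row.realized_identity:.4f}\n"
            )


def read_truth(path: Union[str, Path]) -> List[TruthRow]:
    out: List[TruthRow] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, sid, frame, a, b, ident = line.rstrip("\n").split("\t")
            out.append(TruthRow(rid, sid, int(frame), int(a), int(b), float(ident)))
    return out
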