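"""Six-frame translation of DNA reads with coordinate back-mapping.

Codons containing ``N`` translate to ``X`` (any amino acid), stop codons to
``*``.  Negative frames translate the reverse complement; frame offsets are
``0/1/2`` for ``+-1/+-2/+-3``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple

from Bio.Data import CodonTable

from .seq_io import DnaRead

__all__ = [
    "TranslatedFrame",
    "TranslationError",
    "FrameBoundsError",
    "FRAMES",
    "revcomp",
    "translate_frame",
    "six_frame_translate",
    "back_map",
]

FRAMES: Tuple[int, ...] = (1, 2, 3, -1, -2, -3)

STOP = "*"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = STOP

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_ALPHABET = frozenset("ACGTN")


class TranslationError(ValueError):
    """Invalid nucleotide or frame."""


class FrameBoundsError(ValueError):
    """Protein interval outside the translated frame."""


@dataclass
class TranslatedFrame:
    """One of the six protein readings of a DNA read."""

    read_id: str
    frame: int  # one of +-1, +-2, +-3
    residues: str
    dna_length: int


def revcomp(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def _translate_codons(strand: str, offset: int) -> str:
    out = []
    for i in range(offset, len(strand) - 2, 3):
        codon = strand[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)


def translate_frame(
    bases: str, frame: int, read_id: str = "", lenient: bool = False
) -> TranslatedFrame:
    """Translate one reading frame of ``bases``.

    In strict mode (default) characters outside ``{A,C,G,T,N}`` are rejected
    with an error naming the character; in lenient mode they are mapped to
    ``N`` (hence ``X`` in the translation).
    """
    if frame not in FRAMES:
        raise TranslationError(f"invalid frame {frame!r}; expected one of {FRAMES}")
    up = bases.upper()
    bad = [ch for ch in up if ch not in _DNA_ALPHABET]
    if bad:
        if lenient:
            up = "".join(ch if ch in _DNA_ALPHABET else "N" for ch in up)
        else:
            raise TranslationError(
                f"invalid nucleotide {bad[0]!r} in read {read_id!r} "
                "(use lenient mode to map it to N)"
            )
    strand = up if frame > 0 else revcomp(up)
    offset = abs(frame) - 1
    return TranslatedFrame(
        read_id=read_id,
        frame=frame,
        residues=_translate_codons(strand, offset),
        dna_length=len(up),
    )


def six_frame_translate(read: DnaRead, lenient: bool = False) -> List[TranslatedFrame]:
    """All six frames of a read, in order (+1, +2, +3, -1, -2, -3)."""
    if len(read.bases) < 3:
        warnings.warn(
            f"read {read.id!r} is shorter than 3 bases; no frames produced",
            stacklevel=2,
        )
        return []
    return [translate_frame(read.bases, f, read.id, lenient) for f in FRAMES]


def back_map(frame: TranslatedFrame, protein_start: int, protein_len: int) -> Tuple[int, int]:
    """Map a protein interval of a frame to forward-strand DNA coordinates.

    Returns 0-based half-open coordinates on the original (forward) read;
    orientation is carried by the frame sign, not by the interval order.
    """
    if protein_start < 0 or protein_len < 0 or protein_start + protein_len > len(frame.residues):
        raise FrameBoundsError(
            f"protein interval [{protein_start}, {protein_start + protein_len}) "
            f"outside frame of length {len(frame.residues)}"
        )
    offset = abs(frame.frame) - 1
    a = offset + 3 * protein_start
    b = a + 3 * protein_len
    if frame.frame > 0:
        return a, b
    n = frame.dna_length
    return n - b, n - a
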