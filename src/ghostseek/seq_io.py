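"""Sequence I/O: FASTA/FASTQ parsing, read-quality trimming, BLAST-tabular output.

Parsing normalises records to the internal alphabets (uppercase DNA /
uppercase amino acids with out-of-alphabet residues mapped to ``X``).
Coordinates are 0-based half-open everywhere inside the package; the
conversion to 1-based inclusive BLAST coordinates happens only in
:func:`write_tabular`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, TextIO, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "DnaRead",
    "ProteinRecord",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "quality_filter",
    "write_tabular",
    "read_tabular",
    "TabularRow",
]

#: residues kept verbatim by the protein parser; everything else becomes X
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PHRED_OFFSET = 33


class ParseError(ValueError):
    """Malformed FASTA/FASTQ/tabular input."""


@dataclass
class DnaRead:
    """A DNA sequencing read, optionally with per-base Phred qualities."""

    id: str
    bases: str
    quals: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ParseError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ProteinRecord:
    """A protein database sequence over the 20 amino acids plus X."""

    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def _clean_residues(raw: str) -> str:
    up = raw.upper()
    return "".join(ch if ch in AMINO_ALPHABET else "X" for ch in up)


def read_fasta(path: Union[str, Path]) -> Iterator[ProteinRecord]:
    """Stream :class:`ProteinRecord` objects from a FASTA file.

    Headers are truncated at the first whitespace; residues are uppercased
    and characters outside the 20-amino-acid+X alphabet are mapped to X.
    Sequence data before the first header is a :class:`ParseError` naming
    the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header: Optional[str] = None
        parts: List[str] = []
        header_line = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _finish_fasta_record(header, parts, path, header_line)
                header = line[1:].split()[0] if line[1:].split() else ""
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                parts.append(line)
        if header is not None:
            yield _finish_fasta_record(header, parts, path, header_line)


def _finish_fasta_record(
    header: str, parts: List[str], path: Path, lineno: int
) -> ProteinRecord:
    residues = _clean_residues("".join(parts))
    if not residues:
        raise ParseError(f"{path}:{lineno}: record {header!r} has an empty sequence")
    return ProteinRecord(id=header, residues=residues)


def read_fastq(path: Union[str, Path]) -> Iterator[DnaRead]:
    """Stream :class:`DnaRead` objects from a Phred+33 FASTQ file.

    Truncated records and base/quality length mismatches raise
    :class:`ParseError`.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield DnaRead(
                    id=title.split()[0] if title.split() else "",
                    bases=seq.upper(),
                    quals=[ord(c) - PHRED_OFFSET for c in qual],
                )
        except ValueError as exc:  # biopython signals malformed FASTQ this way
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Sequence[ProteinRecord], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_fastq(reads: Sequence[DnaRead], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            if read.quals is None:
                raise ValueError(f"read {read.id!r} has no qualities; use write_fasta")
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def quality_filter(
    read: DnaRead,
    q_min: int = 15,
    min_run: int = 60,
    trim: bool = True,
) -> Optional[DnaRead]:
    """Apply the Q>=15-over->=60-bp read selection rule.

    Finds the longest contiguous run of bases with quality >= ``q_min``
    (leftmost run on ties).  With ``trim=True`` the read is trimmed to that
    run and returned if the run spans at least ``min_run`` bases, otherwise
    ``None``.  With ``trim=False`` the whole read passes or fails on the
    same criterion without trimming.
    """
    if read.quals is None:
        raise ValueError(
            f"read {read.id!r} has no quality scores; quality filtering requires "
            "FASTQ input (use the FASTA path to skip filtering)"
        )
    best_start = best_len = 0
    run_start: Optional[int] = None
    for i, q in enumerate(read.quals + [-1]):  # sentinel terminates last run
        if q >= q_min:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len < min_run:
        return None
    if not trim:
        return read
    end = best_start + best_len
    return DnaRead(
        id=read.id,
        bases=read.bases[best_start:end],
        quals=read.quals[best_start:end],
    )


# ---------------------------------------------------------------------------
# BLAST tabular ("-outfmt 6" / blast8) output
# ---------------------------------------------------------------------------

#: placeholder emitted in the e-value column when e-values are not computed
EVALUE_PLACEHOLDER = "NA"


@dataclass
class TabularRow:
    """One parsed line of 12-column BLAST tabular output."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatches: int
    gap_openings: int
    q_start: int  # 1-based inclusive DNA; > q_end on the reverse strand
    q_end: int
    s_start: int  # 1-based inclusive protein
    s_end: int
    evalue: Optional[float]
    bit_score: float


def _hit_to_columns(hit) -> List[str]:
    if hit.frame > 0:
        q1, q2 = hit.q_start + 1, hit.q_end
    else:
        q1, q2 = hit.q_end, hit.q_start + 1
    ev = EVALUE_PLACEHOLDER if hit.evalue is None else f"{hit.evalue:.2g}"
    return [
        hit.read_id,
        hit.db_seq_id,
        f"{hit.identity_pct:.2f}",
        str(hit.align_len),
        str(hit.mismatches),
        str(hit.gap_openings),
        str(q1),
        str(q2),
        str(hit.s_start + 1),
        str(hit.s_end),
        ev,
        f"{hit.bit_score:.1f}",
    ]


def write_tabular(hits: Sequence, sink: Union[str, Path, TextIO]) -> None:
    """Write hits as 12-column tab-separated BLAST tabular lines."""
    own = False
    if isinstance(sink, (str, Path)):
        fh: TextIO = open(sink, "w")
        own = True
    else:
        fh = sink
    try:
        for hit in hits:
            fh.write("\t".join(_hit_to_columns(hit)) + "\n")
    finally:
        if own:
            fh.close()


def read_tabular(source: Union[str, Path, TextIO]) -> Iterator[TabularRow]:
    """Parse 12-column BLAST tabular output back into :class:`TabularRow`."""
    own = False
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source)
        own = True
    else:
        fh = source
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"line {lineno}: expected 12 columns, got {len(cols)}")
            yield TabularRow(
                query_id=cols[0],
                subject_id=cols[1],
                identity_pct=float(cols[2]),
                align_len=int(cols[3]),
                mismatches=int(cols[4]),
                gap_openings=int(cols[5]),
                q_start=int(cols[6]),
                q_end=int(cols[7]),
                s_start=int(cols[8]),
                s_end=int(cols[9]),
                evalue=None if cols[10] == EVALUE_PLACEHOLDER else float(cols[10]),
                bit_score=float(cols[11]),
            )
    finally:
        if own:
            fh.close()
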