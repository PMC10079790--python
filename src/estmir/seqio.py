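"""FASTA I/O, RNA normalization, and base-composition statistics.

All sequences in the package live in the uppercase RNA alphabet
``{A, C, G, U, N}``; DNA input is normalized on read (``T`` → ``U``).
Coordinates everywhere are 0-based, half-open; strand ``+`` means the
sequence as given, ``-`` its reverse complement.

Composition percentages are *truncated* toward zero at two decimals, not
rounded: published per-miRNA G+C tables (e.g. 6/19 printed as 31.57, 7/18
as 38.88) are reproducible only under truncation. Raw fractions are kept
internally; truncation applies to report fields only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("estmir")

RNA_ALPHABET = frozenset("ACGUN")

_NORMALIZE = str.maketrans("acgutnT", "ACGUUNU")
_RC = str.maketrans("ACGUN", "UGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (message names the offending line)."""


class CompositionError(ValueError):
    """Raised when base composition is undefined (e.g. all-N sequence)."""


def normalize_residues(raw: str) -> str:
    """Uppercase and convert to RNA (T→U). Rejects non-ACGUN characters."""
    residues = raw.translate(_NORMALIZE)
    if not set(residues) <= RNA_ALPHABET:
        bad = sorted(set(residues) - RNA_ALPHABET)
        raise FastaFormatError(f"invalid residue(s) {bad} in sequence")
    return residues


def reverse_complement(residues: str) -> str:
    """Reverse complement in the RNA alphabet (N ↔ N)."""
    return residues.translate(_RC)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (EST, miRNA or transcript), RNA alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        if not set(self.residues) <= RNA_ALPHABET:
            raise FastaFormatError(f"record {self.id!r} has non-RNA residues")

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.residues),
                              self.description)


@dataclass(frozen=True)
class Composition:
    """G+C / A+U content of a sequence; N residues excluded from both sides."""

    gc_fraction: float
    au_fraction: float
    gc_percent_2dp: float
    au_percent_2dp: float


def _truncate_percent(count: int, denom: int) -> float:
    # exact integer truncation at 2 decimals: (count/denom*100) floored
    return (count * 10000 // denom) / 100.0


def composition(seq: str | SequenceRecord) -> Composition:
    """Base composition over non-N residues, with 2-decimal truncated percents.

    Raises :class:`CompositionError` on an empty or all-N sequence. Sequences
    with more than 10% N are flagged in the log (composition still computed).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else normalize_residues(seq)
    if not residues:
        raise CompositionError("empty sequence has no composition")
    n_count = residues.count("N")
    denom = len(residues) - n_count
    if denom == 0:
        raise CompositionError("all-N sequence: composition undefined")
    if n_count > 0.10 * len(residues):
        logger.warning("sequence is >10%% N (%d of %d residues)",
                       n_count, len(residues))
    gc = residues.count("G") + residues.count("C")
    au = denom - gc
    return Composition(
        gc_fraction=gc / denom,
        au_fraction=au / denom,
        gc_percent_2dp=_truncate_percent(gc, denom),
        au_percent_2dp=_truncate_percent(au, denom),
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or single-line) FASTA file into normalized records.

    Order is preserved. Empty files, leading junk before the first header
    and empty sequences raise :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next((i for i, ln in enumerate(lines) if ln.strip()), None)
    if first_content is None:
        raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
    if not lines[first_content].startswith(">"):
        raise FastaFormatError(
            f"{path}: line {first_content + 1} is not a FASTA header")

    records: list[SequenceRecord] = []
    header_line = {}
    lineno = 0
    for ln in lines:
        lineno += 1
        if ln.startswith(">"):
            header_line[len(header_line)] = lineno
    for idx, rec in enumerate(SeqIO.parse(path, "fasta")):
        if len(rec.seq) == 0:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} (header at line "
                f"{header_line.get(idx, '?')}) has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            residues = normalize_residues(str(rec.seq))
        except FastaFormatError as exc:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} (header at line "
                f"{header_line.get(idx, '?')}): {exc}") from exc
        records.append(SequenceRecord(rec.id, residues, desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-record FASTA, 60-column wrapped."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
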