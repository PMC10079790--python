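"""Separate protein-coding from non-coding ESTs.

A precursor-miRNA survey only folds ESTs that are unlikely to be mRNA
fragments. The filter here is a six-frame open-reading-frame heuristic —
an EST is called coding when its longest AUG-initiated, stop-terminated
ORF reaches a codon threshold (default 80 codons ≈ 240 nt) — plus an
import hook for external translated-alignment results in BLAST tabular
(outfmt 6) form, which override the heuristic: any EST with at least one
alignment row is treated as protein-coding.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .seqio import FastaFormatError, SequenceRecord, reverse_complement

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

DEFAULT_ORF_THRESHOLD = 80  # codons


def _longest_orf_in_frame(frame_seq: str) -> int:
    """Longest AUG..stop ORF in one reading frame, in codons (stop excluded)."""
    best = 0
    start = None
    for i in range(0, len(frame_seq) - 2, 3):
        codon = frame_seq[i:i + 3]
        if start is None:
            if codon == "AUG":
                start = i
        elif codon in STOP_CODONS:
            best = max(best, (i - start) // 3)
            start = None
    return best


def longest_orf(seq: SequenceRecord) -> int:
    """Longest AUG-initiated, stop-terminated ORF over all six frames, in
    codons (AUG counted, stop codon not). 0 if no terminated ORF exists."""
    best = 0
    for strand_seq in (seq.residues, reverse_complement(seq.residues)):
        for offset in range(3):
            best = max(best, _longest_orf_in_frame(strand_seq[offset:]))
    return best


def classify_coding(
    seq: SequenceRecord,
    orf_threshold_codons: int = DEFAULT_ORF_THRESHOLD,
    external_coding_ids: set[str] | None = None,
) -> str:
    """Classify an EST as ``"coding"`` or ``"noncoding"``.

    Coding iff the longest six-frame ORF reaches the threshold, or the EST
    id appears in the imported external-alignment call set.
    """
    if orf_threshold_codons <= 0:
        raise ValueError("orf_threshold_codons must be > 0")
    if external_coding_ids and seq.id in external_coding_ids:
        return "coding"
    return "coding" if longest_orf(seq) >= orf_threshold_codons else "noncoding"


def import_external_coding_calls(path: str | Path) -> set[str]:
    """Read a BLAST tabular (outfmt 6 dialect) file; any EST with ≥1 row is
    marked coding. Only the first (query id) column is used; an empty table
    yields no overrides."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", header=None, comment="#",
                            dtype=str, usecols=[0])
    except pd.errors.EmptyDataError:
        return set()
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise FastaFormatError(f"{path}: unreadable tabular file: {exc}") from exc
    return set(table[0].dropna())
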