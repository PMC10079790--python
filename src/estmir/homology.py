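"""Mismatch-tolerant, ungapped homology search of mature miRNAs against ESTs.

Mature plant miRNAs are 18–24 nt, so the BLASTn stage of an EST homology
survey can be replaced by an *exact* exhaustive scan: every full-length,
gap-free placement of the query on either strand of the EST is scored by
Hamming distance. Placements with at most ``max_mismatch`` substitutions
are reported; per-query "top hit" selection mirrors taking the best BLAST
result for each query.

Coordinates of a hit are 0-based offsets **on the hit strand**: for a ``-``
hit, ``est_start`` indexes into the reverse complement of the EST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .seqio import SequenceRecord, reverse_complement

logger = logging.getLogger("estmir")


@dataclass(frozen=True)
class HomologyHit:
    """A full-length, ungapped placement of a reference miRNA on an EST."""

    query_id: str
    est_id: str
    est_start: int      # 0-based, on the hit strand
    strand: str         # '+' or '-'
    mismatches: int
    aligned_length: int


def _hamming_scan(query: str, target: str) -> np.ndarray:
    """Mismatch count of the query at every offset of the target."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    return (windows != q).sum(axis=1)


def find_hits(
    query: SequenceRecord,
    est: SequenceRecord,
    max_mismatch: int = 3,
) -> list[HomologyHit]:
    """All placements of ``query`` on both strands of ``est`` within the
    mismatch budget, sorted by (mismatches, est_start, strand).

    A query longer than the EST yields an empty list (logged).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if query.length > est.length:
        logger.debug("query %s (%d nt) longer than EST %s (%d nt)",
                     query.id, query.length, est.id, est.length)
        return []
    hits = []
    for strand, target in (("+", est.residues),
                           ("-", reverse_complement(est.residues))):
        mm = _hamming_scan(query.residues, target)
        for start in np.nonzero(mm <= max_mismatch)[0]:
            hits.append(HomologyHit(query.id, est.id, int(start), strand,
                                    int(mm[start]), query.length))
    hits.sort(key=lambda h: (h.mismatches, h.est_start, h.strand))
    return hits


def best_hit_per_query(
    queries: list[SequenceRecord],
    ests: list[SequenceRecord],
    max_mismatch: int = 3,
) -> dict[str, HomologyHit]:
    """At most one hit per query over the whole EST set (top-hit semantics).

    The winner minimizes mismatches; ties prefer the longer EST, then the
    lexicographically smaller EST id, then the smaller start, then ``+``
    over ``-``. Queries with no qualifying placement are absent.
    """
    est_len = {e.id: e.length for e in ests}
    best: dict[str, HomologyHit] = {}

    def key(h: HomologyHit):
        return (h.mismatches, -est_len[h.est_id], h.est_id, h.est_start,
                h.strand == "-")

    for query in queries:
        candidates = []
        for est in ests:
            candidates.extend(find_hits(query, est, max_mismatch))
        if candidates:
            best[query.id] = min(candidates, key=key)
    return best


def write_hits_tsv(hits: list[HomologyHit], path) -> None:
    """Tab-separated hit table: query_id, est_id, start, strand, mismatches."""
    with open(path, "w") as fh:
        fh.write("query_id\test_id\test_start\tstrand\tmismatches\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.est_id}\t{h.est_start}\t{h.strand}"
                     f"\t{h.mismatches}\n")
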