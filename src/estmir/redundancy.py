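"""Redundancy removal for EST and miRNA sets.

Reproduces a CD-HIT run at identity cutoff 1.0 with explicit, deterministic
semantics: *exact* mode removes records whose residue string equals an
earlier record's; *containment* mode additionally removes records that are
exact substrings of a longer kept record (what cutoff-1 clustering does for
fragments). Length ties are broken lexicographically by id.
"""

from __future__ import annotations

from .seqio import SequenceRecord

MODES = ("exact", "containment")


def remove_redundant(
    records: list[SequenceRecord],
    mode: str = "containment",
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Remove duplicate (and, in containment mode, contained) records.

    Returns ``(kept, removed_map)`` where ``removed_map`` maps each removed
    record id to the id of its retained representative. ``kept`` preserves
    input order. Exact mode keeps the first-seen copy of each sequence;
    containment mode keeps the longest (ties by id), so a fragment is always
    mapped to a full-length representative.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    removed: dict[str, str] = {}
    if mode == "exact":
        seen: dict[str, str] = {}
        kept = []
        for rec in records:
            rep = seen.get(rec.residues)
            if rep is None:
                seen[rec.residues] = rec.id
                kept.append(rec)
            else:
                removed[rec.id] = rep
        return kept, removed

    # containment: decide representatives longest-first so a substring is
    # always absorbed by the longest matching record
    order = sorted(records, key=lambda r: (-r.length, r.id))
    kept_recs: list[SequenceRecord] = []
    for rec in order:
        rep = next((k for k in kept_recs if rec.residues in k.residues), None)
        if rep is None:
            kept_recs.append(rec)
        else:
            removed[rec.id] = rep.id
    kept_ids = {r.id for r in kept_recs}
    kept = [r for r in records if r.id in kept_ids]
    return kept, removed
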