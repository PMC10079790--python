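"""Candidate acceptance criteria, AMFE/MFEI indices, and naming.

A stem-loop alone does not make a miRNA precursor — mRNA, rRNA and tRNA
fragments fold into comparable hairpins. Candidates are therefore filtered
on thermodynamic indices that discriminate miRNA precursors:

    AMFE = MFE / precursor_length × 100        (kcal/mol per 100 nt)
    MFEI = AMFE / (G+C)%                       (dimensionless)

plus structural rules on the mature:star duplex. Each rule carries an id
so reports are diagnostic; all rules are always evaluated (no
short-circuiting) and every default is configurable.

Default rule set (ids R1–R9):

    R1  mature length within [18, 22] nt
    R2  homolog mismatches ≤ 3
    R3  precursor A+U% within [30, 70]
    R4  MFE < 0
    R5  |MFEI| ≥ 0.50 (MFEI ≤ −0.50)
    R6  mature on a single arm (5p or 3p, not spanning the terminal loop)
    R7  mature:star duplex mismatches ≤ 6 (G:U counts as paired)
    R8  at most 1 internal loop/bulge inside the mature
    R9  no unpaired run inside the mature longer than 3 nt

The MFEI bound is the operative one observed in accepted plant precursor
sets (|MFEI| 0.50–0.84); the stricter 0.85 literature cutoff can be set
through the threshold config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

from .hairpin import PrecursorCandidate
from .homology import HomologyHit
from .seqio import composition


class NamingError(ValueError):
    """Raised when a reference miRNA id cannot be parsed into a family."""


def amfe(mfe: float, precursor_length: int) -> float:
    """MFE adjusted to a 100-nt sequence: mfe / length * 100 (kcal/mol)."""
    if precursor_length <= 0:
        raise ValueError("precursor length must be > 0")
    # multiply first: keeps amfe(m, 100) == m exact in floating point
    return mfe * 100.0 / precursor_length


def mfei(amfe_value: float, gc_percent: float) -> float:
    """Minimal folding free energy index: AMFE / (G+C)%.

    Undefined (raises) for a G+C-free sequence; such candidates are
    rejected downstream.
    """
    if gc_percent <= 0:
        raise ValueError("MFEI undefined for (G+C)% <= 0")
    return amfe_value / gc_percent


@dataclass
class Thresholds:
    """Configurable rule thresholds (defaults follow the rule table above)."""

    mature_len_min: int = 18
    mature_len_max: int = 22
    max_homolog_mismatches: int = 3
    precursor_au_min: float = 30.0
    precursor_au_max: float = 70.0
    mfei_max: float = -0.50          # accept iff mfei <= mfei_max
    max_duplex_mismatches: int = 6
    max_internal_loops: int = 1
    max_bulge: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CriteriaReport:
    """All per-candidate numbers plus pass/fail flags (one table row)."""

    proposed_name: str | None
    family: str | None
    est_id: str
    mature_seq: str
    mature_length: int
    homolog_mismatches: int
    arm: str
    mature_gc_percent_2dp: float
    mature_au_percent_2dp: float
    precursor_gc_percent_2dp: float
    precursor_au_percent_2dp: float
    precursor_length: int
    mfe: float
    amfe: float
    mfei: float | None
    duplex_mismatches: int
    internal_loops_in_mature: int
    passed: bool
    failed_rules: list[str] = field(default_factory=list)


def evaluate(
    candidate: PrecursorCandidate,
    hit: HomologyHit,
    thresholds: Thresholds | None = None,
) -> CriteriaReport:
    """Apply the full rule set to an analyzed candidate.

    The candidate must carry structure fields (``analyze_hairpin`` output).
    All rules are evaluated; ``passed`` is true iff ``failed_rules`` is
    empty. The G+C% used in MFEI is the precursor's untruncated fraction;
    truncation applies only to the report fields.
    """
    t = thresholds or Thresholds()
    if candidate.dot_bracket is None or candidate.arm is None:
        raise ValueError("candidate must be folded and analyzed before "
                         "criteria evaluation")
    m0, m1 = candidate.mature_span
    mature_seq = candidate.sequence[m0:m1]
    pre_comp = composition(candidate.sequence)
    mat_comp = composition(mature_seq)

    mfe = candidate.mfe_kcal_per_mol
    amfe_value = amfe(mfe, len(candidate.sequence))
    pre_gc_percent = pre_comp.gc_fraction * 100.0
    mfei_value = (amfe_value / pre_gc_percent) if pre_gc_percent > 0 else None

    failed: list[str] = []
    if not t.mature_len_min <= (m1 - m0) <= t.mature_len_max:
        failed.append("R1")
    if hit.mismatches > t.max_homolog_mismatches:
        failed.append("R2")
    pre_au_percent = pre_comp.au_fraction * 100.0
    if not t.precursor_au_min <= pre_au_percent <= t.precursor_au_max:
        failed.append("R3")
    if not mfe < 0:
        failed.append("R4")
    if mfei_value is None or not mfei_value <= t.mfei_max:
        failed.append("R5")
    if candidate.arm not in ("5p", "3p"):
        failed.append("R6")
    if candidate.duplex_mismatches > t.max_duplex_mismatches:
        failed.append("R7")
    if candidate.internal_loops_in_mature > t.max_internal_loops:
        failed.append("R8")
    if (candidate.max_internal_run or 0) > t.max_bulge:
        failed.append("R9")

    return CriteriaReport(
        proposed_name=None,
        family=None,
        est_id=candidate.est_id,
        mature_seq=mature_seq,
        mature_length=m1 - m0,
        homolog_mismatches=hit.mismatches,
        arm=candidate.arm,
        mature_gc_percent_2dp=mat_comp.gc_percent_2dp,
        mature_au_percent_2dp=mat_comp.au_percent_2dp,
        precursor_gc_percent_2dp=pre_comp.gc_percent_2dp,
        precursor_au_percent_2dp=pre_comp.au_percent_2dp,
        precursor_length=len(candidate.sequence),
        mfe=mfe,
        amfe=amfe_value,
        mfei=round(mfei_value, 3) if mfei_value is not None else None,
        duplex_mismatches=candidate.duplex_mismatches,
        internal_loops_in_mature=candidate.internal_loops_in_mature,
        passed=not failed,
        failed_rules=failed,
    )


_FAMILY_RE = re.compile(r"^(?P<core>(?:miR|MIR|let)[-\w]*?)(?P<arm>-[35]p)?$")


def parse_family(reference_id: str) -> str:
    """Family token of a miRBase-style id: ``ath-miR5658`` → ``miR5658``,
    ``rgl-miR7805-3p`` → ``miR7805-3p``."""
    parts = reference_id.split("-", 1)
    if len(parts) != 2 or not parts[0]:
        raise NamingError(f"cannot parse reference miRNA id {reference_id!r}")
    family = parts[1]
    if not _FAMILY_RE.match(family):
        raise NamingError(f"cannot parse family from {reference_id!r}")
    return family


def name_mirna(
    family_or_report: str | CriteriaReport,
    species_prefix: str,
    existing_names: set[str],
) -> str:
    """miRBase-style name for a new family member: species prefix + family,
    with letter suffixes (inserted before any -5p/-3p arm tag) on clashes.

    Deterministic: suffix letters are tried in order a, b, c, …
    """
    family = (family_or_report.family
              if isinstance(family_or_report, CriteriaReport)
              else family_or_report)
    if not family:
        raise NamingError("no family to name from")
    m = _FAMILY_RE.match(family)
    if not m:
        raise NamingError(f"cannot parse family token {family!r}")
    core, arm_tag = m.group("core"), m.group("arm") or ""
    base = f"{species_prefix}-{core}{arm_tag}"
    if base not in existing_names:
        return base
    for suffix_idx in range(26 * 27):
        first = suffix_idx // 26
        letters = ("" if first == 0 else chr(ord("a") + first - 1)) \
            + chr(ord("a") + suffix_idx % 26)
        cand = f"{species_prefix}-{core}{letters}{arm_tag}"
        if cand not in existing_names:
            return cand
    raise NamingError(f"suffix space exhausted for family {family!r}")
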