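"""Synthetic EST corpora with planted miRNA hairpins and ground truth.

The generator emulates the statistical structure an EST-based miRNA survey
assumes: a pool of background ESTs of realistic length (300–800 nt) and
A+U-rich composition, a set of reference mature miRNAs, ESTs carrying a
planted 85-nt hairpin precursor whose mature arm differs from its
reference by 0–3 substitutions, protein-coding decoys (≥80-codon ORFs),
and exact duplicate records. Every record is covered by a ground-truth
manifest, and everything is reproducible from a single seed.

Planted matures keep a 5' uracil (substitutions avoid position 1 by
default), matching the 5'-U bias of genuine plant miRNAs. Mutations are
substitutions only — the discovery pipeline is ungapped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coding_filter import classify_coding
from .criteria import Thresholds, evaluate
from .hairpin import PrecursorCandidate, analyze_hairpin, fold
from .homology import HomologyHit
from .seqio import SequenceRecord, reverse_complement, write_fasta

BASES = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

DEFAULT_GC_TARGET = 0.42
DEFAULT_LENGTH_RANGE = (300, 800)
DEFAULT_MUTATION_DISTRIBUTION = {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}
PRECURSOR_LENGTH = 85


class GenerationError(RuntimeError):
    """Raised when a verified hairpin cannot be built within retry bounds."""


@dataclass(frozen=True)
class PrecursorDesign:
    """A designed hairpin precursor with the mature coordinates within it."""

    sequence: str
    mature_span: tuple[int, int]


@dataclass
class ManifestEntry:
    est_id: str
    category: str                    # planted|coding_decoy|duplicate|background
    reference_mirna_id: str = ""
    mature_seq: str = ""
    n_mutations: int = 0
    precursor_start: int = -1        # forward-EST coordinates
    precursor_end: int = -1
    strand: str = ""
    duplicate_of: str = ""


@dataclass
class SyntheticCorpus:
    ests: list[SequenceRecord]
    reference_mirnas: list[SequenceRecord]
    manifest: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.ests, out / "ests.fasta")
        write_fasta(self.reference_mirnas, out / "reference_mirnas.fasta")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(BASES, size=n, p=p))


def _perturb(rng: np.random.Generator, seq: str, n_sub: int,
             avoid: set[int] = frozenset()) -> str:
    """Apply n_sub substitutions at distinct positions outside ``avoid``."""
    positions = [i for i in range(len(seq)) if i not in avoid]
    chosen = rng.choice(positions, size=n_sub, replace=False)
    out = list(seq)
    for pos in chosen:
        alternatives = [b for b in "ACGU" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _contiguous_perturb(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Substitute a contiguous block of ``n_sub`` positions, away from the
    helix ends (real miRNA:miRNA* duplex imperfections are localized
    bulges/loops, not scattered mismatches)."""
    margin = 2
    start = int(rng.integers(margin, len(seq) - margin - n_sub + 1))
    out = list(seq)
    for pos in range(start, start + n_sub):
        alternatives = [b for b in "ACGU" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_precursor(
    mature: str,
    loop_len: int = 10,
    star_mismatches: int = 0,
    seed: int | np.random.Generator = 0,
    max_retries: int = 40,
    au_target: float = 0.60,
) -> PrecursorDesign:
    """Design an 85-nt hairpin precursor carrying ``mature`` on its 5' arm.

    Layout: flank + mature + terminal loop + star + flank, where the star
    is the reverse complement of the mature perturbed by a contiguous
    block of ``star_mismatches`` substitutions, the loop and flanks are
    drawn from the unpairable {A, C} alphabet (C fraction steered so the
    precursor A+U content lands near ``au_target``), and padding brings
    the total to 85 nt. The mature midpoint is placed at the precursor
    midpoint, so a discovery window centered on the mature recovers the
    designed hairpin exactly.

    Every design is verified at generation: the folded structure must
    place the mature on a single arm with at most ``star_mismatches``
    unpaired mature positions, and (for ``star_mismatches`` ≤ 3) the
    candidate must pass the full default acceptance rule set R1–R9.
    Verification failures are retried with fresh randomness; persistent
    failure raises :class:`GenerationError`.
    """
    if not 18 <= len(mature) <= 24:
        raise ValueError("mature length must be in [18, 24]")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    if star_mismatches > 6:
        raise ValueError("star_mismatches must be <= 6")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    core = len(mature) * 2 + loop_len
    pad = PRECURSOR_LENGTH - core
    if pad < 0:
        raise ValueError("mature + loop too long for an 85-nt precursor")
    # mature midpoint at the precursor midpoint (shifted only if the
    # stem+loop would overflow the 3' end)
    left = min(PRECURSOR_LENGTH // 2 - len(mature) // 2, pad)
    right = pad - left
    # steer flank+loop C content so precursor A+U lands near au_target
    mature_au = sum(1 for b in mature if b in "AU") / len(mature)
    filler = loop_len + pad
    c_frac = 1.0 - (PRECURSOR_LENGTH * au_target
                    - 2 * len(mature) * mature_au) / filler
    c_frac = min(max(c_frac, 0.10), 0.90)
    ac = np.array(list("AC"))
    p_ac = [1.0 - c_frac, c_frac]

    for _ in range(max_retries):
        star = reverse_complement(mature)
        if star_mismatches:
            star = _contiguous_perturb(rng, star, star_mismatches)
        flank_l = "".join(rng.choice(ac, size=left, p=p_ac))
        flank_r = "".join(rng.choice(ac, size=right, p=p_ac))
        loop = "".join(rng.choice(ac, size=loop_len, p=p_ac))
        seq = flank_l + mature + loop + star + flank_r
        span = (left, left + len(mature))

        db, mfe = fold(seq)
        try:
            cand = analyze_hairpin(PrecursorCandidate(
                est_id="synthetic", window_start=0, sequence=seq,
                mature_span=span, dot_bracket=db, mfe_kcal_per_mol=mfe))
        except Exception:
            continue
        if cand.arm not in ("5p", "3p") or \
                cand.duplex_mismatches > star_mismatches:
            continue
        if star_mismatches <= 3:
            probe = HomologyHit("probe", "synthetic", span[0], "+", 0,
                                len(mature))
            if not evaluate(cand, probe, Thresholds()).passed:
                continue
        return PrecursorDesign(sequence=seq, mature_span=span)
    raise GenerationError(
        f"could not build a verified hairpin for {mature!r} in "
        f"{max_retries} attempts")


def _coding_sequence(rng: np.random.Generator, n: int, orf_codons: int = 90) -> str:
    """Random sequence of length n containing an AUG..stop ORF of
    ``orf_codons`` codons in frame 0 of the forward strand."""
    sense = [c for c in ("".join(t) for t in itertools.product("ACGU", repeat=3))
             if c not in ("UAA", "UAG", "UGA", "AUG")]
    orf = "AUG" + "".join(rng.choice(sense, size=orf_codons - 1)) + "UAA"
    if n < len(orf) + 6:
        n = len(orf) + 6
    flank_total = n - len(orf)
    left = int(rng.integers(0, flank_total + 1))
    return (_random_seq(rng, left, 0.45) + orf
            + _random_seq(rng, flank_total - left, 0.45))


def generate_corpus(
    n_background: int = 200,
    n_planted: int = 20,
    n_coding: int = 20,
    n_duplicates: int = 10,
    mutation_distribution: dict[int, float] | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    gc_target: float = DEFAULT_GC_TARGET,
    seed: int = 0,
) -> SyntheticCorpus:
    """Generate a full synthetic EST corpus with a ground-truth manifest.

    Planted ESTs embed a verified hairpin whose mature differs from its
    reference miRNA by 0–3 substitutions (drawn from
    ``mutation_distribution``; position 1 never mutated), inserted at a
    random position on a random strand. Coding decoys carry a ≥80-codon
    ORF; duplicates are exact copies of earlier records under new ids.
    Fully reproducible from ``seed``.
    """
    if min(n_background, n_planted, n_coding, n_duplicates) < 0:
        raise ValueError("counts must be >= 0")
    mut_dist = mutation_distribution or DEFAULT_MUTATION_DISTRIBUTION
    muts, probs = zip(*sorted(mut_dist.items()))
    probs = np.asarray(probs, dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("mutation_distribution must be a distribution")
    rng = np.random.default_rng(seed)

    ests: list[SequenceRecord] = []
    refs: list[SequenceRecord] = []
    manifest: list[ManifestEntry] = []

    def est_length() -> int:
        return int(rng.integers(length_range[0], length_range[1] + 1))

    # reference mature miRNAs, one family per planted item, 5'-U biased
    for i in range(n_planted):
        mat_len = int(rng.integers(18, 23))
        mature = "U" + _random_seq(rng, mat_len - 1, 0.40)
        refs.append(SequenceRecord(f"ref-miR{1001 + i}", mature,
                                   "synthetic reference mature miRNA"))

    for i in range(n_background):
        # backgrounds are genuinely non-coding: ~7% of unconstrained random
        # draws at these lengths carry an accidental threshold-length ORF
        # and would be mislabelled, so those draws are rejected
        for _ in range(30):
            rec = SequenceRecord(f"bg{i:04d}", _random_seq(rng, est_length(),
                                                           gc_target))
            if classify_coding(rec) == "noncoding":
                break
        ests.append(rec)
        manifest.append(ManifestEntry(est_id=rec.id, category="background"))

    for i in range(n_planted):
        # a reference that cannot seed a rule-passing hairpin is replaced:
        # real reference sets consist of miRNAs that do fold
        for _ in range(20):
            ref = refs[i]
            n_mut = int(rng.choice(muts, p=probs))
            planted_mature = (_perturb(rng, ref.residues, n_mut, avoid={0})
                              if n_mut else ref.residues)
            star_mm = int(rng.integers(0, 3))
            try:
                design = make_precursor(planted_mature,
                                        star_mismatches=star_mm, seed=rng)
                break
            except GenerationError:
                mat_len = int(rng.integers(18, 23))
                refs[i] = SequenceRecord(
                    ref.id, "U" + _random_seq(rng, mat_len - 1, 0.40),
                    ref.description)
        else:  # pragma: no cover - would need pathological rng
            raise GenerationError(f"no viable reference for slot {i}")
        ref = refs[i]
        # planted ESTs are genuinely non-coding: redraw backbones that
        # happen to carry a threshold-length ORF
        for _ in range(20):
            length = est_length()
            backbone = _random_seq(rng, length, gc_target)
            pos = int(rng.integers(0, length - PRECURSOR_LENGTH + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = (design.sequence if strand == "+"
                      else reverse_complement(design.sequence))
            seq = backbone[:pos] + insert + backbone[pos + PRECURSOR_LENGTH:]
            rec = SequenceRecord(f"planted{i:04d}", seq)
            if classify_coding(rec) == "noncoding":
                break
        ests.append(rec)
        manifest.append(ManifestEntry(
            est_id=rec.id, category="planted",
            reference_mirna_id=ref.id, mature_seq=planted_mature,
            n_mutations=n_mut, precursor_start=pos,
            precursor_end=pos + PRECURSOR_LENGTH, strand=strand))

    for i in range(n_coding):
        rec = SequenceRecord(f"cds{i:04d}",
                             _coding_sequence(rng, est_length()))
        ests.append(rec)
        manifest.append(ManifestEntry(est_id=rec.id, category="coding_decoy"))

    order = rng.permutation(len(ests))
    ests = [ests[k] for k in order]
    manifest = [manifest[k] for k in order]

    for i in range(n_duplicates):
        src = ests[int(rng.integers(0, len(ests) - 1))]
        if src.id.startswith("dup"):
            src = next(e for e in ests if not e.id.startswith("dup"))
        rec = SequenceRecord(f"dup{i:04d}", src.residues)
        ests.append(rec)
        manifest.append(ManifestEntry(est_id=rec.id, category="duplicate",
                                      duplicate_of=src.id))

    mdf = pd.DataFrame([asdict(m) for m in manifest])
    return SyntheticCorpus(ests=ests, reference_mirnas=refs, manifest=mdf)
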