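"""miRNA target prediction by complementarity ("expectation") scoring.

Plant miRNAs act through perfect or near-perfect complementarity to their
mRNA targets, so candidate sites can be found by scanning transcript
windows with a penalty score (the *expectation*, E; lower is better):

    per aligned position, numbered 1..L from the miRNA 5' end:
        Watson–Crick pair   0
        G:U wobble          0.5
        mismatch            1
        gap                 2
    and every penalty is doubled at positions 2–13 (the seed-proximal
    region that governs target recognition in plants).

A site with ≥1 genuine mismatch (non-pair, non-wobble) at miRNA positions
9–11 — the slicing site — is classified as *translational inhibition*;
otherwise as *cleavage*.

Scanning is ungapped: every transcript window of miRNA length is scored,
windows under the expectation cutoff are kept, and overlapping windows are
merged to the best-scoring placement. The complementary region must cover
at least ``hsp`` positions (high-scoring segment pair size), so miRNAs
shorter than ``hsp`` yield no sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SequenceRecord

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

DOUBLED_REGION = (2, 13)      # miRNA positions with doubled penalties
CENTRAL_REGION = (9, 11)      # mismatch here => translational inhibition
DEFAULT_CUTOFF = 3.0
DEFAULT_HSP = 18

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0


@dataclass(frozen=True)
class TargetSite:
    """A scored miRNA:mRNA complementary site."""

    mirna_id: str
    transcript_id: str
    transcript_span: tuple[int, int]   # [start, end), 0-based on transcript
    expectation: float
    mode: str                          # 'cleavage' | 'translation'
    alignment: tuple[str, str, str]    # mRNA 5'→3', match line, miRNA 3'→5'
    mirna_seq: str
    site_seq: str


def _position_class(mirna_base: str, site_base: str) -> str:
    if (mirna_base, site_base) in _WC:
        return "wc"
    if (mirna_base, site_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _classes(mirna: str, site: str) -> list[str]:
    # miRNA position k (0-based from 5') pairs transcript site position
    # L-1-k: the duplex is antiparallel.
    L = len(mirna)
    return [_position_class(mirna[k], site[L - 1 - k]) for k in range(L)]


def score_site(mirna: str, site: str) -> float:
    """Expectation penalty of an ungapped miRNA:site duplex.

    ``site`` is the transcript window, 5'→3'. Raises on length mismatch
    (gapped alignments are not produced by the default scanner).
    """
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must be equal length (ungapped)")
    total = 0.0
    for k, cls in enumerate(_classes(mirna, site)):
        penalty = {"wc": 0.0, "wobble": WOBBLE_PENALTY,
                   "mismatch": MISMATCH_PENALTY}[cls]
        if DOUBLED_REGION[0] <= k + 1 <= DOUBLED_REGION[1]:
            penalty *= 2.0
        total += penalty
    return total


def _alignment_strings(mirna: str, site: str) -> tuple[str, str, str]:
    marks = {"wc": "|", "wobble": "o", "mismatch": " "}
    classes = _classes(mirna, site)
    match_line = "".join(marks[c] for c in reversed(classes))
    return site, match_line, mirna[::-1]


def classify_mode(site: "TargetSite | tuple[str, str]") -> str:
    """'translation' iff a genuine mismatch occurs at miRNA positions 9–11
    (central, slicing-site region); 'cleavage' otherwise."""
    if isinstance(site, TargetSite):
        mirna, window = site.mirna_seq, site.site_seq
    else:
        mirna, window = site
    classes = _classes(mirna, window)
    lo, hi = CENTRAL_REGION
    central = classes[lo - 1:hi]
    return "translation" if "mismatch" in central else "cleavage"


def scan(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    cutoff: float = DEFAULT_CUTOFF,
    hsp: int = DEFAULT_HSP,
) -> list[TargetSite]:
    """All target sites of ``mirna`` on ``transcript`` with expectation ≤
    cutoff; overlapping windows merged to the best-scoring placement,
    sorted by (expectation, position)."""
    L = mirna.length
    if L < hsp or transcript.length < L:
        return []
    raw: list[tuple[int, float]] = []
    for start in range(transcript.length - L + 1):
        window = transcript.residues[start:start + L]
        e = score_site(mirna.residues, window)
        if e <= cutoff:
            raw.append((start, e))
    # merge overlapping placements: keep the best (ties -> leftmost) in
    # each chain of mutually overlapping windows
    merged: list[tuple[int, float]] = []
    i = 0
    while i < len(raw):
        j = i
        best = raw[i]
        while j + 1 < len(raw) and raw[j + 1][0] < raw[j][0] + L:
            j += 1
            if raw[j][1] < best[1]:
                best = raw[j]
        merged.append(best)
        i = j + 1
    sites = []
    for start, e in merged:
        window = transcript.residues[start:start + L]
        sites.append(TargetSite(
            mirna_id=mirna.id,
            transcript_id=transcript.id,
            transcript_span=(start, start + L),
            expectation=e,
            mode=classify_mode((mirna.residues, window)),
            alignment=_alignment_strings(mirna.residues, window),
            mirna_seq=mirna.residues,
            site_seq=window,
        ))
    sites.sort(key=lambda s: (s.expectation, s.transcript_span[0]))
    return sites


def scan_many(
    mirnas: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    cutoff: float = DEFAULT_CUTOFF,
    hsp: int = DEFAULT_HSP,
) -> list[TargetSite]:
    """Scan every miRNA against every transcript (sense strand only)."""
    out: list[TargetSite] = []
    for m in mirnas:
        for t in transcripts:
            out.extend(scan(m, t, cutoff=cutoff, hsp=hsp))
    return out


def write_sites_tsv(sites: list[TargetSite], path,
                    annotations: dict[str, str] | None = None) -> None:
    """Site table as TSV; an optional transcript_id → description map is
    joined through as a final column."""
    with open(path, "w") as fh:
        header = "mirna_id\ttranscript_id\tstart\tend\texpectation\tmode\talignment"
        if annotations is not None:
            header += "\tannotation"
        fh.write(header + "\n")
        for s in sites:
            row = (f"{s.mirna_id}\t{s.transcript_id}\t{s.transcript_span[0]}"
                   f"\t{s.transcript_span[1]}\t{s.expectation:g}\t{s.mode}"
                   f"\t{'/'.join(s.alignment)}")
            if annotations is not None:
                row += "\t" + annotations.get(s.transcript_id, "")
            fh.write(row + "\n")
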