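"""Precursor excision, RNA secondary-structure prediction, hairpin analysis.

A candidate precursor is an 85-nt window centered on the mature homology
hit. Its structure is predicted with a simplified nearest-neighbor model:

* base pairs are the six canonical classes (Watson–Crick A:U, U:A, G:C,
  C:G plus the G:U / U:G wobbles);
* helix stability comes from a 6×6 table of stacking energies (kcal/mol,
  all negative);
* hairpin loops (minimum 3 unpaired nt), bulges and internal loops pay
  affine (linear-in-size) penalties; multibranch loops pay an affine
  penalty per branch and per unpaired base;
* exterior bases are free.

The minimum-free-energy structure is found by Zuker-style dynamic
programming (``fold``); an exhaustive enumerator over all pseudoknot-free
structures (``fold_bruteforce``, sequences ≤ 18 nt) scores structures with
the *identical* energy function and serves as an independent oracle.
``FOLD_BACKENDS`` lets an external thermodynamic folder (e.g. ViennaRNA,
registered automatically when importable) stand in for the internal model;
both produce the same ``(dot_bracket, mfe)`` contract.

The model is deliberately simpler than full Turner rules (no dangles, no
terminal-AU penalties, no tetraloop bonuses), so absolute energies are not
comparable with MFOLD/ViennaRNA output — only the derived indices (AMFE,
MFEI) computed consistently within one run are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

from .homology import HomologyHit
from .seqio import SequenceRecord, reverse_complement

logger = logging.getLogger("estmir")

# ---------------------------------------------------------------------------
# Energy model (kcal/mol). Shared verbatim by the DP and the brute-force
# oracle; every structure is scored by loop decomposition over this table.
# ---------------------------------------------------------------------------

PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})
MIN_HAIRPIN_LOOP = 3       # minimum unpaired bases closing a hairpin
MAX_INTERIOR_UNPAIRED = 30  # cap on bulge/internal loop size in the DP

_P = ("AU", "CG", "GC", "GU", "UA", "UG")
_STACK_ROWS = {
    #        AU    CG    GC    GU    UA    UG   (inner pair)
    "AU": (-0.9, -2.2, -2.1, -0.6, -1.1, -1.4),
    "CG": (-2.1, -3.3, -2.4, -1.4, -2.1, -2.1),
    "GC": (-2.4, -3.4, -3.3, -1.5, -2.2, -2.5),
    "GU": (-1.3, -2.5, -2.1, -0.5, -1.4, -1.2),
    "UA": (-1.3, -2.4, -2.1, -1.0, -0.9, -1.3),
    "UG": (-1.0, -1.5, -1.4, -0.3, -0.6, -0.5),
}
STACK_ENERGY = {
    (outer, inner): _STACK_ROWS[outer][k]
    for outer in _P for k, inner in enumerate(_P)
}

# affine loop penalties
HAIRPIN_A, HAIRPIN_B = 4.0, 0.25     # hairpin loop: A + B*size
BULGE_A, BULGE_B = 3.5, 0.30         # bulge: one side of the stem
INTERNAL_A, INTERNAL_B = 3.0, 0.30   # internal loop: both sides
MULTI_A, MULTI_B, MULTI_C = 4.0, 0.5, 0.2  # multiloop: close, per branch, per nt

_INF = float("inf")


class FoldError(ValueError):
    """Raised for alphabet violations or refused folding inputs."""


class StructureError(ValueError):
    """Raised when hairpin analysis is impossible (e.g. no pairs)."""


def _check_alphabet(seq: str) -> None:
    if not seq or not set(seq) <= set("ACGUN"):
        raise FoldError("sequence must be nonempty over {A,C,G,U,N}")


def can_pair(a: str, b: str) -> bool:
    return a + b in PAIRS


def hairpin_penalty(n: int) -> float:
    return HAIRPIN_A + HAIRPIN_B * n


def bulge_penalty(n: int) -> float:
    return BULGE_A + BULGE_B * n


def internal_penalty(n: int) -> float:
    return INTERNAL_A + INTERNAL_B * n


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Free energy of an arbitrary pseudoknot-free structure by loop
    decomposition under the shared model (exterior bases free)."""
    partner: dict[int, int] = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0.0
    for i, j in pairs:
        if i > j:
            continue
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                total += STACK_ENERGY[(seq[i] + seq[j], seq[k] + seq[l])]
            elif u1 == 0 or u2 == 0:
                total += bulge_penalty(u1 + u2)
            else:
                total += internal_penalty(u1 + u2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += MULTI_A + MULTI_B * (len(children) + 1) + MULTI_C * unpaired
    return total


# ---------------------------------------------------------------------------
# MFE folding by dynamic programming
# ---------------------------------------------------------------------------

def _fold_internal(seq: str) -> tuple[str, float]:
    n = len(seq)
    pairable = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            pairable[i][j] = can_pair(seq[i], seq[j])

    V = [[_INF] * n for _ in range(n)]   # best energy, i pairs j
    WM = [[_INF] * n for _ in range(n)]  # multiloop segment, >= 1 branch

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i][j]:
                e = hairpin_penalty(j - i - 1)
                # interior loop / bulge / stack to an inner pair (k,l)
                kmax = min(j - MIN_HAIRPIN_LOOP - 1,
                           i + MAX_INTERIOR_UNPAIRED + 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN_LOOP + 1,
                               j - 1 - (MAX_INTERIOR_UNPAIRED - u1))
                    for l in range(lmin, j):
                        if not pairable[k][l] or V[k][l] == _INF:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            cost = STACK_ENERGY[(seq[i] + seq[j],
                                                 seq[k] + seq[l])]
                        elif u1 == 0 or u2 == 0:
                            cost = bulge_penalty(u1 + u2)
                        else:
                            cost = internal_penalty(u1 + u2)
                        if cost + V[k][l] < e:
                            e = cost + V[k][l]
                # multibranch closing
                WMi = WM[i + 1]
                for m in range(i + 1, j - 1):
                    if WMi[m] == _INF or WM[m + 1][j - 1] == _INF:
                        continue
                    cand = MULTI_A + MULTI_B + WMi[m] + WM[m + 1][j - 1]
                    if cand < e:
                        e = cand
                V[i][j] = e

            # WM: segment inside a multiloop carrying >= 1 branch
            w = _INF
            if V[i][j] != _INF:
                w = V[i][j] + MULTI_B
            if WM[i][j - 1] != _INF:
                w = min(w, WM[i][j - 1] + MULTI_C)
            if i + 1 <= j and WM[i + 1][j] != _INF:
                w = min(w, WM[i + 1][j] + MULTI_C)
            for k in range(i + 1, j + 1):
                if WM[i][k - 1] != _INF and WM[k][j] != _INF:
                    w = min(w, WM[i][k - 1] + WM[k][j])
            WM[i][j] = w

    # exterior loop
    W = [0.0] * (n + 1)  # W[j+1] = best over prefix seq[:j+1]
    for j in range(n):
        best = W[j]
        for i in range(0, j):
            if V[i][j] != _INF:
                cand = W[i] + V[i][j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    mfe = min(W[n], 0.0)

    # traceback
    pairs: list[tuple[int, int]] = []
    eps = 1e-9

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        e = V[i][j]
        if abs(e - hairpin_penalty(j - i - 1)) < eps:
            return
        kmax = min(j - MIN_HAIRPIN_LOOP - 1, i + MAX_INTERIOR_UNPAIRED + 1)
        for k in range(i + 1, kmax + 1):
            u1 = k - i - 1
            lmin = max(k + MIN_HAIRPIN_LOOP + 1,
                       j - 1 - (MAX_INTERIOR_UNPAIRED - u1))
            for l in range(lmin, j):
                if not pairable[k][l] or V[k][l] == _INF:
                    continue
                u2 = j - l - 1
                if u1 == 0 and u2 == 0:
                    cost = STACK_ENERGY[(seq[i] + seq[j], seq[k] + seq[l])]
                elif u1 == 0 or u2 == 0:
                    cost = bulge_penalty(u1 + u2)
                else:
                    cost = internal_penalty(u1 + u2)
                if abs(e - (cost + V[k][l])) < eps:
                    trace_V(k, l)
                    return
        for m in range(i + 1, j - 1):
            if WM[i + 1][m] == _INF or WM[m + 1][j - 1] == _INF:
                continue
            if abs(e - (MULTI_A + MULTI_B + WM[i + 1][m]
                        + WM[m + 1][j - 1])) < eps:
                trace_WM(i + 1, m)
                trace_WM(m + 1, j - 1)
                return
        raise AssertionError("traceback failed in V")  # pragma: no cover

    def trace_WM(i: int, j: int) -> None:
        w = WM[i][j]
        if V[i][j] != _INF and abs(w - (V[i][j] + MULTI_B)) < eps:
            trace_V(i, j)
            return
        if WM[i][j - 1] != _INF and abs(w - (WM[i][j - 1] + MULTI_C)) < eps:
            trace_WM(i, j - 1)
            return
        if WM[i + 1][j] != _INF and abs(w - (WM[i + 1][j] + MULTI_C)) < eps:
            trace_WM(i + 1, j)
            return
        for k in range(i + 1, j + 1):
            if WM[i][k - 1] != _INF and WM[k][j] != _INF and \
                    abs(w - (WM[i][k - 1] + WM[k][j])) < eps:
                trace_WM(i, k - 1)
                trace_WM(k, j)
                return
        raise AssertionError("traceback failed in WM")  # pragma: no cover

    def trace_W(j: int) -> None:
        while j >= 0:
            if abs(W[j + 1] - W[j]) < eps:
                j -= 1
                continue
            for i in range(0, j):
                if V[i][j] != _INF and abs(W[j + 1] - (W[i] + V[i][j])) < eps:
                    trace_V(i, j)
                    j = i - 1
                    break
            else:  # pragma: no cover
                raise AssertionError("traceback failed in W")

    if mfe < 0.0:
        trace_W(n - 1)

    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), round(mfe, 10)


def _fold_vienna(seq: str) -> tuple[str, float]:  # pragma: no cover - optional
    import RNA
    db, mfe = RNA.fold(seq)
    return db, float(mfe)


FOLD_BACKENDS = {"internal": _fold_internal}
try:  # ViennaRNA python bindings, if present, as a drop-in backend
    import RNA  # noqa: F401
    FOLD_BACKENDS["vienna"] = _fold_vienna
except ImportError:  # pragma: no cover
    pass


def fold(seq: str, backend: str = "internal") -> tuple[str, float]:
    """Predict the MFE structure of ``seq``.

    Returns ``(dot_bracket, mfe_kcal_per_mol)``; the empty structure is
    always admissible, so the MFE is ≤ 0. Deterministic for a given backend.
    """
    _check_alphabet(seq)
    return FOLD_BACKENDS[backend](seq)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

MAX_BRUTEFORCE = 18


def _enumerate_structures(seq: str):
    """All pseudoknot-free structures (lists of pairs) of ``seq``."""

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i + 1 <= MIN_HAIRPIN_LOOP:
            return ((),)
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if not can_pair(seq[i], seq[k]):
                continue
            for left in enum(i + 1, k - 1):
                for right in enum(k + 1, j):
                    out.append(((i, k),) + left + right)
        return tuple(out)

    if len(seq) < 2:
        return [()]
    return enum(0, len(seq) - 1)


def fold_bruteforce(seq: str) -> tuple[str, float]:
    """Exhaustive-enumeration MFE (sequences ≤ 18 nt), same energy model.

    The oracle scores every legal structure with :func:`structure_energy`
    and returns the optimum, so it is independent of the DP recurrences.
    """
    _check_alphabet(seq)
    if len(seq) > MAX_BRUTEFORCE:
        raise FoldError(
            f"brute-force folding refused for length {len(seq)} > "
            f"{MAX_BRUTEFORCE}")
    best_pairs: tuple = ()
    best_e = 0.0
    for pairs in _enumerate_structures(seq):
        e = structure_energy(seq, list(pairs))
        if e < best_e - 1e-12:
            best_e, best_pairs = e, pairs
    db = ["."] * len(seq)
    for i, j in best_pairs:
        db[i], db[j] = "(", ")"
    return "".join(db), best_e


# ---------------------------------------------------------------------------
# Precursor excision and hairpin analysis
# ---------------------------------------------------------------------------

DEFAULT_WINDOW = 85


@dataclass
class PrecursorCandidate:
    """An excised precursor window with (optionally) predicted structure."""

    est_id: str
    window_start: int              # 0-based on the hit strand
    sequence: str
    mature_span: tuple[int, int]   # [start, end) within the precursor
    strand: str = "+"
    dot_bracket: str | None = None
    mfe_kcal_per_mol: float | None = None
    arm: str | None = None         # '5p' | '3p' | 'loop_spanning'
    star_span: tuple[int, int] | None = None
    duplex_mismatches: int | None = None
    internal_loops_in_mature: int | None = None
    max_internal_run: int | None = None    # longest unpaired run inside mature
    terminal_loop_span: tuple[int, int] | None = None


def excise_precursor(
    est: SequenceRecord,
    hit: HomologyHit,
    window: int = DEFAULT_WINDOW,
) -> PrecursorCandidate:
    """Excise the precursor window around a homology hit.

    The window is centered on the mature hit midpoint on the hit strand and
    shifted (never truncated) to stay within the EST; an EST shorter than
    the window is used whole. ``mature_span`` is recorded relative to the
    window. Raises if the EST is shorter than the mature hit or the window
    is smaller than the hit.
    """
    if hit.est_id != est.id:
        raise ValueError(f"hit refers to {hit.est_id!r}, not {est.id!r}")
    if est.length < hit.aligned_length:
        raise ValueError("EST shorter than the mature sequence")
    if window < hit.aligned_length:
        raise ValueError("window smaller than the mature hit")
    residues = (est.residues if hit.strand == "+"
                else reverse_complement(est.residues))
    if est.length <= window:
        start = 0
        length = est.length
    else:
        mid = hit.est_start + hit.aligned_length // 2
        start = min(max(mid - window // 2, 0), est.length - window)
        length = window
    seq = residues[start:start + length]
    mature = (hit.est_start - start, hit.est_start - start + hit.aligned_length)
    if mature[0] < 0 or mature[1] > length:  # pragma: no cover - defensive
        raise AssertionError("mature span escaped the excised window")
    return PrecursorCandidate(est_id=est.id, window_start=start, sequence=seq,
                              mature_span=mature, strand=hit.strand)


def _pair_partner(dot_bracket: str) -> dict[int, int]:
    stack: list[int] = []
    partner: dict[int, int] = {}
    for idx, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError("unbalanced dot-bracket string")
            i = stack.pop()
            partner[i] = idx
            partner[idx] = i
        elif ch != ".":
            raise StructureError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise StructureError("unbalanced dot-bracket string")
    return partner


def _terminal_loop(partner: dict[int, int]) -> tuple[int, int]:
    """Unpaired run enclosed by the innermost pair of the longest stem."""
    opens = sorted(i for i, j in partner.items() if i < j)
    parent_child: dict[tuple[int, int], list[tuple[int, int]]] = {}
    parents: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for i in opens:
        j = partner[i]
        while stack and stack[-1][1] < i:
            stack.pop()
        parent = stack[-1] if stack else None
        parents[(i, j)] = parent
        parent_child.setdefault(parent, []).append((i, j))
        stack.append((i, j))

    best = None
    for i in opens:
        j = partner[i]
        if parent_child.get((i, j)):
            continue  # has inner pairs: not a hairpin-closing pair
        # stem length: walk outward while each parent carries a single child
        stem = 1
        node = (i, j)
        while True:
            parent = parents[node]
            if parent is None or len(parent_child.get(parent, [])) != 1:
                break
            stem += 1
            node = parent
        cand = (stem, -i)  # ties: leftmost loop
        if best is None or cand > best[0]:
            best = (cand, (i + 1, j))
    assert best is not None
    return best[1]


def analyze_hairpin(candidate: PrecursorCandidate) -> PrecursorCandidate:
    """Derive arm placement, star span, duplex mismatches and loop counts
    from the predicted structure.

    G:U counts as paired in duplex-mismatch accounting. A structure with no
    pairs at all cannot place the mature on an arm and raises
    :class:`StructureError`.
    """
    if candidate.dot_bracket is None:
        raise ValueError("candidate has no predicted structure")
    partner = _pair_partner(candidate.dot_bracket)
    if not partner:
        raise StructureError("structure has no pairs: arm undeterminable")

    loop = _terminal_loop(partner)
    m0, m1 = candidate.mature_span
    if m1 <= loop[0]:
        arm = "5p"
    elif m0 >= loop[1]:
        arm = "3p"
    else:
        arm = "loop_spanning"

    partners = [partner[p] for p in range(m0, m1) if p in partner]
    star = (min(partners), max(partners) + 1) if partners else None
    duplex_mm = sum(1 for p in range(m0, m1) if p not in partner)

    # maximal unpaired runs strictly inside the mature span (flanked by
    # paired mature positions on both sides)
    runs: list[int] = []
    run = 0
    for p in range(m0, m1):
        if p not in partner:
            run += 1
        else:
            if run and p - run > m0:
                runs.append(run)
            run = 0
    # a run touching the 3' end of the span is not "strictly inside"
    internal_loops = len(runs)
    max_internal_run = max(runs, default=0)

    return replace(candidate, arm=arm, star_span=star,
                   duplex_mismatches=duplex_mm,
                   internal_loops_in_mature=internal_loops,
                   max_internal_run=max_internal_run,
                   terminal_loop_span=loop)
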