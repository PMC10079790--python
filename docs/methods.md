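# Methods

`estmir` implements an EST-based survey for conserved plant miRNAs: known
mature miRNAs are searched against an EST corpus, candidate precursor
windows are excised and folded, and candidates are accepted or rejected on
explicit thermodynamic and structural criteria. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Pipeline model

The survey assumes that conserved miRNAs can be recognized in ESTs of a
species without a reference genome, because (i) mature plant miRNAs are
highly conserved (so a known mature sequence places itself on an EST with
at most a few substitutions), and (ii) genuine precursors fold into
characteristic stem-loops that random transcript fragments rarely imitate.
The pipeline is a strict filtering funnel:

1. **Redundancy removal** (ESTs and reference miRNAs) at identity
   cutoff 1. *Exact* mode removes byte-identical sequences; the default
   *containment* mode additionally absorbs exact substrings into the
   longest matching record (what cutoff-1 clustering does to EST
   fragments). Representatives are the longest record, ties broken by id,
   so the outcome is order-independent.
2. **Homology search.** Because queries are 18–24 nt, BLAST-style seeded
   alignment is replaced by an exhaustive, exact scan: every full-length
   ungapped placement of each query on both strands of each EST is scored
   by Hamming distance; placements with ≤ `max_mismatch` (default 3)
   substitutions are hits. Gapped placements are excluded: all downstream
   mismatch accounting is substitution-based. Top-hit selection keeps one
   hit per query — minimal mismatches, ties preferring the longer EST,
   then smaller EST id, smaller offset, and `+` over `-`. These tie-break
   rules are this package's own; a seeded aligner's default scoring could
   order ties differently.
3. **Coding filter.** A six-frame ORF heuristic stands in for a translated
   search against a protein database: an EST is coding when its longest
   AUG-initiated, stop-terminated ORF reaches `orf_threshold` codons
   (default 80 ≈ 240 nt, comfortably above the ORF lengths random
   300–800-nt sequences typically reach and below nearly all genuine
   coding regions sampled by ESTs). Externally computed translated-search
   results can be imported as BLAST outfmt-6 tables; any EST with a row is
   coding, overriding the heuristic.
4. **Precursor excision.** An 85-nt window (the conventional candidate
   precursor length for this kind of survey) is excised around each hit,
   centered on the mature midpoint on the hit strand:
   `start = clamp(mid − window//2, 0, len − window)`. The window is
   shifted, never truncated, at EST edges; ESTs shorter than the window
   are used whole.
5. **Folding.** See below.
6. **Criteria.** Rules R1–R9 (see below), all evaluated, all failures
   reported.
7. **Naming.** Accepted candidates inherit the family of their best
   reference homolog (`ath-miR5658` → `<prefix>-miR5658`), with letter
   suffixes inserted before any `-5p/-3p` arm tag on clashes.
8. **Targets** (optional). Transcript windows scored with the Allen-style
   penalty scheme: Watson–Crick 0, G:U 0.5, mismatch 1, gap 2, all
   doubled at miRNA positions 2–13; sites kept at expectation ≤ 3.0;
   a genuine mismatch at positions 9–11 classifies a site as
   translational inhibition rather than cleavage. The published server
   this mirrors does not document one canonical arithmetic, so the scheme
   is explicit here and swappable in config. Scanning is ungapped and
   sense-strand only (targets are mRNAs).
9. **Phylogeny** (optional). p-distance over unit-cost global alignments
   (edlib), neighbor joining (scikit-bio), Newick output with 6-decimal
   branch lengths. For 18–24-nt sequences a profile MSA adds nothing
   testable, so pairwise alignment suffices. Negative NJ branch estimates
   are clamped to zero and the clamped amount logged.

## Folding model

The internal folder is a simplified nearest-neighbor model chosen to be
*fully specifiable and exactly testable* rather than to reproduce any
particular published energy table:

* pairs: A:U, U:A, G:C, C:G, G:U, U:G; minimum hairpin loop 3 nt;
* helix stability from a 6×6 stacking table (all entries negative,
  −0.3 … −3.4 kcal/mol, Turner-like ordering: G:C stacks strongest, G:U
  weakest);
* affine loop penalties: hairpin 4.0 + 0.25·n, bulge 3.5 + 0.30·n,
  internal 3.0 + 0.30·n kcal/mol; multibranch 4.0 + 0.5/branch +
  0.2/unpaired nt; exterior bases free; no dangles, terminal-AU
  penalties or tetraloop bonuses.

The MFE structure is computed by Zuker-style dynamic programming (O(n³),
interior loops capped at 30 unpaired nt) with a deterministic traceback.
An exhaustive enumerator over all pseudoknot-free structures (≤ 18 nt)
scores candidates with the *same* loop-decomposition energy function and
serves as an independent oracle; the DP is property-tested against it.
The backend is pluggable (`FOLD_BACKENDS`); ViennaRNA's bindings register
as `"vienna"` when importable. Because the model is simplified, absolute
MFE values are not comparable with MFOLD/ViennaRNA output; the derived
indices (AMFE, MFEI) are meaningful when computed consistently within one
run, which is how the acceptance rules use them.

## Acceptance criteria (rules R1–R9)

| rule | quantity | default |
|------|----------|---------|
| R1 | mature length | 18–22 nt |
| R2 | mismatches to the reference homolog | ≤ 3 |
| R3 | precursor A+U content | 30–70 % |
| R4 | MFE | < 0 kcal/mol |
| R5 | MFEI = AMFE / (G+C)% | ≤ −0.50 |
| R6 | mature arm | 5p or 3p (not loop-spanning) |
| R7 | mature:star duplex mismatches (G:U counts paired) | ≤ 6 |
| R8 | internal loops/bulges inside the mature | ≤ 1 |
| R9 | longest unpaired run inside the mature | ≤ 3 nt |

AMFE = MFE / precursor length × 100. Composition percentages are
truncated (not rounded) at two decimals — published per-miRNA tables of
G+C% are reproducible only under truncation — but all rule arithmetic
uses untruncated fractions; truncation is display-only. The MFEI bound
is the operative range observed in accepted plant precursor sets
(|MFEI| 0.50–0.84); the stricter 0.85 literature cutoff would reject
much of that range and can be set in config. N residues are excluded
from composition numerator and denominator; an all-N sequence has no
composition and is an error.

The terminal loop is the unpaired run enclosed by the innermost pair of
the longest stem (ties: leftmost); the arm is 5p/3p by whether the mature
lies entirely left/right of it. The star span is the region pairing with
mature positions, with no 2-nt offset correction applied (no processing
offset is assumed anywhere else either).

## Synthetic corpus

The generator emulates the statistical structure the analysis assumes,
with defaults acting as the study conditions: 200 background ESTs, 20
planted, 20 coding decoys, 10 exact duplicates; lengths uniform 300–800
nt; background G+C 0.42 (plant precursor surveys report A+U-rich
precursors, ~54–72 % A+U, hence G+C ≈ 0.28–0.46; 0.42 sits in that
band); mature mutations uniform on {0,1,2,3}, never at position 1 (the
5'-U bias of genuine plant miRNAs); star mismatches 0–2 placed as one
contiguous block (real duplex imperfections are localized bulges).

Planted hairpins are *verified at generation*: each design (flank +
mature + loop + star + flank, flanks/loop from the unpairable {A,C}
alphabet with C content steered so precursor A+U lands near 0.60) is
folded and must pass the full default rule set; failures are retried and
a reference that cannot seed a passing hairpin is redrawn. The mature
midpoint sits at the precursor midpoint so the discovery window recovers
the designed hairpin exactly. Backgrounds and planted backbones are
redrawn if they contain an accidental threshold-length ORF, keeping
manifest categories truthful (~7 % of unconstrained draws would
otherwise be mislabelled).

What the generator does **not** emulate: sequencing error, EST chimerism,
paralogous families, genomic repeats, or realistic codon usage in decoys.
Passing tests therefore demonstrate that the pipeline's stages do what
they claim under the assumed statistics, not that its thresholds are
optimal for any particular real corpus.

## Numerical and determinism notes

* All percentages truncate via integer arithmetic
  (`count * 10000 // total / 100`), exact for any count/total.
* AMFE multiplies before dividing so `amfe(m, 100) == m` holds exactly in
  floating point.
* The DP traceback re-derives each decision with an absolute tolerance of
  1e-9; brute-force/DP energy comparisons use the same tolerance.
* p-distance aligns each pair in lexicographic order: optimal unit-cost
  alignments are not unique and their lengths can differ, so the
  canonical order keeps the distance symmetric.
* The discovery pipeline is fully deterministic; randomness exists only
  in the corpus generator and is controlled by one integer seed
  (identical config + seed → byte-identical report tables).
* Problem sizes in the test suite and the acceptance script (60–250-EST
  corpora, 300–500 oracle sequences of 12–16 nt, 60–100 NJ replicates of
  ≤ 12 taxa) are chosen so a full run completes in well under a minute
  on one core while still exercising every stage at the default study
  conditions.

## Known limitations

* The energy model is intentionally minimal; structures near the MFE of
  the full Turner model can differ, so per-candidate MFE/MFEI values are
  not comparable across folding backends.
* Top-hit tie-breaking differs in principle from seeded-aligner scoring;
  on real corpora the selected EST can differ for tied candidates.
* The coding filter's ORF heuristic misses coding ESTs that sample a CDS
  out of frame or across an intron-containing UTR fragment; the outfmt-6
  import hook exists for exactly that reason.
* `remove_redundant` in containment mode is O(n²) in the number of kept
  records; adequate for EST corpora in the 10⁵ range but not for
  assembled transcriptomes.
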