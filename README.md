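# estmir

EST-based discovery of conserved plant miRNAs.

Mature plant miRNAs are strongly conserved across species, so a species
without a reference genome can still be surveyed for miRNAs by searching
known mature sequences against its Expressed Sequence Tags (ESTs) and
asking whether each match sits inside a transcript region that folds into
a genuine precursor hairpin. `estmir` implements that survey end to end
for people who work on non-model plants: redundancy removal at identity
cutoff 1, exhaustive ungapped homology search (queries are 18–24 nt, so
exact scanning replaces seeded alignment), a six-frame ORF coding filter,
85-nt precursor excision and secondary-structure prediction, candidate
acceptance on explicit thermodynamic criteria, complementarity-based
target scanning, and a neighbor-joining phylogeny of the accepted miRNAs
with their family homologs.

The thermodynamic indices at the core of candidate acceptance are

```
AMFE = MFE / L_precursor × 100          (kcal/mol per 100 nt)
MFEI = AMFE / (G+C)%                    (dimensionless)
```

where MFE is the minimum folding free energy of the precursor window.
miRNA precursors are A+U-rich yet fold unusually stably for their
composition, so they separate from mRNA/rRNA/tRNA fragments by MFEI.
Accepted candidates must satisfy nine rules (mature length 18–22 nt,
≤ 3 mismatches to the homolog, precursor A+U 30–70 %, MFE < 0,
MFEI ≤ −0.50, mature on a single arm, ≤ 6 mature:star duplex mismatches
with G:U counted as paired, ≤ 1 internal loop inside the mature, no
unpaired run > 3 nt inside the mature); every threshold is configurable.
See `docs/methods.md` for the folding model, the scoring schemes, and the
design decisions.

A synthetic-corpus generator plants verified hairpins (matures mutated
0–3 substitutions from their reference), coding decoys and exact
duplicates into background ESTs, with a ground-truth manifest, so the
whole pipeline is testable without any downloads.

## Worked example

Generate a small synthetic corpus and run the discovery pipeline:

```
$ estmir synth --seed 7 --out data --n-background 60 --n-planted 6 \
      --n-coding 5 --n-duplicates 3
wrote 74 ESTs, 6 reference miRNAs and manifest to data

$ estmir discover --ests data/ests.fasta --mirnas data/reference_mirnas.fasta \
      --out run --species-prefix syn --tree
accepted 6 candidate miRNA(s); artifacts in /tmp/demo/run
```

`run/counts.json` records the filtering funnel — 74 input ESTs, 71 after
redundancy removal (the 3 planted duplicates collapse), 6 ESTs carrying a
top homology hit, all 6 non-coding, 6 folded, 6 passing all rules:

```json
{
  "ests_input": 74,
  "ests_nonredundant": 71,
  "ests_with_hits": 6,
  "ests_hit_nonredundant": 6,
  "ests_noncoding": 6,
  "candidates_folded": 6,
  "candidates_passed": 6
}
```

`run/report.tsv` holds one row per candidate with every measured
quantity. The accepted rows of this run:

```
proposed_name      est_id  mature_length  homolog_mismatches arm  precursor_au_percent_2dp   mfe   mfei
  syn-miR1001 planted0000             22                   2  5p                     57.64 -37.0 -1.028
  syn-miR1002 planted0001             21                   0  5p                     65.88 -23.3 -0.803
  syn-miR1003 planted0002             18                   3  5p                     57.64 -22.6 -0.628
  syn-miR1004 planted0003             20                   3  5p                     60.00 -22.4 -0.659
  syn-miR1005     dup0002             19                   3  5p                     67.05 -21.3 -0.761
  syn-miR1006 planted0005             18                   3  5p                     57.64 -18.1 -0.503
```

Each accepted mature is named after its reference family
(`syn-miR1001` from `ref-miR1001`); `mfe` is the precursor window's
folding energy in kcal/mol, and `mfei` its folding index — all six fall
in the A+U and MFEI ranges genuine plant precursors occupy. One
candidate surfaces under the id `dup0002` because redundancy removal
kept the duplicate copy of its EST as representative; the manifest's
`duplicate_of` column resolves it. With `--tree`, `run/tree.nwk` holds
the NJ tree of accepted matures and their homologs; each accepted miRNA
pairs with its own reference family, e.g.

```
((syn-miR1001:0.049155,ref-miR1001:0.041754):0.201470,...);
```

The same operations are available as a library
(`estmir.find_hits`, `estmir.fold`, `estmir.evaluate`,
`estmir.run_pipeline`, …) for use on real EST and miRNA FASTA files.

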