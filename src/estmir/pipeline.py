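"""End-to-end discovery workflow with per-stage artifacts.

Stage order (a strictly narrowing funnel):

    1. deduplicate reference miRNAs
    2. deduplicate ESTs
    3. top homology hit per miRNA query
    4. deduplicate the hit ESTs (hits re-pointed to representatives)
    5. coding filter (six-frame ORF heuristic, optional BLASTX import)
    6. excise 85-nt precursors, fold, analyze hairpins
    7. criteria evaluation (rules R1–R9)
    8. naming of accepted candidates
    9. optional: target scan against a transcript FASTA
   10. optional: NJ tree of accepted matures with their reference homologs

The discovery pipeline itself is fully deterministic; randomness exists
only in the synthetic corpus generator. Every run writes stage counts, a
per-candidate report table, FASTAs of accepted mature/precursor
sequences, and a JSONL log carrying the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import coding_filter, criteria, homology, phylo, redundancy, target_pred
from .criteria import CriteriaReport, Thresholds
from .hairpin import (DEFAULT_WINDOW, StructureError, analyze_hairpin,
                      excise_precursor, fold)
from .homology import HomologyHit
from .seqio import SequenceRecord, read_fasta, reverse_complement, write_fasta

logger = logging.getLogger("estmir")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and offending record."""


@dataclass
class PipelineConfig:
    ests: str = ""
    mirnas: str = ""
    transcripts: str | None = None
    out_dir: str = "run"
    species_prefix: str = "new"
    dedup_mode: str = "containment"
    max_mismatch: int = 3
    orf_threshold: int = coding_filter.DEFAULT_ORF_THRESHOLD
    blastx_table: str | None = None
    window: int = DEFAULT_WINDOW
    fold_backend: str = "internal"
    thresholds: Thresholds = field(default_factory=Thresholds)
    target_cutoff: float = target_pred.DEFAULT_CUTOFF
    hsp: int = target_pred.DEFAULT_HSP
    make_tree: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thresholds = Thresholds.from_dict(raw.pop("thresholds", {}) or {})
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thresholds, **known)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    out_dir: Path
    counts: dict[str, int]
    reports: list[CriteriaReport]
    accepted: list[CriteriaReport]
    tree_newick: str | None = None


def _repoint_hit(hit: HomologyHit, dup: SequenceRecord,
                 rep: SequenceRecord) -> HomologyHit:
    """Translate hit coordinates from a removed duplicate EST onto its
    retained representative (the duplicate is a substring of it)."""
    offset = rep.residues.find(dup.residues)
    if offset < 0:  # pragma: no cover - guaranteed by containment dedup
        raise PipelineError(f"dedup representative {rep.id} does not "
                            f"contain {dup.id}")
    if hit.strand == "+":
        new_start = offset + hit.est_start
    else:
        rc_offset = rep.length - (offset + dup.length)
        new_start = rc_offset + hit.est_start
    return HomologyHit(hit.query_id, rep.id, new_start, hit.strand,
                       hit.mismatches, hit.aligned_length)


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full discovery workflow; see the module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    events: list[dict] = []

    def log(stage: str, **kv) -> None:
        events.append({"t": round(time.time(), 3), "stage": stage, **kv})
        logger.info("%s: %s", stage, kv)

    def fail(stage: str, record: str, msg: str) -> PipelineError:
        log(stage, error=msg, record=record)
        _flush()
        return PipelineError(f"stage {stage!r}, record {record!r}: {msg}")

    def _flush() -> None:
        with open(log_path, "w") as fh:
            for ev in events:
                fh.write(json.dumps(ev) + "\n")

    log("config", hash=config.digest(), seed=config.seed)
    counts: dict[str, int] = {}

    # 1-2: load + deduplicate
    try:
        mirnas = read_fasta(config.mirnas)
    except Exception as exc:
        raise fail("load_mirnas", str(config.mirnas), str(exc)) from exc
    counts["mirnas_input"] = len(mirnas)
    mirnas, _ = redundancy.remove_redundant(mirnas, mode=config.dedup_mode)
    counts["mirnas_nonredundant"] = len(mirnas)

    try:
        ests = read_fasta(config.ests)
    except Exception as exc:
        raise fail("load_ests", str(config.ests), str(exc)) from exc
    counts["ests_input"] = len(ests)
    ests, _ = redundancy.remove_redundant(ests, mode=config.dedup_mode)
    counts["ests_nonredundant"] = len(ests)
    log("dedup", mirnas=counts["mirnas_nonredundant"],
        ests=counts["ests_nonredundant"])

    # 3: top hit per query
    best = homology.best_hit_per_query(mirnas, ests,
                                       max_mismatch=config.max_mismatch)
    hit_est_ids = {h.est_id for h in best.values()}
    counts["queries_with_hit"] = len(best)
    counts["ests_with_hits"] = len(hit_est_ids)
    log("homology", queries=len(mirnas), with_hit=len(best))

    # 4: dedup the hit ESTs, re-pointing hits to representatives
    est_by_id = {e.id: e for e in ests}
    hit_ests = [e for e in ests if e.id in hit_est_ids]
    hit_ests_kept, removed = redundancy.remove_redundant(
        hit_ests, mode=config.dedup_mode)
    kept_by_id = {e.id: e for e in hit_ests_kept}
    counts["ests_hit_nonredundant"] = len(hit_ests_kept)
    best = {
        q: (h if h.est_id in kept_by_id
            else _repoint_hit(h, est_by_id[h.est_id],
                              est_by_id[removed[h.est_id]]))
        for q, h in best.items()
    }

    # 5: coding filter
    overrides = (coding_filter.import_external_coding_calls(config.blastx_table)
                 if config.blastx_table else set())
    noncoding_ids = {
        e.id for e in hit_ests_kept
        if coding_filter.classify_coding(
            e, config.orf_threshold, overrides) == "noncoding"
    }
    counts["ests_noncoding"] = len(noncoding_ids)
    log("coding_filter", noncoding=len(noncoding_ids),
        coding=len(hit_ests_kept) - len(noncoding_ids))

    # 6-7: excise, fold, analyze, evaluate
    reports: list[CriteriaReport] = []
    folded = 0
    for query_id in sorted(best):
        hit = best[query_id]
        if hit.est_id not in noncoding_ids:
            continue
        est = est_by_id[hit.est_id]
        try:
            cand = excise_precursor(est, hit, window=config.window)
            db, mfe = fold(cand.sequence, backend=config.fold_backend)
            cand.dot_bracket, cand.mfe_kcal_per_mol = db, mfe
            cand = analyze_hairpin(cand)
        except StructureError as exc:
            log("hairpin", record=hit.est_id, query=query_id,
                rejected=str(exc))
            continue
        except Exception as exc:
            raise fail("hairpin", hit.est_id, str(exc)) from exc
        folded += 1
        report = criteria.evaluate(cand, hit, config.thresholds)
        report.family = criteria.parse_family(query_id)
        report._candidate = cand      # kept for downstream artifact output
        report._query_id = query_id
        reports.append(report)
    counts["candidates_folded"] = folded

    # 8: name accepted candidates (deterministic: sorted by query id)
    accepted = [r for r in reports if r.passed]
    taken: set[str] = set()
    for rep in accepted:
        rep.proposed_name = criteria.name_mirna(rep.family,
                                                config.species_prefix, taken)
        taken.add(rep.proposed_name)
    counts["candidates_passed"] = len(accepted)
    log("criteria", evaluated=len(reports), passed=len(accepted))

    # artifacts
    report_df = pd.DataFrame([
        {k: v for k, v in asdict(r).items()} | {
            "failed_rules": ",".join(r.failed_rules)}
        for r in reports
    ])
    report_df.to_csv(out / "report.tsv", sep="\t", index=False)
    write_fasta(
        [SequenceRecord(r.proposed_name, r.mature_seq,
                        f"mature miRNA from {r.est_id}")
         for r in accepted],
        out / "accepted_mature.fasta")
    write_fasta(
        [SequenceRecord(r.proposed_name + "-precursor",
                        r._candidate.sequence,
                        f"precursor window on {r.est_id} ({r._candidate.strand})")
         for r in accepted],
        out / "accepted_precursors.fasta")
    with open(out / "structures.txt", "w") as fh:  # plain-text dump
        for r in accepted:
            c = r._candidate
            m0, m1 = c.mature_span
            fh.write(f"> {r.proposed_name}  {r.est_id}  strand {c.strand}  "
                     f"mfe {c.mfe_kcal_per_mol:.2f} kcal/mol\n")
            fh.write(c.sequence + "\n" + c.dot_bracket + "\n")
            fh.write(" " * m0 + "^" * (m1 - m0) + " (mature)\n\n")

    # 9: optional target scan
    if config.transcripts:
        try:
            transcripts = read_fasta(config.transcripts)
        except Exception as exc:
            raise fail("load_transcripts", str(config.transcripts),
                       str(exc)) from exc
        sites = target_pred.scan_many(
            [SequenceRecord(r.proposed_name, r.mature_seq) for r in accepted],
            transcripts, cutoff=config.target_cutoff, hsp=config.hsp)
        target_pred.write_sites_tsv(sites, out / "targets.tsv")
        counts["target_sites"] = len(sites)
        log("targets", sites=len(sites))

    # 10: optional phylogeny of accepted matures + their reference homologs
    tree_newick = None
    if config.make_tree and accepted:
        mirna_by_id = {m.id: m for m in mirnas}
        labels, seqs = [], []
        for r in accepted:
            labels.append(r.proposed_name)
            seqs.append(r.mature_seq)
            homolog = mirna_by_id.get(r._query_id)
            if homolog is not None:
                labels.append(homolog.id)
                seqs.append(homolog.residues)
        if len(labels) >= 3:
            dm = phylo.distance_matrix(seqs, labels)
            tree = phylo.nj_tree(dm)
            tree_newick = phylo.to_newick(tree)
            (out / "tree.nwk").write_text(tree_newick + "\n")
            log("phylo", taxa=len(labels))

    with open(out / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    _flush()
    return RunResult(out_dir=out, counts=counts, reports=reports,
                     accepted=accepted, tree_newick=tree_newick)
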