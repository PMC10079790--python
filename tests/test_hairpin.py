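"""Folding model, brute-force oracle, precursor excision, hairpin analysis."""

import pytest
from hypothesis import given, settings, strategies as st

from estmir import (FoldError, HomologyHit, PrecursorCandidate, SequenceRecord,
                    StructureError, analyze_hairpin, excise_precursor, fold,
                    fold_bruteforce, reverse_complement, structure_energy)
from estmir.hairpin import FOLD_BACKENDS

rna = st.text(alphabet="ACGU", min_size=12, max_size=16)


class TestExcise:
    def test_window_centered_on_mature_midpoint(self):
        est = SequenceRecord("e", "A" * 200)
        hit = HomologyHit("q", "e", 90, "+", 0, 18)
        cand = excise_precursor(est, hit, window=85)
        # mature midpoint 99 -> window [57, 142)
        assert cand.window_start == 57 and len(cand.sequence) == 85
        assert cand.mature_span == (33, 51)

    def test_window_shifted_not_truncated_at_edge(self):
        est = SequenceRecord("e", "A" * 200)
        hit = HomologyHit("q", "e", 0, "+", 0, 18)
        cand = excise_precursor(est, hit, window=85)
        assert cand.window_start == 0 and len(cand.sequence) == 85
        assert cand.mature_span == (0, 18)

    def test_short_est_used_whole(self):
        est = SequenceRecord("e", "ACGU" * 15)  # 60 nt
        hit = HomologyHit("q", "e", 10, "+", 0, 18)
        cand = excise_precursor(est, hit, window=85)
        assert len(cand.sequence) == 60 and cand.mature_span == (10, 28)

    def test_minus_strand_excises_from_reverse_complement(self):
        seq = "ACGU" * 30
        est = SequenceRecord("e", seq)
        hit = HomologyHit("q", "e", 5, "-", 0, 18)
        cand = excise_precursor(est, hit, window=85)
        rc = reverse_complement(seq)
        m0 = cand.mature_span[0]
        assert cand.sequence == rc[cand.window_start:cand.window_start + 85]
        assert cand.sequence[m0:m0 + 18] == rc[5:23]

    def test_est_shorter_than_mature_rejected(self):
        with pytest.raises(ValueError):
            excise_precursor(SequenceRecord("e", "ACGU"),
                             HomologyHit("q", "e", 0, "+", 0, 18))


class TestFold:
    def test_unpairable_sequence_is_open(self):
        db, mfe = fold("AAAAAAAAAAAA")
        assert db == "." * 12 and mfe == 0.0

    def test_gquad_free_stem(self):
        db, mfe = fold("GGGGAAAACCCC")
        assert db == "((((....))))" and mfe < 0

    def test_bruteforce_palindromic_stem(self):
        db, mfe = fold_bruteforce("GGGAAACCC")
        assert db == "(((...)))" and mfe < 0

    def test_bruteforce_too_short_to_pair(self):
        db, mfe = fold_bruteforce("ACGU")
        assert db == "...." and mfe == 0.0

    def test_bruteforce_refuses_long_input(self):
        with pytest.raises(FoldError):
            fold_bruteforce("A" * 19)

    def test_alphabet_violation(self):
        with pytest.raises(FoldError):
            fold("ACGT")

    @given(seq=rna)
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_dp_matches_bruteforce_energy(self, seq):
        assert fold(seq)[1] == pytest.approx(fold_bruteforce(seq)[1],
                                             abs=1e-9)

    @given(seq=rna)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_reported_structure_scores_its_own_energy(self, seq):
        db, mfe = fold(seq)
        stack, pairs = [], []
        for i, ch in enumerate(db):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                pairs.append((stack.pop(), i))
        assert structure_energy(seq, pairs) == pytest.approx(mfe, abs=1e-9)

    def test_poly_a_flanks_do_not_weaken_core(self):
        core = "GGGGCGAAAACGCCCC"
        _, mfe_core = fold(core)
        _, mfe_flanked = fold("AAAAAA" + core + "AAAAAA")
        assert mfe_flanked <= mfe_core

    def test_reverse_complement_of_hairpin_is_hairpin(self):
        seq = "GGGCUGCAAAAGCAGCCC"
        db, mfe = fold(seq)
        db_rc, mfe_rc = fold(reverse_complement(seq))
        assert "(" in db and "(" in db_rc and mfe < 0 and mfe_rc < 0

    def test_vienna_backend_agrees_qualitatively(self):
        # the external thermodynamic backend sees the same hairpin
        if "vienna" not in FOLD_BACKENDS:
            return
        seq = "CCAAAC" + "GUGCUAGCUAGCAUCGAUGC" + "AACAA" \
            + reverse_complement("GUGCUAGCUAGCAUCGAUGC") + "CAAACC"
        db_i, mfe_i = fold(seq, backend="internal")
        db_v, mfe_v = fold(seq, backend="vienna")
        assert mfe_i < -10 and mfe_v < -10
        assert db_i.count("(") >= 15 and db_v.count("(") >= 15


class TestAnalyzeHairpin:
    def test_perfect_stem_mature_on_5p(self, perfect_hairpin_candidate):
        cand = analyze_hairpin(perfect_hairpin_candidate)
        assert cand.arm == "5p"
        assert cand.duplex_mismatches == 0
        assert cand.internal_loops_in_mature == 0
        assert cand.star_span == (25, 45)
        assert cand.terminal_loop_span == (20, 25)

    def test_bulged_mature_counts_mismatches(self):
        stem5 = "GUGCUAGCUAGCAUCGAUGC"
        # break pairing of two interior mature positions by mutating the star
        star = list(reverse_complement(stem5))
        star[10] = "A" if star[10] != "A" else "C"
        star[11] = "A" if star[11] != "A" else "C"
        seq = stem5 + "AAACA" + "".join(star)
        db, mfe = fold(seq)
        cand = analyze_hairpin(PrecursorCandidate(
            est_id="x", window_start=0, sequence=seq, mature_span=(0, 20),
            dot_bracket=db, mfe_kcal_per_mol=mfe))
        assert cand.duplex_mismatches == 2
        assert cand.internal_loops_in_mature <= 2

    def test_mature_straddling_loop_is_loop_spanning(self,
                                                     perfect_hairpin_candidate):
        from dataclasses import replace
        cand = replace(perfect_hairpin_candidate, mature_span=(12, 30))
        assert analyze_hairpin(cand).arm == "loop_spanning"

    def test_mature_on_3p_arm(self, perfect_hairpin_candidate):
        from dataclasses import replace
        cand = replace(perfect_hairpin_candidate, mature_span=(25, 45))
        out = analyze_hairpin(cand)
        assert out.arm == "3p" and out.star_span == (0, 20)

    def test_pairless_structure_rejected(self):
        cand = PrecursorCandidate(est_id="x", window_start=0,
                                  sequence="A" * 30, mature_span=(0, 18),
                                  dot_bracket="." * 30, mfe_kcal_per_mol=0.0)
        with pytest.raises(StructureError):
            analyze_hairpin(cand)
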