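"""AMFE/MFEI arithmetic, acceptance rules, miRBase-style naming."""

import pytest
from hypothesis import given, settings, strategies as st

from estmir import (HomologyHit, NamingError, Thresholds, amfe, evaluate,
                    mfei, name_mirna, parse_family)


class TestFormulas:
    def test_amfe_is_identity_at_length_100(self):
        for m in (-50.0, -23.7, 0.0):
            assert amfe(m, 100) == m

    def test_amfe_of_85nt_precursor(self):
        assert amfe(-23.70, 85) == pytest.approx(-27.88235294, abs=1e-6)

    def test_amfe_zero_mfe(self):
        assert amfe(0.0, 77) == 0.0

    def test_amfe_rejects_zero_length(self):
        with pytest.raises(ValueError):
            amfe(-10.0, 0)

    def test_mfei_direct(self):
        assert mfei(-30.0, 50.0) == pytest.approx(-0.600)

    def test_mfei_independent_arithmetic(self):
        assert mfei(-27.88, 41.17) == pytest.approx(-0.677, abs=5e-4)

    def test_mfei_scale_invariance(self):
        assert mfei(-25.0, 40.0) == pytest.approx(mfei(-50.0, 80.0))

    def test_mfei_rejects_zero_gc(self):
        with pytest.raises(ValueError):
            mfei(-30.0, 0.0)

    @given(m=st.floats(min_value=-80, max_value=-0.01),
           gc=st.floats(min_value=5, max_value=95))
    @settings(derandomize=True, max_examples=100)
    def test_mfei_sign_matches_mfe_sign(self, m, gc):
        assert mfei(amfe(m, 85), gc) < 0


def _evaluated(candidate, mismatches=0, thresholds=None):
    hit = HomologyHit("ath-miR9999", candidate.est_id,
                      candidate.mature_span[0], "+", mismatches,
                      candidate.mature_span[1] - candidate.mature_span[0])
    return evaluate(candidate, hit, thresholds)


class TestEvaluate:
    def test_perfect_hairpin_passes_all_rules(self):
        from estmir import analyze_hairpin, make_precursor, fold
        from estmir.hairpin import PrecursorCandidate
        design = make_precursor("UGAUGCUGAUGAUGAGGA", seed=5)
        db, mfe = fold(design.sequence)
        cand = analyze_hairpin(PrecursorCandidate(
            est_id="e", window_start=0, sequence=design.sequence,
            mature_span=design.mature_span, dot_bracket=db,
            mfe_kcal_per_mol=mfe))
        report = _evaluated(cand)
        assert report.passed and report.failed_rules == []
        assert report.mfe < 0 and report.mfei <= -0.50

    def test_each_rule_fails_independently(self, perfect_hairpin_candidate):
        from dataclasses import replace
        from estmir import analyze_hairpin
        base = analyze_hairpin(perfect_hairpin_candidate)

        r = _evaluated(replace(base, duplex_mismatches=7))
        assert "R7" in r.failed_rules
        r = _evaluated(base, mismatches=4)
        assert "R2" in r.failed_rules
        r = _evaluated(replace(base, arm="loop_spanning"))
        assert "R6" in r.failed_rules
        r = _evaluated(replace(base, internal_loops_in_mature=2))
        assert "R8" in r.failed_rules
        r = _evaluated(replace(base, max_internal_run=4))
        assert "R9" in r.failed_rules
        r = _evaluated(replace(base, mfe_kcal_per_mol=0.0))
        assert {"R4", "R5"} <= set(r.failed_rules)

    def test_au_out_of_range_fails_r3(self):
        from estmir import analyze_hairpin, fold
        from estmir.hairpin import PrecursorCandidate
        # AU-rich hairpin: A+U ~ 76% > 70
        stem = "UAUAUUAUAUGCUAAUAU"
        from estmir import reverse_complement
        seq = "AAAA" + stem + "AACAA" + reverse_complement(stem) + "AAAA"
        db, mfe = fold(seq)
        cand = analyze_hairpin(PrecursorCandidate(
            est_id="e", window_start=0, sequence=seq, mature_span=(4, 22),
            dot_bracket=db, mfe_kcal_per_mol=mfe))
        report = _evaluated(cand)
        assert report.precursor_au_percent_2dp > 70
        assert "R3" in report.failed_rules

    def test_relaxing_a_threshold_never_shrinks_passes(self,
                                                       perfect_hairpin_candidate):
        from dataclasses import replace
        from estmir import analyze_hairpin
        base = analyze_hairpin(perfect_hairpin_candidate)
        bulged = replace(base, duplex_mismatches=7)
        strict = _evaluated(bulged)
        relaxed = _evaluated(bulged,
                             thresholds=Thresholds(max_duplex_mismatches=8))
        assert not strict.passed and set(relaxed.failed_rules) <= \
            set(strict.failed_rules)

    def test_unanalyzed_candidate_rejected(self):
        from estmir.hairpin import PrecursorCandidate
        cand = PrecursorCandidate(est_id="e", window_start=0,
                                  sequence="ACGU" * 10, mature_span=(0, 18))
        with pytest.raises(ValueError):
            _evaluated(cand)


class TestNaming:
    def test_family_transfer_simple(self):
        assert parse_family("ath-miR5658") == "miR5658"
        assert name_mirna("miR5658", "jcu", set()) == "jcu-miR5658"

    def test_family_with_arm_suffix(self):
        assert parse_family("rgl-miR7805-3p") == "miR7805-3p"
        assert name_mirna("miR7805-3p", "jcu", set()) == "jcu-miR7805-3p"

    def test_clash_gets_letter_before_arm_tag(self):
        taken = {"jcu-miR7805-3p"}
        assert name_mirna("miR7805-3p", "jcu", taken) == "jcu-miR7805a-3p"
        taken.add("jcu-miR7805a-3p")
        assert name_mirna("miR7805-3p", "jcu", taken) == "jcu-miR7805b-3p"

    def test_unparseable_reference_raises(self):
        with pytest.raises(NamingError):
            parse_family("garbage")
        with pytest.raises(NamingError):
            parse_family("ath-xyz123")
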