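"""Six-pattern rule engine: per-biopsy rules, patient aggregation, concordance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ichthyoscore.cohort import (
    BiopsyFindings,
    Cohort,
    DiagnosisGroup,
    PatternLabel,
    Regularity,
)
from ichthyoscore.grading import CollapsePolicy
from ichthyoscore.grammar import Grade, GradeSpan, parse_corneum, parse_grade_span
from ichthyoscore.patterns import (
    DEFAULT_EXCEPTION_REGISTRY,
    RuleConfig,
    UnclassifiableError,
    classify_biopsy,
    classify_patient,
    concordance,
)

M = "−"


def findings(sc, sg, ac, infl, reg=Regularity.UNSPECIFIED, flags=()):
    return BiopsyFindings(
        sc=parse_corneum(sc),
        sg=parse_grade_span(sg),
        acanthosis=parse_grade_span(ac),
        inflammation=parse_grade_span(infl),
        acanthosis_regularity=reg,
        flags=frozenset(flags),
    )


class TestClassifyBiopsy:
    def test_ortho_with_absent_sg_is_pattern_one(self):
        # reference patient 1
        a = classify_biopsy(findings("+, OK, lamellar", f"{M}{M}", "+", "+"))
        assert a.primary is PatternLabel.I

    def test_ortho_with_developed_sg_is_pattern_two(self):
        # reference patient 30
        a = classify_biopsy(
            findings("++, OK, compact > lamellar", "+", "++", "+", Regularity.REGULAR)
        )
        assert a.primary is PatternLabel.II

    def test_staggered_ortho_para_with_preserved_sg_is_pattern_three(self):
        # reference patient 38
        a = classify_biopsy(
            findings("+/++, OK/PK, lamellar", "+", "+", "+", Regularity.IRREGULAR)
        )
        assert a.primary is PatternLabel.III

    def test_ehk_flag_is_pattern_four_unconditionally(self):
        # reference patient 43
        a = classify_biopsy(
            findings("+++, OK, compact/lamellar", "+", "++", "+",
                     Regularity.REGULAR, flags=("EHK", "EHK_continuous"))
        )
        assert a.primary is PatternLabel.IV
        # II is also satisfied but IV takes precedence
        assert PatternLabel.II in a.satisfied

    def test_vacuoles_plus_binucleation_is_pattern_five(self):
        a = classify_biopsy(
            findings("+, PK", f"{M}{M}", "++", "+", Regularity.REGULAR,
                     flags=("perinuclear_vacuoles", "binucleated_keratinocytes"))
        )
        assert a.primary is PatternLabel.V

    def test_psoriasiform_gate_is_pattern_six(self):
        # reference patient 45
        a = classify_biopsy(
            findings("+, OK, focal PK, lamellar", "+/++", "++", "++",
                     Regularity.REGULAR, flags=("kissing_vessels",))
        )
        assert a.primary is PatternLabel.VI

    def test_vi_needs_parakeratosis(self):
        a = classify_biopsy(
            findings("++/+++, OK, lamellar", "++", "++", "+/++", Regularity.REGULAR)
        )
        assert a.primary is PatternLabel.II

    def test_vi_architecture_marker_requirement_is_configurable(self):
        f = findings("+, OK, focal PK, lamellar", "+/++", "++", "++")
        strict = RuleConfig(vi_requires_architecture_marker=True)
        assert classify_biopsy(f).primary is PatternLabel.VI
        assert classify_biopsy(f, strict).primary is PatternLabel.II
        with_marker = findings("+, OK, focal PK, lamellar", "+/++", "++", "++",
                               flags=("kissing_vessels",))
        assert classify_biopsy(with_marker, strict).primary is PatternLabel.VI

    def test_sg_policy_changes_span_reading(self):
        f = findings("+, OK, lamellar", f"{M}/+", "+", "+")
        assert classify_biopsy(f).primary is PatternLabel.II
        pessimistic = RuleConfig(sg_policy=CollapsePolicy.PESSIMISTIC_MIN)
        assert classify_biopsy(f, pessimistic).primary is PatternLabel.I

    def test_unclassifiable_names_missing_evidence(self):
        f = BiopsyFindings(
            sc=parse_corneum("+, OK, lamellar"),
            sg=parse_grade_span("n.a."),
            acanthosis=parse_grade_span("+"),
            inflammation=parse_grade_span("+"),
        )
        with pytest.raises(UnclassifiableError, match="granulosum"):
            classify_biopsy(f)

    def test_determinism(self):
        f = findings("+, OK, focal PK, lamellar", "+/++", "++", "++")
        assert classify_biopsy(f) == classify_biopsy(f)

    def test_trace_covers_every_rule(self):
        a = classify_biopsy(findings("+, OK, lamellar", f"{M}{M}", "+", "+"))
        assert [e.rule for e in a.trace] == list(
            (PatternLabel.IV, PatternLabel.V, PatternLabel.VI,
             PatternLabel.III, PatternLabel.I, PatternLabel.II)
        )


class TestClassifyPatient:
    def test_single_biopsy_patient_matches_biopsy_call(self, fixture_cohort):
        p = fixture_cohort.get(1)
        assert classify_patient(p).primary == classify_biopsy(p.biopsies[0]).primary

    def test_multi_biopsy_patient_takes_highest_precedence(self, fixture_cohort):
        # patient 50: several of the 14 biopsies meet the psoriasis-like gate
        assert classify_patient(fixture_cohort.get(50)).primary is PatternLabel.VI
        # patient 46: both biopsies meet it
        assert classify_patient(fixture_cohort.get(46)).primary is PatternLabel.VI

    def test_all_spink5_patients_classify_to_pattern_six(self, fixture_cohort):
        for p in fixture_cohort.patients:
            if p.gene == "SPINK5":
                assert classify_patient(p).primary is PatternLabel.VI

    def test_all_ehk_flagged_patients_classify_to_pattern_four(self, fixture_cohort):
        flagged = [
            p for p in fixture_cohort.patients
            if any("EHK" in b.flags for b in p.biopsies)
        ]
        assert len(flagged) == 5  # the keratinopathic ichthyosis group
        for p in flagged:
            assert classify_patient(p).primary is PatternLabel.IV


class TestConcordance:
    def test_fixture_concordance_at_least_ninety_percent(self, fixture_cohort):
        rep = concordance(fixture_cohort)
        assert rep.fraction >= 0.90

    def test_every_disagreement_is_a_registered_exception(self, fixture_cohort):
        rep = concordance(fixture_cohort)
        assert rep.unregistered_disagreements == ()
        assert {d.patient_id for d in rep.disagreements} == set(
            DEFAULT_EXCEPTION_REGISTRY
        )

    def test_every_patient_receives_a_primary_pattern(self, fixture_cohort):
        rep = concordance(fixture_cohort)
        assert set(rep.assignments) == {p.id for p in fixture_cohort.patients}

    def test_ei_subset_concordance_is_perfect(self, fixture_cohort):
        ei = fixture_cohort.subset(
            lambda p: p.diagnosis_group is DiagnosisGroup.EI
        )
        rep = concordance(ei)
        assert rep.fraction == 1.0

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            concordance(Cohort(patients=()))


@settings(max_examples=150, deadline=None)
@given(
    infl=st.sampled_from([Grade.HIGH, Grade.TOP]),
    ac=st.sampled_from([Grade.HIGH, Grade.TOP]),
    bump_infl=st.integers(min_value=0, max_value=2),
    bump_ac=st.integers(min_value=0, max_value=2),
)
def test_vi_gate_is_monotone_in_grades(infl, ac, bump_infl, bump_ac):
    """Raising inflammation or acanthosis never un-fires a fired VI rule."""
    def fire(i, a):
        f = BiopsyFindings(
            sc=parse_corneum("+, OK, focal PK, lamellar"),
            sg=parse_grade_span("+"),
            acanthosis=GradeSpan.single(a),
            inflammation=GradeSpan.single(i),
        )
        return PatternLabel.VI in classify_biopsy(f).satisfied

    assert fire(infl, ac)
    higher_i = Grade(min(infl + bump_infl, Grade.TOP))
    higher_a = Grade(min(ac + bump_ac, Grade.TOP))
    assert fire(higher_i, higher_a)
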