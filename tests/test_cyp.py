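"""Domain 1: two-step normalization and developmental tier grading.

The grading sweep is checked against an interval-membership oracle built
from an independent transcription of the printed developmental tables
(one representative age per bin, lower tier edges in %Adult).
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mviscore import ConfigurationError, normalize_to_adult, grade_isoform, score_domain1
from mviscore.core import GenotypeClass, Isoform, Measure, ValidityState, ValidityStatus
from mviscore.cyp import CypMeasurement, GradeTier, is_implausible

OPTIMAL = ValidityStatus(state=ValidityState.optimal)
NS_LIVER = ValidityStatus(state=ValidityState.NS, reason="PMI exceeds maximum")

# Independent transcription of the printed developmental fraction tables:
# (isoform, measure) -> list of (representative age in days,
#                                (normal_min, mild_low, moderate_low) or None)
ORACLE_TABLES = {
    (Isoform.CYP3A4, Measure.protein_abundance): [
        (3, None), (15, (5, 4, 3)), (45, (15, 12, 11)), (75, (35, 28, 25)),
        (120, (35, 28, 25)), (250, (60, 48, 42)), (400, (85, 68, 60)),
    ],
    (Isoform.CYP2D6, Measure.protein_abundance): [
        (3, None), (15, (5, 4, 3)), (45, (10, 8, 7)), (75, (25, 20, 18)),
        (120, (25, 20, 18)), (250, (60, 48, 42)), (400, (85, 68, 60)),
    ],
    (Isoform.CYP2C19, Measure.protein_abundance): [
        (15, None), (45, (5, 4, 3)), (75, (20, 16, 14)), (120, (20, 16, 14)),
        (250, (60, 48, 42)), (400, (85, 68, 60)),
    ],
    (Isoform.CYP3A5, Measure.protein_abundance): [
        (100, (70, 56, 49)), (400, None),
    ],
    (Isoform.CYP3A4, Measure.probe_activity): [
        (3, None), (15, (5, 4, 3.5)), (45, (20, 16, 14)), (75, (30, 24, 21)),
        (120, (40, 32, 28)), (250, (50, 40, 35)), (400, (80, 64, 56)),
    ],
    (Isoform.CYP2D6, Measure.probe_activity): [
        (3, None), (15, (5, 4, 3.5)), (45, (15, 12, 10)), (75, (25, 20, 17)),
        (120, (40, 32, 28)), (250, (60, 48, 42)), (400, (90, 72, 63)),
    ],
    (Isoform.CYP2C19, Measure.probe_activity): [
        (3, None), (15, (10, 8, 7)), (45, (25, 20, 18)), (75, (35, 28, 25)),
        (120, (50, 40, 35)), (250, (70, 56, 49)), (400, (90, 72, 63)),
    ],
    (Isoform.CYP3A5, Measure.probe_activity): [
        (3, (10, 8, 7)), (15, (20, 16, 14)), (45, (30, 24, 21)), (75, (40, 32, 28)),
        (120, (50, 40, 35)), (250, (70, 56, 49)), (400, (90, 72, 63)),
    ],
}


def oracle_tier(pct, edges):
    """Brute-force interval membership on the printed lower edges."""
    normal, mild, moderate = edges
    if pct >= normal:
        return 0
    if pct >= mild:
        return 1
    if pct >= moderate:
        return 2
    return 3


def _measure(isoform, value, measure=Measure.protein_abundance):
    return CypMeasurement(isoform=isoform, measure=measure, value=value)


class TestNormalization:
    def test_protein_uses_adult_mean(self, refset):
        ref = refset.adult_reference(Isoform.CYP3A4, Measure.protein_abundance)
        assert normalize_to_adult(_measure(Isoform.CYP3A4, 85.8), ref) == pytest.approx(100.0)
        assert normalize_to_adult(_measure(Isoform.CYP3A4, 42.9), ref) == pytest.approx(50.0)

    def test_zero_value_is_zero_percent(self, refset):
        ref = refset.adult_reference(Isoform.CYP2D6, Measure.protein_abundance)
        assert normalize_to_adult(_measure(Isoform.CYP2D6, 0.0), ref) == 0.0

    def test_activity_uses_range_midpoint(self, refset):
        ref = refset.adult_reference(Isoform.CYP3A4, Measure.probe_activity)
        m = _measure(Isoform.CYP3A4, 200.0, Measure.probe_activity)
        assert normalize_to_adult(m, ref) == pytest.approx(50.0)  # 200/400

    def test_isoform_mismatch_is_configuration_error(self, refset):
        ref = refset.adult_reference(Isoform.CYP2D6, Measure.protein_abundance)
        with pytest.raises(ConfigurationError):
            normalize_to_adult(_measure(Isoform.CYP3A4, 10.0), ref)

    def test_plausibility_flag(self, refset):
        ref = refset.adult_reference(Isoform.CYP3A4, Measure.protein_abundance)
        m = _measure(Isoform.CYP3A4, 300.0)  # above printed adult max 246.2
        assert is_implausible(m, ref, normalize_to_adult(m, ref))
        m2 = _measure(Isoform.CYP3A4, 85.8)
        assert not is_implausible(m2, ref, 100.0)


class TestGrading:
    @pytest.mark.parametrize(
        "pct,expected",
        [(60.0, GradeTier.normal), (50.0, GradeTier.mild), (59.9, GradeTier.mild),
         (47.9, GradeTier.moderate), (42.0, GradeTier.moderate),
         (41.9, GradeTier.severe), (0.0, GradeTier.severe)],
    )
    def test_cyp3a4_protein_six_to_twelve_months(self, refset, pct, expected):
        grade = grade_isoform(pct, Isoform.CYP3A4, Measure.protein_abundance,
                              200, GenotypeClass.expressor, refset)
        assert grade.tier is expected

    def test_neonatal_age_not_gradable(self, refset):
        for pct in (0.0, 50.0, 120.0):
            grade = grade_isoform(pct, Isoform.CYP3A4, Measure.protein_abundance,
                                  5, GenotypeClass.expressor, refset)
            assert grade.tier is GradeTier.not_gradable

    def test_cyp3a5_non_expressor_zeroed_regardless_of_value(self, refset):
        for value in range(0, 1001, 50):
            pct = 100.0 * value / 4.0
            grade = grade_isoform(pct, Isoform.CYP3A5, Measure.protein_abundance,
                                  90, GenotypeClass.non_expressor, refset)
            assert grade.tier is GradeTier.genotype_zeroed

    def test_cyp3a5_unknown_genotype_graded_as_expressor(self, refset):
        grade = grade_isoform(30.0, Isoform.CYP3A5, Measure.protein_abundance,
                              90, GenotypeClass.unknown, refset)
        assert grade.tier is GradeTier.severe  # below the 49% moderate edge

    def test_printed_minimum_grades_normal_everywhere(self, refset):
        for (isoform, measure), rows in ORACLE_TABLES.items():
            for age, edges in rows:
                if edges is None:
                    continue
                grade = grade_isoform(float(edges[0]), isoform, measure, age,
                                      GenotypeClass.expressor, refset)
                assert grade.tier is GradeTier.normal, (isoform, measure, age)

    def test_exhaustive_sweep_matches_oracle(self, refset):
        """0.1%-step sweep over every gradable bin of all eight tables."""
        for (isoform, measure), rows in ORACLE_TABLES.items():
            for age, edges in rows:
                for k in range(0, 1201):
                    pct = k / 10.0
                    grade = grade_isoform(pct, isoform, measure, age,
                                          GenotypeClass.expressor, refset)
                    if edges is None:
                        assert grade.tier is GradeTier.not_gradable
                    else:
                        assert grade.tier.score == oracle_tier(pct, edges), (
                            isoform, measure, age, pct)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        pct_a=st.floats(min_value=0, max_value=150, allow_nan=False),
        pct_b=st.floats(min_value=0, max_value=150, allow_nan=False),
    )
    def test_monotone_severity(self, refset, pct_a, pct_b):
        """Lower %Adult never lowers the tier number."""
        lo, hi = sorted((pct_a, pct_b))
        t_lo = grade_isoform(lo, Isoform.CYP2D6, Measure.protein_abundance,
                             250, GenotypeClass.expressor, refset).tier.score
        t_hi = grade_isoform(hi, Isoform.CYP2D6, Measure.protein_abundance,
                             250, GenotypeClass.expressor, refset).tier.score
        assert t_lo >= t_hi


class TestDomain1:
    def test_max_aggregation_across_isoforms(self, refset):
        measurements = [
            _measure(Isoform.CYP3A4, 0.1 * 85.8),   # 10% -> severe at 200 d
            _measure(Isoform.CYP2D6, 0.9 * 7.90),   # 90% -> normal
        ]
        score = score_domain1(measurements, GenotypeClass.expressor, 200, OPTIMAL, refset)
        assert score.score == 3

    def test_all_normal_scores_zero(self, refset):
        measurements = [
            _measure(Isoform.CYP3A4, 85.8), _measure(Isoform.CYP2D6, 7.90),
            _measure(Isoform.CYP2C19, 5.02), _measure(Isoform.CYP3A5, 4.00),
        ]
        score = score_domain1(measurements, GenotypeClass.expressor, 400, OPTIMAL, refset)
        # CYP3A5 protein has no printed tiers past 12 months; others normal
        assert score.score == 0

    def test_liver_ns_propagates(self, refset):
        score = score_domain1([_measure(Isoform.CYP3A4, 40.0)],
                              GenotypeClass.expressor, 200, NS_LIVER, refset)
        assert score.score is None and "PMI" in score.ns_reason

    def test_empty_measurement_list_is_ns(self, refset):
        score = score_domain1([], GenotypeClass.expressor, 200, OPTIMAL, refset)
        assert score.score is None and "no CYP measurements" in score.ns_reason

    def test_all_isoforms_non_gradable_is_ns(self, refset):
        measurements = [
            _measure(Isoform.CYP3A4, 1.0), _measure(Isoform.CYP2D6, 0.5),
            _measure(Isoform.CYP2C19, 0.2),
        ]
        score = score_domain1(measurements, GenotypeClass.expressor, 3, OPTIMAL, refset)
        assert score.score is None
        assert "no gradable isoform at this age" in score.ns_reason

    def test_genotype_zeroed_only_isoform_scores_zero(self, refset):
        score = score_domain1([_measure(Isoform.CYP3A5, 0.1)],
                              GenotypeClass.non_expressor, 90, OPTIMAL, refset)
        assert score.score == 0

    def test_activity_fallback_requires_qc(self, refset):
        unqualified = CypMeasurement(isoform=Isoform.CYP3A4,
                                     measure=Measure.probe_activity, value=100.0)
        score = score_domain1([unqualified], GenotypeClass.expressor, 200, OPTIMAL, refset)
        assert score.score is None
        qualified = CypMeasurement(isoform=Isoform.CYP3A4, measure=Measure.probe_activity,
                                   value=100.0, qc_qualified=True)
        score = score_domain1([qualified], GenotypeClass.expressor, 200, OPTIMAL, refset)
        # 100/400 = 25% adult, below the 35% moderate edge at 6-12 months
        assert score.score == 3
        assert any("QC-qualified probe activity" in f for f in score.flags)

    def test_protein_preferred_activity_corroborative(self, refset):
        protein = _measure(Isoform.CYP3A4, 0.55 * 85.8)          # 55% -> mild at 200 d
        activity = CypMeasurement(isoform=Isoform.CYP3A4, measure=Measure.probe_activity,
                                  value=40.0, qc_qualified=True)  # 10% -> severe if used
        score = score_domain1([protein, activity], GenotypeClass.expressor,
                              200, OPTIMAL, refset)
        assert score.score == 1
        assert any("corroboration" in f for f in score.flags)
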