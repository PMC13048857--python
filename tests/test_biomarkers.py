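"""Domains 2-5: ordinal binning with lower-inclusive edges, cytokine
max-aggregation, redox tissue handling, and adjudicated pass-through."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mviscore import bin_analyte, score_domain2, score_domain3, score_modifier
from mviscore.biomarkers import (
    AdjudicatedDomain,
    AdjudicatedOrdinal,
    BiomarkerPanel,
    RedoxTissue,
)
from mviscore.core import Analyte, DomainRole, ValidityState, ValidityStatus

OPTIMAL = ValidityStatus(state=ValidityState.optimal)
NS_BLOOD = ValidityStatus(state=ValidityState.NS, reason="PMI exceeds maximum")

# Independent truth table transcribed from the printed bin rows:
# analyte -> (edges, [(value, expected bin), ...]) covering each printed
# edge exactly and just above it.
EDGE_ORACLE = {
    Analyte.IL6: (30, 80, 300),
    Analyte.CRP: (10, 40, 150),
    Analyte.F2_ISOPROSTANE_FOLD: (1, 2, 4),
    Analyte.VITREOUS_BHB: (2.5, 5, 10),
    Analyte.VITREOUS_GLUCOSE: (10, 15, 25),
}


def oracle_bin(value, edges):
    e0, e1, e2 = edges
    if value <= e0:
        return 0
    if value <= e1:
        return 1
    if value <= e2:
        return 2
    return 3


@pytest.mark.parametrize(
    "analyte,value,expected",
    [
        (Analyte.IL6, 30.0, 0), (Analyte.IL6, 350.0, 3),
        (Analyte.CRP, 0.0, 0), (Analyte.CRP, 160.0, 3),
        (Analyte.F2_ISOPROSTANE_FOLD, 3.0, 2),
        (Analyte.VITREOUS_BHB, 2.5, 0), (Analyte.VITREOUS_GLUCOSE, 14.0, 1),
    ],
)
def test_bin_printed_examples(refset, analyte, value, expected):
    assert bin_analyte(value, refset.bin_spec(analyte)) == expected


def test_edges_are_lower_inclusive(refset):
    """A value exactly on a shared printed edge falls in the LOWER bin."""
    eps = 1e-9
    for analyte, edges in EDGE_ORACLE.items():
        spec = refset.bin_spec(analyte)
        for i, edge in enumerate(edges):
            assert bin_analyte(edge, spec) == i
            assert bin_analyte(edge + eps, spec) == i + 1


def test_bin_matches_oracle_on_dense_sweep(refset):
    for analyte, edges in EDGE_ORACLE.items():
        spec = refset.bin_spec(analyte)
        top = edges[2] * 1.5
        for k in range(0, 2001):
            value = top * k / 2000.0
            assert bin_analyte(value, spec) == oracle_bin(value, edges), (analyte, value)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(
    a=st.floats(min_value=0, max_value=500, allow_nan=False),
    b=st.floats(min_value=0, max_value=500, allow_nan=False),
)
def test_bin_monotone(refset, a, b):
    spec = refset.bin_spec(Analyte.IL6)
    lo, hi = sorted((a, b))
    assert bin_analyte(lo, spec) <= bin_analyte(hi, spec)


class TestDomain2:
    def test_max_of_markers(self, refset):
        panel = BiomarkerPanel(il6_pg_ml=120.0, crp_mg_l=20.0)  # bins 2, 1
        assert score_domain2(panel, OPTIMAL, refset).score == 2

    def test_invariant_under_marker_swap(self, refset):
        # same bins attained by the other marker
        p1 = BiomarkerPanel(il6_pg_ml=120.0, crp_mg_l=20.0)   # IL-6 carries the max
        p2 = BiomarkerPanel(il6_pg_ml=50.0, crp_mg_l=100.0)   # CRP carries the max
        assert score_domain2(p1, OPTIMAL, refset).score == score_domain2(p2, OPTIMAL, refset).score

    def test_single_marker_sufficient(self, refset):
        panel = BiomarkerPanel(crp_mg_l=160.0)
        assert score_domain2(panel, OPTIMAL, refset).score == 3

    def test_no_markers_is_ns(self, refset):
        score = score_domain2(BiomarkerPanel(), OPTIMAL, refset)
        assert score.score is None and "no cytokine markers" in score.ns_reason

    def test_blood_ns_propagates(self, refset):
        panel = BiomarkerPanel(il6_pg_ml=500.0)
        assert score_domain2(panel, NS_BLOOD, refset).score is None


class TestDomain3:
    @pytest.mark.parametrize("fold,expected", [(1.0, 0), (1.5, 1), (3.0, 2), (4.5, 3)])
    def test_liver_fold_bins(self, refset, fold, expected):
        panel = BiomarkerPanel(redox_fold=fold)
        score = score_domain3(panel, OPTIMAL, refset)
        assert score.score == expected and not any("corroborative" in f for f in score.flags)

    def test_kidney_only_scored_but_flagged(self, refset):
        panel = BiomarkerPanel(redox_fold=2.5, redox_tissue=RedoxTissue.kidney)
        score = score_domain3(panel, OPTIMAL, refset)
        assert score.score == 2
        assert any("corroborative tissue only" in f for f in score.flags)

    def test_raw_value_divided_by_lab_reference(self):
        from mviscore import load_reference_set

        refs = load_reference_set({"redox_reference": 100.0})
        panel = BiomarkerPanel(redox_raw_ng_g=300.0)  # 3x -> bin 2
        assert score_domain3(panel, OPTIMAL, refs).score == 2

    def test_missing_result_is_ns(self, refset):
        score = score_domain3(BiomarkerPanel(), OPTIMAL, refset)
        assert score.score is None


class TestModifiers:
    def test_neurochemical_pass_through(self):
        adj = AdjudicatedOrdinal(domain=AdjudicatedDomain.neurochemical, score=1,
                                 basis="brainstem IHC")
        score = score_modifier(adj)
        assert (score.domain, score.score, score.role) == (4, 1, DomainRole.modifier)

    def test_xenobiotic_pass_through(self):
        adj = AdjudicatedOrdinal(domain=AdjudicatedDomain.xenobiotic_metal, score=2,
                                 basis="toxicology + ICP-MS")
        score = score_modifier(adj)
        assert (score.domain, score.score) == (5, 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(Exception):
            AdjudicatedOrdinal(domain=AdjudicatedDomain.neurochemical, score=5, basis="x")

    def test_ns_propagates_with_reason(self):
        adj = AdjudicatedOrdinal(domain=AdjudicatedDomain.neurochemical, score=None,
                                 ns_reason="autolysis precludes IHC")
        score = score_modifier(adj)
        assert score.score is None and score.ns_reason == "autolysis precludes IHC"
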