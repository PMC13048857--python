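"""End-to-end case scoring: gate specimens, score the five domains,
summarize CMSP and the vitreous pattern, assign the archetype, and
assemble the final MVI report.

The MVI total is the sum of the scorable domain ordinals, reported over a
scorable maximum of 3 x (number of scorable domains): an NS domain
shrinks the denominator rather than being imputed as 0, so severity is
never deflated by missing data.  The report is deterministic — identical
inputs produce a byte-identical serialized report — and carries the
reference-set version tag for reproducibility across laboratory
overrides.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .archetypes import ArchetypeAssignment, DomainPattern, assign_archetype
from .biomarkers import (
    REDOX_SPECIMEN,
    AdjudicatedDomain,
    bin_analyte,
    missing_modifier,
    score_domain2,
    score_domain3,
    score_modifier,
)
from .cmsp import CmspResult, VitreousPattern, cmsp_core, vitreous_pattern
from .core import Analyte, AnalyteGroup, DomainScore, Specimen, ValidityStatus
from .cyp import score_domain1
from .gating import gate_specimen, not_collected_status
from .records import CaseRecord
from .references import ReferenceSet


class MVIReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    domain_scores: tuple[DomainScore, ...]
    mvi_total: int
    scorable_max: int
    archetype: ArchetypeAssignment
    cmsp: CmspResult
    vitreous: VitreousPattern
    flags: tuple[str, ...]
    reference_set_version: str

    @model_validator(mode="after")
    def _bounds(self) -> "MVIReport":
        scorable = [s.score for s in self.domain_scores if s.score is not None]
        if self.mvi_total != sum(scorable):
            raise ValueError("mvi_total must equal the sum of scorable domain scores")
        if self.scorable_max != 3 * len(scorable):
            raise ValueError("scorable_max must be 3 x number of scorable domains")
        if not (0 <= self.mvi_total <= self.scorable_max <= 15):
            raise ValueError("0 <= mvi_total <= scorable_max <= 15 violated")
        return self

    def to_markdown(self) -> str:
        lines = [
            f"# MVI report - case {self.case_id}",
            "",
            "| Domain | Score | Role | Basis |",
            "|---|---|---|---|",
        ]
        from .core import DOMAIN_NAMES

        for s in self.domain_scores:
            lines.append(
                f"| {s.domain} {DOMAIN_NAMES[s.domain]} | {s.display()} "
                f"| {s.role.value} | {s.basis or s.ns_reason} |"
            )
        lines += [
            "",
            f"**MVI total:** {self.mvi_total}/{self.scorable_max}",
        ]
        if self.archetype.ref_no is None:
            lines.append(f"**Archetype:** none ({self.archetype.mechanistic_class})")
        else:
            mods = ", ".join(
                f"D{m.domain} ({m.role.value})" for m in self.archetype.modifier_domains
            )
            lines.append(
                f"**Archetype:** #{self.archetype.ref_no} {self.archetype.mechanistic_class}"
                + (f"; modifiers: {mods}" if mods else "")
            )
        if self.cmsp.core_sum is None:
            lines.append(f"**CMSP Core:** NS ({self.cmsp.ns_reason})")
        else:
            lines.append(
                f"**CMSP Core:** {self.cmsp.core_sum}/9 ({self.cmsp.core_label.value})"
            )
        lines.append(f"**Vitreous pattern:** {self.vitreous.label.value}")
        if self.flags:
            lines.append("")
            lines.append("Flags:")
            lines += [f"- {f}" for f in self.flags]
        lines.append("")
        lines.append(f"_Reference set: {self.reference_set_version}_")
        return "\n".join(lines)


def _gate(case: CaseRecord, specimen: Specimen, group: AnalyteGroup,
          ref: ReferenceSet) -> ValidityStatus:
    obs = case.find_observation(specimen, group)
    if obs is None:
        return not_collected_status(specimen)
    return gate_specimen(obs, ref.validity_window(specimen, group))


def mvi_totals(scores: tuple[DomainScore, ...] | list[DomainScore]) -> tuple[int, int]:
    """(total over scorable domains, 3 x number of scorable domains)."""
    scorable = [s.score for s in scores if s.score is not None]
    return sum(scorable), 3 * len(scorable)


def compute_mvi(case: CaseRecord, ref: ReferenceSet) -> MVIReport:
    """Score a validated case record through the full pipeline."""
    liver_validity = _gate(case, Specimen.liver, AnalyteGroup.cyp_proteomics, ref)
    blood_validity = _gate(case, Specimen.femoral_blood, AnalyteGroup.cytokines, ref)
    redox_specimen = REDOX_SPECIMEN[case.biomarkers.redox_tissue]
    redox_validity = _gate(case, redox_specimen, AnalyteGroup.f2_isoprostanes, ref)
    vitreous_validity = _gate(case, Specimen.vitreous, AnalyteGroup.glucose_bhb, ref)

    d1 = score_domain1(
        list(case.cyp_measurements), case.cyp3a5_genotype, case.age_days,
        liver_validity, ref,
    )
    d2 = score_domain2(case.biomarkers, blood_validity, ref)
    d3 = score_domain3(case.biomarkers, redox_validity, ref)
    by_domain = {a.domain: a for a in case.adjudicated}
    d4 = (
        score_modifier(by_domain[AdjudicatedDomain.neurochemical])
        if AdjudicatedDomain.neurochemical in by_domain
        else missing_modifier(4)
    )
    d5 = (
        score_modifier(by_domain[AdjudicatedDomain.xenobiotic_metal])
        if AdjudicatedDomain.xenobiotic_metal in by_domain
        else missing_modifier(5)
    )
    scores = (d1, d2, d3, d4, d5)

    # CMSP anchors: individual marker bins, NS-gated like their domains.
    panel = case.biomarkers
    il6_bin = (
        bin_analyte(panel.il6_pg_ml, ref.bin_spec(Analyte.IL6))
        if panel.il6_pg_ml is not None and blood_validity.scorable
        else None
    )
    crp_bin = (
        bin_analyte(panel.crp_mg_l, ref.bin_spec(Analyte.CRP))
        if panel.crp_mg_l is not None and blood_validity.scorable
        else None
    )
    fold = panel.resolved_redox_fold(ref)
    redox_bin = (
        bin_analyte(fold, ref.bin_spec(Analyte.F2_ISOPROSTANE_FOLD))
        if fold is not None and redox_validity.scorable
        else None
    )
    cmsp = cmsp_core(il6_bin, crp_bin, redox_bin)

    glucose_bin = (
        bin_analyte(panel.vitreous_glucose_mmol_l, ref.bin_spec(Analyte.VITREOUS_GLUCOSE))
        if panel.vitreous_glucose_mmol_l is not None and vitreous_validity.scorable
        else None
    )
    bhb_bin = (
        bin_analyte(panel.vitreous_bhb_mmol_l, ref.bin_spec(Analyte.VITREOUS_BHB))
        if panel.vitreous_bhb_mmol_l is not None and vitreous_validity.scorable
        else None
    )
    vitreous = vitreous_pattern(glucose_bin, bhb_bin)

    archetype = assign_archetype(DomainPattern.from_domain_scores(scores))
    total, scorable_max = mvi_totals(scores)

    flags: list[str] = []
    for s in scores:
        flags.extend(s.flags)
        if s.score is None:
            flags.append(f"domain {s.domain} NS: {s.ns_reason}")
    flags.extend(archetype.flags)
    if not vitreous_validity.scorable:
        flags.append(f"vitreous: {vitreous_validity.reason}")

    return MVIReport(
        case_id=case.case_id,
        domain_scores=scores,
        mvi_total=total,
        scorable_max=scorable_max,
        archetype=archetype,
        cmsp=cmsp,
        vitreous=vitreous,
        flags=tuple(flags),
        reference_set_version=ref.version_tag,
    )
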