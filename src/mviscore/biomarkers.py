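"""Domains 2-5: cytokine and redox ordinal binning, and validated
pass-through of adjudicated neurochemical / xenobiotic ordinals.

Domain 2 (cytokine load) bins femoral IL-6 (pg/mL) and CRP (mg/L, not
hs-CRP) and takes the worse of the two.  Domain 3 (redox balance) bins the
tissue F2-isoprostane (8-iso-PGF2alpha) fold over the laboratory reference
— liver is the default tissue, kidney cortex is corroborative only.
Domains 4 and 5 have no printed bin tables; they accept ordinals
adjudicated from their operational anchors (brainstem neuropathology +/-
SERT/TPH2 IHC; comprehensive toxicology +/- ICP-MS metals).

Shared bin edges are lower-inclusive: a value exactly on a printed edge
falls in the lower bin ((e0, e1]-style intervals).
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    Analyte,
    DomainRole,
    DomainScore,
    InputError,
    Specimen,
    ValidityState,
    ValidityStatus,
)
from .references import OrdinalBinSpec, ReferenceSet


class RedoxTissue(str, Enum):
    liver = "liver"
    kidney = "kidney"


class BiomarkerPanel(BaseModel):
    model_config = ConfigDict(frozen=True)

    il6_pg_ml: float | None = Field(default=None, ge=0)
    crp_mg_l: float | None = Field(default=None, ge=0)
    redox_fold: float | None = Field(default=None, ge=0)
    redox_raw_ng_g: float | None = Field(default=None, ge=0)
    redox_tissue: RedoxTissue = RedoxTissue.liver
    vitreous_glucose_mmol_l: float | None = Field(default=None, ge=0)
    vitreous_bhb_mmol_l: float | None = Field(default=None, ge=0)

    def resolved_redox_fold(self, ref: ReferenceSet) -> float | None:
        """Fold over reference; a raw ng/g value is divided by the
        laboratory redox reference when no fold is given directly."""
        if self.redox_fold is not None:
            return self.redox_fold
        if self.redox_raw_ng_g is not None and ref.redox_reference_ng_g:
            return self.redox_raw_ng_g / ref.redox_reference_ng_g
        return None


class AdjudicatedDomain(str, Enum):
    neurochemical = "neurochemical"
    xenobiotic_metal = "xenobiotic_metal"


_ADJ_DOMAIN_NO = {AdjudicatedDomain.neurochemical: 4, AdjudicatedDomain.xenobiotic_metal: 5}


class AdjudicatedOrdinal(BaseModel):
    model_config = ConfigDict(frozen=True)

    domain: AdjudicatedDomain
    score: int | None = None  # None = NS
    basis: str = ""
    ns_reason: str = ""

    @model_validator(mode="after")
    def _check(self) -> "AdjudicatedOrdinal":
        if self.score is not None:
            if not (0 <= self.score <= 3):
                raise ValueError(f"adjudicated score {self.score} outside 0-3")
            if not self.basis:
                raise ValueError("scored adjudicated ordinal requires a basis")
        elif not self.ns_reason:
            raise ValueError("NS adjudicated ordinal requires ns_reason")
        return self


def bin_analyte(value: float, spec: OrdinalBinSpec) -> int:
    """Ordinal bin 0..3 for a non-negative value; lower-inclusive edges."""
    if value < 0:
        raise InputError(f"{spec.analyte.value}: negative value {value}")
    e0, e1, e2 = spec.edges
    if value <= e0:
        return 0
    if value <= e1:
        return 1
    if value <= e2:
        return 2
    return 3


def score_domain2(
    panel: BiomarkerPanel, blood_validity: ValidityStatus, ref: ReferenceSet
) -> DomainScore:
    """Cytokine load: worse of the IL-6 and CRP ordinal bins."""
    if not blood_validity.scorable:
        return DomainScore(
            domain=2, score=None, role=DomainRole.core,
            ns_reason=blood_validity.reason or "femoral blood not scorable",
        )
    flags: list[str] = []
    if blood_validity.state is ValidityState.acceptable_flagged:
        flags.append(f"femoral blood: {blood_validity.reason}")
    parts: list[str] = []
    bins: list[int] = []
    if panel.il6_pg_ml is not None:
        b = bin_analyte(panel.il6_pg_ml, ref.bin_spec(Analyte.IL6))
        bins.append(b)
        parts.append(f"IL-6 {panel.il6_pg_ml:g} pg/mL -> {b}")
    if panel.crp_mg_l is not None:
        b = bin_analyte(panel.crp_mg_l, ref.bin_spec(Analyte.CRP))
        bins.append(b)
        parts.append(f"CRP {panel.crp_mg_l:g} mg/L -> {b}")
    if not bins:
        return DomainScore(
            domain=2, score=None, role=DomainRole.core,
            ns_reason="no cytokine markers", flags=tuple(flags),
        )
    return DomainScore(
        domain=2, score=max(bins), role=DomainRole.core,
        basis="; ".join(parts), flags=tuple(flags),
    )


def score_domain3(
    panel: BiomarkerPanel, tissue_validity: ValidityStatus, ref: ReferenceSet
) -> DomainScore:
    """Redox balance: tissue F2-isoprostane fold over reference."""
    if not tissue_validity.scorable:
        return DomainScore(
            domain=3, score=None, role=DomainRole.core,
            ns_reason=tissue_validity.reason or "redox tissue not scorable",
        )
    flags: list[str] = []
    if tissue_validity.state is ValidityState.acceptable_flagged:
        flags.append(f"{panel.redox_tissue.value}: {tissue_validity.reason}")
    fold = panel.resolved_redox_fold(ref)
    if fold is None:
        return DomainScore(
            domain=3, score=None, role=DomainRole.core,
            ns_reason="no F2-isoprostane result", flags=tuple(flags),
        )
    if panel.redox_tissue is RedoxTissue.kidney:
        flags.append("corroborative tissue only (kidney cortex; liver default absent)")
    b = bin_analyte(fold, ref.bin_spec(Analyte.F2_ISOPROSTANE_FOLD))
    return DomainScore(
        domain=3, score=b, role=DomainRole.core,
        basis=f"8-iso-PGF2a {fold:g}x reference ({panel.redox_tissue.value}) -> {b}",
        flags=tuple(flags),
    )


def score_modifier(adj: AdjudicatedOrdinal) -> DomainScore:
    """Validated pass-through for Domains 4 and 5."""
    domain = _ADJ_DOMAIN_NO[adj.domain]
    if adj.score is None:
        return DomainScore(
            domain=domain, score=None, role=DomainRole.modifier,
            ns_reason=adj.ns_reason,
        )
    return DomainScore(
        domain=domain, score=adj.score, role=DomainRole.modifier, basis=adj.basis
    )


def missing_modifier(domain: int) -> DomainScore:
    name = "neurochemical" if domain == 4 else "xenobiotic/metal"
    return DomainScore(
        domain=domain, score=None, role=DomainRole.modifier,
        ns_reason=f"no adjudicated {name} ordinal",
    )


REDOX_SPECIMEN = {RedoxTissue.liver: Specimen.liver, RedoxTissue.kidney: Specimen.kidney}
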