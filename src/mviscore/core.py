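"""Shared enumerations, value objects, and exceptions.

Everything downstream (reference tables, specimen gating, domain scoring,
archetype assignment, report assembly) builds on the vocabulary defined
here: the four hepatic CYP isoforms, the specimen/analyte taxonomy, the
three-state specimen validity result, and the per-domain ordinal score.
Scores are ordinal 0-3; a domain that cannot be scored is NS ("not
scorable") and always carries a reason.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, model_validator


class MviError(Exception):
    """Base class for all package errors."""


class InputError(MviError):
    """A caller-supplied value violates a documented precondition."""


class ConfigurationError(MviError):
    """A reference table or laboratory override violates an invariant."""


class GenerationError(MviError):
    """A synthetic-case target cannot be realized (e.g. non-gradable age)."""


class Isoform(str, Enum):
    CYP3A4 = "CYP3A4"
    CYP2D6 = "CYP2D6"
    CYP2C19 = "CYP2C19"
    CYP3A5 = "CYP3A5"


class Measure(str, Enum):
    protein_abundance = "protein_abundance"  # pmol/mg microsomal protein
    probe_activity = "probe_activity"        # pmol/min/mg


class Specimen(str, Enum):
    liver = "liver"
    femoral_blood = "femoral_blood"
    vitreous = "vitreous"
    kidney = "kidney"


class AnalyteGroup(str, Enum):
    cyp_proteomics = "cyp_proteomics"
    cytokines = "cytokines"
    f2_isoprostanes = "f2_isoprostanes"
    glucose_bhb = "glucose_bhb"


class Analyte(str, Enum):
    IL6 = "IL6"
    CRP = "CRP"
    F2_ISOPROSTANE_FOLD = "F2_ISOPROSTANE_FOLD"
    VITREOUS_BHB = "VITREOUS_BHB"
    VITREOUS_GLUCOSE = "VITREOUS_GLUCOSE"


class GenotypeClass(str, Enum):
    """CYP3A5 expressor status (*1 carrier vs *3/*3 non-expressor)."""

    expressor = "expressor"
    non_expressor = "non_expressor"
    unknown = "unknown"


class ValidityState(str, Enum):
    """Three-state specimen validity.

    ``optimal``            PMI inside the "best within" handling target.
    ``acceptable_flagged`` PMI between the target and the sampling maximum;
                           scorable, but the result is flagged.
    ``NS``                 not scorable (maximum exceeded, or specimen
                           never collected).
    """

    optimal = "optimal"
    acceptable_flagged = "acceptable_flagged"
    NS = "NS"


# Ordering used by the monotonicity property: higher is worse.
_VALIDITY_ORDER = {
    ValidityState.optimal: 0,
    ValidityState.acceptable_flagged: 1,
    ValidityState.NS: 2,
}


class ValidityStatus(BaseModel):
    model_config = ConfigDict(frozen=True)

    state: ValidityState
    reason: str = ""

    @model_validator(mode="after")
    def _ns_has_reason(self) -> "ValidityStatus":
        if self.state is ValidityState.NS and not self.reason:
            raise ValueError("NS validity status requires a non-empty reason")
        return self

    @property
    def scorable(self) -> bool:
        return self.state is not ValidityState.NS

    def severity_rank(self) -> int:
        return _VALIDITY_ORDER[self.state]


class DomainRole(str, Enum):
    core = "core"        # Domains 1-3
    modifier = "modifier"  # Domains 4-5


DOMAIN_NAMES = {
    1: "CYP450 capacity",
    2: "Cytokine load",
    3: "Redox balance",
    4: "Neurochemical integrity",
    5: "Xenobiotic/metal burden",
}


def role_for_domain(domain: int) -> DomainRole:
    return DomainRole.core if domain <= 3 else DomainRole.modifier


class DomainScore(BaseModel):
    """One domain's ordinal result: 0-3, or NS with a reason."""

    model_config = ConfigDict(frozen=True)

    domain: int = Field(ge=1, le=5)
    score: int | None = Field(default=None, ge=0, le=3)
    role: DomainRole
    basis: str = ""
    ns_reason: str = ""
    flags: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "DomainScore":
        if self.role is not role_for_domain(self.domain):
            raise ValueError(
                f"domain {self.domain} must have role {role_for_domain(self.domain).value}"
            )
        if self.score is None and not self.ns_reason:
            raise ValueError("NS domain score requires ns_reason")
        return self

    @property
    def scorable(self) -> bool:
        return self.score is not None

    def display(self) -> str:
        return str(self.score) if self.scorable else f"NS ({self.ns_reason})"
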