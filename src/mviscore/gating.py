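"""Postmortem-interval specimen validity gating.

Each biomarker domain is anchored to a specimen with a published handling
target ("best within" PMI) and a sampling maximum.  A measurement whose
specimen PMI is under the target is optimal; between the target and the
maximum (inclusive) it is scorable but flagged; beyond the maximum — or if
the specimen was never collected — it is NS and gates the domain off.
Boundary convention mirrors the printed inequalities: the target is
exclusive (<24 h), the maximum inclusive (<=48 h / <=72 h).
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import AnalyteGroup, InputError, Specimen, ValidityState, ValidityStatus
from .references import ValidityWindow


class SpecimenObservation(BaseModel):
    """A collected (or explicitly uncollected) specimen and its PMI.

    ``analyte_group`` may be None, meaning the observation applies to every
    analyte group of that specimen (e.g. a single liver PMI covering both
    CYP proteomics and tissue isoprostanes).
    """

    model_config = ConfigDict(frozen=True)

    specimen: Specimen
    analyte_group: AnalyteGroup | None = None
    pmi_h: float | None = Field(default=None, ge=0)
    collected: bool = True

    @model_validator(mode="after")
    def _pmi_when_collected(self) -> "SpecimenObservation":
        if self.collected and self.pmi_h is None:
            raise ValueError(f"{self.specimen.value}: pmi_h required when collected")
        return self


def gate_specimen(obs: SpecimenObservation, window: ValidityWindow) -> ValidityStatus:
    """Gate one specimen observation against its validity window."""
    if obs.specimen is not window.specimen:
        raise InputError(
            f"observation specimen {obs.specimen.value} does not match "
            f"window specimen {window.specimen.value}"
        )
    if obs.analyte_group is not None and obs.analyte_group is not window.analyte_group:
        raise InputError(
            f"observation analyte group {obs.analyte_group.value} does not match "
            f"window group {window.analyte_group.value}"
        )
    if not obs.collected:
        return ValidityStatus(state=ValidityState.NS, reason="specimen not collected")
    pmi = obs.pmi_h
    assert pmi is not None
    if pmi < 0:
        raise InputError(f"negative PMI {pmi}")
    if pmi < window.best_within_h:
        return ValidityStatus(state=ValidityState.optimal)
    if pmi <= window.max_pmi_h:
        return ValidityStatus(
            state=ValidityState.acceptable_flagged,
            reason=(
                f"PMI {pmi:g} h past handling target "
                f"{window.best_within_h:g} h (max {window.max_pmi_h:g} h)"
            ),
        )
    return ValidityStatus(
        state=ValidityState.NS,
        reason=(
            f"PMI exceeds maximum: {pmi:g} h > {window.max_pmi_h:g} h "
            f"({obs.specimen.value})"
        ),
    )


def not_collected_status(specimen: Specimen) -> ValidityStatus:
    return ValidityStatus(
        state=ValidityState.NS, reason=f"specimen not collected ({specimen.value})"
    )
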