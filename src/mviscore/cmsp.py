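"""CMSP Core summary and the vitreous glucose/BHB contextual pattern.

Both are reporting artifacts layered over the anchor ordinals.  The CMSP
Core is the unweighted sum of the IL-6, CRP, and F2-isoprostane bins
(0-9), labelled minimal (0-1) / mild (2-4) / moderate (5-7) / severe
(8-9); any NS anchor makes the core NS.  The vitreous pattern is a fixed
quadrant label over the glucose and beta-hydroxybutyrate bins.  Neither
ever modifies a domain score, the MVI total, or the archetype.
"""

from __future__ import annotations

from enum import Enum

from pydantic import BaseModel, ConfigDict, model_validator


class CmspLabel(str, Enum):
    minimal = "minimal"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"


_LABEL_EDGES = ((1, CmspLabel.minimal), (4, CmspLabel.mild), (7, CmspLabel.moderate),
                (9, CmspLabel.severe))


class CmspResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    il6_bin: int | None
    crp_bin: int | None
    redox_bin: int | None
    core_sum: int | None
    core_label: CmspLabel | None
    ns_reason: str = ""

    @model_validator(mode="after")
    def _consistent(self) -> "CmspResult":
        bins = (self.il6_bin, self.crp_bin, self.redox_bin)
        if any(b is None for b in bins):
            if self.core_sum is not None or self.core_label is not None:
                raise ValueError("NS anchor requires NS core")
            if not self.ns_reason:
                raise ValueError("NS core requires ns_reason")
        else:
            if self.core_sum != sum(bins):  # type: ignore[arg-type]
                raise ValueError("core_sum must equal the sum of the anchor bins")
        return self


def _check_bin(name: str, value: int | None) -> None:
    if value is not None and not (0 <= value <= 3):
        raise ValueError(f"{name} bin {value} outside 0-3")


def cmsp_core(
    il6_bin: int | None, crp_bin: int | None, redox_bin: int | None
) -> CmspResult:
    """CMSP Core from the three anchor bins; NS-propagating."""
    for name, b in (("IL-6", il6_bin), ("CRP", crp_bin), ("redox", redox_bin)):
        _check_bin(name, b)
    missing = [
        name
        for name, b in (("IL-6", il6_bin), ("CRP", crp_bin), ("redox", redox_bin))
        if b is None
    ]
    if missing:
        return CmspResult(
            il6_bin=il6_bin, crp_bin=crp_bin, redox_bin=redox_bin,
            core_sum=None, core_label=None,
            ns_reason=f"anchor not scorable: {', '.join(missing)}",
        )
    total = il6_bin + crp_bin + redox_bin  # type: ignore[operator]
    label = next(lab for edge, lab in _LABEL_EDGES if total <= edge)
    return CmspResult(
        il6_bin=il6_bin, crp_bin=crp_bin, redox_bin=redox_bin,
        core_sum=total, core_label=label,
    )


class VitreousLabel(str, Enum):
    minimal_deviation = "minimal_deviation"
    stress_hyperglycemia = "stress_hyperglycemia"
    ketosis = "ketosis"
    mixed_dysregulation = "mixed_dysregulation"
    indeterminate_NS = "indeterminate_NS"


class VitreousPattern(BaseModel):
    model_config = ConfigDict(frozen=True)

    glucose_bin: int | None
    bhb_bin: int | None
    label: VitreousLabel
    ns_reason: str = ""


def vitreous_pattern(glucose_bin: int | None, bhb_bin: int | None) -> VitreousPattern:
    """Contextual quadrant label over the glucose and BHB ordinals.

    Either marker NS makes the pattern indeterminate (the NS row keys on
    BHB; NS handling is applied symmetrically to glucose).
    """
    _check_bin("glucose", glucose_bin)
    _check_bin("BHB", bhb_bin)
    if bhb_bin is None or glucose_bin is None:
        missing = [n for n, b in (("glucose", glucose_bin), ("BHB", bhb_bin)) if b is None]
        return VitreousPattern(
            glucose_bin=glucose_bin, bhb_bin=bhb_bin,
            label=VitreousLabel.indeterminate_NS,
            ns_reason=f"not scorable: vitreous {', '.join(missing)}",
        )
    glucose_high = glucose_bin >= 2
    bhb_high = bhb_bin >= 2
    if glucose_high and bhb_high:
        label = VitreousLabel.mixed_dysregulation
    elif glucose_high:
        label = VitreousLabel.stress_hyperglycemia
    elif bhb_high:
        label = VitreousLabel.ketosis
    else:
        label = VitreousLabel.minimal_deviation
    return VitreousPattern(glucose_bin=glucose_bin, bhb_bin=bhb_bin, label=label)
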