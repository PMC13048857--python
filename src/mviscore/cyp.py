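"""Domain 1: hepatic CYP capacity via two-step normalization.

Step 1 expresses a measured isoform value as %Adult — protein abundance is
divided by the adult reference mean, probe activity by the midpoint of the
printed adult range.  Step 2 compares %Adult against the age-matched
developmental expectation and grades suppression on the ordinal tier scale
(normal=0 / mild=1 / moderate=2 / severe=3).  This separates physiologic
immaturity (low absolute values that are normal for age) from pathologic
suppression (values below the age-matched minimum).

Special cases: age bins where an isoform is physiologically near zero are
not gradable; CYP3A5 non-expressors (*3/*3) are never graded and carry a
physiologic score of 0 regardless of the measured value; an unknown or
indeterminate CYP3A5 genotype is graded as an expressor.

The domain score is the worst (maximum) tier across gradable isoforms:
reserve limitation is driven by the most-affected clearance pathway, and
the maximum is the only unweighted aggregation preserving the 0-3 ordinal
codomain.
"""

from __future__ import annotations

import math
from enum import Enum

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    ConfigurationError,
    DomainRole,
    DomainScore,
    GenotypeClass,
    Isoform,
    Measure,
    ValidityStatus,
)
from .references import IsoformAdultReference, ReferenceSet

PLAUSIBILITY_PCT = 150.0  # %Adult above which a value is flagged (QC only)


class CypMeasurement(BaseModel):
    model_config = ConfigDict(frozen=True)

    isoform: Isoform
    measure: Measure
    value: float = Field(ge=0)
    qc_qualified: bool = False  # activity assays only

    @model_validator(mode="after")
    def _finite(self) -> "CypMeasurement":
        if not math.isfinite(self.value):
            raise ValueError("measurement value must be finite")
        return self


class GradeTier(str, Enum):
    normal = "normal"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"
    not_gradable = "not_gradable"
    genotype_zeroed = "genotype_zeroed"

    @property
    def score(self) -> int | None:
        return _TIER_SCORE.get(self)


_TIER_SCORE = {
    GradeTier.normal: 0,
    GradeTier.mild: 1,
    GradeTier.moderate: 2,
    GradeTier.severe: 3,
}


class IsoformGrade(BaseModel):
    model_config = ConfigDict(frozen=True)

    isoform: Isoform
    measure: Measure
    pct_adult: float
    tier: GradeTier
    plausibility_flag: bool = False


def normalize_to_adult(m: CypMeasurement, ref: IsoformAdultReference) -> float:
    """Express a measured value as %Adult of the reference scalar."""
    if m.isoform is not ref.isoform or m.measure is not ref.measure:
        raise ConfigurationError(
            f"measurement {m.isoform.value}/{m.measure.value} does not match "
            f"reference {ref.isoform.value}/{ref.measure.value}"
        )
    scalar = ref.normalization_scalar
    if scalar <= 0:
        raise ConfigurationError(
            f"{ref.isoform.value}/{ref.measure.value}: non-positive normalization scalar"
        )
    return 100.0 * m.value / scalar


def is_implausible(m: CypMeasurement, ref: IsoformAdultReference, pct_adult: float) -> bool:
    """Order-of-magnitude QC flag; never alters the score."""
    return pct_adult > PLAUSIBILITY_PCT or m.value > ref.range_high


def grade_isoform(
    pct_adult: float,
    isoform: Isoform,
    measure: Measure,
    age_days: int,
    genotype: GenotypeClass,
    ref: ReferenceSet,
    *,
    plausibility_flag: bool = False,
) -> IsoformGrade:
    """Grade a %Adult value against the age-matched tier table.

    Total over pct_adult >= 0; genotype applies to CYP3A5 only.
    """
    if isoform is Isoform.CYP3A5 and genotype is GenotypeClass.non_expressor:
        return IsoformGrade(
            isoform=isoform, measure=measure, pct_adult=pct_adult,
            tier=GradeTier.genotype_zeroed, plausibility_flag=plausibility_flag,
        )
    row = ref.tier_table(isoform, measure).row_for_age(age_days)
    if not row.gradable:
        tier = GradeTier.not_gradable
    elif pct_adult >= row.normal_min_pct:
        tier = GradeTier.normal
    elif pct_adult >= row.mild_low_pct:
        tier = GradeTier.mild
    elif pct_adult >= row.moderate_low_pct:
        tier = GradeTier.moderate
    else:
        tier = GradeTier.severe
    return IsoformGrade(
        isoform=isoform, measure=measure, pct_adult=pct_adult,
        tier=tier, plausibility_flag=plausibility_flag,
    )


def _select_measurements(
    measurements: list[CypMeasurement],
) -> tuple[list[CypMeasurement], list[str]]:
    """Pick one measurement per isoform: protein preferred, QC-qualified
    activity as fallback; activity alongside protein is corroboration only."""
    flags: list[str] = []
    selected: list[CypMeasurement] = []
    by_iso: dict[Isoform, dict[Measure, CypMeasurement]] = {}
    for m in measurements:
        by_iso.setdefault(m.isoform, {})[m.measure] = m
    for iso in Isoform:
        if iso not in by_iso:
            continue
        slot = by_iso[iso]
        protein = slot.get(Measure.protein_abundance)
        activity = slot.get(Measure.probe_activity)
        if protein is not None:
            selected.append(protein)
            if activity is not None:
                flags.append(
                    f"{iso.value}: probe activity reported as corroboration only"
                )
        elif activity is not None:
            if activity.qc_qualified:
                selected.append(activity)
                flags.append(f"{iso.value}: graded on QC-qualified probe activity")
            else:
                flags.append(
                    f"{iso.value}: activity not QC-qualified; excluded from grading"
                )
    return selected, flags


def grade_measurements(
    measurements: list[CypMeasurement],
    genotype: GenotypeClass,
    age_days: int,
    ref: ReferenceSet,
) -> tuple[list[IsoformGrade], list[str]]:
    """Normalize and grade the selected per-isoform measurements."""
    selected, flags = _select_measurements(measurements)
    grades: list[IsoformGrade] = []
    for m in selected:
        adult = ref.adult_reference(m.isoform, m.measure)
        pct = normalize_to_adult(m, adult)
        flag = is_implausible(m, adult, pct)
        if flag:
            flags.append(
                f"{m.isoform.value}: implausibly high value "
                f"({m.value:g} {'pmol/mg' if m.measure is Measure.protein_abundance else 'pmol/min/mg'}, "
                f"{pct:.0f}% adult); QC review advised"
            )
        grades.append(
            grade_isoform(
                pct, m.isoform, m.measure, age_days, genotype, ref,
                plausibility_flag=flag,
            )
        )
    return grades, flags


def score_domain1(
    measurements: list[CypMeasurement],
    genotype: GenotypeClass,
    age_days: int,
    liver_validity: ValidityStatus,
    ref: ReferenceSet,
) -> DomainScore:
    """Aggregate per-isoform grades into the Domain 1 ordinal score."""
    if not liver_validity.scorable:
        return DomainScore(
            domain=1, score=None, role=DomainRole.core,
            ns_reason=liver_validity.reason or "liver specimen not scorable",
        )
    flags: list[str] = []
    if liver_validity.state.value == "acceptable_flagged":
        flags.append(f"liver: {liver_validity.reason}")
    if not measurements:
        return DomainScore(
            domain=1, score=None, role=DomainRole.core,
            ns_reason="no CYP measurements", flags=tuple(flags),
        )
    grades, grade_flags = grade_measurements(measurements, genotype, age_days, ref)
    flags.extend(grade_flags)
    if not grades:
        return DomainScore(
            domain=1, score=None, role=DomainRole.core,
            ns_reason="no gradable CYP measurement", flags=tuple(flags),
        )
    graded = [g for g in grades if g.tier.score is not None]
    zeroed = [g for g in grades if g.tier is GradeTier.genotype_zeroed]
    basis = "; ".join(
        f"{g.isoform.value} {g.pct_adult:.1f}% adult -> {g.tier.value}" for g in grades
    )
    if graded:
        score = max(g.tier.score for g in graded)  # type: ignore[type-var]
    elif zeroed:
        # CYP3A5 non-expressor as the only isoform: physiologic 0.
        score = 0
    else:
        return DomainScore(
            domain=1, score=None, role=DomainRole.core,
            ns_reason="no gradable isoform at this age",
            basis=basis, flags=tuple(flags),
        )
    return DomainScore(
        domain=1, score=score, role=DomainRole.core, basis=basis, flags=tuple(flags)
    )
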