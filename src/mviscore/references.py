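"""Framework reference tables: adult CYP references, developmental tier
tables, ordinal bin specifications, and specimen validity windows.

All constants of the framework live here as immutable, validated lookup
structures.  The built-in dataset is versioned; a laboratory may override
the adult means/ranges and the redox reference via a YAML/JSON config, but
never the developmental tier fractions, the ordinal bin edges, or the
validity windows — those are framework constants.

Developmental expectation is expressed as %Adult: a measured CYP value is
first normalized to the adult reference scalar, then compared against the
age bin's minimum expected fraction.  Tier edges are realized as half-open
real intervals keyed by their printed lower edges: for a row with edges
(normal_min, mild_low, moderate_low),

    normal   = [normal_min, inf)
    mild     = [mild_low, normal_min)
    moderate = [moderate_low, mild_low)
    severe   = [0, moderate_low)

Age bins are half-open day intervals partitioning [0, inf):
"0-7 days"=[0,8), "1-4 weeks"=[8,31), "0-4 weeks"=[0,31),
"1-2 months"=[31,61), "2-3 months"=[61,91), "3-6 months"=[91,183),
"6-12 months"=[183,366), ">12 months"=[366,inf), "0-12 months"=[0,366).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    Analyte,
    AnalyteGroup,
    ConfigurationError,
    InputError,
    Isoform,
    Measure,
    Specimen,
)

BUILTIN_VERSION = "builtin-1.0.0"


class AgeBin(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    low_days: int = Field(ge=0)
    high_days: int | None = None  # exclusive; None = open-ended

    @model_validator(mode="after")
    def _ordered(self) -> "AgeBin":
        if self.high_days is not None and self.high_days <= self.low_days:
            raise ValueError(f"age bin {self.label}: high_days must exceed low_days")
        return self

    def contains(self, age_days: int) -> bool:
        if age_days < self.low_days:
            return False
        return self.high_days is None or age_days < self.high_days


class TierRow(BaseModel):
    """One age bin's tier edges (as %Adult), or a non-gradable row."""

    model_config = ConfigDict(frozen=True)

    age_bin: AgeBin
    gradable: bool
    normal_min_pct: float | None = None
    mild_low_pct: float | None = None
    moderate_low_pct: float | None = None

    @model_validator(mode="after")
    def _edges(self) -> "TierRow":
        edges = (self.normal_min_pct, self.mild_low_pct, self.moderate_low_pct)
        if self.gradable:
            if any(e is None for e in edges):
                raise ValueError(f"gradable row {self.age_bin.label}: all tier edges required")
            if not (self.moderate_low_pct < self.mild_low_pct < self.normal_min_pct):
                raise ValueError(
                    f"row {self.age_bin.label}: tier edges must be strictly ascending"
                )
        elif any(e is not None for e in edges):
            raise ValueError(f"non-gradable row {self.age_bin.label} carries tier edges")
        return self


class DevelopmentalTierTable(BaseModel):
    model_config = ConfigDict(frozen=True)

    isoform: Isoform
    measure: Measure
    rows: tuple[TierRow, ...]

    @model_validator(mode="after")
    def _partition_and_monotone(self) -> "DevelopmentalTierTable":
        rows = self.rows
        if not rows or rows[0].age_bin.low_days != 0:
            raise ValueError("tier table must start at age 0")
        for prev, cur in zip(rows, rows[1:]):
            if prev.age_bin.high_days != cur.age_bin.low_days:
                raise ValueError(
                    f"{self.isoform.value}/{self.measure.value}: age bins "
                    f"{prev.age_bin.label} and {cur.age_bin.label} do not abut"
                )
        if rows[-1].age_bin.high_days is not None:
            raise ValueError("last age bin must be open-ended")
        mins = [r.normal_min_pct for r in rows if r.gradable]
        if any(b < a for a, b in zip(mins, mins[1:])):
            raise ValueError(
                f"{self.isoform.value}/{self.measure.value}: normal minima must be non-decreasing"
            )
        return self

    def row_for_age(self, age_days: int) -> TierRow:
        if age_days < 0:
            raise InputError(f"age_days must be non-negative, got {age_days}")
        for row in self.rows:
            if row.age_bin.contains(age_days):
                return row
        raise InputError(f"no age bin covers {age_days} days")  # pragma: no cover


def resolve_age_bin(table: DevelopmentalTierTable, age_days: int) -> AgeBin:
    """Return the unique age bin of ``table`` containing ``age_days``."""
    return table.row_for_age(age_days).age_bin


class IsoformAdultReference(BaseModel):
    """Adult reference for one isoform/measure: the normalization anchor.

    Protein references carry a mean (the normalization scalar) plus a
    plausibility range; activity references carry only a range, and the
    range midpoint is the normalization scalar.
    """

    model_config = ConfigDict(frozen=True)

    isoform: Isoform
    measure: Measure
    mean: float | None = None
    range_low: float = Field(ge=0)
    range_high: float
    probe_reaction: str | None = None
    genotype_stratified: bool = False

    @model_validator(mode="after")
    def _check(self) -> "IsoformAdultReference":
        if self.range_low > self.range_high:
            raise ValueError(
                f"{self.isoform.value}/{self.measure.value}: range_low exceeds range_high"
            )
        if self.measure is Measure.protein_abundance:
            if self.mean is None or self.mean <= 0:
                raise ValueError(
                    f"{self.isoform.value}: protein adult mean must be strictly positive"
                )
        return self

    @property
    def normalization_scalar(self) -> float:
        if self.measure is Measure.protein_abundance:
            assert self.mean is not None
            return self.mean
        return (self.range_low + self.range_high) / 2.0


class OrdinalBinSpec(BaseModel):
    """Three ascending edges (e0, e1, e2) defining ordinal bins 0..3.

    Lower-inclusive closure: value <= e0 -> 0; e0 < value <= e1 -> 1;
    e1 < value <= e2 -> 2; value > e2 -> 3.
    """

    model_config = ConfigDict(frozen=True)

    analyte: Analyte
    units: str
    edges: tuple[float, float, float]
    role: str  # cytokine_anchor | redox_anchor | contextual

    @model_validator(mode="after")
    def _ascending(self) -> "OrdinalBinSpec":
        e0, e1, e2 = self.edges
        if not (e0 < e1 < e2):
            raise ValueError(f"{self.analyte.value}: bin edges must be strictly ascending")
        return self


class ValidityWindow(BaseModel):
    model_config = ConfigDict(frozen=True)

    specimen: Specimen
    analyte_group: AnalyteGroup
    best_within_h: float = Field(gt=0)
    max_pmi_h: float

    @model_validator(mode="after")
    def _ordered(self) -> "ValidityWindow":
        if self.best_within_h > self.max_pmi_h:
            raise ValueError(
                f"{self.specimen.value}/{self.analyte_group.value}: "
                "best_within_h exceeds max_pmi_h"
            )
        return self


# ---------------------------------------------------------------------------
# Built-in dataset (printed framework constants)
# ---------------------------------------------------------------------------

_SEVEN_BINS = (
    ("0-7 days", 0, 8),
    ("1-4 weeks", 8, 31),
    ("1-2 months", 31, 61),
    ("2-3 months", 61, 91),
    ("3-6 months", 91, 183),
    ("6-12 months", 183, 366),
    (">12 months", 366, None),
)

# (isoform, measure) -> list of (label, lo, hi, edges-or-None)
# edges = (normal_min, mild_low, moderate_low) in %Adult; None = not gradable
_TIER_DATA: dict[tuple[Isoform, Measure], list[tuple[str, int, int | None, tuple | None]]] = {
    (Isoform.CYP3A4, Measure.protein_abundance): [
        (*_SEVEN_BINS[0], None),
        (*_SEVEN_BINS[1], (5, 4, 3)),
        (*_SEVEN_BINS[2], (15, 12, 11)),
        (*_SEVEN_BINS[3], (35, 28, 25)),
        (*_SEVEN_BINS[4], (35, 28, 25)),
        (*_SEVEN_BINS[5], (60, 48, 42)),
        (*_SEVEN_BINS[6], (85, 68, 60)),
    ],
    (Isoform.CYP2D6, Measure.protein_abundance): [
        (*_SEVEN_BINS[0], None),
        (*_SEVEN_BINS[1], (5, 4, 3)),
        (*_SEVEN_BINS[2], (10, 8, 7)),
        (*_SEVEN_BINS[3], (25, 20, 18)),
        (*_SEVEN_BINS[4], (25, 20, 18)),
        (*_SEVEN_BINS[5], (60, 48, 42)),
        (*_SEVEN_BINS[6], (85, 68, 60)),
    ],
    (Isoform.CYP2C19, Measure.protein_abundance): [
        ("0-4 weeks", 0, 31, None),
        (*_SEVEN_BINS[2], (5, 4, 3)),
        (*_SEVEN_BINS[3], (20, 16, 14)),
        (*_SEVEN_BINS[4], (20, 16, 14)),
        (*_SEVEN_BINS[5], (60, 48, 42)),
        (*_SEVEN_BINS[6], (85, 68, 60)),
    ],
    # CYP3A5 protein prints only a 0-12 month row; beyond that no tier
    # edges exist, so grading is refused rather than extrapolated.
    (Isoform.CYP3A5, Measure.protein_abundance): [
        ("0-12 months", 0, 366, (70, 56, 49)),
        (">12 months", 366, None, None),
    ],
    (Isoform.CYP3A4, Measure.probe_activity): [
        (*_SEVEN_BINS[0], None),
        (*_SEVEN_BINS[1], (5, 4, 3.5)),
        (*_SEVEN_BINS[2], (20, 16, 14)),
        (*_SEVEN_BINS[3], (30, 24, 21)),
        (*_SEVEN_BINS[4], (40, 32, 28)),
        (*_SEVEN_BINS[5], (50, 40, 35)),
        (*_SEVEN_BINS[6], (80, 64, 56)),
    ],
    (Isoform.CYP2D6, Measure.probe_activity): [
        (*_SEVEN_BINS[0], None),
        (*_SEVEN_BINS[1], (5, 4, 3.5)),
        (*_SEVEN_BINS[2], (15, 12, 10)),
        (*_SEVEN_BINS[3], (25, 20, 17)),
        (*_SEVEN_BINS[4], (40, 32, 28)),
        (*_SEVEN_BINS[5], (60, 48, 42)),
        (*_SEVEN_BINS[6], (90, 72, 63)),
    ],
    (Isoform.CYP2C19, Measure.probe_activity): [
        (*_SEVEN_BINS[0], None),
        (*_SEVEN_BINS[1], (10, 8, 7)),
        (*_SEVEN_BINS[2], (25, 20, 18)),
        (*_SEVEN_BINS[3], (35, 28, 25)),
        (*_SEVEN_BINS[4], (50, 40, 35)),
        (*_SEVEN_BINS[5], (70, 56, 49)),
        (*_SEVEN_BINS[6], (90, 72, 63)),
    ],
    (Isoform.CYP3A5, Measure.probe_activity): [
        (*_SEVEN_BINS[0], (10, 8, 7)),
        (*_SEVEN_BINS[1], (20, 16, 14)),
        (*_SEVEN_BINS[2], (30, 24, 21)),
        (*_SEVEN_BINS[3], (40, 32, 28)),
        (*_SEVEN_BINS[4], (50, 40, 35)),
        (*_SEVEN_BINS[5], (70, 56, 49)),
        (*_SEVEN_BINS[6], (90, 72, 63)),
    ],
}

# isoform -> (mean, range_low, range_high) pmol/mg
_ADULT_PROTEIN = {
    Isoform.CYP3A4: (85.8, 6.96, 246.2),
    Isoform.CYP2D6: (7.90, 0.00, 25.1),
    Isoform.CYP2C19: (5.02, 0.02, 25.0),
    Isoform.CYP3A5: (4.00, 0.31, 34.2),
}

# isoform -> (probe reaction, range_low, range_high) pmol/min/mg
_ADULT_ACTIVITY = {
    Isoform.CYP3A4: ("Midazolam -> 1'-hydroxymidazolam", 350.0, 450.0),
    Isoform.CYP2D6: ("Dextromethorphan -> dextrorphan", 120.0, 160.0),
    Isoform.CYP2C19: ("S-mephenytoin -> 4'-hydroxymephenytoin", 60.0, 90.0),
    Isoform.CYP3A5: ("Midazolam -> 1'-hydroxymidazolam", 100.0, 250.0),
}

_BIN_SPECS = [
    (Analyte.IL6, "pg/mL", (30.0, 80.0, 300.0), "cytokine_anchor"),
    (Analyte.CRP, "mg/L", (10.0, 40.0, 150.0), "cytokine_anchor"),
    (Analyte.F2_ISOPROSTANE_FOLD, "fold over reference", (1.0, 2.0, 4.0), "redox_anchor"),
    (Analyte.VITREOUS_BHB, "mmol/L", (2.5, 5.0, 10.0), "contextual"),
    (Analyte.VITREOUS_GLUCOSE, "mmol/L", (10.0, 15.0, 25.0), "contextual"),
]

_VALIDITY_WINDOWS = [
    (Specimen.liver, AnalyteGroup.cyp_proteomics, 24.0, 48.0),
    (Specimen.femoral_blood, AnalyteGroup.cytokines, 24.0, 48.0),
    (Specimen.liver, AnalyteGroup.f2_isoprostanes, 24.0, 48.0),
    (Specimen.kidney, AnalyteGroup.f2_isoprostanes, 24.0, 48.0),
    (Specimen.vitreous, AnalyteGroup.glucose_bhb, 24.0, 72.0),
]


def _ref_key(isoform: Isoform, measure: Measure) -> str:
    return f"{isoform.value}:{measure.value}"


def _window_key(specimen: Specimen, group: AnalyteGroup) -> str:
    return f"{specimen.value}:{group.value}"


class ReferenceSet(BaseModel):
    """The complete validated lookup set consumed by the scoring engine."""

    model_config = ConfigDict(frozen=True)

    version: str
    adult_references: dict[str, IsoformAdultReference]
    tier_tables: dict[str, DevelopmentalTierTable]
    bin_specs: dict[Analyte, OrdinalBinSpec]
    validity_windows: dict[str, ValidityWindow]
    redox_reference_ng_g: float | None = None

    def adult_reference(self, isoform: Isoform, measure: Measure) -> IsoformAdultReference:
        return self.adult_references[_ref_key(isoform, measure)]

    def tier_table(self, isoform: Isoform, measure: Measure) -> DevelopmentalTierTable:
        return self.tier_tables[_ref_key(isoform, measure)]

    def bin_spec(self, analyte: Analyte) -> OrdinalBinSpec:
        return self.bin_specs[analyte]

    def validity_window(self, specimen: Specimen, group: AnalyteGroup) -> ValidityWindow:
        key = _window_key(specimen, group)
        if key not in self.validity_windows:
            raise InputError(f"no validity window for {key}")
        return self.validity_windows[key]

    def content_hash(self) -> str:
        payload = self.model_dump_json(exclude={"version"})
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def version_tag(self) -> str:
        return f"{self.version}+{self.content_hash()}"

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceSet":
        return cls.model_validate_json(text)


def _build_tier_table(isoform: Isoform, measure: Measure) -> DevelopmentalTierTable:
    rows = []
    for label, lo, hi, edges in _TIER_DATA[(isoform, measure)]:
        bin_ = AgeBin(label=label, low_days=lo, high_days=hi)
        if edges is None:
            rows.append(TierRow(age_bin=bin_, gradable=False))
        else:
            n, m, mo = edges
            rows.append(
                TierRow(
                    age_bin=bin_, gradable=True,
                    normal_min_pct=float(n), mild_low_pct=float(m), moderate_low_pct=float(mo),
                )
            )
    return DevelopmentalTierTable(isoform=isoform, measure=measure, rows=tuple(rows))


def builtin_reference_set() -> ReferenceSet:
    """The versioned built-in dataset with the printed framework constants."""
    adult: dict[str, IsoformAdultReference] = {}
    for iso, (mean, lo, hi) in _ADULT_PROTEIN.items():
        adult[_ref_key(iso, Measure.protein_abundance)] = IsoformAdultReference(
            isoform=iso, measure=Measure.protein_abundance,
            mean=mean, range_low=lo, range_high=hi,
            genotype_stratified=(iso is Isoform.CYP3A5),
        )
    for iso, (probe, lo, hi) in _ADULT_ACTIVITY.items():
        adult[_ref_key(iso, Measure.probe_activity)] = IsoformAdultReference(
            isoform=iso, measure=Measure.probe_activity,
            range_low=lo, range_high=hi, probe_reaction=probe,
            genotype_stratified=(iso is Isoform.CYP3A5),
        )
    tier_tables = {
        _ref_key(iso, meas): _build_tier_table(iso, meas) for iso, meas in _TIER_DATA
    }
    bins = {
        analyte: OrdinalBinSpec(analyte=analyte, units=units, edges=edges, role=role)
        for analyte, units, edges, role in _BIN_SPECS
    }
    windows = {
        _window_key(spec, grp): ValidityWindow(
            specimen=spec, analyte_group=grp, best_within_h=best, max_pmi_h=maxh
        )
        for spec, grp, best, maxh in _VALIDITY_WINDOWS
    }
    return ReferenceSet(
        version=BUILTIN_VERSION,
        adult_references=adult,
        tier_tables=tier_tables,
        bin_specs=bins,
        validity_windows=windows,
    )


_OVERRIDABLE_FIELDS = {"mean", "range_low", "range_high"}


def load_reference_set(
    config: Mapping[str, Any] | str | Path | None = None,
) -> ReferenceSet:
    """Load the built-in reference set, optionally applying lab overrides.

    ``config`` maps isoform name -> {mean, range_low, range_high} (protein
    adult references) plus an optional ``redox_reference`` scalar (ng/g
    8-iso-PGF2alpha).  Tier fractions, bin edges, and validity windows are
    framework constants and cannot be overridden.
    """
    base = builtin_reference_set()
    if config is None:
        return base
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = yaml.safe_load(text) or {}
    if not isinstance(config, Mapping):
        raise ConfigurationError("reference override config must be a mapping")

    adult = dict(base.adult_references)
    redox_ref = base.redox_reference_ng_g
    for key, value in config.items():
        if key == "redox_reference":
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigurationError("redox_reference must be a positive number")
            redox_ref = float(value)
            continue
        try:
            iso = Isoform(key)
        except ValueError:
            raise ConfigurationError(f"unknown override table '{key}'") from None
        if not isinstance(value, Mapping):
            raise ConfigurationError(f"override for {key} must be a mapping")
        unknown = set(value) - _OVERRIDABLE_FIELDS
        if unknown:
            raise ConfigurationError(
                f"override for {key}: fields {sorted(unknown)} are not overridable"
            )
        rkey = _ref_key(iso, Measure.protein_abundance)
        current = adult[rkey].model_dump()
        current.update({k: float(v) for k, v in value.items()})
        try:
            adult[rkey] = IsoformAdultReference.model_validate(current)
        except ValueError as exc:
            raise ConfigurationError(
                f"invalid override for adult reference {key}: {exc}"
            ) from None

    version = BUILTIN_VERSION + "+lab-override"
    return ReferenceSet(
        version=version,
        adult_references=adult,
        tier_tables=base.tier_tables,
        bin_specs=base.bin_specs,
        validity_windows=base.validity_windows,
        redox_reference_ng_g=redox_ref,
    )


def override_schema() -> dict:
    """JSON-schema-style description of the laboratory override file."""
    iso_schema = {
        "type": "object",
        "properties": {
            "mean": {"type": "number", "exclusiveMinimum": 0},
            "range_low": {"type": "number", "minimum": 0},
            "range_high": {"type": "number"},
        },
        "additionalProperties": False,
    }
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "MVI laboratory reference overrides",
        "type": "object",
        "properties": {
            **{iso.value: iso_schema for iso in Isoform},
            "redox_reference": {"type": "number", "exclusiveMinimum": 0},
        },
        "additionalProperties": False,
    }
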