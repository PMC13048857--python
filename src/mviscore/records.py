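"""Case-record schema and file readers/writers (JSON, JSON-lines, CSV).

A CaseRecord collects one decedent's raw inputs: age at death (integer
days), per-specimen postmortem intervals (decimal hours), hepatic CYP
measurements, CYP3A5 genotype class, the biomarker panel, and adjudicated
ordinals for the two modifier domains.  Batch readers validate row by
row: malformed records are collected into an itemized error report while
valid rows proceed.

The CSV dialect is UTF-8 comma-separated with fixed snake_case headers;
nested lists are flattened (one PMI column per specimen, indexed
``cyp{i}_*`` columns for measurements).  JSON-lines is preferred for
batches and can additionally carry analyte-group-specific specimen
observations that the flat CSV cannot express.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .biomarkers import AdjudicatedOrdinal, BiomarkerPanel
from .core import GenotypeClass, InputError, Specimen
from .cyp import CypMeasurement
from .gating import SpecimenObservation

logger = logging.getLogger("mviscore")


class CaseRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    age_days: int = Field(ge=0)
    specimens: tuple[SpecimenObservation, ...] = ()
    cyp_measurements: tuple[CypMeasurement, ...] = ()
    cyp3a5_genotype: GenotypeClass = GenotypeClass.unknown
    biomarkers: BiomarkerPanel = BiomarkerPanel()
    adjudicated: tuple[AdjudicatedOrdinal, ...] = ()

    def find_observation(
        self, specimen: Specimen, group
    ) -> SpecimenObservation | None:
        """Exact specimen+group match, else a specimen-level observation."""
        fallback = None
        for obs in self.specimens:
            if obs.specimen is not specimen:
                continue
            if obs.analyte_group is group:
                return obs
            if obs.analyte_group is None:
                fallback = obs
        return fallback


@dataclass
class RowError:
    index: int
    case_id: str | None
    message: str


@dataclass
class ReadResult:
    records: list[CaseRecord] = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


_FORMATS = ("json", "jsonl", "csv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise InputError(f"cannot infer format from '{path.name}'; pass format explicitly")


def _validate_rows(raw_rows: Iterable[dict[str, Any]]) -> ReadResult:
    result = ReadResult()
    seen_ids: set[str] = set()
    for i, raw in enumerate(raw_rows):
        try:
            rec = CaseRecord.model_validate(raw)
        except ValidationError as exc:
            fields = "; ".join(
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors()
            )
            result.errors.append(RowError(i, raw.get("case_id"), fields))
            continue
        if rec.case_id in seen_ids:
            result.errors.append(
                RowError(i, rec.case_id, "duplicate case_id within batch")
            )
            continue
        seen_ids.add(rec.case_id)
        result.records.append(rec)
    return result


def read_cases(path: str | Path, format: str | None = None) -> ReadResult:
    """Read and schema-validate case records; row errors are collected."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise InputError(f"unsupported format '{fmt}' (expected one of {_FORMATS})")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        warnings.warn(f"{path.name}: empty input file", stacklevel=2)
        return ReadResult()
    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise InputError(f"{path.name}: malformed JSON: {exc}") from None
        rows = data if isinstance(data, list) else [data]
    elif fmt == "jsonl":
        rows = []
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip():
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise InputError(f"{path.name}:{lineno}: malformed JSON line: {exc}") from None
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        rows = [unflatten_case_row(dict(row)) for _, row in frame.iterrows()]
    return _validate_rows(rows)


def write_cases(records: Iterable[CaseRecord], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    records = list(records)
    if fmt == "json":
        path.write_text(
            json.dumps([r.model_dump(mode="json") for r in records], indent=2) + "\n"
        )
    elif fmt == "jsonl":
        path.write_text(
            "".join(r.model_dump_json() + "\n" for r in records)
        )
    elif fmt == "csv":
        frames = [flatten_case_row(r) for r in records]
        n_cyp = max((len(r.cyp_measurements) for r in records), default=0)
        columns = _csv_columns(n_cyp)
        pd.DataFrame(frames, columns=columns).to_csv(path, index=False)
    else:
        raise InputError(f"unsupported format '{fmt}'")


# --- CSV flattening -------------------------------------------------------

_PMI_COLUMNS = {
    Specimen.liver: "pmi_liver_h",
    Specimen.femoral_blood: "pmi_femoral_blood_h",
    Specimen.vitreous: "pmi_vitreous_h",
    Specimen.kidney: "pmi_kidney_h",
}

_PANEL_COLUMNS = (
    "il6_pg_ml", "crp_mg_l", "redox_fold", "redox_raw_ng_g",
    "vitreous_glucose_mmol_l", "vitreous_bhb_mmol_l",
)


def _csv_columns(n_cyp: int) -> list[str]:
    cols = ["case_id", "age_days", "cyp3a5_genotype"]
    cols += list(_PMI_COLUMNS.values())
    for i in range(1, max(n_cyp, 1) + 1):
        cols += [f"cyp{i}_isoform", f"cyp{i}_measure", f"cyp{i}_value", f"cyp{i}_qc_qualified"]
    cols += list(_PANEL_COLUMNS) + ["redox_tissue"]
    cols += [
        "neurochemical_score", "neurochemical_basis",
        "xenobiotic_metal_score", "xenobiotic_metal_basis",
    ]
    return cols


def flatten_case_row(rec: CaseRecord) -> dict[str, Any]:
    row: dict[str, Any] = {
        "case_id": rec.case_id,
        "age_days": rec.age_days,
        "cyp3a5_genotype": rec.cyp3a5_genotype.value,
    }
    for specimen, col in _PMI_COLUMNS.items():
        obs = rec.find_observation(specimen, None)
        row[col] = "" if obs is None or not obs.collected else obs.pmi_h
    for i, m in enumerate(rec.cyp_measurements, 1):
        row[f"cyp{i}_isoform"] = m.isoform.value
        row[f"cyp{i}_measure"] = m.measure.value
        row[f"cyp{i}_value"] = m.value
        row[f"cyp{i}_qc_qualified"] = str(m.qc_qualified).lower()
    panel = rec.biomarkers
    for col in _PANEL_COLUMNS:
        value = getattr(panel, col)
        row[col] = "" if value is None else value
    row["redox_tissue"] = panel.redox_tissue.value
    for adj in rec.adjudicated:
        prefix = adj.domain.value
        row[f"{prefix}_score"] = "NS" if adj.score is None else adj.score
        row[f"{prefix}_basis"] = adj.basis if adj.score is not None else adj.ns_reason
    return row


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    return float(raw) if raw else None


def unflatten_case_row(row: dict[str, str]) -> dict[str, Any]:
    """Rebuild a nested raw record from one CSV row (strings in)."""
    record: dict[str, Any] = {
        "case_id": row.get("case_id", ""),
        "age_days": row.get("age_days", ""),
        "cyp3a5_genotype": row.get("cyp3a5_genotype", "unknown") or "unknown",
    }
    specimens = []
    for specimen, col in _PMI_COLUMNS.items():
        pmi = _opt_float(row.get(col, ""))
        if pmi is not None:
            specimens.append({"specimen": specimen.value, "pmi_h": pmi})
    record["specimens"] = specimens
    measurements = []
    i = 1
    while row.get(f"cyp{i}_isoform", "").strip():
        measurements.append(
            {
                "isoform": row[f"cyp{i}_isoform"].strip(),
                "measure": row[f"cyp{i}_measure"].strip(),
                "value": row[f"cyp{i}_value"].strip(),
                "qc_qualified": row.get(f"cyp{i}_qc_qualified", "false").strip().lower()
                in ("true", "1", "yes"),
            }
        )
        i += 1
    record["cyp_measurements"] = measurements
    panel: dict[str, Any] = {
        col: _opt_float(row.get(col, "")) for col in _PANEL_COLUMNS
    }
    panel = {k: v for k, v in panel.items() if v is not None}
    tissue = row.get("redox_tissue", "").strip()
    if tissue:
        panel["redox_tissue"] = tissue
    record["biomarkers"] = panel
    adjudicated = []
    for prefix in ("neurochemical", "xenobiotic_metal"):
        score_raw = row.get(f"{prefix}_score", "").strip()
        if not score_raw:
            continue
        basis = row.get(f"{prefix}_basis", "").strip()
        if score_raw.upper() == "NS":
            adjudicated.append(
                {"domain": prefix, "score": None, "ns_reason": basis or "NS in source record"}
            )
        else:
            adjudicated.append({"domain": prefix, "score": score_raw, "basis": basis})
    record["adjudicated"] = adjudicated
    return record


def case_record_schema() -> dict:
    """Published JSON schema for CaseRecord."""
    return CaseRecord.model_json_schema()
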