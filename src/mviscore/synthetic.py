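"""Seeded synthetic case generator (structural fixtures, not epidemiology).

Cases are built by inverse binning: given a target score vector, each
measured value is placed strictly inside the interval that scores to the
target tier — at the tier midpoint plus bounded jitter, never closer to a
shared edge than 5% of the tier width — so scoring a generated case
reproduces its targets exactly under the lower-inclusive edge convention.
NS targets are realized by placing the specimen PMI beyond its sampling
maximum (exercising the validity gate) for domains 1-3, and by NS
adjudications for domains 4-5.

The generator covers every scoring path: all gradable age bins, CYP3A5
genotype classes, validity states, and — in coverage mode — all 31
non-empty domain-support subsets.  It makes no attempt to emulate
realistic joint biology; values within a tier are placed independently.
"""

from __future__ import annotations

import warnings
from itertools import chain, combinations
from typing import Any, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .biomarkers import AdjudicatedOrdinal, AdjudicatedDomain, BiomarkerPanel, RedoxTissue
from .core import Analyte, AnalyteGroup, GenerationError, GenotypeClass, Isoform, Measure, Specimen
from .cyp import CypMeasurement
from .gating import SpecimenObservation
from .records import CaseRecord
from .references import ReferenceSet, TierRow, load_reference_set

NS = "NS"

_DEFAULT_GENOTYPE_MIX = {
    GenotypeClass.expressor: 0.85,
    GenotypeClass.non_expressor: 0.10,
    GenotypeClass.unknown: 0.05,
}


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int = Field(ge=0)
    n_cases: int = Field(ge=1, default=1)
    target_pattern: tuple[int, ...] | None = None  # fixed support subset
    age_bin_mix: dict[str, float] | None = None    # CYP3A4-protein bin label -> weight
    pmi_hours: tuple[float, float] = (4.0, 20.0)   # scorable-specimen PMI range
    genotype_mix: dict[GenotypeClass, float] = Field(
        default_factory=lambda: dict(_DEFAULT_GENOTYPE_MIX)
    )
    jitter: float = Field(default=0.9, ge=0.0, le=0.9)  # fraction of tier half-width

    @model_validator(mode="after")
    def _check(self) -> "ScenarioSpec":
        if self.target_pattern is not None:
            if not set(self.target_pattern) <= {1, 2, 3, 4, 5}:
                raise ValueError("target_pattern must be a subset of domains 1-5")
        for name, mix in (("genotype_mix", self.genotype_mix),
                          ("age_bin_mix", self.age_bin_mix)):
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        lo, hi = self.pmi_hours
        if not (0 <= lo <= hi):
            raise ValueError("pmi_hours must be an ordered non-negative range")
        return self


def _place(rng: np.random.Generator, low: float, high: float, jitter: float) -> float:
    """Midpoint of (low, high) plus bounded jitter, >=5% of width off edges."""
    width = high - low
    mid = low + width / 2.0
    offset = jitter * 0.5 * width * float(rng.uniform(-0.9, 0.9))
    return mid + offset


def _tier_interval(row: TierRow, target: int) -> tuple[float, float]:
    """%Adult interval that grades to the target tier in a gradable row."""
    assert row.gradable
    n, m, mo = row.normal_min_pct, row.mild_low_pct, row.moderate_low_pct
    if target == 0:
        return n, max(min(145.0, n * 1.4), n + 1.0)
    if target == 1:
        return m, n
    if target == 2:
        return mo, m
    return 0.0, mo


def _bin_interval(edges: tuple[float, float, float], target: int) -> tuple[float, float]:
    e0, e1, e2 = edges
    return ((0.0, e0), (e0, e1), (e1, e2), (e2, 2 * e2))[target]


def _normalize_targets(
    target_scores: Mapping[int, Any] | Sequence[Any] | None,
    rng: np.random.Generator,
) -> dict[int, int | None]:
    if target_scores is None:
        return {d: int(rng.integers(0, 4)) for d in range(1, 6)}
    if not isinstance(target_scores, Mapping):
        seq = list(target_scores)
        if len(seq) != 5:
            raise GenerationError("target score vector must have five entries")
        target_scores = {d: v for d, v in zip(range(1, 6), seq)}
    out: dict[int, int | None] = {}
    for d in range(1, 6):
        raw = target_scores.get(d, 0)
        if raw is None or (isinstance(raw, str) and raw.upper() == NS):
            out[d] = None
        else:
            score = int(raw)
            if not (0 <= score <= 3):
                raise GenerationError(f"domain {d} target {raw} outside 0-3 / NS")
            out[d] = score
    return out


def _sample_age(
    spec: ScenarioSpec,
    targets: dict[int, int | None],
    ref: ReferenceSet,
    rng: np.random.Generator,
    age_days: int | None,
) -> int:
    table = ref.tier_table(Isoform.CYP3A4, Measure.protein_abundance)
    d1 = targets[1]
    if age_days is not None:
        row = table.row_for_age(age_days)
        if d1 is not None and not row.gradable:
            raise GenerationError(
                f"Domain 1 target {d1} unreachable at age {age_days} d: "
                f"CYP3A4 protein is not gradable in bin '{row.age_bin.label}'"
            )
        return age_days
    rows = {r.age_bin.label: r for r in table.rows}
    if spec.age_bin_mix:
        labels = list(spec.age_bin_mix)
        weights = np.array([spec.age_bin_mix[l] for l in labels])
        unknown = set(labels) - set(rows)
        if unknown:
            raise GenerationError(f"unknown age bin labels in mix: {sorted(unknown)}")
    else:
        labels = [l for l, r in rows.items() if r.gradable]
        weights = np.full(len(labels), 1.0 / len(labels))
    if d1 is not None:
        keep = [i for i, l in enumerate(labels) if rows[l].gradable]
        if not keep:
            raise GenerationError(
                f"Domain 1 target {d1} unreachable: no gradable age bin in the mix"
            )
        labels = [labels[i] for i in keep]
        weights = weights[keep]
    weights = weights / weights.sum()
    label = labels[int(rng.choice(len(labels), p=weights))]
    row = rows[label]
    low = row.age_bin.low_days
    high = row.age_bin.high_days if row.age_bin.high_days is not None else 731
    return int(rng.integers(low, high))


def _pmi(spec: ScenarioSpec, rng: np.random.Generator, max_pmi: float,
         scorable: bool) -> float:
    if scorable:
        lo, hi = spec.pmi_hours
        return round(float(rng.uniform(lo, min(hi, max_pmi))), 1)
    return round(max_pmi + float(rng.uniform(2.0, 24.0)), 1)


def generate_case(
    spec: ScenarioSpec,
    target_scores: Mapping[int, Any] | Sequence[Any] | None = None,
    *,
    case_id: str = "case-0001",
    age_days: int | None = None,
    ref: ReferenceSet | None = None,
    rng: np.random.Generator | None = None,
) -> CaseRecord:
    """Emit one CaseRecord whose scored domain vector equals the targets."""
    ref = ref if ref is not None else load_reference_set()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    targets = _normalize_targets(target_scores, rng)
    age = _sample_age(spec, targets, ref, rng, age_days)
    jit = spec.jitter

    genotypes = list(spec.genotype_mix)
    probs = np.array([spec.genotype_mix[g] for g in genotypes])
    genotype = genotypes[int(rng.choice(len(genotypes), p=probs))]

    # Domain 1: one CYP3A4 protein value inverse-binned for the target.
    d1 = targets[1]
    liver_window = ref.validity_window(Specimen.liver, AnalyteGroup.cyp_proteomics)
    liver_pmi = _pmi(spec, rng, liver_window.max_pmi_h, d1 is not None)
    adult = ref.adult_reference(Isoform.CYP3A4, Measure.protein_abundance)
    table = ref.tier_table(Isoform.CYP3A4, Measure.protein_abundance)
    row = table.row_for_age(age)
    if row.gradable:
        pct = _place(rng, *_tier_interval(row, d1 if d1 is not None else 0), jit)
    else:  # NS target at a non-gradable age: physiologically near-zero value
        pct = float(rng.uniform(0.0, 2.0))
    cyp_value = round(pct / 100.0 * adult.normalization_scalar, 4)
    measurements = (
        CypMeasurement(
            isoform=Isoform.CYP3A4, measure=Measure.protein_abundance, value=cyp_value
        ),
    )

    # Domain 2: IL-6 and CRP both placed in the target bin.
    d2 = targets[2]
    blood_window = ref.validity_window(Specimen.femoral_blood, AnalyteGroup.cytokines)
    blood_pmi = _pmi(spec, rng, blood_window.max_pmi_h, d2 is not None)
    tb = d2 if d2 is not None else int(rng.integers(0, 4))
    il6 = round(_place(rng, *_bin_interval(ref.bin_spec(Analyte.IL6).edges, tb), jit), 2)
    crp = round(_place(rng, *_bin_interval(ref.bin_spec(Analyte.CRP).edges, tb), jit), 2)

    # Domain 3: liver F2-isoprostane fold in the target bin.
    d3 = targets[3]
    redox_window = ref.validity_window(Specimen.liver, AnalyteGroup.f2_isoprostanes)
    tb3 = d3 if d3 is not None else int(rng.integers(0, 4))
    fold = round(
        _place(rng, *_bin_interval(ref.bin_spec(Analyte.F2_ISOPROSTANE_FOLD).edges, tb3), jit),
        3,
    )
    # Liver serves both CYP proteomics and redox; a single liver PMI would
    # tie their validity together, so redox NS with D1 scorable (or vice
    # versa) uses a group-specific observation pair.
    if (d1 is None) == (d3 is None):
        liver_obs = (SpecimenObservation(specimen=Specimen.liver, pmi_h=liver_pmi),)
    else:
        redox_pmi = _pmi(spec, rng, redox_window.max_pmi_h, d3 is not None)
        liver_obs = (
            SpecimenObservation(
                specimen=Specimen.liver,
                analyte_group=AnalyteGroup.cyp_proteomics, pmi_h=liver_pmi,
            ),
            SpecimenObservation(
                specimen=Specimen.liver,
                analyte_group=AnalyteGroup.f2_isoprostanes, pmi_h=redox_pmi,
            ),
        )

    # Vitreous: contextual only; random bins within the validity window.
    vit_window = ref.validity_window(Specimen.vitreous, AnalyteGroup.glucose_bhb)
    vit_pmi = _pmi(spec, rng, vit_window.max_pmi_h, True)
    glucose = round(
        _place(rng, *_bin_interval(ref.bin_spec(Analyte.VITREOUS_GLUCOSE).edges,
                                   int(rng.integers(0, 4))), jit), 2)
    bhb = round(
        _place(rng, *_bin_interval(ref.bin_spec(Analyte.VITREOUS_BHB).edges,
                                   int(rng.integers(0, 4))), jit), 2)

    adjudicated = []
    for domain_no, adj_domain, basis in (
        (4, AdjudicatedDomain.neurochemical, "brainstem neuropathology + SERT/TPH2 IHC"),
        (5, AdjudicatedDomain.xenobiotic_metal, "comprehensive toxicology + ICP-MS metals"),
    ):
        t = targets[domain_no]
        if t is None:
            adjudicated.append(
                AdjudicatedOrdinal(
                    domain=adj_domain, score=None,
                    ns_reason="anchor studies not performed",
                )
            )
        else:
            adjudicated.append(
                AdjudicatedOrdinal(domain=adj_domain, score=t, basis=basis)
            )

    return CaseRecord(
        case_id=case_id,
        age_days=age,
        specimens=liver_obs + (
            SpecimenObservation(specimen=Specimen.femoral_blood, pmi_h=blood_pmi),
            SpecimenObservation(specimen=Specimen.vitreous, pmi_h=vit_pmi),
        ),
        cyp_measurements=measurements,
        cyp3a5_genotype=genotype,
        biomarkers=BiomarkerPanel(
            il6_pg_ml=il6, crp_mg_l=crp,
            redox_fold=fold, redox_tissue=RedoxTissue.liver,
            vitreous_glucose_mmol_l=glucose, vitreous_bhb_mmol_l=bhb,
        ),
        adjudicated=tuple(adjudicated),
    )


def all_support_subsets() -> list[tuple[int, ...]]:
    domains = (1, 2, 3, 4, 5)
    return [
        tuple(c)
        for c in chain.from_iterable(combinations(domains, k) for k in range(1, 6))
    ]


def _targets_for_support(
    support: Sequence[int], rng: np.random.Generator
) -> dict[int, int]:
    return {
        d: (int(rng.integers(1, 4)) if d in support else 0) for d in range(1, 6)
    }


def generate_cohort(
    spec: ScenarioSpec,
    *,
    coverage: bool = False,
    ref: ReferenceSet | None = None,
) -> tuple[list[CaseRecord], dict]:
    """Generate ``spec.n_cases`` records plus a manifest of seed/targets.

    In coverage mode the first 31 cases target each non-empty domain
    subset once; remaining cases (and all cases otherwise) use random
    targets, restricted to ``spec.target_pattern`` when given.
    """
    ref = ref if ref is not None else load_reference_set()
    subsets = all_support_subsets()
    cases: list[CaseRecord] = []
    manifest_cases: list[dict] = []
    missing: list[tuple[int, ...]] = []
    if coverage and spec.n_cases < len(subsets):
        missing = subsets[spec.n_cases:]
        warnings.warn(
            f"coverage requested with n_cases={spec.n_cases} < {len(subsets)}; "
            f"{len(missing)} subsets not covered",
            stacklevel=2,
        )
    for i in range(spec.n_cases):
        rng = np.random.default_rng([spec.seed, i])
        if coverage and i < len(subsets):
            targets: Mapping[int, Any] = _targets_for_support(subsets[i], rng)
        elif spec.target_pattern is not None:
            targets = _targets_for_support(spec.target_pattern, rng)
        else:
            targets = {d: int(rng.integers(0, 4)) for d in range(1, 6)}
        case_id = f"case-{i + 1:04d}"
        cases.append(
            generate_case(spec, targets, case_id=case_id, ref=ref, rng=rng)
        )
        manifest_cases.append(
            {"case_id": case_id, "targets": {str(d): targets[d] for d in range(1, 6)}}
        )
    manifest = {
        "seed": spec.seed,
        "n_cases": spec.n_cases,
        "coverage": coverage,
        "target_pattern": list(spec.target_pattern) if spec.target_pattern else None,
        "cases": manifest_cases,
        "missing_subsets": [list(s) for s in missing],
    }
    return cases, manifest
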