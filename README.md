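# mviscore

A deterministic, auditable scoring engine for the **Metabolic Vulnerability
Index (MVI)** and **Cytokine-Metabolic Suppression Profile (CMSP)** —
structured interpretive tools for postmortem review of unexplained infant
deaths (SUID/SIDS case work). It is aimed at forensic pathology and
laboratory-informatics teams who need the scoring arithmetic, threshold
tables, and archetype lookup applied reproducibly, with every not-scorable
(NS) result reported with its reason. It is **not** a diagnostic or
certification tool and produces no cause-of-death statement.

## The index

Five analytic domains are each scored on a coarse ordinal 0–3 scale and
summed to an MVI total of 0–15:

1. **CYP450 capacity** — hepatic isoform protein abundance (pmol/mg;
   QC-qualified probe activity as fallback) for CYP3A4, CYP2D6, CYP2C19,
   CYP3A5, interpreted by *two-step normalization*: the measured value is
   expressed as %Adult of the adult reference scalar, then compared with
   the age-matched developmental minimum for the isoform. This keeps
   physiologic immaturity from being misread as suppression. The domain
   score is the worst tier across gradable isoforms. CYP3A5 \*3/\*3
   non-expressors are never graded and contribute a physiologic 0.
2. **Cytokine load** — femoral IL-6 (pg/mL) and CRP (mg/L) binned at
   30/80/300 and 10/40/150; domain = max of the two.
3. **Redox balance** — tissue F2-isoprostane (8-iso-PGF2α) fold over the
   laboratory reference, binned at 1×/2×/4× (liver default; kidney cortex
   corroborative only).
4. **Neurochemical integrity** (modifier) — adjudicated ordinal from
   brainstem neuropathology ± SERT/TPH2 IHC.
5. **Xenobiotic/metal burden** (modifier/exposure context) — adjudicated
   ordinal from comprehensive toxicology ± ICP-MS metals.

Every measurement is first gated by its specimen's postmortem interval
(liver/femoral blood ≤48 h, vitreous ≤72 h; "best within" 24 h); beyond
the maximum the analyte is NS and the scorable denominator shrinks —
reports print `total/scorable_max` rather than imputing zeros.

The pattern of non-zero domains (31 possible subsets) resolves through a
lookup-and-referral table to one of **14 mechanistic archetypes** (e.g.
\#6 immune-mediated phenoconversion, \#11 core multi-axis metabolic
collapse), with Domain 4/5 documented as modifier or exposure context.
Two subsets are score-conditional (dominance comparisons). The CMSP core
(sum of the IL-6/CRP/redox bins, 0–9) and the vitreous glucose/β-hydroxy-
butyrate pattern are reporting layers only: they never alter a domain
score, the total, or the archetype.

## Worked example

```python
from mviscore import compute_mvi, load_reference_set
from mviscore.synthetic import ScenarioSpec, generate_case

refs = load_reference_set()                      # printed framework constants
case = generate_case(ScenarioSpec(seed=1), (3, 2, 2, 1, 2), case_id="worked")
report = compute_mvi(case, refs)
print(report.to_markdown())
```

prints

```
# MVI report - case worked

| Domain | Score | Role | Basis |
|---|---|---|---|
| 1 CYP450 capacity | 3 | core | CYP3A4 8.7% adult -> severe |
| 2 Cytokine load | 2 | core | IL-6 248.4 pg/mL -> 2; CRP 86.91 mg/L -> 2 |
| 3 Redox balance | 2 | core | 8-iso-PGF2a 3.08x reference (liver) -> 2 |
| 4 Neurochemical integrity | 1 | modifier | brainstem neuropathology + SERT/TPH2 IHC |
| 5 Xenobiotic/metal burden | 2 | modifier | comprehensive toxicology + ICP-MS metals |

**MVI total:** 10/15
**Archetype:** #11 CYP + Cytokine + Redox (Core-Multi-Axis Metabolic Collapse); modifiers: D4 (modifier), D5 (exposure_context)
**CMSP Core:** 6/9 (moderate)
**Vitreous pattern:** mixed_dysregulation
```

The severe CYP grade (8.7% adult in an infant whose age bin expects ≥60%),
moderate cytokine and redox bins, and both modifier domains non-zero put
all five domains in support, which the lookup refers to archetype #11 with
Domains 4 and 5 documented alongside.

A command-line surface wraps the same library:

```bash
mvi simulate --seed 7 --n 31 --coverage --out sim/   # synthetic cohort + manifest
mvi score --in sim/cohort.jsonl --out reports/       # one JSON + markdown report per case
mvi enumerate-archetypes --out map.json              # audit export of the lookup table
mvi validate --in cases.csv                          # schema check only
mvi references --config lab.yaml                     # active reference set + version hash
```

## Layout

- `src/mviscore/references.py` — all printed constants (adult references,
  developmental tier tables, bin edges, validity windows) with laboratory
  override support
- `gating.py`, `cyp.py`, `biomarkers.py` — specimen validity and Domains 1–5
- `cmsp.py`, `archetypes.py`, `assembly.py` — summary layers, lookup engine,
  report assembly
- `synthetic.py` — seeded inverse-binning case generator
- `records.py`, `cli.py` — case-record schema, JSON/JSONL/CSV I/O, CLI

See `docs/methods.md` for the scoring conventions, design choices, and
limitations.
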