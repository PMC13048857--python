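# Methods

## Scope and intent

`mviscore` implements the operational core of a five-domain ordinal
scoring framework for postmortem infant case review: specimen validity
gating, two-step CYP normalization against developmental expectations,
ordinal biomarker binning, archetype lookup with referral resolution, and
report assembly. It deliberately excludes everything interpretive beyond
the fixed labels: no severity grading within an archetype, no causal or
certification language, no population inference.

## Specimen validity gating

Each domain anchor is tied to a specimen with a handling target
("best within" PMI) and a sampling maximum, in hours postmortem:

| specimen | analyte group | best within | maximum |
|---|---|---|---|
| liver | CYP proteomics | 24 | 48 |
| femoral blood | IL-6 / CRP | 24 | 48 |
| liver or kidney cortex | F2-isoprostanes | 24 | 48 |
| vitreous humor | glucose / BHB | 24 | 72 |

The gate is three-state: `optimal` (PMI < target), `acceptable_flagged`
(target ≤ PMI ≤ maximum — scorable, flagged, never down-weighted), and
`NS` (PMI > maximum, or specimen not collected; always with a reason).
Boundary conventions mirror the printed inequalities: the target is
exclusive, the maximum inclusive, so PMI exactly at the maximum is
scorable-flagged. A specimen observation may be specimen-level (one liver
PMI gating both CYP and redox work, the usual collection situation) or
analyte-group-specific when the two liver workflows were sampled
separately.

## Domain 1: two-step CYP normalization

Step 1 — %Adult. Protein abundance (pmol/mg microsomal protein) is
divided by the adult reference mean (CYP3A4 85.8, CYP2D6 7.90, CYP2C19
5.02, CYP3A5 4.00). Probe activity (pmol/min/mg) is divided by the
midpoint of the printed adult range (e.g. CYP3A4 350–450 → 400), since
only ranges are printed for activity. Values above 150 %Adult or above
the printed adult maximum raise a plausibility flag (QC only; never
changes the score).

Step 2 — age-matched tier. The %Adult value is compared with the age
bin's expected minimum. Printed tier ranges are realized as half-open
intervals keyed by their lower edges: for a row with edges
(normal_min, mild_low, moderate_low),
normal = [normal_min, ∞), mild = [mild_low, normal_min),
moderate = [moderate_low, mild_low), severe = [0, moderate_low). A value
exactly at the printed minimum grades normal. Age bins are half-open day
intervals partitioning [0, ∞): "0-7 days" = [0, 8), "1-4 weeks" = [8, 31),
"1-2 months" = [31, 61), "2-3 months" = [61, 91), "3-6 months" = [91, 183),
"6-12 months" = [183, 366), ">12 months" = [366, ∞); CYP2C19 protein uses
"0-4 weeks" = [0, 31) and CYP3A5 protein "0-12 months" = [0, 366). Ages in
a physiologically-near-zero bin are *not gradable* (immaturity is not
suppression). CYP3A5 protein has no printed tiers past 12 months, so that
age range is likewise not gradable rather than extrapolated.

Genotype rule: CYP3A5 \*3/\*3 non-expressors are never graded; the isoform
contributes a physiologic 0 regardless of measured value. Unknown or
indeterminate genotype is graded as an expressor.

Aggregation: protein is primary; activity is graded only when no protein
value exists for the isoform *and* the assay is QC-qualified (activity
alongside protein is recorded as corroboration). The domain score is the
**maximum** tier across gradable isoforms — reserve limitation is driven
by the most-affected clearance pathway, and the maximum is the only
unweighted aggregation that preserves the 0–3 codomain. At least one
gradable isoform suffices; if none is gradable at the case's age the
domain is NS.

## Domains 2–5

Ordinal bins are lower-inclusive ((e0, e1]-style): a value exactly on a
shared printed edge falls in the lower bin, keeping the bin function
total and monotone on [0, ∞).

| analyte | units | edges (0/1/2/3) |
|---|---|---|
| IL-6 | pg/mL | 30 / 80 / 300 |
| CRP (not hs-CRP) | mg/L | 10 / 40 / 150 |
| 8-iso-PGF2α | fold over lab reference | 1 / 2 / 4 |
| vitreous BHB | mmol/L | 2.5 / 5 / 10 |
| vitreous glucose | mmol/L | 10 / 15 / 25 |

Domain 2 is the max of the available IL-6/CRP bins (either marker is
sufficient evidence of severity; no combination rule is printed, and max
preserves the codomain); both absent → NS. Domain 3 prefers a directly
reported fold; a raw tissue concentration (ng/g) is divided by the
laboratory redox reference when one is configured. A kidney-cortex-only
value is scored but flagged corroborative, not down-scored. Domains 4 and
5 are validated pass-throughs of adjudicated ordinals — the framework
prints anchor descriptions, not bin tables, for these domains, so
adjudication stays with the reviewing specialists.

## CMSP core and vitreous pattern

The CMSP core is the unweighted sum (0–9) of the IL-6, CRP, and redox
bins, labelled minimal (0–1), mild (2–4), moderate (5–7), severe (8–9);
the sum is the minimal symmetric aggregation given that no combination
formula is printed. Any NS anchor makes the core NS. The vitreous pattern
is a quadrant label over the glucose/BHB bins (high = bin 2–3):
minimal deviation, stress hyperglycemia, ketosis, mixed dysregulation;
either marker NS → indeterminate (the printed NS row keys on BHB; NS
handling is applied symmetrically to glucose as the conservative
reading). Both layers are reporting artifacts: an end-to-end test
perturbs them across a thousand cases and asserts no effect on any
domain score, the total, or the archetype.

## Archetype lookup

The support set (domains scoring ≥1, NS excluded) resolves through the
31-subset map to one of 14 core archetypes; referral rows document the
remaining domains as modifier (Domain 4) or exposure context (Domain 5)
and resolve in at most two hops. Score-conditional rules: {4,5} goes to
the dominant domain's singleton archetype — a tie breaks to #4 (lower
domain number, deterministic and auditable) with a dominance note — and
{2,4,5} goes to #5 only when the Domain 5 score strictly exceeds
Domain 2's. An NS core domain (1–3) is excluded from the support and the
assignment proceeds with an interpretive-limitation flag, since the NS
rules require reporting, not abortion of the case. The full map,
including conditional branches, is exportable
(`mvi enumerate-archetypes`) for audit.

## Report assembly

The MVI total is the sum of scorable domain ordinals over a denominator
of 3 × (scorable domains), printed as `total/scorable_max` — NS shrinks
the denominator instead of imputing 0, so missing data never deflates
severity. Reports are deterministic (identical inputs give byte-identical
JSON) and carry the reference-set version plus a content hash, so results
under laboratory overrides are distinguishable from the built-in tables.
Overrides may replace only adult means/ranges and the redox reference;
tier fractions, bin edges, and validity windows are framework constants.

## Synthetic case generator

The generator is a *structural* fixture tool, not an epidemiologic
simulator: it makes no attempt at realistic joint distributions of
analytes, and passing round-trip tests therefore demonstrates scoring
correctness, not real-data performance. Given a target score vector it
inverse-bins each value — placed at the target tier's midpoint plus
bounded jitter, never nearer a shared edge than 5% of the tier width —
so the pipeline reproduces targets exactly under the lower-inclusive
convention. Unbounded tiers are capped for placement only (top bins at
2× their highest edge; the normal CYP tier at 1.4× the age minimum,
≤145 %Adult, clear of the plausibility flag). NS targets for domains 1–3
are realized by pushing the specimen PMI 2–24 h past its maximum
(exercising the gate) rather than deleting values; NS modifiers become
NS adjudications. Defaults, chosen as ordinary laboratory conditions:
ages uniform over gradable age bins, scorable PMIs uniform on 4–20 h,
genotype mix 85% expressor / 10% non-expressor / 5% unknown. Coverage
mode targets each of the 31 support subsets once in the first 31 cases.
All randomness flows from a single integer seed through per-case
`numpy` generators seeded as (seed, case index), so cohorts are
reproducible case-by-case across platforms.

## Numerical and validation choices

- All thresholds are compared with plain floating-point comparisons; the
  generator's edge margins make round-trips insensitive to representation.
- Problem sizes in the test suite (dense 0.1 %Adult sweeps over every
  gradable bin of all eight tier tables; 4^5 score-vector enumeration;
  thousand-case round-trip and non-interference runs) were chosen to be
  exhaustive at desk scale — the whole suite runs in a few seconds.
- Validation is pydantic-based end to end; batch readers collect
  row-level errors and let valid rows proceed, and CSV round-trips are
  guaranteed for the documented flat dialect (specimen-level PMIs).

## Known limitations

- The tier tables are implemented exactly as printed; the framework's
  design-rationale description of CYP thresholds as 75/50/25% does not
  match the printed tier arithmetic and is not used.
- Contextual cytokines without printed thresholds (IL-1β, TNF-α, CCL2)
  are out of scope, as are hs-CRP, star-allele calling for CYP2D6/CYP2C19,
  analyte decay/temperature modelling, and any raw assay processing.
- Between the handling target and the sampling maximum results are
  flagged but not down-weighted; no printed rule quantifies degradation.
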