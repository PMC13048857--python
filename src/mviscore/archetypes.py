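"""Archetype assignment: domain-combination lookup with referral rules.

The support of a case is the set of domains with a non-zero, scorable
ordinal.  Each of the 31 non-empty subsets of {1..5} resolves to exactly
one of 14 core archetypes, either directly (the subset is itself a core
pattern) or through a referral row that names a core archetype and
documents the remaining domains as modifiers (Domain 4, neurochemical) or
exposure context (Domain 5, xenobiotic/metal).  Two subsets are
score-conditional: {4,5} goes to the dominant domain's singleton
archetype, and {2,4,5} goes to #5 when the Domain 5 score strictly
exceeds Domain 2's.

A domain that is NS is excluded from the support; when the NS domain is a
core domain (1-3) the assignment carries an interpretive-limitation flag.
The {4,5} dominance tie is broken toward #4 (lower domain number) with a
dominance note.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import chain, combinations
from typing import Callable, Iterable

from pydantic import BaseModel, ConfigDict, model_validator

from .core import DomainScore, InputError

CORE_ARCHETYPES: dict[int, str] = {
    1: "Isolated CYP impairment (Isolated metabolic limitation)",
    2: "Isolated Cytokine Elevation (Isolated immune activation)",
    3: "Isolated Redox Depletion (Isolated oxidative/mitochondrial stress)",
    4: "Isolated Neurochemical Imbalance (Isolated autonomic vulnerability)",
    5: "Isolated Xenobiotic/metal Burden (Exposure without overload)",
    6: "CYP + Cytokine (Immune-mediated phenoconversion)",
    7: "CYP + Redox (Metabolic-mitochondrial coupling failure)",
    8: "Cytokine + Redox (Inflammatory-oxidative amplification)",
    9: "Cytokine or Redox + Neurochemical (Autonomic destabilization under systemic stress)",
    10: "CYP or Redox + Xenobiotic (Exogenous load exceeding reserve)",
    11: "CYP + Cytokine + Redox (Core-Multi-Axis Metabolic Collapse)",
    12: "Cytokine + Redox + Neurochemical (Inflammatory-oxidative autonomic failure)",
    13: "CYP + Redox + Neurochemical (Neuro-metabolic vulnerability)",
    14: "CYP + Cytokine or Redox + Xenobiotic/metal (Terminal Multi-Axis Overload)",
}

NO_ARCHETYPE_LABEL = "minimal multidomain deviation"


class ModifierRole(str, Enum):
    modifier = "modifier"
    exposure_context = "exposure_context"


class ModifierTag(BaseModel):
    model_config = ConfigDict(frozen=True)

    domain: int
    role: ModifierRole


class DomainPattern(BaseModel):
    """Scores by domain (0-3 or None=NS) and the derived support set."""

    model_config = ConfigDict(frozen=True)

    scores: dict[int, int | None]

    @model_validator(mode="after")
    def _valid(self) -> "DomainPattern":
        if set(self.scores) != {1, 2, 3, 4, 5}:
            raise ValueError("scores must cover domains 1-5 exactly")
        for d, s in self.scores.items():
            if s is not None and not (0 <= s <= 3):
                raise ValueError(f"domain {d} score {s} outside 0-3")
        return self

    @property
    def support(self) -> frozenset[int]:
        return frozenset(d for d, s in self.scores.items() if s is not None and s >= 1)

    @property
    def ns_domains(self) -> frozenset[int]:
        return frozenset(d for d, s in self.scores.items() if s is None)

    @classmethod
    def from_vector(cls, vector: Iterable[int | None]) -> "DomainPattern":
        vec = list(vector)
        if len(vec) != 5:
            raise InputError("score vector must have exactly five entries")
        return cls(scores={d: v for d, v in zip(range(1, 6), vec)})

    @classmethod
    def from_domain_scores(cls, scores: Iterable[DomainScore]) -> "DomainPattern":
        return cls(scores={s.domain: s.score for s in scores})


class ArchetypeAssignment(BaseModel):
    model_config = ConfigDict(frozen=True)

    ref_no: int | None
    mechanistic_class: str
    core_domains: tuple[int, ...]
    modifier_domains: tuple[ModifierTag, ...]
    referral_trail: tuple[str, ...] = ()
    dominance_note: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class _Branch:
    """One resolution of a subset: optional score condition + outcome."""

    condition: Callable[[dict[int, int]], bool] | None
    condition_label: str
    ref_no: int
    modifiers: tuple[tuple[int, ModifierRole], ...]
    trail: tuple[str, ...]
    hops: int
    dominance_note: str | None = None


def _b(
    ref_no: int,
    modifiers: tuple[tuple[int, ModifierRole], ...] = (),
    trail: tuple[str, ...] = (),
    condition: Callable[[dict[int, int]], bool] | None = None,
    condition_label: str = "",
    dominance_note: str | None = None,
) -> _Branch:
    return _Branch(condition, condition_label, ref_no, modifiers, trail, len(trail),
                   dominance_note)


_M4 = (4, ModifierRole.modifier)
_M5 = (5, ModifierRole.exposure_context)
_M5_MOD = (5, ModifierRole.modifier)
_M2 = (2, ModifierRole.modifier)


def _ref_step(subset_label: str, ref_no: int) -> str:
    return f"referral: {subset_label} -> #{ref_no} ({CORE_ARCHETYPES[ref_no].split(' (')[0]})"


# subset -> ordered branches (first matching condition wins; None = default)
_RULES: dict[frozenset[int], tuple[_Branch, ...]] = {
    # Single-domain patterns map to their own archetype.
    frozenset({1}): (_b(1),),
    frozenset({2}): (_b(2),),
    frozenset({3}): (_b(3),),
    frozenset({4}): (_b(4),),
    frozenset({5}): (_b(5),),
    # Two-domain core patterns.
    frozenset({1, 2}): (_b(6),),
    frozenset({1, 3}): (_b(7),),
    frozenset({2, 3}): (_b(8),),
    frozenset({2, 4}): (_b(9),),
    frozenset({3, 4}): (_b(9),),
    frozenset({1, 5}): (_b(10),),
    frozenset({3, 5}): (_b(10),),
    # Two-domain referral rows.
    frozenset({1, 4}): (_b(1, (_M4,), (_ref_step("D1+D4", 1),)),),
    frozenset({2, 5}): (_b(2, (_M5_MOD,), (_ref_step("D2+D5", 2),)),),
    frozenset({4, 5}): (
        _b(4, (_M5_MOD,), (_ref_step("D4+D5", 4),),
           condition=lambda s: s[4] > s[5], condition_label="D4 > D5"),
        _b(5, (_M4,), (_ref_step("D4+D5", 5),),
           condition=lambda s: s[5] > s[4], condition_label="D5 > D4"),
        _b(4, (_M5_MOD,), (_ref_step("D4+D5", 4),),
           condition_label="D4 = D5 (tie)",
           dominance_note="dominance tie D4 = D5; lower-domain precedence -> #4"),
    ),
    # Three-domain core patterns.
    frozenset({1, 2, 3}): (_b(11),),
    frozenset({2, 3, 4}): (_b(12),),
    frozenset({1, 3, 4}): (_b(13),),
    frozenset({1, 2, 5}): (_b(14),),
    frozenset({1, 3, 5}): (_b(14),),
    # Three-domain referral rows.
    frozenset({1, 2, 4}): (_b(6, (_M4,), (_ref_step("D1+D2+D4", 6),)),),
    frozenset({2, 3, 5}): (_b(8, (_M5,), (_ref_step("D2+D3+D5", 8),)),),
    frozenset({1, 4, 5}): (_b(10, (_M4,), (_ref_step("D1+D4+D5", 10),)),),
    frozenset({3, 4, 5}): (_b(10, (_M4,), (_ref_step("D3+D4+D5", 10),)),),
    frozenset({2, 4, 5}): (
        _b(5, (_M2, _M4), (_ref_step("D2+D4+D5", 5),),
           condition=lambda s: s[5] > s[2], condition_label="D5 > D2"),
        _b(2, (_M5, _M4), (_ref_step("D2+D4+D5", 2),),
           condition_label="D5 <= D2"),
    ),
    # Four-domain referral rows.
    frozenset({1, 2, 3, 4}): (_b(11, (_M4,), (_ref_step("D1+D2+D3+D4", 11),)),),
    frozenset({1, 2, 3, 5}): (_b(11, (_M5,), (_ref_step("D1+D2+D3+D5", 11),)),),
    frozenset({1, 2, 4, 5}): (
        _b(14, (_M4,),
           ("referral: D1+D2+D4+D5 -> three-domain pattern D1+D2+D5",
            _ref_step("D1+D2+D5", 14))),
    ),
    frozenset({1, 3, 4, 5}): (
        _b(14, (_M4,),
           ("referral: D1+D3+D4+D5 -> three-domain pattern D1+D3+D5",
            _ref_step("D1+D3+D5", 14))),
    ),
    frozenset({2, 3, 4, 5}): (_b(8, (_M4, _M5), (_ref_step("D2+D3+D4+D5", 8),)),),
    # Five-domain referral row.
    frozenset({1, 2, 3, 4, 5}): (
        _b(11, (_M4, _M5), (_ref_step("D1+D2+D3+D4+D5", 11),)),
    ),
}


def _resolve_branch(support: frozenset[int], scores: dict[int, int]) -> _Branch:
    branches = _RULES[support]
    for branch in branches:
        if branch.condition is None or branch.condition(scores):
            return branch
    raise AssertionError("branch list must terminate with an unconditional default")


def assign_archetype(pattern: DomainPattern) -> ArchetypeAssignment:
    """Map the pattern of non-zero, scorable domains to an archetype."""
    support = pattern.support
    flags = tuple(
        f"core domain {d} not scorable - interpretive limitation"
        for d in sorted(pattern.ns_domains)
        if d <= 3
    )
    if not support:
        return ArchetypeAssignment(
            ref_no=None, mechanistic_class=NO_ARCHETYPE_LABEL,
            core_domains=(), modifier_domains=(), flags=flags,
        )
    scores = {d: (s if s is not None else 0) for d, s in pattern.scores.items()}
    branch = _resolve_branch(support, scores)
    modifier_domains = tuple(
        ModifierTag(domain=d, role=r) for d, r in sorted(branch.modifiers)
    )
    core = tuple(sorted(support - {d for d, _ in branch.modifiers}))
    return ArchetypeAssignment(
        ref_no=branch.ref_no,
        mechanistic_class=CORE_ARCHETYPES[branch.ref_no],
        core_domains=core,
        modifier_domains=modifier_domains,
        referral_trail=branch.trail,
        dominance_note=branch.dominance_note,
        flags=flags,
    )


class ArchetypeMapRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    subset: tuple[int, ...]
    condition: str
    ref_no: int
    mechanistic_class: str
    modifiers: tuple[ModifierTag, ...]
    referral_hops: int


def _all_subsets() -> list[frozenset[int]]:
    domains = (1, 2, 3, 4, 5)
    return [
        frozenset(c)
        for c in chain.from_iterable(combinations(domains, k) for k in range(1, 6))
    ]


def enumerate_archetype_map() -> list[ArchetypeMapRow]:
    """Audit export: every non-empty subset with its resolution(s),
    including conditional branches."""
    rows: list[ArchetypeMapRow] = []
    for subset in sorted(_all_subsets(), key=lambda s: (len(s), sorted(s))):
        for branch in _RULES[subset]:
            rows.append(
                ArchetypeMapRow(
                    subset=tuple(sorted(subset)),
                    condition=branch.condition_label,
                    ref_no=branch.ref_no,
                    mechanistic_class=CORE_ARCHETYPES[branch.ref_no],
                    modifiers=tuple(
                        ModifierTag(domain=d, role=r) for d, r in sorted(branch.modifiers)
                    ),
                    referral_hops=branch.hops,
                )
            )
    return rows
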