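"""Social-support codebook and tally/proportion computation.

Coded communications (posts, comments, polls) carry up to three rubric
codes.  The rubric is a three-level social-support taxonomy: a direction
(seeking support, providing support, or neither), five support categories
(informational, emotional, esteem-related, network, tangible), and within
each category a set of third-level codes (advice, referral, sympathy,
compliment, ...).  A disjoint set of non-support codes covers socializing,
administrative traffic, banter, and the like.

Tallies count *code applications*: a communication carrying three codes
contributes three.  Conservation invariants (category counts sum to the
support count; third-level counts sum to their category) hold by
construction and are re-checked on every tally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .io_model import CodeAssignment

__all__ = [
    "SupportTaxonomy",
    "DEFAULT_TAXONOMY",
    "CodeTally",
    "tally",
    "proportions",
    "round_half_up",
]

DIRECTIONS = ("seeking_support", "providing_support", "neither")

_THIRD_LEVEL = {
    "informational": (
        "advice",
        "referral",
        "situational_appraisal",
        "teaching",
        "other_informational",
    ),
    "emotional": (
        "relationship",
        "physical_affection",
        "confidentiality",
        "sympathy",
        "empathy",
        "encouragement",
        "prayer",
        "other_emotional",
    ),
    "esteem_related": ("compliment", "validation", "relief_of_blame", "other_esteem"),
    "network": ("access", "presence", "companionship", "other_network"),
    "tangible": (
        "loan",
        "perform_direct_task",
        "perform_indirect_task",
        "active_participation",
        "express_willingness",
        "other_tangible",
    ),
}

_OTHER_CODES = (
    "socializing",
    "conversation_starters",
    "administrative",
    "gratitude",
    "banter_memes",
    "research",
    "congratulations",
    "group_cohesion",
    "negative_interaction",
    "community_protection",
    "nonverbal_cues",
    "miscellaneous",
)


@dataclass(frozen=True)
class SupportTaxonomy:
    directions: tuple = DIRECTIONS
    third_level: Mapping[str, tuple] = field(default_factory=lambda: dict(_THIRD_LEVEL))
    other_codes: tuple = _OTHER_CODES

    def __post_init__(self) -> None:
        seen: dict = {}
        for cat, codes in self.third_level.items():
            for c in codes:
                if c in seen:
                    raise ValueError(f"code {c!r} in both {seen[c]!r} and {cat!r}")
                seen[c] = cat
        overlap = set(seen) & set(self.other_codes)
        if overlap:
            raise ValueError(f"other_codes overlap support codes: {sorted(overlap)}")

    @property
    def categories(self) -> tuple:
        return tuple(self.third_level)

    def category_of(self, code: str) -> Optional[str]:
        for cat, codes in self.third_level.items():
            if code in codes:
                return cat
        return None

    def is_support(self, code: str) -> bool:
        return self.category_of(code) is not None

    def all_codes(self) -> tuple:
        return tuple(c for codes in self.third_level.values() for c in codes) + tuple(
            self.other_codes
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "directions": list(self.directions),
            "categories": {cat: list(codes) for cat, codes in self.third_level.items()},
            "other_codes": list(self.other_codes),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


DEFAULT_TAXONOMY = SupportTaxonomy()


@dataclass
class CodeTally:
    total_codes: int
    support_codes: int
    nonsupport_codes: int
    by_direction: dict
    by_category: dict
    by_third_level: dict

    def check(self) -> "CodeTally":
        if self.support_codes + self.nonsupport_codes != self.total_codes:
            raise AssertionError("support + nonsupport != total")
        if sum(self.by_category.values()) != self.support_codes:
            raise AssertionError("category counts do not sum to support count")
        for cat, n in self.by_category.items():
            got = sum(v for (c, _), v in self.by_third_level.items() if c == cat)
            if got != n:
                raise AssertionError(f"third-level counts for {cat!r} sum to {got}, not {n}")
        return self


def tally(
    assignments: Iterable[CodeAssignment],
    taxonomy: SupportTaxonomy = DEFAULT_TAXONOMY,
) -> CodeTally:
    """Count every applied code exactly once, in assignment-order-invariant
    fashion.  Support-code applications inherit the assignment's direction.
    Unknown codes raise."""
    total = support = nonsupport = 0
    by_dir = {d: 0 for d in taxonomy.directions}
    by_cat = {c: 0 for c in taxonomy.categories}
    by_third: dict = {}
    for a in assignments:
        for code in a.codes:
            cat = taxonomy.category_of(code)
            if cat is None and code not in taxonomy.other_codes:
                raise ValueError(f"unknown code {code!r}")
            total += 1
            if cat is None:
                nonsupport += 1
                continue
            support += 1
            by_cat[cat] += 1
            key = (cat, code)
            by_third[key] = by_third.get(key, 0) + 1
            if a.direction in by_dir:
                by_dir[a.direction] += 1
    return CodeTally(
        total_codes=total,
        support_codes=support,
        nonsupport_codes=nonsupport,
        by_direction=by_dir,
        by_category=by_cat,
        by_third_level=by_third,
    ).check()


def round_half_up(x: float, places: int) -> float:
    """Decimal half-up rounding (printed proportions use this convention)."""
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def proportions(tally_: CodeTally, rounding: int = 1) -> dict:
    """Named percentage shares: support/non-support of all codes, category
    and direction shares of support codes.  Zero denominators yield None
    (reported, not raised)."""

    def pct(num: int, den: int) -> Optional[float]:
        if den == 0:
            return None
        return round_half_up(100.0 * num / den, rounding)

    total = tally_.total_codes
    sup = tally_.support_codes
    out = {
        "support_share_of_total": pct(sup, total),
        "nonsupport_share_of_total": pct(tally_.nonsupport_codes, total),
        "category_share_of_support": {
            cat: pct(n, sup) for cat, n in tally_.by_category.items()
        },
        "direction_share_of_support": {
            d: pct(n, sup) for d, n in tally_.by_direction.items()
        },
        "third_level_share_of_category": {
            f"{cat}:{code}": pct(n, tally_.by_category[cat])
            for (cat, code), n in sorted(tally_.by_third_level.items())
        },
    }
    return out
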