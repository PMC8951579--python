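"""Config-driven Lung-RADS category assignment.

Lung-RADS screening-management categories are assigned by an ordered rule
table over (texture, margin, size) rather than by a learned model: the
standard is revised from time to time, and a data-driven table can simply
be replaced when a new version appears.  The shipped default transcribes the
ACR Lung-RADS v1.1 baseline size cut-offs into a branch structure where
texture decides the path and margin matters only for subsolid nodules.

Load-time validation enforces two global properties so lookup can never
fail or be ambiguous: totality (every texture × margin × positive size
combination matches at least one rule) and determinism (overlapping rules
must agree on the category; the first match wins).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources
from math import inf
from pathlib import Path
from typing import Optional, Union

import yaml

from .schema import MarginLabel, TextureLabel

__all__ = [
    "LungRADSCategory",
    "Rule",
    "RuleTable",
    "RuleTableError",
    "load_rule_table",
    "default_rule_table",
    "assign_category",
    "enumerate_truth_table",
]


class RuleTableError(ValueError):
    """Rule table fails parsing, totality, or determinism validation."""


class LungRADSCategory(enum.Enum):
    """Supported output categories (baseline exam, no priors needed)."""

    CAT_2 = "2"
    CAT_3 = "3"
    CAT_4A = "4A"
    CAT_4B = "4B"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, token: str) -> "LungRADSCategory":
        key = str(token).strip().upper()
        for member in cls:
            if key == member.value:
                return member
        raise RuleTableError(f"unknown Lung-RADS category {token!r}")


#: ordering used by the monotonicity property (2 < 3 < 4A < 4B)
CATEGORY_ORDER = {c: i for i, c in enumerate(LungRADSCategory)}


@dataclass(frozen=True)
class Rule:
    """One row: texture subset × margin subset (or wildcard) × size interval."""

    texture_set: frozenset
    margin_set: Optional[frozenset]  # None = wildcard (any margin)
    size_lo: float
    size_hi: float  # exclusive; may be +inf
    category: LungRADSCategory

    def matches(self, texture: TextureLabel, margin: MarginLabel,
                size_mm: float) -> bool:
        if texture not in self.texture_set:
            return False
        if self.margin_set is not None and margin not in self.margin_set:
            return False
        return self.size_lo <= size_mm < self.size_hi


@dataclass(frozen=True)
class RuleTable:
    """Validated, ordered Lung-RADS rule list."""

    version: str
    rules: tuple[Rule, ...]


def _parse_rule(raw: dict, index: int) -> Rule:
    try:
        textures = frozenset(TextureLabel.parse(t) for t in raw["texture"])
        margin_raw = raw["margin"]
        margins = (None if margin_raw in ("*", None)
                   else frozenset(MarginLabel.parse(m) for m in margin_raw))
        lo, hi = raw["size"]
        lo = float(lo)
        hi = inf if hi is None else float(hi)
        category = LungRADSCategory.parse(raw["category"])
    except (KeyError, TypeError, ValueError) as exc:
        raise RuleTableError(f"rule {index}: {exc}") from exc
    if not textures:
        raise RuleTableError(f"rule {index}: empty texture set")
    if margins is not None and not margins:
        raise RuleTableError(f"rule {index}: empty margin set (use '*' for any)")
    if not lo < hi:
        raise RuleTableError(f"rule {index}: size interval [{lo}, {hi}) is empty")
    return Rule(textures, margins, lo, hi, category)


def _validate_table(table: RuleTable) -> None:
    """Totality and determinism over the full combinatorial domain.

    Size intervals partition (0, ∞) into finitely many cells via the sorted
    rule boundaries, so checking one probe size per cell is exhaustive.
    """
    bounds = sorted({0.0} | {b for r in table.rules for b in (r.size_lo, r.size_hi)
                            if b != inf})
    probes = [(max(lo, 0.0) + hi) / 2 for lo, hi in zip(bounds, bounds[1:]) if hi > 0]
    probes.append(bounds[-1] + 1.0)
    probes.extend(b for b in bounds if b > 0)  # exact boundary points

    for texture, margin in itertools.product(TextureLabel, MarginLabel):
        for size in probes:
            matches = [r for r in table.rules if r.matches(texture, margin, size)]
            if not matches:
                raise RuleTableError(
                    f"totality violation: no rule covers "
                    f"({texture.value}, {margin.value}, {size:g} mm)"
                )
            categories = {r.category for r in matches}
            if len(categories) > 1:
                raise RuleTableError(
                    f"determinism violation: ({texture.value}, {margin.value}, "
                    f"{size:g} mm) matches conflicting categories "
                    f"{sorted(c.value for c in categories)}"
                )


def load_rule_table(path: Union[str, Path]) -> RuleTable:
    """Parse and validate a YAML/JSON rule table file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "rules" not in raw:
        raise RuleTableError("rule file must be a mapping with a 'rules' list")
    rules = tuple(_parse_rule(r, i) for i, r in enumerate(raw["rules"]))
    if not rules:
        raise RuleTableError("rule table has no rules")
    table = RuleTable(version=str(raw.get("version", "unversioned")), rules=rules)
    _validate_table(table)
    return table


def default_rule_table() -> RuleTable:
    """The shipped v1.1-baseline default table."""
    ref = resources.files("lungreport.data") / "lungrads_v11_default.yaml"
    with resources.as_file(ref) as path:
        return load_rule_table(path)


def assign_category(
    texture: TextureLabel,
    margin: MarginLabel,
    size_mm: float,
    table: RuleTable,
) -> LungRADSCategory:
    """Category of the first matching rule; raises on nonpositive size."""
    if not size_mm > 0:
        raise ValueError(f"size_mm must be positive, got {size_mm}")
    for rule in table.rules:
        if rule.matches(texture, margin, size_mm):
            return rule.category
    raise RuntimeError(  # unreachable for a validated table
        f"no rule matches ({texture.value}, {margin.value}, {size_mm} mm)"
    )


def enumerate_truth_table(
    table: RuleTable,
    size_grid: list[float],
) -> list[tuple[TextureLabel, MarginLabel, float, LungRADSCategory]]:
    """Exhaustive (texture × margin × size) → category listing.

    Brute-force companion to :func:`assign_category`, used for validation,
    documentation, and as a test oracle.
    """
    if not size_grid:
        raise ValueError("size grid must be nonempty")
    if any(not s > 0 for s in size_grid):
        raise ValueError("size grid entries must be positive")
    return [
        (texture, margin, float(size), assign_category(texture, margin, size, table))
        for texture in TextureLabel
        for margin in MarginLabel
        for size in size_grid
    ]
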