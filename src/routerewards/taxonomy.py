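"""Hierarchical reaction-class codes and the edit-cost scheme built on them.

Reaction steps in a retrosynthetic route are labeled with codes from a
three-level taxonomy: superclass ``X``, class ``X.Y`` and named reaction
``X.Y.Z`` (for example ``3.1.2 Chloro Suzuki coupling``).  Route
signatures are sets of such codes truncated to a chosen level, and the
rename cost used by the tree edit distance depends on the shallowest
level at which two codes disagree: superclass disagreement is the most
expensive rename, a named-reaction swap within the same class the
cheapest.

Codes that could not be classified are represented by the sentinel
:data:`UNRECOGNIZED` (rendered ``0.0``), which differs from every real
code at the superclass level and equals only itself.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path


class TaxonomyError(ValueError):
    """Raised for malformed reaction codes or invalid truncations."""


class SignatureLevel(enum.IntEnum):
    """Depth of the reaction taxonomy at which codes are compared."""

    SUPERCLASS = 1
    CLASS = 2
    NAMED = 3


@dataclass(frozen=True, slots=True)
class ReactionCode:
    """A hierarchical reaction label ``X``, ``X.Y`` or ``X.Y.Z``.

    The optional ``display`` text (the human-readable reaction name) is
    carried along but excluded from equality and hashing, so codes
    compare purely on their numeric identity.
    """

    superclass: int
    class_id: int | None = None
    named_id: int | None = None
    display: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.superclass < 0:
            raise TaxonomyError(f"negative superclass in {self!r}")
        if self.named_id is not None and self.class_id is None:
            raise TaxonomyError("named reaction id requires a class id")

    @property
    def depth(self) -> int:
        if self.named_id is not None:
            return 3
        if self.class_id is not None:
            return 2
        return 1

    @property
    def is_unrecognized(self) -> bool:
        return self.superclass == 0

    def render(self) -> str:
        parts = [str(self.superclass)]
        if self.class_id is not None:
            parts.append(str(self.class_id))
        if self.named_id is not None:
            parts.append(str(self.named_id))
        return ".".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


#: Sentinel for reactions the classifier could not assign a real code.
UNRECOGNIZED = ReactionCode(0, 0)


def parse_code(text: str) -> ReactionCode:
    """Parse ``"X[.Y[.Z]] [name]"`` into a :class:`ReactionCode`.

    Any text after the first whitespace is kept as the display name.
    """
    stripped = text.strip()
    if not stripped:
        raise TaxonomyError("empty reaction code")
    head, _, rest = stripped.partition(" ")
    parts = head.split(".")
    if not 1 <= len(parts) <= 3 or not all(p.isdigit() for p in parts):
        raise TaxonomyError(f"malformed reaction code: {text!r}")
    nums = [int(p) for p in parts]
    return ReactionCode(
        nums[0],
        nums[1] if len(nums) > 1 else None,
        nums[2] if len(nums) > 2 else None,
        display=rest.strip() or None,
    )


def truncate(code: ReactionCode, level: SignatureLevel) -> ReactionCode:
    """Drop components deeper than ``level``.

    Truncating to a level deeper than the code itself is an error: a
    class-level code carries no named-reaction information to expose.
    """
    if code.depth < int(level):
        raise TaxonomyError(
            f"cannot truncate {code.render()!r} (depth {code.depth}) "
            f"to level {level.name}"
        )
    if code.depth == int(level):
        return code
    if level is SignatureLevel.SUPERCLASS:
        return ReactionCode(code.superclass)
    return ReactionCode(code.superclass, code.class_id)


@dataclass(frozen=True, slots=True)
class TedCostScheme:
    """Edit costs for the route-tree edit distance.

    Deleting or inserting a reaction node costs 4.0; renames are scaled
    by the taxonomic depth of the first disagreement so that a rename is
    always cheaper than a delete+insert pair.
    """

    delete_cost: float = 4.0
    insert_cost: float = 4.0
    rename_superclass: float = 3.0
    rename_class: float = 2.0
    rename_named: float = 1.0

    def __post_init__(self) -> None:
        costs = (
            self.delete_cost,
            self.insert_cost,
            self.rename_superclass,
            self.rename_class,
            self.rename_named,
        )
        if any(c < 0 for c in costs):
            raise TaxonomyError("edit costs must be non-negative")
        if not self.rename_superclass >= self.rename_class >= self.rename_named:
            raise TaxonomyError("rename costs must not increase with depth")
        if self.rename_superclass > self.delete_cost + self.insert_cost:
            raise TaxonomyError("rename must not exceed delete+insert")


DEFAULT_SCHEME = TedCostScheme()


def rename_cost(
    a: ReactionCode, b: ReactionCode, scheme: TedCostScheme = DEFAULT_SCHEME
) -> float:
    """Cost of relabeling ``a`` as ``b``.

    0 for identical codes; otherwise the cost attached to the shallowest
    level of disagreement.  A component that is absent in one code but
    present in the other counts as a disagreement at that depth; two
    absent components agree.
    """
    if (a.superclass, a.class_id, a.named_id) == (b.superclass, b.class_id, b.named_id):
        return 0.0
    if a.superclass != b.superclass:
        return scheme.rename_superclass
    if a.class_id != b.class_id:
        return scheme.rename_class
    return scheme.rename_named


def load_taxonomy_table(path: str | Path) -> dict[str, str]:
    """Read an optional ``code,name`` CSV of display names."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["code"].strip()] = row["name"].strip()
    return table
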