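"""Per-molecule extrinsic rewards: synthetic feasibility and route similarity.

The synthetic-feasibility score (SFScore) of a single route tree is the
product of three multiplicative factors:

* stock factor — product over leaf precursors of a per-status score
  (internal 1.0, commercial 0.8, unavailable 0.1 by default);
* reaction factor — product over reaction steps (preferred reactions
  1.0, all others 0.1 by default);
* step factor — ``k**n`` with ``0 < k < 1`` (default 0.9) and ``n`` the
  number of reaction steps, so a three-step route contributes 0.729.

A molecule is scored as its highest-scoring tree.  The reference-route
score (RRScore) instead measures how close a molecule's best *solved*
route comes to a predefined reference tree, via the tree edit distance
mapped through a strictly decreasing transform with ``transform(0) = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .route_model import (
    RouteTree,
    StockCatalog,
    StockStatus,
    canonical_reaction_tree,
    count_steps,
)
from .taxonomy import (
    DEFAULT_SCHEME,
    ReactionCode,
    SignatureLevel,
    TedCostScheme,
    truncate,
)
from .ted import OrderedTree, tree_edit_distance


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SFConfig:
    """Factor scores and options for the synthetic-feasibility reward."""

    internal_score: float = 1.0
    commercial_score: float = 0.8
    unavailable_score: float = 0.1
    preferred_reactions: frozenset[ReactionCode] = frozenset()
    preferred_score: float = 1.0
    other_reaction_score: float = 0.1
    step_coefficient: float = 0.9
    use_unsolved: bool = True
    max_steps: int | None = None  # optional score-time route-length filter

    def __post_init__(self) -> None:
        if not 0.0 < self.step_coefficient < 1.0:
            raise ConfigurationError("step coefficient must lie in (0, 1)")
        for name in (
            "internal_score",
            "commercial_score",
            "unavailable_score",
            "preferred_score",
            "other_reaction_score",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1]")


def stock_score(
    tree: RouteTree, catalog: StockCatalog | None, cfg: SFConfig = SFConfig()
) -> float:
    """Product of per-leaf stock scores.

    Statuses are looked up in the catalog at score time (so swapping
    catalogs re-scores correctly); without a catalog the statuses cached
    on the parsed tree are used.
    """
    table = {
        StockStatus.INTERNAL: cfg.internal_score,
        StockStatus.COMMERCIAL: cfg.commercial_score,
        StockStatus.UNAVAILABLE: cfg.unavailable_score,
    }
    score = 1.0
    for leaf in tree.leaves():
        status = catalog.lookup(leaf.mol_id) if catalog is not None else leaf.stock_status
        score *= table[status]
    return score


def is_preferred(code: ReactionCode, preferred: Iterable[ReactionCode]) -> bool:
    """Whether a route code matches any preferred entry.

    Preferred entries may sit at any taxonomy level; a named-level route
    code matches a class-level entry (e.g. ``3.1`` admits every Suzuki
    named reaction).  Unrecognized codes never match.
    """
    if code.is_unrecognized:
        return False
    for pref in preferred:
        if code.depth >= pref.depth and truncate(
            code, SignatureLevel(pref.depth)
        ) == pref:
            return True
    return False


def reaction_score(tree: RouteTree, cfg: SFConfig = SFConfig()) -> float:
    """Product over reaction steps; the empty product (0 steps) is 1."""
    score = 1.0
    for reaction in tree.reaction_nodes():
        score *= (
            cfg.preferred_score
            if is_preferred(reaction.code, cfg.preferred_reactions)
            else cfg.other_reaction_score
        )
    return score


def step_score(n: int, k: float = 0.9) -> float:
    """Exponential step penalty ``k**n``; 1.0 for stock-available targets."""
    if not 0.0 < k < 1.0:
        raise ConfigurationError("step coefficient must lie in (0, 1)")
    if n < 0:
        raise ValueError("step count must be non-negative")
    return k**n


def sfscore_tree(
    tree: RouteTree, catalog: StockCatalog | None, cfg: SFConfig = SFConfig()
) -> float:
    return (
        stock_score(tree, catalog, cfg)
        * reaction_score(tree, cfg)
        * step_score(count_steps(tree), cfg.step_coefficient)
    )


def sfscore_molecule(
    trees: Iterable[RouteTree],
    catalog: StockCatalog | None,
    cfg: SFConfig = SFConfig(),
) -> float:
    """Maximum tree score over the molecule's routes; 0 with no routes."""
    best = 0.0
    for tree in trees:
        if not cfg.use_unsolved and not tree.solved:
            continue
        if cfg.max_steps is not None and count_steps(tree) > cfg.max_steps:
            continue
        best = max(best, sfscore_tree(tree, catalog, cfg))
    return best


@dataclass(frozen=True)
class RRConfig:
    """Reference route and distance-to-similarity transform."""

    reference: OrderedTree
    scheme: TedCostScheme = DEFAULT_SCHEME
    transform: str = "reciprocal"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.reference is None:
            raise ConfigurationError("reference route must be non-empty")
        if self.transform not in ("reciprocal", "exponential"):
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.scale <= 0:
            raise ConfigurationError("transform scale must be positive")


def similarity(distance: float, cfg: RRConfig) -> float:
    """Map a TED value to (0, 1]; 1 at distance 0, strictly decreasing."""
    if cfg.transform == "reciprocal":
        return 1.0 / (1.0 + distance / cfg.scale)
    return math.exp(-distance / cfg.scale)


def best_reference_distance(
    trees: Iterable[RouteTree], cfg: RRConfig
) -> float | None:
    """Minimum TED to the reference over solved routes; None if none solved."""
    best: float | None = None
    for tree in trees:
        if not tree.solved:
            continue
        d = tree_edit_distance(canonical_reaction_tree(tree), cfg.reference, cfg.scheme)
        if best is None or d < best:
            best = d
    return best


def rrscore_molecule(trees: Iterable[RouteTree], cfg: RRConfig) -> float:
    """Maximum reference-route similarity over solved routes; 0 if none."""
    d = best_reference_distance(trees, cfg)
    return 0.0 if d is None else similarity(d, cfg)
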