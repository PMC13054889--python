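"""Shared fixtures: hand-built routes, catalogs and random tree factories."""

from __future__ import annotations

import numpy as np
import pytest

from routerewards.route_model import (
    MoleculeNode,
    MoleculeRecord,
    ReactionNode,
    RouteTree,
    StockCatalog,
    StockStatus,
)
from routerewards.taxonomy import parse_code
from routerewards.ted import OrderedTree


def leaf(mol_id: str, status: str = "internal") -> MoleculeNode:
    return MoleculeNode(MoleculeRecord(mol_id, StockStatus(status)))


def reaction(code_text: str, *children: MoleculeNode) -> ReactionNode:
    """A reaction node; unparseable text becomes the unrecognized sentinel."""
    from routerewards.route_model import _parse_classification

    code, raw = _parse_classification(code_text)
    return ReactionNode(code, raw, list(children))


def route(root_id: str, rnode: ReactionNode | None = None) -> RouteTree:
    tree = RouteTree(MoleculeNode(MoleculeRecord(root_id), rnode))
    tree.solved = all(
        r.stock_status is not StockStatus.UNAVAILABLE for r in tree.leaves()
    )
    return tree


def linear_route(
    root_id: str,
    codes: list[str],
    leaf_status: str = "internal",
    solved: bool = True,
) -> RouteTree:
    """A linear chain route; each step has one extra stock precursor."""
    inner: MoleculeNode | None = None
    for depth, text in enumerate(reversed(codes)):
        children = [inner] if inner is not None else []
        while len(children) < 2:
            status = leaf_status if solved else "unavailable"
            children.append(leaf(f"L{root_id}-{depth}-{len(children)}", status))
        target = (
            MoleculeRecord(root_id)
            if depth == len(codes) - 1
            else MoleculeRecord(f"I{root_id}-{depth}")
        )
        inner = MoleculeNode(target, reaction(text, *children))
    assert inner is not None
    return route(root_id, inner.reaction)


def chain_tree(*code_texts: str) -> OrderedTree:
    """An ordered reaction tree that is a simple labeled chain."""
    tree: OrderedTree | None = None
    for text in reversed(code_texts):
        tree = OrderedTree(parse_code(text), (tree,) if tree else ())
    assert tree is not None
    return tree


def random_tree(rng: np.random.Generator, max_nodes: int = 6) -> OrderedTree | None:
    """A random small labeled tree (possibly empty) for oracle comparison."""
    n = int(rng.integers(0, max_nodes + 1))
    if n == 0:
        return None
    labels = [
        parse_code(
            f"{int(rng.integers(1, 4))}.{int(rng.integers(1, 3))}"
            f".{int(rng.integers(1, 4))}"
        )
        for _ in range(n)
    ]
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[int(rng.integers(i))].append(i)

    def build(i: int) -> OrderedTree:
        return OrderedTree(labels[i], tuple(build(c) for c in children[i]))

    return build(0)


@pytest.fixture
def catalog() -> StockCatalog:
    return StockCatalog(
        {
            "A": StockStatus.INTERNAL,
            "B": StockStatus.INTERNAL,
            "C": StockStatus.COMMERCIAL,
        }
    )
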