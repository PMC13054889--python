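"""Tree edit distance between canonical reaction trees.

Routes are compared as ordered, labeled trees of reaction codes
(molecule nodes are elided beforehand and child order is made
deterministic by canonical sorting, so ordered TED is well defined on
chemically identical routes).  :func:`tree_edit_distance` is the
Zhang–Shasha dynamic program, exact for ordered labeled trees under
unit-independent delete/insert costs and the hierarchical rename costs
of :class:`~routerewards.taxonomy.TedCostScheme`.

:func:`brute_force_ted` enumerates every valid edit mapping (the
ancestor- and sibling-order-preserving partial matchings that define
TED) and is intended purely as an independent oracle on tiny trees.
"""

from __future__ import annotations

from dataclasses import dataclass

from .taxonomy import DEFAULT_SCHEME, ReactionCode, TedCostScheme, rename_cost


@dataclass(frozen=True, slots=True)
class OrderedTree:
    """An ordered labeled tree; the empty tree is represented by ``None``."""

    label: ReactionCode
    children: tuple["OrderedTree", ...] = ()

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)


def tree_size(tree: OrderedTree | None) -> int:
    return 0 if tree is None else tree.size()


def _annotate(root: OrderedTree) -> tuple[list[ReactionCode], list[int]]:
    """Postorder labels and leftmost-leaf indices (Zhang–Shasha tables)."""
    labels: list[ReactionCode] = []
    lml: list[int] = []

    def rec(node: OrderedTree) -> int:
        child_first = [rec(c) for c in node.children]
        idx = len(labels)
        labels.append(node.label)
        lml.append(child_first[0] if child_first else idx)
        return lml[idx]

    rec(root)
    return labels, lml


def _keyroots(lml: list[int]) -> list[int]:
    seen: set[int] = set()
    roots: list[int] = []
    for i in range(len(lml) - 1, -1, -1):
        if lml[i] not in seen:
            roots.append(i)
            seen.add(lml[i])
    roots.reverse()
    return roots


def tree_edit_distance(
    t1: OrderedTree | None,
    t2: OrderedTree | None,
    scheme: TedCostScheme = DEFAULT_SCHEME,
) -> float:
    """Exact minimum-cost ordered tree edit distance.

    Symmetric whenever ``delete_cost == insert_cost``; either argument
    may be ``None`` (the empty tree), in which case the distance is the
    cost of inserting or deleting the other tree wholesale.
    """
    if t1 is None and t2 is None:
        return 0.0
    if t1 is None:
        return scheme.insert_cost * t2.size()  # type: ignore[union-attr]
    if t2 is None:
        return scheme.delete_cost * t1.size()

    lab1, l1 = _annotate(t1)
    lab2, l2 = _annotate(t2)
    n, m = len(lab1), len(lab2)
    dc, ic = scheme.delete_cost, scheme.insert_cost
    td = [[0.0] * m for _ in range(n)]

    for i in _keyroots(l1):
        for j in _keyroots(l2):
            li, lj = l1[i], l2[j]
            rows, cols = i - li + 2, j - lj + 2
            fd = [[0.0] * cols for _ in range(rows)]
            for di in range(1, rows):
                fd[di][0] = fd[di - 1][0] + dc
            for dj in range(1, cols):
                fd[0][dj] = fd[0][dj - 1] + ic
            for di in range(1, rows):
                i1 = li + di - 1
                for dj in range(1, cols):
                    j1 = lj + dj - 1
                    if l1[i1] == li and l2[j1] == lj:
                        fd[di][dj] = min(
                            fd[di - 1][dj] + dc,
                            fd[di][dj - 1] + ic,
                            fd[di - 1][dj - 1]
                            + rename_cost(lab1[i1], lab2[j1], scheme),
                        )
                        td[i1][j1] = fd[di][dj]
                    else:
                        fd[di][dj] = min(
                            fd[di - 1][dj] + dc,
                            fd[di][dj - 1] + ic,
                            fd[l1[i1] - li][l2[j1] - lj] + td[i1][j1],
                        )
    return td[n - 1][m - 1]


def brute_force_ted(
    t1: OrderedTree | None,
    t2: OrderedTree | None,
    scheme: TedCostScheme = DEFAULT_SCHEME,
    max_nodes: int = 7,
) -> float:
    """Minimum cost over all valid edit mappings, by exhaustive search.

    A mapping is a partial one-to-one node matching that preserves
    postorder (sibling) order and the ancestor relation; its cost is the
    sum of rename costs over matched pairs plus delete/insert costs for
    unmatched nodes.  Refuses trees larger than ``max_nodes`` — this is
    a test oracle, not a production path.
    """
    n1, n2 = tree_size(t1), tree_size(t2)
    if n1 > max_nodes or n2 > max_nodes:
        raise ValueError(f"oracle limited to {max_nodes} nodes per tree")
    if n1 == 0 or n2 == 0:
        return scheme.delete_cost * n1 + scheme.insert_cost * n2

    lab1, l1 = _annotate(t1)  # type: ignore[arg-type]
    lab2, l2 = _annotate(t2)  # type: ignore[arg-type]
    base = scheme.delete_cost * n1 + scheme.insert_cost * n2
    best = [base]
    pairs: list[tuple[int, int]] = []

    def compatible(i: int, j: int) -> bool:
        # i strictly ancestor of k iff l1[i] <= k < i (postorder indexing);
        # matched pairs must agree on that relation on both sides.
        for i2, j2 in pairs:
            if (l1[i] <= i2) != (l2[j] <= j2):
                return False
        return True

    def search(i: int, min_j: int, delta: float) -> None:
        if base + delta < best[0]:
            best[0] = base + delta
        if i == len(lab1):
            return
        search(i + 1, min_j, delta)
        for j in range(min_j, len(lab2)):
            if compatible(i, j):
                pairs.append((i, j))
                gain = (
                    rename_cost(lab1[i], lab2[j], scheme)
                    - scheme.delete_cost
                    - scheme.insert_cost
                )
                search(i + 1, j + 1, delta + gain)
                pairs.pop()

    search(0, 0, 0.0)
    return best[0]
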