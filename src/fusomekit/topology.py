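"""Cell lineage trees of germline cysts.

A germline cyst is modelled as an unrooted tree: nodes are cells, edges are
ring canals (intercellular bridges) left behind by incomplete cytokinesis.
Starting from a single founder cell, each round of synchronous division
replaces every cell by two daughters joined by a new ring canal; the mother's
existing canals are partitioned between the daughters.  In the female cyst
every division buds a new terminal cell, producing the unique "maximally
branched" tree; in males, internal cells may instead divide "in line",
splitting their canals between two internal daughters and breaking maximal
branching.

This module provides the canonical female trees, the division operator, the
enumeration of reachable topologies up to isomorphism, and a polynomial
subtree-embedding test used to flag male fusome fragments whose connectivity
is incompatible with a maximally branched cyst.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "CystTree",
    "InvalidTreeError",
    "InvalidSizeError",
    "InconsistentChoiceError",
    "SizeLimitError",
    "EnumerationResult",
    "canonical_max_branched",
    "division_choices",
    "divide_all",
    "trees_isomorphic",
    "canonical_key",
    "enumerate_topologies",
    "is_max_branched",
    "is_embeddable",
    "random_division_tree",
]

Edge = Tuple[int, int]


class InvalidTreeError(ValueError):
    """Raised when a node/edge set does not form a connected acyclic graph."""


class InvalidSizeError(ValueError):
    """Raised for cyst sizes that are not a power of two <= 16."""


class InconsistentChoiceError(ValueError):
    """Raised when a division choice references canals not incident to its cell."""


class SizeLimitError(ValueError):
    """Raised when exhaustive enumeration is requested beyond 8 starting cells."""


def _edge(a: int, b: int) -> Edge:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CystTree:
    """Unrooted cyst lineage tree: cells (nodes) joined by ring canals (edges).

    ``labels`` optionally maps nodes to canonical cell numbers 1..n; it does
    not participate in equality or hashing.
    """

    cells: FrozenSet[int]
    canals: FrozenSet[Edge]
    labels: Optional[Tuple[Tuple[int, int], ...]] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.cells:
            raise InvalidTreeError("tree must contain at least one cell")
        for a, b in self.canals:
            if a not in self.cells or b not in self.cells:
                raise InvalidTreeError(f"canal ({a},{b}) references unknown cell")
            if a == b:
                raise InvalidTreeError("self-loop canal")
        if len(self.canals) != len(self.cells) - 1:
            raise InvalidTreeError(
                f"{len(self.cells)} cells need {len(self.cells) - 1} canals, "
                f"got {len(self.canals)}"
            )
        # connectivity (acyclicity follows from the edge count)
        adj = self.adjacency()
        seen = {next(iter(self.cells))}
        stack = list(seen)
        while stack:
            for u in adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if seen != self.cells:
            raise InvalidTreeError("tree is not connected")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def adjacency(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {c: [] for c in self.cells}
        for a, b in self.canals:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def incident(self, cell: int) -> FrozenSet[Edge]:
        return frozenset(e for e in self.canals if cell in e)

    def degree(self, cell: int) -> int:
        return sum(1 for e in self.canals if cell in e)

    def degree_sequence(self) -> Tuple[int, ...]:
        return tuple(sorted((self.degree(c) for c in self.cells), reverse=True))

    def neighbors(self, cell: int) -> List[int]:
        return self.adjacency()[cell]

    # -- constructors / export --------------------------------------------

    @staticmethod
    def from_edges(edges: Iterable[Sequence[int]], cells: Optional[Iterable[int]] = None,
                   labels: Optional[Mapping[int, int]] = None) -> "CystTree":
        canals = frozenset(_edge(int(a), int(b)) for a, b in edges)
        node_set = set()
        for a, b in canals:
            node_set.update((a, b))
        if cells is not None:
            node_set.update(int(c) for c in cells)
        lab = tuple(sorted((int(k), int(v)) for k, v in labels.items())) if labels else None
        return CystTree(frozenset(node_set), canals, lab)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.cells)
        g.add_edges_from(self.canals)
        return g

    def to_json(self) -> str:
        obj = {
            "cells": sorted(self.cells),
            "canals": sorted([list(e) for e in self.canals]),
        }
        if self.labels is not None:
            obj["labels"] = {str(k): v for k, v in self.labels}
        return json.dumps(obj, indent=1)

    @staticmethod
    def from_json(text: str) -> "CystTree":
        obj = json.loads(text)
        labels = {int(k): int(v) for k, v in obj.get("labels", {}).items()} or None
        return CystTree.from_edges(obj["canals"], cells=obj["cells"], labels=labels)

    def newick(self, root: Optional[int] = None) -> str:
        """Rooted Newick-like export for display (default root: lowest cell id)."""
        root = min(self.cells) if root is None else root
        adj = self.adjacency()

        def rec(v: int, parent: Optional[int]) -> str:
            kids = [rec(u, v) for u in sorted(adj[v]) if u != parent]
            return (f"({','.join(kids)}){v}" if kids else str(v))

        return rec(root, None) + ";"


# ---------------------------------------------------------------------------
# canonical female trees and the division operator
# ---------------------------------------------------------------------------

def canonical_max_branched(n_cells: int) -> CystTree:
    """The unique maximally branched cyst tree with canonical labels.

    Convention: at division round k, cell i (1 <= i <= 2**(k-1)) buds daughter
    i + 2**(k-1); the mother retains all of its existing ring canals.  The two
    cells with the most canals (the pro-oocytes at n=16) are cells 1 and 2.
    """
    if n_cells not in (1, 2, 4, 8, 16):
        raise InvalidSizeError(f"cyst size must be a power of 2 <= 16, got {n_cells}")
    edges = []
    n = 1
    while n < n_cells:
        edges.extend((i, i + n) for i in range(1, n + 1))
        n *= 2
    labels = {i: i for i in range(1, n_cells + 1)}
    return CystTree.from_edges(edges, cells=range(1, n_cells + 1), labels=labels)


def division_choices(tree: CystTree, cell: int) -> List[FrozenSet[Edge]]:
    """All distinct ways ``cell`` can partition its canals between daughters.

    A choice is represented by the canal subset retained by the daughter that
    keeps the mother's identity; the unordered partition is enumerated once by
    fixing which side receives the lexicographically smallest incident canal.
    A degree-d cell has 2**(d-1) choices; retaining *all* canals is the
    branching choice (the other daughter is a new terminal cell).
    """
    inc = sorted(tree.incident(cell))
    if not inc:
        return [frozenset()]
    first, rest = inc[0], inc[1:]
    out = []
    for r in range(len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            out.append(frozenset((first,) + combo))
    return out


def divide_all(tree: CystTree, choices: Mapping[int, Iterable[Edge]]) -> CystTree:
    """One synchronous round of divisions.

    Every cell c is replaced by daughters c and c+N (N = max cell id) joined
    by a new canal; c keeps the canals in ``choices[c]`` and c+N inherits the
    rest.  The result has 2*|cells| nodes and is again a tree.
    """
    if set(choices) != set(tree.cells):
        missing = set(tree.cells) - set(choices)
        extra = set(choices) - set(tree.cells)
        raise InconsistentChoiceError(f"choices missing={missing} extra={extra}")
    offset = max(tree.cells)
    kept: Dict[int, FrozenSet[Edge]] = {}
    for c, sel in choices.items():
        sel = frozenset(_edge(*e) for e in sel)
        if not sel <= tree.incident(c):
            raise InconsistentChoiceError(
                f"cell {c}: choice references canals not incident to it"
            )
        kept[c] = sel

    new_edges: List[Edge] = []
    for e in tree.canals:
        a, b = e
        na = a if e in kept[a] else a + offset
        nb = b if e in kept[b] else b + offset
        new_edges.append(_edge(na, nb))
    new_edges.extend(_edge(c, c + offset) for c in tree.cells)
    cells = set(tree.cells) | {c + offset for c in tree.cells}
    return CystTree.from_edges(new_edges, cells=cells)


# ---------------------------------------------------------------------------
# isomorphism via AHU canonical encoding rooted at the tree center
# ---------------------------------------------------------------------------

def _centers(tree: CystTree) -> List[int]:
    """Center node(s) by iterative leaf pruning (1 or 2 nodes)."""
    adj = {c: set(ns) for c, ns in tree.adjacency().items()}
    remaining = set(tree.cells)
    while len(remaining) > 2:
        leaves = [c for c in remaining if len(adj[c]) <= 1]
        for leaf in leaves:
            for u in adj[leaf]:
                adj[u].discard(leaf)
            adj[leaf].clear()
            remaining.discard(leaf)
    return sorted(remaining)


def _rooted_key(adj: Dict[int, List[int]], v: int, parent: Optional[int]) -> str:
    subs = sorted(_rooted_key(adj, u, v) for u in adj[v] if u != parent)
    return "(" + "".join(subs) + ")"


def canonical_key(tree: CystTree) -> str:
    """Canonical string of the unrooted tree (AHU encoding at the center).

    When the tree has two centers, both rootings are encoded and the
    lexicographically smaller string is taken.
    """
    adj = tree.adjacency()
    return min(_rooted_key(adj, c, None) for c in _centers(tree))


def trees_isomorphic(a: CystTree, b: CystTree) -> bool:
    """True iff an edge-preserving bijection between the cell sets exists."""
    if a.n_cells != b.n_cells or a.degree_sequence() != b.degree_sequence():
        return False
    return canonical_key(a) == canonical_key(b)


def is_max_branched(tree: CystTree) -> bool:
    """True iff the tree is isomorphic to the canonical maximally branched one."""
    if tree.n_cells not in (1, 2, 4, 8, 16):
        raise InvalidSizeError(f"cyst size must be a power of 2 <= 16, got {tree.n_cells}")
    return trees_isomorphic(tree, canonical_max_branched(tree.n_cells))


# ---------------------------------------------------------------------------
# enumeration of topologies reachable by one synchronous round
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnumerationResult:
    """Isomorphism classes of one synchronous division round."""

    representatives: Tuple[CystTree, ...]
    n_labeled: int          # labeled outcomes = 2**sum(d_i - 1)
    n_classes: int          # isomorphism classes among them
    n_max_branched: int     # classes isomorphic to the canonical tree


def enumerate_topologies(start: CystTree) -> EnumerationResult:
    """Apply one synchronous division round over every combination of choices.

    Returns one representative tree per isomorphism class of the products,
    together with the labeled-outcome count and how many classes are
    maximally branched.  Guarded to starts of at most 8 cells (the product
    space doubles per unit of total degree).
    """
    if start.n_cells > 8:
        raise SizeLimitError("enumeration is limited to starting cysts of <= 8 cells")
    cells = sorted(start.cells)
    per_cell = [division_choices(start, c) for c in cells]
    reps: Dict[str, CystTree] = {}
    n_labeled = 0
    n_max = 0
    target = canonical_key(canonical_max_branched(2 * start.n_cells)) \
        if 2 * start.n_cells in (2, 4, 8, 16) else None
    for combo in itertools.product(*per_cell):
        n_labeled += 1
        child = divide_all(start, dict(zip(cells, combo)))
        key = canonical_key(child)
        if key not in reps:
            reps[key] = child
            if key == target:
                n_max += 1
    return EnumerationResult(tuple(reps.values()), n_labeled, len(reps), n_max)


# ---------------------------------------------------------------------------
# subtree embedding (rooted DP with child matching)
# ---------------------------------------------------------------------------

def is_embeddable(fragment_tree: CystTree, host: CystTree) -> bool:
    """Can ``fragment_tree`` be mapped onto a connected subtree of ``host``?

    Rooted dynamic programme: the fragment is rooted at an arbitrary node and
    tried against every host node as the image of the root; children are
    paired by a small bipartite matching.  Used to test whether a male fusome
    fragment's connectivity is consistent with a maximally branched cyst.
    """
    if fragment_tree.n_cells > host.n_cells:
        return False
    fadj = fragment_tree.adjacency()
    hadj = host.adjacency()
    root = min(fragment_tree.cells)
    memo: Dict[Tuple[int, Optional[int], int, Optional[int]], bool] = {}

    def fits(u: int, pu: Optional[int], v: int, pv: Optional[int]) -> bool:
        key = (u, pu, v, pv)
        if key in memo:
            return memo[key]
        f_kids = [x for x in fadj[u] if x != pu]
        h_kids = [y for y in hadj[v] if y != pv]
        if len(f_kids) > len(h_kids):
            memo[key] = False
            return False
        ok = [[fits(x, u, y, v) for y in h_kids] for x in f_kids]

        # exact matching by backtracking (degrees <= 4, trivial sizes)
        def match(i: int, used: int) -> bool:
            if i == len(f_kids):
                return True
            for j in range(len(h_kids)):
                if not used & (1 << j) and ok[i][j] and match(i + 1, used | (1 << j)):
                    return True
            return False

        memo[key] = match(0, 0)
        return memo[key]

    return any(fits(root, None, v, None) for v in host.cells)


# ---------------------------------------------------------------------------
# random division sequences (used by the synthetic-data generator and tests)
# ---------------------------------------------------------------------------

def random_division_tree(n_rounds: int, rng, p_branch: float = 1.0) -> CystTree:
    """Grow a cyst by ``n_rounds`` synchronous divisions with random choices.

    Each cell picks the branching choice with probability ``p_branch``;
    otherwise a uniformly random in-line partition of its canals.  With
    ``p_branch=1`` this reproduces ``canonical_max_branched(2**n_rounds)``.
    """
    if not 0 <= n_rounds <= 4:
        raise InvalidSizeError("n_rounds must be between 0 and 4")
    tree = CystTree(frozenset({1}), frozenset())
    for _ in range(n_rounds):
        choices = {}
        for c in sorted(tree.cells):
            opts = division_choices(tree, c)
            branching = max(opts, key=len)  # keep-all = branching
            if len(opts) == 1 or rng.random() < p_branch:
                choices[c] = branching
            else:
                others = [o for o in opts if o != branching]
                choices[c] = others[rng.integers(len(others))]
        tree = divide_all(tree, choices)
    return tree
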