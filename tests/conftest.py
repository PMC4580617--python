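"""Shared fixtures and oracle helpers for the test suite.

The oracles here are deliberately independent of the library's fast paths:
brute-force minimisation over all internal state assignments, exhaustive
topology enumeration via recursive leaf insertion on edge lists, and direct
set counting for consensus.  They are only feasible at tiny sizes, which is
exactly where they are used.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from parsimonia.matrix import (CharacterMatrix, CharacterMeta, MISSING,
                               INAPPLICABLE, StateSet)


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def matrix_from_strings(rows: dict[str, str]) -> CharacterMatrix:
    """Build a matrix from {'taxon': '01?{01}-2', ...} shorthand."""
    taxa, cells = [], []
    for taxon, s in rows.items():
        taxa.append(taxon)
        row, i = [], 0
        while i < len(s):
            ch = s[i]
            if ch == "?":
                row.append(MISSING)
            elif ch == "-":
                row.append(INAPPLICABLE)
            elif ch == "{":
                j = s.index("}", i)
                row.append(StateSet(frozenset(int(c) for c in s[i + 1:j])))
                i = j
            else:
                row.append(StateSet.of(int(ch)))
            i += 1
        cells.append(row)
    return CharacterMatrix(taxa, cells)


def random_matrix(rng: np.random.Generator, n_taxa: int, n_chars: int,
                  n_states: int = 3, p_missing: float = 0.1,
                  p_poly: float = 0.05) -> CharacterMatrix:
    """Random matrix with missing and polymorphic cells."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            u = rng.random()
            if u < p_missing:
                row.append(MISSING)
            elif u < p_missing + p_poly and n_states >= 2:
                pair = rng.choice(n_states, size=2, replace=False)
                row.append(StateSet(frozenset(int(x) for x in pair)))
            else:
                row.append(StateSet.of(int(rng.integers(n_states))))
        cells.append(row)
    metas = [CharacterMeta(index=j + 1, n_states=n_states)
             for j in range(n_chars)]
    return CharacterMatrix(taxa, cells, metas)


# ---------------------------------------------------------------------------
# brute-force parsimony oracles
# ---------------------------------------------------------------------------

def brute_force_tree_length(tree_children: dict, leaf_states: dict[str, frozenset[int]],
                            n_states: int) -> int:
    """Minimum changes over ALL internal state assignments of a rooted tree.

    *tree_children*: {node: (child, child, ...)}; leaves absent from it.
    Missing cells are modelled as the full state set.
    """
    internal = list(tree_children)
    leaves = sorted(leaf_states)
    best = None
    for assign in product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assign))
        # leaves may pick any member of their set: choose the best
        cost = 0
        for node, kids in tree_children.items():
            for kid in kids:
                if kid in tree_children:
                    cost += state[kid] != state[node]
                else:
                    # a tip resolves to its cheapest member state
                    cost += 0 if state[node] in leaf_states[kid] else 1
        if best is None or cost < best:
            best = cost
    return best


def oracle_unrooted_length(column: list[frozenset[int]], topology,
                           n_states: int) -> int:
    """Exact unrooted length of one character by brute force.

    *topology* is nested tuples of leaf indices, e.g. ((0, 1), (2, 3)).
    """
    counter = [0]
    children: dict = {}

    def build(node):
        if isinstance(node, int):
            return f"L{node}"
        counter[0] += 1
        name = f"N{counter[0]}"
        children[name] = tuple(build(c) for c in node)
        return name

    root = build(topology)
    leaf_states = {f"L{i}": column[i] for i in range(len(column))}
    return brute_force_tree_length(children, leaf_states, n_states)


def exhaustive_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1 as nested tuples,
    built independently of the search module (edge-list insertion)."""
    # represent a topology as a frozenset of splits for identity, but yield
    # a nested-tuple rooted form for scoring
    def insert_everywhere(shape, leaf):
        # shape is a nested tuple rooted at a trifurcation: (a, b, c)
        out = []

        def sub_insert(node):
            # returns list of versions of `node` with leaf inserted inside
            versions = [(node, leaf)]
            if isinstance(node, tuple):
                for i, child in enumerate(node):
                    for v in sub_insert(child):
                        versions.append(tuple(v if j == i else c
                                              for j, c in enumerate(node)))
            return versions

        for i, part in enumerate(shape):
            for v in sub_insert(part):
                out.append(tuple(v if j == i else p
                                 for j, p in enumerate(shape)))
        return out

    shapes = [(0, 1, 2)]
    for leaf in range(3, n):
        shapes = [s2 for s in shapes for s2 in insert_everywhere(s, leaf)]
    return shapes


def topology_splits(shape, n: int) -> frozenset:
    """Non-trivial splits of a nested-tuple topology (side without leaf 0)."""
    all_leaves = frozenset(range(n))
    splits = set()

    def walk(node) -> frozenset:
        if isinstance(node, int):
            return frozenset([node])
        below = frozenset().union(*(walk(c) for c in node))
        if 1 < len(below) < n - 1:
            splits.add(below if 0 not in below else all_leaves - below)
        return below

    for part in shape:
        walk(part)
    return frozenset(splits)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
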