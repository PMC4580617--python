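"""Tree search under the parsimony criterion.

Exact search is a branch-and-bound over unrooted binary topologies built by
stepwise taxon addition: a partial tree is abandoned as soon as its length
plus an admissible lower bound for the unplaced taxa exceeds the best length
found so far (plus the requested slack, when enumerating near-optimal trees
for Bremer support).  The heuristic fallback is a random-addition-sequence
Wagner build refined by tree-bisection-reconnection (TBR) to a local
optimum, deterministic for a given seed.

Internally trees are undirected adjacency maps whose leaves are row indices
into the matrix's state-bitmask array; conversion to labelled
:class:`~parsimonia.trees.Tree` objects happens only at the result boundary.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import fitch_length_adj, fitch_steps_adj, sankoff_steps_adj
from .trees import Tree, TreeNode


class SearchError(ValueError):
    pass


class SearchTimeout(RuntimeError):
    """Raised when an exact search exceeds its time budget."""


@dataclass
class SearchResult:
    trees: list[Tree]
    best_length: int
    exact: bool
    collapse_rule: str
    stats: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# adjacency plumbing
# ---------------------------------------------------------------------------

def _edges(adj: dict) -> list[tuple[int, int]]:
    out = []
    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                out.append((u, v))
    return out


def _copy(adj: dict) -> dict:
    return {k: list(v) for k, v in adj.items()}


def _insert_leaf(adj: dict, leaf: int, edge: tuple[int, int], new_node: int) -> dict:
    u, v = edge
    out = _copy(adj)
    out[u].remove(v)
    out[v].remove(u)
    out[u].append(new_node)
    out[v].append(new_node)
    out[new_node] = [u, v, leaf]
    out[leaf] = [new_node]
    return out


def _signature(adj: dict, leaf_ids: set[int]) -> frozenset:
    """Canonical set of non-trivial splits (sides not containing the
    smallest leaf), identifying an unrooted topology."""
    all_leaves = frozenset(leaf_ids)
    ref = min(all_leaves)
    splits = set()
    seen_root = next(iter(adj))
    below: dict = {}

    for node, parent in _postorder_pairs(adj, seen_root):
        if node in leaf_ids:
            below[node] = frozenset([node])
        else:
            kids = [nb for nb in adj[node] if nb != parent]
            below[node] = frozenset().union(*(below[c] for c in kids))
        if parent is not None and 1 < len(below[node]) < len(all_leaves) - 1:
            side = below[node]
            splits.add(side if ref not in side else all_leaves - side)
    return frozenset(splits)


def _postorder_pairs(adj: dict, root) -> list[tuple]:
    order, stack = [], [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    order.reverse()
    return order


def adjacency_to_tree(adj: dict, taxa: Sequence[str]) -> Tree:
    """Labelled unrooted Tree (basal polytomy at an internal node)."""
    leaf_ids = {x for x in adj if len(adj[x]) == 1 and x < len(taxa)}
    internal = [x for x in adj if x not in leaf_ids]
    root = max(internal) if internal else min(adj)

    def build(node, parent) -> TreeNode:
        kids = [nb for nb in adj[node] if nb != parent]
        if not kids and node in leaf_ids:
            return TreeNode(label=taxa[node])
        return TreeNode(children=[build(c, node) for c in kids])

    return Tree(build(root, None), rooted=False)


def all_topologies(n: int) -> Iterator[dict]:
    """Every unrooted binary topology over leaves 0..n-1 (1*3*5*...*(2n-5))."""
    if n < 3:
        raise SearchError("need at least 3 taxa")

    def grow(adj: dict, next_leaf: int, next_internal: int) -> Iterator[dict]:
        if next_leaf == n:
            yield adj
            return
        for edge in _edges(adj):
            yield from grow(_insert_leaf(adj, next_leaf, edge, next_internal),
                            next_leaf + 1, next_internal + 1)

    star = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    yield from grow(star, 3, n + 1)


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------

def _addition_order(matrix: CharacterMatrix) -> list[int]:
    """Taxa sorted by decreasing participation in informative characters,
    ties broken by input order (tightens bounds early)."""
    metas = matrix.active_characters()
    informative_cols = []
    for m in metas:
        col = matrix.column(m.index)
        counts: dict[int, int] = {}
        for cell in col:
            if not cell.is_uncertain and len(cell.states) == 1:
                s = next(iter(cell.states))
                counts[s] = counts.get(s, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            informative_cols.append(m.index)
    scores = []
    for i, taxon in enumerate(matrix.taxa):
        score = 0
        for idx in informative_cols:
            cell = matrix.column(idx)[i]
            if not cell.is_uncertain:
                score += 1
        scores.append((-score, i))
    return [i for _, i in sorted(scores)]


def _remaining_bound(masks: np.ndarray, partial_union: np.ndarray,
                     remaining: list[int]) -> int:
    """Admissible lower bound: each unplaced taxon whose possible states are
    disjoint from everything already available forces at least one step."""
    bound = 0
    avail = partial_union
    for r in remaining:
        row = masks[r]
        disjoint = (row & avail) == 0
        n = int(disjoint.sum())
        if n:
            bound += n
            avail = np.where(disjoint, avail | row, avail)
    return bound


def _bnb(matrix: CharacterMatrix, slack: int,
         deadline: float | None = None) -> tuple[int, list[tuple[dict, int]], dict]:
    masks, _ = matrix.state_masks()
    n = matrix.n_taxa
    order = _addition_order(matrix)
    first, rest = order[:3], order[3:]
    leaf_set = set(order)

    # seed the bound with a deterministic greedy Wagner tree
    best = _wagner_length(masks, order)
    completes: list[tuple[dict, int]] = []
    stats = {"visited": 0, "pruned": 0}
    start_internal = n

    def recurse(adj: dict, placed: int, union: np.ndarray, next_internal: int):
        nonlocal best
        stats["visited"] += 1
        if deadline is not None and stats["visited"] % 256 == 0:
            if time.monotonic() > deadline:
                raise SearchTimeout("branch-and-bound exceeded its time budget")
        length = fitch_length_adj(adj, {x: x for x in adj if x in leaf_set}, masks)
        remaining = rest[placed:]
        if length + _remaining_bound(masks, union, remaining) > best + slack:
            stats["pruned"] += 1
            return
        if not remaining:
            if length < best:
                best = length
                completes[:] = [(a, l) for a, l in completes if l <= best + slack]
            completes.append((adj, length))
            return
        leaf = remaining[0]
        for edge in _edges(adj):
            recurse(_insert_leaf(adj, leaf, edge, next_internal),
                    placed + 1, union | masks[leaf], next_internal + 1)

    a, b, c = first
    star = {start_internal: [a, b, c], a: [start_internal],
            b: [start_internal], c: [start_internal]}
    union0 = masks[a] | masks[b] | masks[c]
    recurse(star, 0, union0, start_internal + 1)
    completes = [(adj, l) for adj, l in completes if l <= best + slack]
    return best, completes, stats


def _wagner_length(masks: np.ndarray, order: list[int]) -> int:
    adj = _wagner_build(masks, order)
    leaf_rows = {x: x for x in adj if len(adj[x]) == 1}
    return fitch_length_adj(adj, leaf_rows, masks)


def _wagner_build(masks: np.ndarray, order: list[int]) -> dict:
    """Greedy stepwise addition: each taxon goes to the cheapest edge."""
    n = masks.shape[0]
    a, b, c = order[:3]
    adj = {n: [a, b, c], a: [n], b: [n], c: [n]}
    next_internal = n + 1
    for leaf in order[3:]:
        best_len, best_adj = None, None
        for edge in _edges(adj):
            cand = _insert_leaf(adj, leaf, edge, next_internal)
            leaf_rows = {x: x for x in cand if len(cand[x]) == 1}
            length = fitch_length_adj(cand, leaf_rows, masks)
            if best_len is None or length < best_len:
                best_len, best_adj = length, cand
        adj = best_adj
        next_internal += 1
    return adj


def branch_and_bound(matrix: CharacterMatrix, collapse_rule: str = "min",
                     time_budget: float | None = None) -> SearchResult:
    """Exact search: all most-parsimonious trees by implicit enumeration."""
    if matrix.n_taxa < 3:
        raise SearchError("branch-and-bound needs at least 3 taxa")
    deadline = time.monotonic() + time_budget if time_budget else None
    best, completes, stats = _bnb(matrix, slack=0, deadline=deadline)
    trees = _finalise(completes, matrix, collapse_rule)
    return SearchResult(trees=trees, best_length=best, exact=True,
                        collapse_rule=collapse_rule, stats=stats)


def enumerate_suboptimal(matrix: CharacterMatrix, slack: int,
                         time_budget: float | None = None) -> list[tuple[Tree, int]]:
    """Every distinct binary topology within *slack* steps of the optimum
    (slack=0 gives exactly the MPT set); used for Bremer support."""
    if slack < 0:
        raise SearchError("slack must be >= 0")
    if matrix.n_taxa < 3:
        raise SearchError("need at least 3 taxa")
    deadline = time.monotonic() + time_budget if time_budget else None
    _, completes, _ = _bnb(matrix, slack=slack, deadline=deadline)
    seen = set()
    out = []
    leaf_ids = set(range(matrix.n_taxa))
    for adj, length in sorted(completes, key=lambda p: p[1]):
        sig = _signature(adj, {x for x in adj if x in leaf_ids})
        if sig in seen:
            continue
        seen.add(sig)
        out.append((adjacency_to_tree(adj, matrix.taxa), length))
    return out


def _finalise(completes: list[tuple[dict, int]], matrix: CharacterMatrix,
              collapse_rule: str) -> list[Tree]:
    best = min(l for _, l in completes)
    optima = [adj for adj, l in completes if l == best]
    masks, metas = matrix.state_masks()
    n_states = [m.n_states for m in metas]
    leaf_ids = set(range(matrix.n_taxa))
    seen, trees = set(), []
    for adj in optima:
        if collapse_rule == "min":
            adj = _collapse_min_zero(adj, masks, n_states, leaf_ids, best)
        sig = _signature(adj, {x for x in adj if x in leaf_ids})
        if sig not in seen:
            seen.add(sig)
            trees.append(adjacency_to_tree(adj, matrix.taxa))
    return trees


def _collapse_min_zero(adj: dict, masks: np.ndarray, n_states: list[int],
                       leaf_ids: set[int], length: int) -> dict:
    """Collapse every internal branch whose minimum length over optimal
    reconstructions is zero: contract it and keep the contraction whenever
    the exact (Sankoff) length of the resulting polytomous tree is unchanged."""
    internal_edges = [(u, v) for u, v in _edges(adj)
                      if u not in leaf_ids and v not in leaf_ids]
    to_collapse = []
    for u, v in internal_edges:
        contracted = _contract(adj, u, v)
        leaf_rows = {x: x for x in contracted if x in leaf_ids}
        steps = sankoff_steps_adj(contracted, leaf_rows, masks,
                                  n_states, [False] * len(n_states))
        if int(steps.sum()) == length:
            to_collapse.append((u, v))
    out = adj
    for u, v in to_collapse:
        if v in out and u in out[v]:
            out = _contract(out, u, v)
    return out


def _contract(adj: dict, u: int, v: int) -> dict:
    """Merge node v into node u."""
    out = _copy(adj)
    for nb in out[v]:
        if nb != u:
            out[nb] = [u if x == v else x for x in out[nb]]
            out[u].append(nb)
    out[u] = [x for x in out[u] if x != v]
    del out[v]
    return out


# ---------------------------------------------------------------------------
# heuristic search: random addition + TBR
# ---------------------------------------------------------------------------

def _split(adj: dict, u: int, v: int) -> tuple[dict, dict]:
    """Remove edge u-v; return the two components (degree-2 nodes spliced)."""
    out = _copy(adj)
    out[u].remove(v)
    out[v].remove(u)
    for x in (u, v):
        if len(out[x]) == 2:
            a, b = out[x]
            out[a] = [b if y == x else y for y in out[a]]
            out[b] = [a if y == x else y for y in out[b]]
            del out[x]

    comp_u: dict = {}
    anchor = u if u in out else out.get(v) and None
    # collect component containing u (or its splice survivor)
    start_u = u if u in out else adj[u][0] if adj[u][0] in out else None
    # robust: walk from a known member
    def component(start):
        comp, stack = {}, [start]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp[x] = list(out[x])
            stack.extend(out[x])
        return comp

    members_u = _reach(adj, u, forbidden=(u, v))
    any_u = next(iter(members_u & set(out)))
    comp_a = component(any_u)
    comp_b = {k: v2 for k, v2 in out.items() if k not in comp_a}
    return comp_a, comp_b


def _reach(adj: dict, start: int, forbidden: tuple[int, int]) -> set[int]:
    """Nodes reachable from *start* without crossing the forbidden edge."""
    u, v = forbidden
    seen, stack = set(), [start]
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        for nb in adj[x]:
            if (x, nb) == (u, v) or (x, nb) == (v, u):
                continue
            stack.append(nb)
    return seen


def _join(comp_a: dict, edge_a, comp_b: dict, edge_b, next_id: int) -> dict:
    """Reconnect two components, subdividing the chosen edge on each side."""
    out = {**_copy(comp_a), **_copy(comp_b)}

    def attach_point(comp, edge, new_node):
        if edge is None:  # single-node component: the node itself
            (node,) = comp
            return node
        p, q = edge
        out[p] = [x for x in out[p] if x != q] + [new_node]
        out[q] = [x for x in out[q] if x != p] + [new_node]
        out[new_node] = [p, q]
        return new_node

    x = attach_point(comp_a, edge_a, next_id)
    y = attach_point(comp_b, edge_b, next_id + 1)
    out[x].append(y)
    out[y].append(x)
    return out


def _tbr_neighbors(adj: dict) -> Iterator[dict]:
    next_id = max(adj) + 1
    for u, v in _edges(adj):
        comp_a, comp_b = _split(adj, u, v)
        edges_a = _edges(comp_a) or [None]
        edges_b = _edges(comp_b) or [None]
        if len(comp_a) == 1 and len(comp_b) == 1:
            continue
        for ea in edges_a:
            for eb in edges_b:
                yield _join(comp_a, ea, comp_b, eb, next_id)


def _local_search(adj: dict, masks: np.ndarray) -> tuple[dict, int]:
    """Steepest-descent TBR until no neighbor improves."""
    leaf_rows = {x: x for x in adj if len(adj[x]) == 1}
    current = adj
    current_len = fitch_length_adj(current, leaf_rows, masks)
    improved = True
    while improved:
        improved = False
        best_nb, best_len = None, current_len
        for cand in _tbr_neighbors(current):
            rows = {x: x for x in cand if len(cand[x]) == 1}
            length = fitch_length_adj(cand, rows, masks)
            if length < best_len:
                best_nb, best_len = cand, length
        if best_nb is not None:
            current, current_len = best_nb, best_len
            improved = True
    return current, current_len


def heuristic_search(matrix: CharacterMatrix, n_replicates: int = 10,
                     seed: int = 0, collapse_rule: str = "min") -> SearchResult:
    """Random-addition-sequence Wagner trees refined by TBR.

    Deterministic for a given seed; replicate r draws its addition sequence
    from ``seed + r``.  Lengths are an upper bound on the exact optimum.
    """
    if matrix.n_taxa < 4:
        raise SearchError("heuristic search needs at least 4 taxa")
    masks, metas = matrix.state_masks()
    n = matrix.n_taxa
    results: list[tuple[dict, int]] = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        order = [int(x) for x in rng.permutation(n)]
        adj = _wagner_build(masks, order)
        adj, length = _local_search(adj, masks)
        results.append((adj, length))
    best = min(l for _, l in results)
    completes = [(adj, l) for adj, l in results if l == best]
    trees = _finalise(completes, matrix, collapse_rule)
    return SearchResult(trees=trees, best_length=best, exact=False,
                        collapse_rule=collapse_rule,
                        stats={"replicates": n_replicates, "seed": seed})
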