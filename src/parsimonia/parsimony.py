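"""Parsimony scoring: Fitch and Sankoff lengths, per-character step bounds,
and the ensemble consistency / retention indices.

The scoring kernels work on an undirected adjacency view of the tree with
leaf cells encoded as state bitmasks, so the same code serves the tree-search
module (many partial trees per second) and user-level scoring of finished
trees.  Unordered characters use Fitch set operations; ordered characters use
Sankoff dynamic programming with linear step costs c(i,j) = |i-j|.

Polytomies are scored with the sequential Fitch convention: children are
folded left to right into a running intersection, adding one step and taking
the union whenever the next child's set is disjoint.  On binary trees this is
exactly the Fitch/ Sankoff minimum; on polytomous (consensus) trees it is the
convention under which their lengths are reported.  The branch-collapse test
in the search module uses exact Sankoff scoring instead, where the true
hard-polytomy minimum matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CharacterMatrix, StateSet
from .trees import Tree, _to_adjacency

_INF = 1 << 20


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ParsimonyScore:
    """Tree length with its per-character decomposition and homoplasy indices."""

    length: int
    per_char: tuple[int, ...]
    min_sum: int
    max_sum: int
    ci: float
    ri: float

    def __str__(self) -> str:
        return (f"L={self.length} CI={self.ci:.2f} RI={self.ri:.2f} "
                f"(min {self.min_sum}, max {self.max_sum})")


# ---------------------------------------------------------------------------
# kernels on adjacency views
# ---------------------------------------------------------------------------

def fitch_steps_adj(adj: dict, leaf_rows: dict, masks: np.ndarray) -> np.ndarray:
    """Per-character steps under (generalized) Fitch.

    *adj* maps node id -> neighbor ids; *leaf_rows* maps leaf node ids to
    rows of *masks* (shape: n_taxa x n_chars, state bitmasks).
    """
    n_chars = masks.shape[1]
    steps = np.zeros(n_chars, dtype=np.int64)
    if len(adj) < 2:
        return steps
    if len(adj) == 2:
        a, b = adj
        return steps + ((masks[leaf_rows[a]] & masks[leaf_rows[b]]) == 0)
    # root on the edge adjacent to the smallest leaf id
    top = min(leaf_rows)
    start = adj[top][0]
    sets: dict = {}
    stack = [(start, top, False)]
    while stack:
        node, parent, expanded = stack.pop()
        if node in leaf_rows:
            sets[node] = masks[leaf_rows[node]]
            continue
        if not expanded:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
        else:
            children = [nb for nb in adj[node] if nb != parent]
            running = sets[children[0]]
            for child in children[1:]:
                s = sets[child]
                inter = running & s
                disjoint = inter == 0
                steps += disjoint
                running = np.where(disjoint, running | s, inter)
            sets[node] = running
    steps += (sets[start] & masks[leaf_rows[top]]) == 0
    return steps


def fitch_length_adj(adj: dict, leaf_rows: dict, masks: np.ndarray) -> int:
    return int(fitch_steps_adj(adj, leaf_rows, masks).sum())


def sankoff_steps_adj(adj: dict, leaf_rows: dict, masks: np.ndarray,
                      n_states: list[int], ordered: list[bool]) -> np.ndarray:
    """Exact per-character minimum steps by Sankoff dynamic programming.

    Correct on polytomies; used for ordered characters and wherever the true
    hard-polytomy minimum is required.
    """
    n_chars = masks.shape[1]
    out = np.zeros(n_chars, dtype=np.int64)
    if len(adj) < 2:
        return out
    internal = [x for x in adj if x not in leaf_rows]
    root = internal[0] if internal else min(leaf_rows)
    order = _postorder(adj, root)
    for j in range(n_chars):
        k = n_states[j]
        if ordered[j]:
            dist = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :])
        else:
            dist = 1 - np.eye(k, dtype=np.int64)
        cost: dict = {}
        for node, parent in order:
            if node in leaf_rows:
                mask = int(masks[leaf_rows[node], j])
                allowed = np.array([(mask >> s) & 1 for s in range(k)], bool)
                cost[node] = np.where(allowed, 0, _INF)
            else:
                total = np.zeros(k, dtype=np.int64)
                for nb in adj[node]:
                    if nb != parent:
                        total += np.min(cost[nb][None, :] + dist, axis=1)
                cost[node] = total
        out[j] = int(cost[root].min())
    return out


def _postorder(adj: dict, root) -> list[tuple]:
    """(node, parent) pairs, children before parents."""
    order, stack = [], [(root, None)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    order.reverse()
    return order


# ---------------------------------------------------------------------------
# Tree-level scoring
# ---------------------------------------------------------------------------

def _tree_adjacency(tree: Tree, matrix: CharacterMatrix):
    adj, labels, _ = _to_adjacency(tree)
    tree_taxa = sorted(labels.values())
    if sorted(matrix.taxa) != tree_taxa or len(set(tree_taxa)) != len(tree_taxa):
        raise ScoringError("tree leaves do not match the matrix taxa")
    row_of = {t: i for i, t in enumerate(matrix.taxa)}
    leaf_rows = {nid: row_of[lab] for nid, lab in labels.items()}
    return adj, leaf_rows


def score_tree(tree: Tree, matrix: CharacterMatrix,
               respect_ordered: bool = True) -> ParsimonyScore:
    """Score a tree against the active characters of a matrix."""
    adj, leaf_rows = _tree_adjacency(tree, matrix)
    masks, metas = matrix.state_masks()
    ordered = [m.ordered and respect_ordered for m in metas]
    n_states = [m.n_states for m in metas]
    unordered_cols = [j for j, o in enumerate(ordered) if not o]
    per_char = np.zeros(len(metas), dtype=np.int64)
    if unordered_cols:
        per_char[unordered_cols] = fitch_steps_adj(adj, leaf_rows,
                                                   masks[:, unordered_cols])
    ordered_cols = [j for j, o in enumerate(ordered) if o]
    if ordered_cols:
        per_char[ordered_cols] = sankoff_steps_adj(
            adj, leaf_rows, masks[:, ordered_cols],
            [n_states[j] for j in ordered_cols], [True] * len(ordered_cols))
    columns = [matrix.column(m.index) for m in metas]
    min_sum = sum(char_min_steps(col, ordered=o)
                  for col, o in zip(columns, ordered))
    max_sum = sum(char_max_steps(col, ordered=o)
                  for col, o in zip(columns, ordered))
    length = int(per_char.sum())
    ci, ri = ensemble_indices(length, min_sum, max_sum)
    return ParsimonyScore(length, tuple(int(x) for x in per_char),
                          min_sum, max_sum, ci, ri)


def tree_length(tree: Tree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Fitch length: every character treated as unordered."""
    return score_tree(tree, matrix, respect_ordered=False)


def ordered_length(tree: Tree, matrix: CharacterMatrix) -> ParsimonyScore:
    """Length honouring per-character ordered flags (Sankoff |i-j| costs)."""
    return score_tree(tree, matrix, respect_ordered=True)


# ---------------------------------------------------------------------------
# Per-character bounds and ensemble indices
# ---------------------------------------------------------------------------

def _observed_sets(column: list[StateSet]) -> list[frozenset[int]]:
    return [c.states for c in column if not c.is_uncertain]


def char_min_steps(column: list[StateSet], ordered: bool = False) -> int:
    """Minimum conceivable steps on any tree, minimised over resolutions of
    polymorphic and missing cells."""
    sets = _observed_sets(column)
    if not sets:
        return 0
    if ordered:
        lo = max(min(s) for s in sets)
        hi = min(max(s) for s in sets)
        return max(0, lo - hi)
    universe = sorted(set().union(*sets))
    if len(universe) == 1:
        return 0
    # smallest set of states hitting every cell's state set
    for size in range(1, len(universe) + 1):
        if _hitting_set_exists(sets, universe, size):
            return size - 1
    return len(universe) - 1  # pragma: no cover


def _hitting_set_exists(sets, universe, size) -> bool:
    from itertools import combinations
    for combo in combinations(universe, size):
        chosen = set(combo)
        if all(chosen & s for s in sets):
            return True
    return False


def char_max_steps(column: list[StateSet], ordered: bool = False) -> int:
    """Worst-case (star tree) steps, the M term of the retention index.

    Polymorphic cells are resolved to their most globally frequent member
    state; missing cells drop out (their best resolution adds one tip and one
    count to the modal state, leaving the bound unchanged).
    """
    sets = _observed_sets(column)
    if len(sets) <= 1:
        return 0
    if ordered:
        lo = min(min(s) for s in sets)
        hi = max(max(s) for s in sets)
        return min(
            sum(min(abs(s - z) for s in cell) for cell in sets)
            for z in range(lo, hi + 1)
        )
    counts: dict[int, int] = {}
    for s in sets:
        if len(s) == 1:
            state = next(iter(s))
            counts[state] = counts.get(state, 0) + 1
    resolved = []
    for s in sets:
        if len(s) == 1:
            resolved.append(next(iter(s)))
        else:
            resolved.append(max(sorted(s), key=lambda st: (counts.get(st, 0), -st)))
    freq: dict[int, int] = {}
    for s in resolved:
        freq[s] = freq.get(s, 0) + 1
    return len(resolved) - max(freq.values())


def ensemble_indices(length: int, min_sum: int, max_sum: int) -> tuple[float, float]:
    """(CI, RI) with the conventional degenerate-case values.

    CI = min_sum/length (1 when length is 0); RI = (max_sum-length) /
    (max_sum-min_sum), defined as 1 when every character is uninformative
    (max_sum == min_sum).
    """
    if not (min_sum <= length <= max_sum):
        raise ScoringError(
            f"inconsistent sums: min {min_sum} <= L {length} <= max {max_sum} violated")
    ci = 1.0 if length == 0 else min_sum / length
    ri = 1.0 if max_sum == min_sum else (max_sum - length) / (max_sum - min_sum)
    return ci, ri
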