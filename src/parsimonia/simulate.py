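"""Synthetic trees and discrete character matrices for end-to-end testing.

Characters evolve on a known binary tree under a per-branch Bernoulli change
model: with probability ``p_change`` a branch changes the state, the new
state drawn uniformly from the remaining ones.  This is deliberately simpler
than a continuous-time Markov model — the point is controllable homoplasy
for exercising the search and consensus machinery, not evolutionary realism.
Missing data and polymorphism are injected cell-wise at configurable
fractions to mimic fossil matrices.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, CharacterMatrix, CharacterMeta, StateSet
from .trees import Tree, TreeNode


@dataclass
class SimulationConfig:
    n_taxa: int = 20
    n_chars: int = 50
    states_per_char: int | list[int] = 2
    p_change: float = 0.1
    missing_fraction: float = 0.0
    polymorphic_fraction: float = 0.0
    seed: int = 0
    tree_mode: str = "uniform"  # "uniform" | "yule"

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.n_chars < 1:
            raise ValueError("need at least 1 character")
        if not 0 <= self.p_change < 1:
            raise ValueError("p_change must be in [0, 1)")
        for frac in (self.missing_fraction, self.polymorphic_fraction):
            if not 0 <= frac < 1:
                raise ValueError("fractions must be in [0, 1)")

    def states(self) -> list[int]:
        if isinstance(self.states_per_char, int):
            return [self.states_per_char] * self.n_chars
        if len(self.states_per_char) != self.n_chars:
            raise ValueError("states_per_char list must have n_chars entries")
        return list(self.states_per_char)


def simulate_tree(n_taxa: int, seed: int = 0, mode: str = "uniform") -> Tree:
    """Random unrooted binary tree with leaves t1..tn.

    ``uniform`` draws uniformly over unrooted binary topologies (sequential
    insertion on a uniformly chosen edge); ``yule`` splits a uniformly chosen
    extant lineage at each step.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    if mode == "uniform":
        return _uniform_tree(labels, rng)
    if mode == "yule":
        return _yule_tree(labels, rng)
    raise ValueError(f"unknown tree mode {mode!r}")


def _uniform_tree(labels: list[str], rng) -> Tree:
    n = len(labels)
    adj = {n: [0, 1, 2], 0: [n], 1: [n], 2: [n]}
    next_internal = n + 1
    for leaf in range(3, n):
        edges = [(u, v) for u in sorted(adj) for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        adj[u].remove(v)
        adj[v].remove(u)
        w = next_internal
        adj[u].append(w)
        adj[v].append(w)
        adj[w] = [u, v, leaf]
        adj[leaf] = [w]
        next_internal += 1

    def build(node, parent) -> TreeNode:
        kids = [x for x in adj[node] if x != parent]
        if not kids:
            return TreeNode(label=labels[node])
        return TreeNode(children=[build(k, node) for k in kids])

    return Tree(build(n, None), rooted=False)


def _yule_tree(labels: list[str], rng) -> Tree:
    n = len(labels)
    tips = [TreeNode(), TreeNode()]
    root = TreeNode(children=tips)
    while len(tips) < n:
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        node.children = [TreeNode(), TreeNode()]
        tips.extend(node.children)
    order = rng.permutation(n)
    for tip, j in zip(tips, order):
        tip.label = labels[int(j)]
    return Tree(root, rooted=False)


def evolve_characters(tree: Tree, config: SimulationConfig) -> CharacterMatrix:
    """Evolve characters down *tree* under the per-branch change model."""
    rng = np.random.default_rng(config.seed)
    states = config.states()
    taxa = tree.leaf_labels
    data: dict[str, list[int]] = {t: [] for t in taxa}
    for k in states:
        root_state = int(rng.integers(k))
        _drop(tree.root, root_state, k, config.p_change, rng, data)
    cells = []
    for t in taxa:
        row = []
        for j, s in enumerate(data[t]):
            cell: StateSet = StateSet.of(s)
            u = rng.random()
            if u < config.missing_fraction:
                cell = MISSING
            elif u < config.missing_fraction + config.polymorphic_fraction and states[j] >= 2:
                other = int(rng.integers(states[j] - 1))
                if other >= s:
                    other += 1
                cell = StateSet(frozenset({s, other}))
            row.append(cell)
        cells.append(row)
    metas = [CharacterMeta(index=j + 1, n_states=k)
             for j, k in enumerate(states)]
    return CharacterMatrix(taxa, cells, metas)


def _drop(node: TreeNode, state: int, k: int, p: float, rng, data) -> None:
    if node.is_leaf:
        data[node.label].append(state)
        return
    for child in node.children:
        s = state
        if rng.random() < p and k >= 2:
            step = int(rng.integers(k - 1))
            s = step if step < state else step + 1
        _drop(child, s, k, p, rng, data)


def simulate_dataset(config: SimulationConfig) -> tuple[Tree, CharacterMatrix]:
    """(true tree, evolved matrix) under one config; both seed-deterministic."""
    tree = simulate_tree(config.n_taxa, seed=config.seed, mode=config.tree_mode)
    matrix = evolve_characters(tree, config)
    return tree, matrix


def low_noise_config(seed: int = 0) -> SimulationConfig:
    """The generator's low-homoplasy reference condition for parameter
    recovery: 20 taxa, 50 five-state characters, per-branch change
    probability 0.08.

    At this size an unrooted binary tree has 37 branches, so p=0.08 leaves a
    branch unmarked by all 50 characters with probability (1-p)^50 ~ 0.015
    (nearly every true clade has at least one potential synapomorphy) while
    each character carries only ~3 expected changes spread over 5 states,
    keeping convergent changes rare.  Lower p starves branches of changes;
    higher p erases them with homoplasy.
    """
    return SimulationConfig(n_taxa=20, n_chars=50, states_per_char=5,
                            p_change=0.08, seed=seed)


def fossil_study_matrix(seed: int = 0, n_taxa: int = 25,
                      missing_fraction: float = 0.2) -> CharacterMatrix:
    """A matrix shaped like a fossil hyaenodont dataset: 50 characters of
    which one five-state (an ordinal size character), 32 binary and 17
    three-to-four-state, with a realistic missing-data fraction."""
    states = [5] + [2] * 32 + [3] * 9 + [4] * 8
    config = SimulationConfig(n_taxa=n_taxa, n_chars=50,
                              states_per_char=states,
                              p_change=0.15,
                              missing_fraction=missing_fraction,
                              polymorphic_fraction=0.02,
                              seed=seed)
    _, matrix = simulate_dataset(config)
    return matrix
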