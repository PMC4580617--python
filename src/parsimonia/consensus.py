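"""Strict and majority-rule consensus trees, clade percentages, and Bremer
(decay) support computed from an enumeration of near-optimal trees.

Consensus is computed on unrooted bipartitions; the resulting tree can be
rooted on a designated outgroup for display.  A clade's Bremer support is the
extra length of the best tree that lacks the clade: it is read off the
suboptimal-tree enumeration (all trees within ``slack`` steps of the
optimum), and reported as a lower bound ``>= slack + 1`` when every tree in
the enumeration still contains the clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matrix import CharacterMatrix
from .parsimony import ParsimonyScore, score_tree
from .trees import Tree, TreeNode, tree_from_clades


class ConsensusError(ValueError):
    pass


@dataclass
class CladeSupport:
    percent: float | None = None
    bremer: int | None = None
    bremer_is_lower_bound: bool = False


@dataclass
class ConsensusTree:
    tree: Tree
    kind: str  # "strict" | "majority"
    clades: dict[frozenset, CladeSupport]
    score: ParsimonyScore | None = None
    outgroup: str | None = None

    @property
    def length(self) -> int | None:
        return self.score.length if self.score else None

    def to_newick(self, annotate: str = "support") -> str:
        return self.tree.to_newick(annotate=annotate)

    def clade_table(self) -> pd.DataFrame:
        rows = []
        for clade, sup in sorted(self.clades.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))):
            bremer = sup.bremer
            if bremer is not None and sup.bremer_is_lower_bound:
                bremer = f">={sup.bremer}"
            rows.append({
                "clade": " ".join(sorted(clade)),
                "n_taxa": len(clade),
                "percent": None if sup.percent is None else round(sup.percent),
                "bremer": bremer,
            })
        return pd.DataFrame(rows, columns=["clade", "n_taxa", "percent", "bremer"])


def _check_leaf_sets(trees: list[Tree]) -> frozenset:
    if not trees:
        raise ConsensusError("need at least one input tree")
    leaf_sets = {frozenset(t.leaf_labels) for t in trees}
    if len(leaf_sets) != 1:
        raise ConsensusError("input trees have different leaf sets")
    return next(iter(leaf_sets))


def _as_clade(split: frozenset, all_leaves: frozenset, outgroup: str | None) -> frozenset:
    """Orient a split as the side not containing the outgroup (or the
    reference taxon when no outgroup is set)."""
    if outgroup is not None and outgroup in split:
        return all_leaves - split
    return split


def _build(all_leaves: frozenset, splits, percents, kind, matrix, outgroup,
           leaf_order) -> ConsensusTree:
    clades = {_as_clade(s, all_leaves, outgroup): s for s in splits}
    tree = tree_from_clades(leaf_order, clades.keys(), rooted=outgroup is not None)
    if outgroup is not None:
        # put the outgroup first among the root's children for display
        tree.root.children.sort(key=lambda c: c.label != outgroup)
    support = {clade: CladeSupport(percent=percents[s])
               for clade, s in clades.items()}
    for node in tree.postorder():
        c = node.annotation.get("clade")
        if c in support:
            node.annotation["support"] = round(support[c].percent)
    score = score_tree(tree, matrix) if matrix is not None else None
    return ConsensusTree(tree=tree, kind=kind, clades=support, score=score,
                         outgroup=outgroup)


def strict_consensus(trees: list[Tree], matrix: CharacterMatrix | None = None,
                     outgroup: str | None = None) -> ConsensusTree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    all_leaves = _check_leaf_sets(trees)
    common = frozenset.intersection(*(t.bipartitions() for t in trees))
    percents = {s: 100.0 for s in common}
    leaf_order = trees[0].leaf_labels
    return _build(all_leaves, common, percents, "strict", matrix, outgroup,
                  leaf_order)


def majority_consensus(trees: list[Tree], threshold: float = 0.5,
                       matrix: CharacterMatrix | None = None,
                       outgroup: str | None = None) -> ConsensusTree:
    """Tree of bipartitions occurring in strictly more than *threshold* of
    the inputs, annotated with occurrence percentages."""
    if threshold < 0.5:
        raise ConsensusError("majority threshold must be >= 0.5")
    all_leaves = _check_leaf_sets(trees)
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.bipartitions():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    kept = {s: 100.0 * c / n for s, c in counts.items() if c / n > threshold}
    leaf_order = trees[0].leaf_labels
    return _build(all_leaves, kept.keys(), kept, "majority", matrix, outgroup,
                  leaf_order)


def bremer_support(matrix: CharacterMatrix, consensus: ConsensusTree,
                   suboptimal: list[tuple[Tree, int]], slack: int) -> ConsensusTree:
    """Annotate each consensus clade with its Bremer (decay) support.

    *suboptimal* must be the complete set of topologies within *slack* steps
    of the optimum (see :func:`parsimonia.search.enumerate_suboptimal`).
    """
    if not suboptimal:
        raise ConsensusError("empty suboptimal tree set")
    best = min(length for _, length in suboptimal)
    all_leaves = frozenset(suboptimal[0][0].leaf_labels)
    if all_leaves != frozenset(consensus.tree.leaf_labels):
        raise ConsensusError("suboptimal trees and consensus differ in leaf set")
    splits = [(t.bipartitions(), length) for t, length in suboptimal]
    for clade, sup in consensus.clades.items():
        split = clade if min(all_leaves) not in clade else all_leaves - clade
        without = [length for bip, length in splits if split not in bip]
        if without:
            sup.bremer = min(without) - best
            sup.bremer_is_lower_bound = False
        else:
            sup.bremer = slack + 1
            sup.bremer_is_lower_bound = True
    for node in consensus.tree.postorder():
        c = node.annotation.get("clade")
        if c in consensus.clades and consensus.clades[c].bremer is not None:
            sup = consensus.clades[c]
            node.annotation["bremer"] = (f">={sup.bremer}"
                                         if sup.bremer_is_lower_bound else sup.bremer)
    return consensus
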