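"""Phylogenetic tree container shared by the scoring, search and consensus modules.

Trees are stored rooted for traversal but carry unrooted semantics unless
``rooted=True``: an unrooted binary tree is held with a basal trifurcation,
and all comparisons go through :meth:`Tree.bipartitions`, which is invariant
to the storage rooting.  Newick serialisation is delegated to dendropy.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("label", "children", "annotation")

    def __init__(self, label: str | None = None,
                 children: Iterable["TreeNode"] | None = None):
        self.label = label
        self.children: list[TreeNode] = list(children) if children else []
        self.annotation: dict = {}

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def copy(self) -> "TreeNode":
        node = TreeNode(self.label, [c.copy() for c in self.children])
        node.annotation = dict(self.annotation)
        return node


class Tree:
    """A tree over taxon labels; internal nodes may be polytomous."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = False) -> "Tree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                return TreeNode(label=dnode.taxon.label if dnode.taxon else dnode.label)
            node = TreeNode(children=[convert(c) for c in dnode.child_nodes()])
            if dnode.label:
                node.annotation["label"] = dnode.label
            return node

        return cls(convert(dtree.seed_node), rooted=rooted)

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), rooted=self.rooted)

    # -- queries -----------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial splits, each given as the leaf set on the side *not*
        containing the lexicographically smallest taxon."""
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        all_leaves = frozenset(labels)
        ref = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        walk(self.root)
        return frozenset(splits)

    def is_binary_unrooted(self) -> bool:
        degrees_ok = all(
            len(n.children) in (0, 2) for n in self.root.postorder()
            if n is not self.root
        )
        return degrees_ok and len(self.root.children) == 3

    # -- rerooting ---------------------------------------------------

    def rooted_on(self, outgroup: str) -> "Tree":
        """Return a copy rooted for display on the edge leading to *outgroup*."""
        if outgroup not in self.leaf_labels:
            raise TreeError(f"outgroup {outgroup!r} is not a leaf of this tree")
        adj, labels, leaf_ids = _to_adjacency(self)
        og = next(i for i, lab in labels.items() if lab == outgroup)
        (neigh,) = adj[og]
        root_children = [_build_directed(og, neigh, adj, labels),
                         _build_directed(neigh, og, adj, labels)]
        tree = Tree(TreeNode(children=root_children), rooted=True)
        return tree

    # -- serialisation -----------------------------------------------

    def to_newick(self, annotate: str | None = None) -> str:
        """Newick string; *annotate* names an annotation key written as the
        internal-node label (e.g. ``"support"`` or ``"bremer"``)."""

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return _quote(node.label)
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if annotate and annotate in node.annotation:
                label = str(node.annotation[annotate])
            elif node.annotation.get("label"):
                label = str(node.annotation["label"])
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.to_newick()}>"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`+<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _to_adjacency(tree: Tree):
    """Undirected view: node ids -> neighbor ids, leaf id -> label."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = [0]

    def new_id() -> int:
        counter[0] += 1
        return counter[0]

    def walk(node: TreeNode, parent_id: int | None) -> int:
        nid = new_id()
        adj[nid] = []
        if node.is_leaf:
            labels[nid] = node.label
        if parent_id is not None:
            adj[nid].append(parent_id)
            adj[parent_id].append(nid)
        for c in node.children:
            walk(c, nid)
        return nid

    root_id = walk(tree.root, None)
    # suppress a degree-2 storage root so unrooted semantics are clean
    if len(adj[root_id]) == 2:
        a, b = adj[root_id]
        adj[a].remove(root_id)
        adj[b].remove(root_id)
        adj[a].append(b)
        adj[b].append(a)
        del adj[root_id]
    leaf_ids = set(labels)
    return adj, labels, leaf_ids


def _build_directed(nid: int, parent: int | None, adj, labels) -> TreeNode:
    children = [n for n in adj[nid] if n != parent]
    if not children:
        return TreeNode(label=labels[nid])
    return TreeNode(children=[_build_directed(c, nid, adj, labels)
                              for c in children])


def tree_from_clades(leaf_labels: Iterable[str],
                     clades: Iterable[frozenset[str]],
                     rooted: bool = False) -> Tree:
    """Build a (possibly polytomous) tree from a compatible set of clades.

    Each clade is a proper subset of the leaves; nesting follows set
    containment.  Used to assemble consensus trees from retained splits.
    """
    leaf_labels = list(leaf_labels)
    all_set = frozenset(leaf_labels)
    clades = sorted(set(clades), key=len, reverse=True)
    for c in clades:
        if not c < all_set or len(c) < 2:
            raise TreeError(f"invalid clade {sorted(c)}")
    root = TreeNode()
    owner: dict[frozenset, TreeNode] = {all_set: root}
    for c in clades:
        parent = min((p for p in owner if c < p), key=len)
        node = TreeNode()
        node.annotation["clade"] = c
        owner[c] = node
        owner[parent].children.append(node)
    for label in leaf_labels:
        parent = min((p for p in owner if label in p), key=len)
        owner[parent].children.append(TreeNode(label=label))
    # verify compatibility: every clade must own exactly its leaves
    for c, node in owner.items():
        got = frozenset(l.label for l in node.postorder() if l.is_leaf)
        if got != c:
            raise TreeError("clades are not mutually compatible")
    return Tree(root, rooted=rooted)
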