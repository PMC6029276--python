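"""A small mutable phylogenetic tree plus Newick round-tripping.

The tree type here is deliberately minimal: named leaves, optional
internal labels, non-negative branch lengths, and a ``rooted`` view
derived from the root degree (two children = rooted, three or more =
the conventional trifurcation placeholder for an unrooted tree).
Parsing is delegated to dendropy; serialisation is done locally so the
output dialect is pinned (labels matching ``[A-Za-z0-9_.|-]+`` are
written bare, anything else is single-quoted; branch lengths carry 10
significant digits).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "read_newick",
    "write_newick",
    "parse_newick",
    "to_newick",
    "tree_splits",
    "restricted_splits",
]


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node", length: float | None = None) -> "Node":
        if length is not None:
            child.length = length
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        clone = Node(self.name, self.length)
        for child in self.children:
            clone.add(child.copy())
        return clone


class PhyloTree:
    """A tree over uniquely labelled leaves with branch lengths >= 0."""

    def __init__(self, root: Node) -> None:
        self.root = root
        names = [leaf.name for leaf in root.leaves()]
        if any(n is None or n == "" for n in names):
            raise ValueError("every leaf must be labelled")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in root.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(
                    f"negative branch length {node.length} at {node.name!r}"
                )

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy())

    def find_leaf(self, name: str) -> Node:
        for leaf in self.root.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    # -- structural edits ------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Tree induced on the ``keep`` leaves.

        Dropped leaves are removed; internal nodes left with a single
        child are spliced out with their branch lengths summed.
        """
        keep = set(keep)
        missing = keep - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        root = self.root.copy()

        def _prune(node: Node) -> Node | None:
            if node.is_leaf:
                return node if node.name in keep else None
            kept = []
            for child in node.children:
                sub = _prune(child)
                if sub is not None:
                    kept.append(sub)
            if not kept:
                return None
            if len(kept) == 1:
                only = kept[0]
                if node.length is not None or only.length is not None:
                    only.length = (node.length or 0.0) + (only.length or 0.0)
                only.parent = None
                return only
            node.children = []
            for child in kept:
                node.add(child)
            return node

        pruned = _prune(root)
        if pruned is None:
            raise ValueError("restriction removed every leaf")
        pruned.parent = None
        pruned.length = None
        return PhyloTree(pruned)

    def unrooted(self) -> "PhyloTree":
        """Collapse a degree-2 root into the trifurcation placeholder."""
        tree = self.copy()
        root = tree.root
        if len(root.children) == 2:
            a, b = root.children
            inner = a if not a.is_leaf else b
            outer = b if inner is a else a
            if inner.is_leaf:  # two-leaf tree cannot be unrooted further
                return tree
            merged = (a.length or 0.0) + (b.length or 0.0)
            root.children = []
            for child in inner.children:
                root.add(child)
            root.add(outer, merged)
            root.name = root.name or inner.name
        return PhyloTree(tree.root)

    def root_above(self, node: Node, *, first: str = "target") -> "PhyloTree":
        """Re-root on the edge above ``node``, splitting it at its midpoint.

        ``node`` must belong to this tree.  With ``first="target"`` the
        targeted subtree becomes the first child of the new root.
        """
        if node.parent is None:
            raise ValueError("cannot root above the root")
        half = (node.length or 0.0) / 2
        parent = node.parent
        parent.children.remove(node)
        node.parent = None
        rest = _rehang(parent)
        extra = 0.0
        while not rest.is_leaf and len(rest.children) == 1:
            only = rest.children[0]
            extra += only.length or 0.0
            only.parent = None
            rest = only
        new_root = Node()
        if first == "target":
            new_root.add(node, half)
            new_root.add(rest, half + extra)
        else:
            new_root.add(rest, half + extra)
            new_root.add(node, half)
        node_tree = PhyloTree(new_root)
        self.root = new_root  # the old structure was consumed
        return node_tree


def _rehang(node: Node) -> Node:
    """Reverse the parent chain of ``node`` so it becomes a local root."""
    parent = node.parent
    old_length = node.length
    node.parent = None
    node.length = None
    if parent is not None:
        parent.children.remove(node)
        sub = _rehang(parent)
        node.add(sub, old_length)
    return node


# -- Newick ---------------------------------------------------------------

_BARE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _format_label(label: str) -> str:
    if _BARE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _serialize(node: Node) -> str:
    if node.is_leaf:
        out = _format_label(node.name or "")
    else:
        inner = ",".join(_serialize(child) for child in node.children)
        out = f"({inner})"
        if node.name:
            out += _format_label(node.name)
    if node.length is not None:
        out += f":{node.length:.10g}"
    return out


def to_newick(tree: PhyloTree) -> str:
    return _serialize(tree.root) + ";"


def parse_newick(text: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy has its own exception hierarchy
        message = str(exc)
        if "uplicate" in message or "multiple" in message.lower():
            raise ValueError(f"duplicate leaf labels in newick: {message}") from exc
        raise ValueError(f"malformed newick: {message}") from exc

    def _convert(dnode: dendropy.Node) -> Node:
        if dnode.taxon is not None:
            name = dnode.taxon.label
        else:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root)  # PhyloTree.__init__ rejects duplicate leaves


def read_newick(path: str | Path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(to_newick(tree) + "\n")


# -- bipartitions ---------------------------------------------------------


def _leafsets(root: Node) -> dict[Node, frozenset[str]]:
    sets: dict[Node, frozenset[str]] = {}
    for node in root.postorder():
        if node.is_leaf:
            sets[node] = frozenset([node.name])
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= sets[child]
            sets[node] = frozenset(acc)
    return sets


def restricted_splits(
    tree: "PhyloTree | Node", taxa: Iterable[str]
) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the tree restricted to ``taxa``.

    Each split is canonicalised as the side *not* containing the
    lexicographically smallest taxon, so the set is order-free and
    invariant to the root placement.  Accepts a tree or a bare root node.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    taxa = frozenset(taxa)
    if len(taxa) < 4:
        return set()
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    sets = _leafsets(root)
    for node, below in sets.items():
        if node.parent is None:
            continue
        side = below & taxa
        if ref in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return splits


def tree_splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial splits over all leaves (unrooted view)."""
    return restricted_splits(tree, tree.leaf_names())
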