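"""Backbone-constrained distance tree inference.

The full rRNA tree must *induce* the trusted multi-gene backbone
topology on the backbone taxa — that containment is the whole point of
constraining a single-gene tree with a phylogenomic one.  Inference
here is distance-based minimum evolution under ordinary least squares
(OLS):

1. start from the backbone topology, branch lengths refit from the
   distance matrix by OLS;
2. insert every non-backbone taxon, in ascending id order, on the edge
   that minimises the OLS minimum-evolution criterion (total fitted
   tree length, negative estimates clamped to zero), ties broken by
   the lowest edge index in a fixed postorder — leaf insertions can
   never break an induced backbone split;
3. hill-climb with nearest-neighbour interchanges on the same
   criterion, rejecting any rearrangement that would lose a backbone
   split.

The output is deterministic for identical inputs and always satisfies
``check_constraint(output, backbone)``.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .trees import Node, PhyloTree, restricted_splits, tree_splits

__all__ = [
    "prune_constraint",
    "backbone_splits",
    "check_constraint",
    "constrained_build",
    "ols_fit",
]


def prune_constraint(backbone: PhyloTree, available_taxa: set[str]) -> PhyloTree:
    """Drop backbone taxa that are unavailable (e.g. no usable rRNA gene)."""
    leaves = set(backbone.leaf_names())
    if len(leaves) < 4:
        raise ValueError("backbone must have at least 4 leaves")
    surviving = leaves & set(available_taxa)
    if len(surviving) < 3:
        raise ValueError(
            f"only {len(surviving)} backbone taxa available; need at least 3"
        )
    if surviving == leaves:
        return backbone.copy()
    return backbone.restrict(surviving)


def backbone_splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of the (unrooted view of the) tree."""
    return tree_splits(tree)


def check_constraint(
    tree: PhyloTree, backbone: PhyloTree
) -> tuple[bool, list[frozenset[str]]]:
    """True iff every backbone split is induced by the tree."""
    btaxa = set(backbone.leaf_names())
    missing = btaxa - set(tree.leaf_names())
    if missing:
        raise ValueError(f"backbone taxa absent from tree: {sorted(missing)}")
    wanted = backbone_splits(backbone)
    induced = restricted_splits(tree, btaxa)
    violated = sorted(wanted - induced, key=sorted)
    return not violated, violated


# -- OLS minimum-evolution machinery --------------------------------------


def _edge_nodes(root: Node) -> list[Node]:
    """Non-root nodes in postorder; each stands for the edge above it."""
    return [n for n in root.postorder() if n.parent is not None]


def _ols_solve(
    root: Node, dist: np.ndarray, index: dict[str, int]
) -> tuple[float, np.ndarray, list[Node]]:
    """OLS branch lengths for a fixed topology.

    Solves the normal equations (A'A) x = A'd where A is the pair-by-
    edge path incidence matrix, assembled combinatorially: two edges of
    a tree are either nested or disjoint, which gives closed forms for
    every entry of A'A, and A'd per edge is the distance mass crossing
    that edge.  Returns (total length with negatives clamped to zero,
    raw edge estimates, postorder edge nodes).
    """
    nodes = _edge_nodes(root)
    n = dist.shape[0]
    n_edges = len(nodes)
    below = np.zeros((n_edges, n), dtype=bool)
    pos: dict[int, int] = {}
    for i, node in enumerate(nodes):
        pos[id(node)] = i
        if node.is_leaf:
            below[i, index[node.name]] = True
        else:
            for child in node.children:
                below[i] |= below[pos[id(child)]]
    sizes = below.sum(axis=1)
    below_f = below.astype(np.float64)
    t = below_f @ dist
    atd = t.sum(axis=1) - (t * below_f).sum(axis=1)
    inter = below_f @ below_f.T  # |S_e ∩ S_f|
    col = sizes[None, :].astype(np.float64)
    row = sizes[:, None].astype(np.float64)
    ata = np.where(
        inter == col,                      # f nested in e (or e == f)
        col * (n - row),
        np.where(inter == row, row * (n - col), row * col),  # else disjoint
    )
    try:
        x = np.linalg.solve(ata, atd)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(ata, atd, rcond=None)[0]
    total = float(np.clip(x, 0.0, None).sum())
    return total, x, nodes


def ols_fit(tree: PhyloTree, dm: DistanceMatrix) -> PhyloTree:
    """Refit the branch lengths of ``tree`` from ``dm`` by OLS."""
    index = {name: i for i, name in enumerate(dm.ids)}
    missing = set(tree.leaf_names()) - set(index)
    if missing:
        raise ValueError(f"distance matrix missing taxa: {sorted(missing)}")
    out = tree.copy()
    sub = np.asarray(dm.data)
    _, x, nodes = _ols_solve(out.root, sub, index)
    for value, node in zip(x, nodes):
        node.length = max(float(value), 0.0)
    return PhyloTree(out.root)


def _attach(edge_node: Node, leaf: Node) -> Node:
    """Insert ``leaf`` on the edge above ``edge_node``; returns the junction."""
    parent = edge_node.parent
    junction = Node()
    slot = parent.children.index(edge_node)
    parent.children[slot] = junction
    junction.parent = parent
    junction.children = [edge_node]
    edge_node.parent = junction
    junction.add(leaf)
    return junction


def _detach(junction: Node) -> Node:
    """Undo :func:`_attach`; returns the detached leaf."""
    edge_node, leaf = junction.children
    parent = junction.parent
    slot = parent.children.index(junction)
    parent.children[slot] = edge_node
    edge_node.parent = parent
    leaf.parent = None
    return leaf


def _suppress_unary(root: Node) -> Node:
    for node in list(root.postorder()):
        if node.parent is not None and len(node.children) == 1:
            only = node.children[0]
            only.length = (only.length or 0.0) + (node.length or 0.0)
            slot = node.parent.children.index(node)
            node.parent.children[slot] = only
            only.parent = node.parent
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return root


def constrained_build(backbone: PhyloTree, dm: DistanceMatrix) -> PhyloTree:
    """Build a tree over all ``dm`` taxa that induces the backbone topology."""
    labels = list(dm.ids)
    index = {name: i for i, name in enumerate(labels)}
    btaxa = backbone.leaf_names()
    missing = set(btaxa) - set(index)
    if missing:
        raise ValueError(f"distance matrix missing backbone taxa: {sorted(missing)}")
    dist = np.asarray(dm.data, dtype=np.float64)

    work = backbone.unrooted()
    root = _suppress_unary(work.root.copy())
    wanted_splits = tree_splits(backbone)
    btaxa_set = frozenset(btaxa)

    # -- sequential OLS-ME insertion -------------------------------------
    for name in sorted(set(labels) - set(btaxa)):
        leaf = Node(name=name)
        candidates = _edge_nodes(root)
        best_total = None
        best_idx = -1
        for idx, edge_node in enumerate(candidates):
            junction = _attach(edge_node, leaf)
            total, _, _ = _ols_solve(root, dist, index)
            _detach(junction)
            if best_total is None or total < best_total - 1e-12:
                best_total = total
                best_idx = idx
        _attach(candidates[best_idx], leaf)

    # -- NNI hill-climbing under the constraint --------------------------
    current, _, _ = _ols_solve(root, dist, index)
    improved = True
    sweeps = 0
    while improved and sweeps < 100:
        improved = False
        sweeps += 1
        for v in _edge_nodes(root):
            if v.is_leaf:
                continue
            u = v.parent
            siblings = [w for w in u.children if w is not v]
            for w in siblings:
                for c in list(v.children):
                    _swap(v, c, u, w)
                    ok = restricted_splits(root, btaxa_set) >= wanted_splits
                    if ok:
                        total, _, _ = _ols_solve(root, dist, index)
                        if total < current - 1e-10:
                            current = total
                            improved = True
                            break
                    _swap(v, w, u, c)  # revert
                else:
                    continue
                break
            else:
                continue
            break

    # -- final branch lengths --------------------------------------------
    _, x, nodes = _ols_solve(root, dist, index)
    for value, node in zip(x, nodes):
        node.length = max(float(value), 0.0)
    return PhyloTree(root)


def _swap(v: Node, c: Node, u: Node, w: Node) -> None:
    """Exchange child ``c`` of ``v`` with child ``w`` of ``u`` in place."""
    ci = v.children.index(c)
    wi = u.children.index(w)
    v.children[ci] = w
    u.children[wi] = c
    w.parent = v
    c.parent = u
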