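"""Independent reference implementations used only as test oracles.

Everything here is deliberately written with different machinery from
the package: a hand-rolled Gotoh dynamic program for pairwise
alignment, explicit path-incidence least squares for OLS tree length,
and adjacency-walk path distances.  Slow and simple on purpose.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1.0, -1.0, -2.0, -1.0
NEG = float("-inf")


def affine_align(a: str, b: str):
    """Global alignment with free end gaps, affine internal gaps.

    Returns ``(n_identical, span_a, span_b)`` where spans are
    (first, last+1) aligned coordinates on each sequence.
    """
    n, m = len(a), len(b)

    def score(x: str, y: str) -> float:
        if x == "N" or y == "N":
            return MISMATCH
        return MATCH if x == y else MISMATCH

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            start = 0.0 if (i == 1 or j == 1) else NEG
            M[i, j] = score(a[i - 1], b[j - 1]) + max(
                M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], start
            )
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXT)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXT)
    best, cell = NEG, None
    for j in range(1, m + 1):
        for mat in (M, X, Y):
            if mat[n, j] > best:
                best, cell = mat[n, j], (n, j, mat)
    for i in range(1, n + 1):
        for mat in (M, X, Y):
            if mat[i, m] > best:
                best, cell = mat[i, m], (i, m, mat)
    if cell is None:  # no aligned pair at all
        return 0, (0, 0), (0, 0)
    i, j, mat = cell
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        if mat is M:
            pairs.append((i - 1, j - 1))
            start = 0.0 if (i == 1 or j == 1) else NEG
            prev = score(a[i - 1], b[j - 1])
            for cand in (M, X, Y):
                if np.isclose(cand[i - 1, j - 1] + prev, M[i, j]):
                    mat = cand
                    break
            else:
                break  # started from the free border
            i, j = i - 1, j - 1
            if mat[i, j] == NEG:
                break
        elif mat is X:
            if np.isclose(M[i - 1, j] + GAP_OPEN, X[i, j]):
                mat = M
            i -= 1
        else:
            if np.isclose(M[i, j - 1] + GAP_OPEN, Y[i, j]):
                mat = M
            j -= 1
    pairs.reverse()
    if not pairs:
        return 0, (0, 0), (0, 0)
    ident = sum(
        1 for i, j in pairs if a[i] == b[j] and a[i] != "N"
    )
    span_a = (pairs[0][0], pairs[-1][0] + 1)
    span_b = (pairs[0][1], pairs[-1][1] + 1)
    return ident, span_a, span_b


def oracle_gates(a: str, b: str, threshold: float, cov_short: float, cov_long: float) -> bool:
    ident, span_a, span_b = affine_align(a, b)
    shorter = min(len(a), len(b))
    cov_a = (span_a[1] - span_a[0]) / len(a)
    cov_b = (span_b[1] - span_b[0]) / len(b)
    if len(a) <= len(b):
        cs, cl = cov_a, cov_b
    else:
        cs, cl = cov_b, cov_a
    return ident / shorter >= threshold and cs >= cov_short and cl >= cov_long


def oracle_greedy(records, threshold=0.975, cov_short=0.9, cov_long=0.0):
    """Brute-force reimplementation of the greedy clustering rule."""
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[dict] = []
    for rec in ordered:
        for cluster in clusters:
            if oracle_gates(
                rec.sequence, cluster["rep_seq"], threshold, cov_short, cov_long
            ):
                cluster["members"].append(rec.id)
                break
        else:
            clusters.append(
                {"rep": rec.id, "rep_seq": rec.sequence, "members": [rec.id]}
            )
    return [(c["rep"], sorted(c["members"])) for c in clusters]


# -- trees ---------------------------------------------------------------


def adjacency(root):
    """Undirected weighted adjacency from a Node tree."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    for node in root.postorder():
        names[id(node)] = node.name
        adj.setdefault(id(node), [])
        if node.parent is not None:
            w = node.length or 0.0
            adj[id(node)].append((id(node.parent), w))
            adj.setdefault(id(node.parent), []).append((id(node), w))
    return adj, names


def path_distances(tree):
    """All-pairs leaf path lengths by breadth-first walks."""
    from skbio import DistanceMatrix

    adj, names = adjacency(tree.root)
    leaves = [(id(l), l.name) for l in tree.root.leaves()]
    order = sorted(nm for _, nm in leaves)
    index = {nm: i for i, nm in enumerate(order)}
    data = np.zeros((len(order), len(order)))
    for nid, nm in leaves:
        dist = {nid: 0.0}
        frontier = [nid]
        while frontier:
            cur = frontier.pop()
            for nb, w in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    frontier.append(nb)
        for oid, om in leaves:
            data[index[nm], index[om]] = dist[oid]
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix((data + data.T) / 2, ids=order)


def ols_total_bruteforce(root, dm) -> float:
    """OLS-fitted total tree length via an explicit incidence matrix."""
    adj, _ = adjacency(root)
    leaves = [(id(l), l.name) for l in root.leaves()]
    idx = {name: i for i, name in enumerate(dm.ids)}
    edges = []
    for node in root.postorder():
        if node.parent is not None:
            edges.append((id(node), id(node.parent)))
    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    rows, rhs = [], []
    dmat = np.asarray(dm.data)
    for (ui, un), (vi, vn) in itertools.combinations(leaves, 2):
        # walk the unique path u -> v
        parentof = {ui: None}
        frontier = [ui]
        while frontier:
            cur = frontier.pop()
            for nb, _ in adj[cur]:
                if nb not in parentof:
                    parentof[nb] = cur
                    frontier.append(nb)
        row = np.zeros(len(edges))
        cur = vi
        while parentof[cur] is not None:
            row[edge_index[frozenset((cur, parentof[cur]))]] = 1.0
            cur = parentof[cur]
        rows.append(row)
        rhs.append(dmat[idx[un], idx[vn]])
    x = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
    return float(np.clip(x, 0.0, None).sum())


def true_fraction_table(metadata, clade_labels) -> dict[str, Fraction]:
    """Recompute per-clade genome fractions straight from emitted metadata."""
    by_clade: dict[str, set[str]] = {}
    genome_backed: dict[str, set[str]] = {}
    for rid, row in metadata.items():
        species = rid.split(".")[0]
        if species not in clade_labels:
            continue
        label = clade_labels[species]
        by_clade.setdefault(label, set()).add(species)
        if row.source == "genome" and not rid.startswith("ghost"):
            genome_backed.setdefault(label, set()).add(species)
    return {
        label: Fraction(len(genome_backed.get(label, set())), len(species))
        for label, species in by_clade.items()
    }
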