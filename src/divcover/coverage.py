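"""Outgroup rooting, clade collapsing, and the sequenced-genome fraction.

The headline statistic: for every named cluster of OTUs, the fraction
of its OTUs whose dereplication cluster contains at least one
genome-derived sequence.  A cluster whose fraction is strictly below
1% is classified ``unsequenced`` — it is essentially invisible to
phylogenomics.  Cohort summaries (min / median / IQR) are computed
over the *sequenced* clusters only, since the unsequenced ones are the
finding, not the background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dereplicate import ClusterSet
from .trees import Node, PhyloTree, to_newick

__all__ = [
    "UNSEQUENCED_THRESHOLD",
    "CladeRecord",
    "CoverageReport",
    "root_on_outgroup",
    "collapse_clusters",
    "sequenced_fraction",
    "summarize",
    "coverage_report",
    "annotated_newick",
    "write_coverage_tsv",
    "write_coverage_json",
]

#: strict classification boundary: fraction < 1% means unsequenced
UNSEQUENCED_THRESHOLD = Fraction(1, 100)


@dataclass(frozen=True)
class CladeRecord:
    cluster_label: str
    n_otus: int
    n_genome_backed_otus: int
    fraction: Fraction
    status: str  # "sequenced" | "unsequenced"
    monophyletic: bool

    def __post_init__(self) -> None:
        if self.n_otus <= 0:
            raise ValueError("a clade must contain at least one OTU")
        if not 0 <= self.n_genome_backed_otus <= self.n_otus:
            raise ValueError("genome-backed count out of range")
        if self.fraction != Fraction(self.n_genome_backed_otus, self.n_otus):
            raise ValueError("fraction must equal the exact ratio")


@dataclass
class CoverageReport:
    clades: list[CladeRecord]
    n_unsequenced: int
    n_total_clusters: int
    #: (min, median, IQR) of fractions over sequenced clades; None when
    #: every clade is unsequenced
    summary_over_sequenced: tuple[float, float, float] | None


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


def root_on_outgroup(tree: PhyloTree, outgroup_taxa: Iterable[str]) -> PhyloTree:
    """Root on the midpoint of the edge subtending a monophyletic outgroup."""
    outgroup = frozenset(outgroup_taxa)
    leaves = frozenset(tree.leaf_names())
    if not outgroup:
        raise ValueError("outgroup is empty")
    if not outgroup < leaves:
        extra = sorted(outgroup - leaves)
        if extra:
            raise ValueError(f"outgroup taxa not in tree: {extra}")
        raise ValueError("outgroup covers every leaf; nothing left to root")
    work = tree.copy()
    sets = _leafsets(work.root)
    target = None
    orientation = "target"
    for node, below in sets.items():
        if node.parent is None:
            continue
        if below == outgroup:
            target = node
            orientation = "target"  # outgroup side becomes first child
            break
        if below == leaves - outgroup:
            target = node
            orientation = "rest"
            break
    if target is None:
        containing = min(
            (
                s
                for node, below in sets.items()
                for s in (below, leaves - below)
                if s >= outgroup
            ),
            key=len,
        )
        intruders = sorted(containing - outgroup)
        raise ValueError(f"outgroup is not monophyletic; intruding taxa: {intruders}")
    return work.root_above(target, first=orientation)


def collapse_clusters(
    rooted_tree: PhyloTree,
    label_map: Mapping[str, str],
    outgroup: Iterable[str] = (),
) -> list[tuple[str, frozenset[str], bool]]:
    """Group ingroup leaves by cluster label, flagging non-monophyly.

    A label is monophyletic iff the MRCA of its leaves contains no leaf
    carrying a different label; paraphyletic labels are reported whole,
    not split.  Returns ``(label, otu_set, monophyletic)`` sorted by
    label.
    """
    outgroup = frozenset(outgroup)
    leaves = {leaf.name: leaf for leaf in rooted_tree.root.leaves()}
    ingroup = frozenset(leaves) - outgroup
    unlabeled = sorted(ingroup - set(label_map))
    if unlabeled:
        raise ValueError(f"unlabeled ingroup OTUs: {unlabeled}")
    by_label: dict[str, set[str]] = {}
    for otu in sorted(ingroup):
        by_label.setdefault(label_map[otu], set()).add(otu)

    sets = _leafsets(rooted_tree.root)
    out: list[tuple[str, frozenset[str], bool]] = []
    for label in sorted(by_label):
        otus = by_label[label]
        mrca = _mrca([leaves[o] for o in otus])
        under = sets[mrca] & ingroup
        monophyletic = under == otus
        out.append((label, frozenset(otus), monophyletic))
    return out


def _mrca(nodes: Sequence[Node]) -> Node:
    paths = []
    for node in nodes:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        paths.append(list(reversed(path)))
    shortest = min(len(p) for p in paths)
    mrca = paths[0][0]
    for level in range(shortest):
        first = paths[0][level]
        if all(p[level] is first for p in paths):
            mrca = first
        else:
            break
    return mrca


def sequenced_fraction(
    otu_set: Iterable[str],
    cluster_set: ClusterSet,
    label: str = "",
    monophyletic: bool = True,
) -> CladeRecord:
    """The ratio of genome-backed OTUs to all OTUs in one clade."""
    otus = sorted(set(otu_set))
    if not otus:
        raise ValueError("empty OTU set")
    membership = cluster_set.cluster_of()
    missing = [o for o in otus if o not in membership]
    if missing:
        raise KeyError(f"OTUs without a cluster: {missing}")
    n = len(otus)
    k = sum(1 for o in otus if membership[o].genome_backed)
    fraction = Fraction(k, n)
    status = "unsequenced" if fraction < UNSEQUENCED_THRESHOLD else "sequenced"
    return CladeRecord(
        cluster_label=label,
        n_otus=n,
        n_genome_backed_otus=k,
        fraction=fraction,
        status=status,
        monophyletic=monophyletic,
    )


def summarize(clades: Sequence[CladeRecord]) -> CoverageReport:
    """Cohort report: unsequenced count plus min/median/IQR of the rest."""
    if not clades:
        raise ValueError("no clades to summarize")
    n_unseq = sum(1 for c in clades if c.status == "unsequenced")
    sequenced = [float(c.fraction) for c in clades if c.status == "sequenced"]
    if sequenced:
        values = np.array(sequenced)
        q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
        summary = (float(values.min()), float(np.median(values)), float(q3 - q1))
    else:
        summary = None
    return CoverageReport(
        clades=list(clades),
        n_unsequenced=n_unseq,
        n_total_clusters=len(clades),
        summary_over_sequenced=summary,
    )


def coverage_report(
    rooted_tree: PhyloTree,
    cluster_set: ClusterSet,
    label_map: Mapping[str, str],
    outgroup: Iterable[str] = (),
) -> CoverageReport:
    """Collapse, score and summarise in one call; checks the partition."""
    groups = collapse_clusters(rooted_tree, label_map, outgroup)
    clades = [
        sequenced_fraction(otus, cluster_set, label=label, monophyletic=mono)
        for label, otus, mono in groups
    ]
    ingroup_count = len(set(rooted_tree.leaf_names()) - set(outgroup))
    if sum(c.n_otus for c in clades) != ingroup_count:
        raise AssertionError("clade OTU counts do not partition the ingroup")
    return summarize(clades)


def annotated_newick(
    rooted_tree: PhyloTree,
    clades: Sequence[CladeRecord],
    groups: Mapping[str, Iterable[str]],
) -> str:
    """Newick with each clade's MRCA labelled ``label [n/k/fraction]``.

    Paraphyletic labels get a trailing ``*`` — the label, not the
    subtree, is the unit being annotated.
    """
    tree = rooted_tree.copy()
    leaves = {leaf.name: leaf for leaf in tree.root.leaves()}
    by_label = {c.cluster_label: c for c in clades}
    for label, otus in groups.items():
        record = by_label[label]
        mrca = _mrca([leaves[o] for o in otus])
        star = "" if record.monophyletic else "*"
        mrca.name = (
            f"{label}{star} [{record.n_otus}/{record.n_genome_backed_otus}/"
            f"{float(record.fraction):.3f}]"
        )
    return to_newick(tree)


def write_coverage_tsv(report: CoverageReport, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("# quantiles: linear interpolation\n")
        fh.write(
            "cluster_label\tn_otus\tn_genome_backed_otus\tfraction\t"
            "status\tmonophyletic\n"
        )
        for c in report.clades:
            fh.write(
                f"{c.cluster_label}\t{c.n_otus}\t{c.n_genome_backed_otus}\t"
                f"{float(c.fraction):.3f}\t{c.status}\t{c.monophyletic}\n"
            )
        fh.write(f"# n_unsequenced\t{report.n_unsequenced}\n")
        fh.write(f"# n_total_clusters\t{report.n_total_clusters}\n")
        if report.summary_over_sequenced is not None:
            mn, med, iqr = report.summary_over_sequenced
            fh.write(
                f"# sequenced_summary\tmin={mn:.3f} median={med:.3f} iqr={iqr:.3f}\n"
            )


def write_coverage_json(report: CoverageReport, path: str | Path) -> None:
    payload = {
        "clades": [
            {
                "cluster_label": c.cluster_label,
                "n_otus": c.n_otus,
                "n_genome_backed_otus": c.n_genome_backed_otus,
                "fraction": float(c.fraction),
                "status": c.status,
                "monophyletic": c.monophyletic,
            }
            for c in report.clades
        ],
        "n_unsequenced": report.n_unsequenced,
        "n_total_clusters": report.n_total_clusters,
        "summary_over_sequenced": report.summary_over_sequenced,
    }
    with open(path, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
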