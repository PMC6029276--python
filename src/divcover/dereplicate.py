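"""Greedy identity-threshold dereplication of rRNA sequences into OTUs.

The clustering reproduces the incremental greedy scheme of cd-hit-est:
records are sorted by decreasing length, each record joins the first
existing cluster whose *representative* it matches, otherwise it founds
a new cluster with itself as representative.  A match requires all
three gates to pass simultaneously:

* identity >= ``threshold`` (default 97.5%), where identity is the
  number of identical aligned positions divided by the length of the
  shorter sequence (cd-hit-est's denominator);
* aligned coverage of the shorter sequence >= ``cov_short_min``
  (default 0.9);
* aligned coverage of the longer sequence >= ``cov_long_min``
  (default 0.0, i.e. unconstrained).

Unlike CD-HIT there is no k-mer prescreen: every candidate
representative is checked by an actual alignment, so the result is
exactly the greedy definition above and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._align import align_stats, make_aligner
from .io import SeqRecord

__all__ = [
    "IdentityResult",
    "OtuCluster",
    "ClusterSet",
    "pairwise_identity",
    "greedy_cluster",
    "promote_genome_representatives",
]


@dataclass(frozen=True)
class IdentityResult:
    """Identity and per-sequence coverage of one pairwise alignment."""

    identity: float
    cov_longer: float
    cov_shorter: float

    def passes(
        self, threshold: float, cov_short_min: float, cov_long_min: float
    ) -> bool:
        return (
            self.identity >= threshold
            and self.cov_shorter >= cov_short_min
            and self.cov_longer >= cov_long_min
        )


@dataclass
class OtuCluster:
    representative_id: str
    member_ids: list[str]
    genome_backed: bool

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"representative {self.representative_id!r} not among members"
            )


@dataclass
class ClusterSet:
    """A partition of record ids into OTU clusters."""

    clusters: list[OtuCluster]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cluster in self.clusters:
            for mid in cluster.member_ids:
                if mid in seen:
                    raise ValueError(f"record {mid!r} appears in two clusters")
                seen.add(mid)

    def __len__(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> set[str]:
        return {m for c in self.clusters for m in c.member_ids}

    def representative_ids(self) -> list[str]:
        return [c.representative_id for c in self.clusters]

    def cluster_of(self) -> dict[str, OtuCluster]:
        return {m: c for c in self.clusters for m in c.member_ids}


def pairwise_identity(a: str, b: str, _aligner=None) -> IdentityResult:
    """Global end-gap-free alignment identity and coverages of two sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner if _aligner is not None else make_aligner()
    identical, span_a, span_b, _ = align_stats(a, b, aligner)
    shorter, longer = sorted((len(a), len(b)))
    cov_a = (span_a[1] - span_a[0]) / len(a)
    cov_b = (span_b[1] - span_b[0]) / len(b)
    if len(a) <= len(b):
        cov_shorter, cov_longer = cov_a, cov_b
    else:
        cov_shorter, cov_longer = cov_b, cov_a
    return IdentityResult(
        identity=identical / shorter,
        cov_longer=cov_longer,
        cov_shorter=cov_shorter,
    )


def greedy_cluster(
    records: list[SeqRecord],
    threshold: float = 0.975,
    cov_short_min: float = 0.9,
    cov_long_min: float = 0.0,
) -> ClusterSet:
    """Cluster records greedily against cluster representatives.

    Records are processed by (length descending, id ascending); ties in
    match eligibility go to the first-founded cluster.  The result is a
    partition: every input id lands in exactly one cluster.
    """
    if not records:
        raise ValueError("no records to cluster")
    aligner = make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SeqRecord] = []
    clusters: list[OtuCluster] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            result = pairwise_identity(rec.sequence, rep.sequence, aligner)
            if result.passes(threshold, cov_short_min, cov_long_min):
                cluster.member_ids.append(rec.id)
                if rec.source == "genome":
                    cluster.genome_backed = True
                placed = True
                break
        if not placed:
            clusters.append(
                OtuCluster(
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    genome_backed=rec.source == "genome",
                )
            )
            reps.append(rec)
    return ClusterSet(clusters=clusters)


def promote_genome_representatives(
    cluster_set: ClusterSet, records: list[SeqRecord]
) -> tuple[ClusterSet, int]:
    """Swap in a genome-derived member as representative where possible.

    In every cluster that contains at least one genome-source member but
    whose current representative is not genome-source, the representative
    is replaced by a genome-source member (longest first, then id
    ascending).  The partition itself never changes.  Returns the new
    cluster set and the number of replacements, mirroring the swap of
    representatives that lets phylogenomic constraints be enforced on the
    rRNA tree.
    """
    by_id = {rec.id: rec for rec in records}
    missing = sorted(cluster_set.member_ids() - set(by_id))
    if missing:
        raise KeyError(f"cluster members without records: {missing}")
    replaced = 0
    new_clusters: list[OtuCluster] = []
    for cluster in cluster_set.clusters:
        genome_members = [
            by_id[m] for m in cluster.member_ids if by_id[m].source == "genome"
        ]
        rep_is_genome = by_id[cluster.representative_id].source == "genome"
        if genome_members and not rep_is_genome:
            new_rep = sorted(genome_members, key=lambda r: (-len(r.sequence), r.id))[0]
            new_clusters.append(
                OtuCluster(
                    representative_id=new_rep.id,
                    member_ids=list(cluster.member_ids),
                    genome_backed=True,
                )
            )
            replaced += 1
        else:
            new_clusters.append(
                OtuCluster(
                    representative_id=cluster.representative_id,
                    member_ids=list(cluster.member_ids),
                    genome_backed=cluster.genome_backed,
                )
            )
    return ClusterSet(clusters=new_clusters), replaced
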