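"""End-to-end orchestration: merge -> dereplicate -> align -> trim ->
distances -> constrained tree -> coverage report.

`run_study` drives the whole chain on an in-memory
:class:`~divcover.simulate.StudyBundle` (or any object with the same
fields built from files) and returns every intermediate product, so
tests and callers can interrogate any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import DistanceMatrix

from .constrained_tree import check_constraint, constrained_build, prune_constraint
from .coverage import CoverageReport, coverage_report, root_on_outgroup
from .dereplicate import ClusterSet, greedy_cluster, promote_genome_representatives
from .distances import distance_matrix
from .io import Alignment, SeqRecord
from .merge import MergeReport, merge_sources
from .msa import TrimResult, extend_alignment, trim_alignment
from .trees import PhyloTree

__all__ = ["PipelineParams", "PipelineResult", "run_study"]


@dataclass(frozen=True)
class PipelineParams:
    identity_threshold: float = 0.975
    cov_short_min: float = 0.9
    cov_long_min: float = 0.0
    entropy_cutoff: float = 0.5
    gap_cutoff: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "identity_threshold",
            "cov_short_min",
            "cov_long_min",
            "entropy_cutoff",
            "gap_cutoff",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class PipelineResult:
    merged: list[SeqRecord]
    merge_report: MergeReport
    cluster_set: ClusterSet
    n_promoted: int
    extended: Alignment
    trim: TrimResult
    dm: DistanceMatrix
    tree: PhyloTree
    constraint_ok: bool
    violated_splits: list
    rooted_tree: PhyloTree
    coverage: CoverageReport


def run_study(bundle, params: PipelineParams | None = None) -> PipelineResult:
    """Run the full pipeline on a study bundle with planted truth."""
    params = params or PipelineParams()
    cfg = bundle.config

    merged, merge_report = merge_sources(
        bundle.reference,
        bundle.genome,
        bundle.collection,
        expected_root=cfg.ingroup_name,
        allowed_clades=(cfg.outgroup_name,),
        metadata=bundle.metadata,
    )

    clusters = greedy_cluster(
        merged,
        threshold=params.identity_threshold,
        cov_short_min=params.cov_short_min,
        cov_long_min=params.cov_long_min,
    )
    clusters, n_promoted = promote_genome_representatives(clusters, merged)

    rep_ids = sorted(clusters.representative_ids())
    by_id = {rec.id: rec for rec in merged}
    seed_ids = set(bundle.seed_alignment.ids)
    new_records = [by_id[rid] for rid in rep_ids if rid not in seed_ids]
    extended, skipped = extend_alignment(bundle.seed_alignment, new_records)
    if skipped:
        raise RuntimeError(f"unplaceable OTU representatives: {skipped}")

    otu_alignment = extended.subset_rows(rep_ids)
    trim = trim_alignment(
        otu_alignment,
        entropy_cutoff=params.entropy_cutoff,
        gap_cutoff=params.gap_cutoff,
    )
    if trim.dropped_rows:
        raise RuntimeError(
            f"OTU rows lost all sites during trimming: {trim.dropped_rows}"
        )

    dm = distance_matrix(trim.alignment)
    backbone = prune_constraint(bundle.backbone, set(dm.ids))
    tree = constrained_build(backbone, dm)
    ok, violated = check_constraint(tree, backbone)

    outgroup = set(bundle.outgroup_ids) & set(tree.leaf_names())
    rooted = root_on_outgroup(tree, outgroup)
    labels = {
        rid: bundle.label_map[rid]
        for rid in tree.leaf_names()
        if rid in bundle.label_map
    }
    report = coverage_report(rooted, clusters, labels, outgroup)

    return PipelineResult(
        merged=merged,
        merge_report=merge_report,
        cluster_set=clusters,
        n_promoted=n_promoted,
        extended=extended,
        trim=trim,
        dm=dm,
        tree=tree,
        constraint_ok=ok,
        violated_splits=violated,
        rooted_tree=rooted,
        coverage=report,
    )
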