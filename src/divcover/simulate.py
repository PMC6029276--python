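"""Synthetic studies with known ground truth.

A study emulates the structure of a genome-representation survey of a
bacterial class: a species tree (pure-birth), HKY-evolved rRNA-like
sequences, per-species database records replicated below the
dereplication threshold, clade-structured genome availability, a
curated seed alignment over a species subset, a backbone constraint
tree over genome-backed species, and an outgroup clan on a long stem
for rooting.  Everything is deterministic under the configured seed,
and the returned :class:`StudyTruth` makes every pipeline stage
checkable against planted truth.

Default study conditions (one species = one OTU):

* 60 ingroup species in 12 clades, 8 outgroup species;
* amplicon-length sequences (450 nt), HKY kappa = 2, no indels;
* ingroup tree depth 0.25 substitutions/site plus a floor of 0.1 on
  the divergence between any two species, far above the 97.5%
  dereplication threshold;
* 1-3 database records per species mutated at 0.3% divergence, far
  below the threshold;
* genome-backed flags drawn per species with its clade's probability
  (four clades are fixed at probability zero — the planted
  "unsequenced" diversity); clades with positive probability are
  conditioned on at least one flagged species, and flags are topped up
  if fewer than ``backbone_size`` species were flagged in total.
"""

from __future__ import annotations


import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .io import (
    Alignment,
    MetadataRow,
    SeqRecord,
    write_alignment_fasta,
    write_fasta,
    write_metadata,
)
from .trees import Node, PhyloTree, write_newick

__all__ = [
    "StudyConfig",
    "StudyTruth",
    "StudyBundle",
    "simulate_yule_tree",
    "evolve_sequences",
    "make_database_records",
    "derive_seed_and_backbone",
    "simulate_study",
    "write_study",
]

_DEFAULT_GENOME_PROBS = (0.0, 0.0, 0.0, 0.0, 0.5, 0.5, 0.7, 0.7, 0.9, 0.9, 1.0, 1.0)


@dataclass(frozen=True)
class StudyConfig:
    n_species: int = 60
    replicates_per_species: tuple[int, int] = (1, 3)
    within_species_divergence: float = 0.003
    seq_length: int = 450
    n_clades: int = 12
    genome_prob_per_clade: tuple[float, ...] = _DEFAULT_GENOME_PROBS
    backbone_size: int = 20
    outgroup_size: int = 8
    seed: int = 0
    # tree geometry (substitutions/site)
    birth_rate: float = 1.0
    tree_depth: float = 0.25
    min_species_separation: float = 0.1
    outgroup_depth: float = 0.08
    outgroup_stem: float = 0.4
    ingroup_stem: float = 0.05
    kappa: float = 2.0
    # database irregularities
    n_incongruent: int = 2
    n_rrna_less_genomes: int = 3
    seed_fraction: float = 0.5
    collection_fraction: float = 0.1
    ingroup_name: str = "Oxyphotobacteria"
    outgroup_name: str = "Melainabacteria"

    def __post_init__(self) -> None:
        if self.n_clades > self.n_species:
            raise ValueError("n_clades must not exceed n_species")
        if len(self.genome_prob_per_clade) != self.n_clades:
            raise ValueError("need one genome probability per clade")
        if not all(0 <= p <= 1 for p in self.genome_prob_per_clade):
            raise ValueError("genome probabilities must be in [0, 1]")
        if self.outgroup_size < 1:
            raise ValueError("outgroup_size must be >= 1")
        lo, hi = self.replicates_per_species
        if not 1 <= lo <= hi:
            raise ValueError("replicates_per_species must be a range >= 1")


@dataclass
class StudyTruth:
    true_tree: PhyloTree  # species tree, ingroup + outgroup clan
    true_partition: dict[str, list[str]]  # species -> record ids
    true_genome_flags: dict[str, bool]
    true_clade_labels: dict[str, str]
    true_fractions: dict[str, Fraction]


@dataclass
class StudyBundle:
    config: StudyConfig
    reference: list[SeqRecord]
    genome: list[SeqRecord]
    collection: list[SeqRecord]
    metadata: dict[str, MetadataRow]
    seed_alignment: Alignment
    backbone: PhyloTree
    outgroup_ids: list[str]
    label_map: dict[str, str]
    truth: StudyTruth

    def all_records(self) -> list[SeqRecord]:
        return self.reference + self.genome + self.collection


def _as_rng(seed: "int | np.random.Generator") -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_yule_tree(
    n_species: int, birth_rate: float = 1.0, seed: "int | np.random.Generator" = 0
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_species`` contemporaneous leaves.

    Waiting times between speciations are Exp(k * birth_rate) while k
    lineages are alive; a final hanging interval Exp(n * birth_rate) is
    included, so the expected root-to-tip depth is the classic
    sum over k = 2..n of 1 / (k * birth_rate).
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _as_rng(seed)
    root = Node()
    first, second = Node(), Node()
    root.add(first)
    root.add(second)
    active: list[tuple[Node, float]] = [(first, 0.0), (second, 0.0)]
    now = 0.0
    while len(active) < n_species:
        k = len(active)
        now += rng.exponential(1.0 / (k * birth_rate))
        node, born = active.pop(int(rng.integers(k)))
        node.length = now - born
        left, right = Node(), Node()
        node.add(left)
        node.add(right)
        active.append((left, now))
        active.append((right, now))
    now += rng.exponential(1.0 / (n_species * birth_rate))
    for i, (leaf, born) in enumerate(active):
        leaf.length = now - born
    for i, leaf in enumerate(root.leaves()):  # stable left-to-right naming
        leaf.name = f"t{i + 1:03d}"
    return PhyloTree(root)


def _tree_depth(tree: PhyloTree) -> float:
    best = 0.0
    for leaf in tree.root.leaves():
        d, node = 0.0, leaf
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        best = max(best, d)
    return best


def _scale_tree(tree: PhyloTree, target_depth: float) -> None:
    depth = _tree_depth(tree)
    if depth <= 0:
        return
    factor = target_depth / depth
    for node in tree.root.postorder():
        if node.length is not None:
            node.length *= factor


def _hky_transition(kappa: float, t: float) -> np.ndarray:
    # equal base frequencies; rate matrix normalised to one expected
    # substitution per site per unit branch length
    q = np.full((4, 4), 1.0)
    q[0, 2] = q[2, 0] = q[1, 3] = q[3, 1] = kappa  # A<->G, C<->T transitions
    np.fill_diagonal(q, 0.0)
    q *= 0.25
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.sum(0.25 * np.diag(q))
    return expm(q * (t / scale))


def evolve_sequences(
    tree: PhyloTree,
    seq_length: int,
    kappa: float = 2.0,
    seed: "int | np.random.Generator" = 0,
) -> dict[str, str]:
    """Simulate sequences down the tree under HKY (equal frequencies).

    Branch lengths are in substitutions/site; there are no indels, so
    every leaf sequence has length ``seq_length`` and the set of leaf
    sequences is, column for column, already aligned.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = _as_rng(seed)
    bases = np.array(list("ACGT"))
    states = {id(tree.root): rng.integers(0, 4, size=seq_length)}
    out: dict[str, str] = {}
    for node in _preorder(tree.root):
        if node.parent is None:
            continue
        parent_state = states[id(node.parent)]
        p = _hky_transition(kappa, node.length or 0.0)
        cum = p.cumsum(axis=1)
        draw = rng.random(seq_length)
        state = (draw[:, None] > cum[parent_state]).sum(axis=1)
        states[id(node)] = state
        if node.is_leaf:
            out[node.name] = "".join(bases[state])
    return out


def _preorder(root: Node):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        for child in reversed(node.children):
            stack.append(child)


def _mutate(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return sequence
    arr = np.array(list(sequence))
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _assign_clades(ingroup_root: Node, n_clades: int) -> dict[str, str]:
    """Partition the ingroup leaves into ``n_clades`` contiguous subtrees."""
    parts: list[Node] = [ingroup_root]
    while len(parts) < n_clades:
        splittable = [p for p in parts if not p.is_leaf]
        largest = max(
            splittable,
            key=lambda p: (len(p.leaves()), min(leaf.name for leaf in p.leaves())),
        )
        parts.remove(largest)
        parts.extend(largest.children)
    labeled: dict[str, str] = {}
    keyed = sorted(parts, key=lambda p: min(leaf.name for leaf in p.leaves()))
    for i, part in enumerate(keyed):
        for leaf in part.leaves():
            labeled[leaf.name] = f"clade_{i + 1:02d}"
    return labeled


def _draw_genome_flags(
    clade_labels: Mapping[str, str],
    probs_by_label: Mapping[str, float],
    backbone_size: int,
    rng: np.random.Generator,
) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    by_clade: dict[str, list[str]] = {}
    for sp in sorted(clade_labels):
        by_clade.setdefault(clade_labels[sp], []).append(sp)
    for label in sorted(by_clade):
        members = by_clade[label]
        p = probs_by_label[label]
        if p == 0:
            for sp in members:
                flags[sp] = False
            continue
        drawn = [bool(rng.random() < p) for _ in members]
        if not any(drawn):  # a "sequenced" clade is sequenced by construction
            drawn[int(rng.integers(len(members)))] = True
        for sp, f in zip(members, drawn):
            flags[sp] = f
    # top up so a backbone of the requested size always exists
    eligible = [
        sp
        for sp in sorted(flags)
        if not flags[sp] and probs_by_label[clade_labels[sp]] > 0
    ]
    shortage = backbone_size - sum(flags.values())
    if shortage > 0:
        if shortage > len(eligible):
            raise ValueError("cannot flag enough species for the backbone")
        extra = rng.choice(len(eligible), size=shortage, replace=False)
        for i in sorted(extra):
            flags[eligible[i]] = True
    return flags


def _species_ids(config: StudyConfig) -> tuple[list[str], list[str]]:
    ingroup = [f"s{i + 1:03d}" for i in range(config.n_species)]
    outgroup = [f"og{i + 1:02d}" for i in range(config.outgroup_size)]
    return ingroup, outgroup


def _build_species_tree(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[PhyloTree, list[str], list[str]]:
    ingroup_names, outgroup_names = _species_ids(config)
    ingroup = simulate_yule_tree(config.n_species, config.birth_rate, rng)
    _scale_tree(ingroup, config.tree_depth)
    for leaf, name in zip(ingroup.root.leaves(), ingroup_names):
        leaf.name = name
        leaf.length = (leaf.length or 0.0) + config.min_species_separation / 2
    if config.outgroup_size >= 3:
        outgroup = simulate_yule_tree(config.outgroup_size, config.birth_rate, rng)
        _scale_tree(outgroup, config.outgroup_depth)
        og_root = outgroup.root
    elif config.outgroup_size == 2:
        og_root = Node()
        og_root.add(Node(), config.outgroup_depth)
        og_root.add(Node(), config.outgroup_depth)
    else:
        og_root = Node()
    og_leaves = og_root.leaves() if not og_root.is_leaf else [og_root]
    for leaf, name in zip(og_leaves, outgroup_names):
        leaf.name = name
        leaf.length = (leaf.length or 0.0) + config.min_species_separation / 2
    root = Node()
    root.add(ingroup.root, config.ingroup_stem)
    root.add(og_root, config.outgroup_stem)
    return PhyloTree(root), ingroup_names, outgroup_names


def make_database_records(
    leaf_sequences: Mapping[str, str],
    clade_labels: Mapping[str, str],
    genome_flags: Mapping[str, bool],
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[list[SeqRecord], dict[str, MetadataRow], dict[str, str], dict[str, list[str]]]:
    """Per-species database records with source tags and lineages.

    A flagged species contributes its exact leaf sequence as a
    genome-source record; all other records are replicates mutated at
    the within-species divergence and tagged reference or collection
    (9:1 by default).  A few extra reference records get a deliberately
    incongruent lineage, and a few metadata-only genome accessions are
    emitted with no sequence at all.
    """
    ingroup_names, outgroup_names = _species_ids(config)
    lo, hi = config.replicates_per_species
    records: list[SeqRecord] = []
    metadata: dict[str, MetadataRow] = {}
    label_map: dict[str, str] = {}
    partition: dict[str, list[str]] = {}

    def _add(rec: SeqRecord, species: str) -> None:
        records.append(rec)
        metadata[rec.id] = MetadataRow(
            rec.id, rec.source, rec.lineage, rec.genome_accession
        )
        partition.setdefault(species, []).append(rec.id)

    acc_counter = 0
    for sp in ingroup_names:
        label = clade_labels[sp]
        lineage = ("Bacteria", "Cyanobacteria", config.ingroup_name, label, sp)
        k = int(rng.integers(lo, hi + 1))
        start = 1
        if genome_flags[sp]:
            acc_counter += 1
            rec = SeqRecord(
                id=f"{sp}.g",
                sequence=leaf_sequences[sp],
                source="genome",
                lineage=lineage,
                genome_accession=f"GCA_{acc_counter:07d}.1",
            )
            _add(rec, sp)
            label_map[rec.id] = label
            k -= 1
        for j in range(start, start + k):
            source = "collection" if rng.random() < config.collection_fraction else "reference"
            rec = SeqRecord(
                id=f"{sp}.a{j}",
                sequence=_mutate(
                    leaf_sequences[sp], config.within_species_divergence, rng
                ),
                source=source,
                lineage=lineage if source == "reference" else (),
                genome_accession=None,
            )
            _add(rec, sp)
            label_map[rec.id] = label
    for sp in outgroup_names:
        lineage = ("Bacteria", "Cyanobacteria", config.outgroup_name, sp)
        rec = SeqRecord(
            id=f"{sp}.a1",
            sequence=_mutate(
                leaf_sequences[sp], config.within_species_divergence, rng
            ),
            source="reference",
            lineage=lineage,
            genome_accession=None,
        )
        _add(rec, sp)
    # mis-lineaged reference records (removed by the congruence filter)
    hosts = rng.choice(len(ingroup_names), size=config.n_incongruent, replace=False)
    for i in sorted(hosts):
        sp = ingroup_names[i]
        rec = SeqRecord(
            id=f"{sp}.x1",
            sequence=_mutate(
                leaf_sequences[sp], config.within_species_divergence, rng
            ),
            source="reference",
            lineage=("Bacteria", "Proteobacteria", sp),
            genome_accession=None,
        )
        _add(rec, sp)
        label_map[rec.id] = clade_labels[sp]
    # genome accessions with no rRNA gene: metadata only, no sequence
    for i in range(config.n_rrna_less_genomes):
        acc_counter += 1
        rid = f"ghost{i + 1:02d}.g"
        metadata[rid] = MetadataRow(
            rid,
            "genome",
            ("Bacteria", "Cyanobacteria", config.ingroup_name),
            f"GCA_{acc_counter:07d}.1",
        )
    return records, metadata, label_map, partition


def derive_seed_and_backbone(
    truth: StudyTruth,
    config: StudyConfig,
    leaf_sequences: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[Alignment, PhyloTree]:
    """Curated seed alignment and backbone constraint tree.

    The seed holds the representative record of a stratified species
    subset (one per clade at least); with no indels the raw sequences
    are already aligned.  The backbone is the true species tree
    restricted to ``backbone_size`` genome-flagged species, with leaves
    renamed to the species' genome record ids — emulating a correct
    phylogenomic constraint over sequenced organisms.
    """
    flagged = [sp for sp in sorted(truth.true_genome_flags) if truth.true_genome_flags[sp]]
    if len(flagged) < config.backbone_size:
        raise ValueError(
            f"only {len(flagged)} genome-flagged species; "
            f"backbone needs {config.backbone_size}"
        )
    rep_of = {
        sp: (f"{sp}.g" if truth.true_genome_flags.get(sp, False) else f"{sp}.a1")
        for sp in truth.true_partition
    }
    # stratified seed subset: ceil(seed_fraction * clade size) per clade
    by_clade: dict[str, list[str]] = {}
    for sp, label in sorted(truth.true_clade_labels.items()):
        by_clade.setdefault(label, []).append(sp)
    seed_species: list[str] = []
    for label in sorted(by_clade):
        members = by_clade[label]
        take = max(1, round(config.seed_fraction * len(members)))
        picked = rng.choice(len(members), size=take, replace=False)
        seed_species.extend(members[i] for i in sorted(picked))
    seed = Alignment(
        ids=[rep_of[sp] for sp in seed_species],
        matrix=[leaf_sequences[sp] for sp in seed_species],
    )
    chosen = rng.choice(len(flagged), size=config.backbone_size, replace=False)
    backbone_species = [flagged[i] for i in sorted(chosen)]
    backbone = truth.true_tree.restrict(backbone_species)
    for leaf in backbone.root.leaves():
        leaf.name = rep_of[leaf.name]
    return seed, backbone


def simulate_study(config: StudyConfig) -> StudyBundle:
    """Generate a complete, internally consistent synthetic study."""
    rng = np.random.default_rng(config.seed)
    tree, ingroup_names, outgroup_names = _build_species_tree(config, rng)
    ingroup_root = tree.root.children[0]
    clade_labels = _assign_clades(ingroup_root, config.n_clades)
    probs_by_label = {
        f"clade_{i + 1:02d}": p for i, p in enumerate(config.genome_prob_per_clade)
    }
    flags = _draw_genome_flags(
        clade_labels, probs_by_label, config.backbone_size, rng
    )
    for sp in outgroup_names:
        flags.setdefault(sp, False)
    leaf_sequences = evolve_sequences(tree, config.seq_length, config.kappa, rng)
    records, metadata, label_map, partition = make_database_records(
        leaf_sequences, clade_labels, flags, config, rng
    )
    fractions: dict[str, Fraction] = {}
    by_clade: dict[str, list[str]] = {}
    for sp, label in clade_labels.items():
        by_clade.setdefault(label, []).append(sp)
    for label, members in sorted(by_clade.items()):
        fractions[label] = Fraction(
            sum(1 for sp in members if flags[sp]), len(members)
        )
    truth = StudyTruth(
        true_tree=tree,
        true_partition=partition,
        true_genome_flags=flags,
        true_clade_labels=clade_labels,
        true_fractions=fractions,
    )
    seed_aln, backbone = derive_seed_and_backbone(truth, config, leaf_sequences, rng)
    outgroup_ids = [rid for sp in outgroup_names for rid in partition[sp]]
    return StudyBundle(
        config=config,
        reference=[r for r in records if r.source == "reference"],
        genome=[r for r in records if r.source == "genome"],
        collection=[r for r in records if r.source == "collection"],
        metadata=metadata,
        seed_alignment=seed_aln,
        backbone=backbone,
        outgroup_ids=outgroup_ids,
        label_map=label_map,
        truth=truth,
    )


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Persist a study as plain-text artifacts; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "genome": out / "genome.fasta",
        "collection": out / "collection.fasta",
        "metadata": out / "metadata.tsv",
        "seed_alignment": out / "seed.afa",
        "backbone": out / "backbone.nwk",
        "outgroup": out / "outgroup.txt",
        "labels": out / "labels.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(bundle.reference, paths["reference"])
    write_fasta(bundle.genome, paths["genome"])
    write_fasta(bundle.collection, paths["collection"])
    write_metadata(bundle.metadata.values(), paths["metadata"])
    write_alignment_fasta(bundle.seed_alignment, paths["seed_alignment"])
    write_newick(bundle.backbone, paths["backbone"])
    paths["outgroup"].write_text("\n".join(bundle.outgroup_ids) + "\n")
    with open(paths["labels"], "w", newline="\n") as fh:
        fh.write("id\tcluster_label\n")
        for rid, label in sorted(bundle.label_map.items()):
            fh.write(f"{rid}\t{label}\n")
    truth = bundle.truth
    payload = {
        "true_partition": truth.true_partition,
        "true_genome_flags": truth.true_genome_flags,
        "true_clade_labels": truth.true_clade_labels,
        "true_fractions": {k: [v.numerator, v.denominator] for k, v in truth.true_fractions.items()},
    }
    with open(paths["truth"], "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
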