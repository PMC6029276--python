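import numpy as np
import pytest


from divcover.constrained_tree import (
    backbone_splits,
    check_constraint,
    constrained_build,
    ols_fit,
    prune_constraint,
)
from divcover.simulate import simulate_yule_tree
from divcover.trees import Node, PhyloTree, parse_newick, to_newick, tree_splits

from _oracles import ols_total_bruteforce, path_distances


def star(n):
    root = Node()
    for i in range(n):
        root.add(Node(name=f"t{i}"), 1.0)
    return PhyloTree(root)


class TestPruneConstraint:
    def test_pruning_named_leaves(self):
        tree = star(6)
        pruned = prune_constraint(tree, {"t0", "t1", "t2", "t3"})
        assert sorted(pruned.leaf_names()) == ["t0", "t1", "t2", "t3"]

    def test_pruning_nothing_keeps_topology(self):
        tree = simulate_yule_tree(8, 1.0, seed=3)
        pruned = prune_constraint(tree, set(tree.leaf_names()))
        assert tree_splits(pruned) == tree_splits(tree)

    def test_pruning_is_idempotent(self):
        tree = simulate_yule_tree(10, 1.0, seed=4)
        keep = set(tree.leaf_names()[:7])
        once = prune_constraint(tree, keep)
        twice = prune_constraint(once, keep)
        assert to_newick(once) == to_newick(twice)

    def test_path_lengths_preserved_through_pruning(self):
        tree = simulate_yule_tree(10, 1.0, seed=5)
        keep = sorted(tree.leaf_names())[:5]
        full = path_distances(tree)
        pruned = path_distances(prune_constraint(tree, set(keep)))
        for u in keep:
            for v in keep:
                assert pruned[u, v] == pytest.approx(full[u, v], rel=1e-9)

    def test_too_few_survivors_is_error(self):
        tree = star(5)
        with pytest.raises(ValueError, match="at least 3"):
            prune_constraint(tree, {"t0", "t1"})


class TestBackboneSplits:
    def test_quartet_has_one_split(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        splits = backbone_splits(tree)
        assert len(splits) == 1
        (split,) = splits
        assert split in ({"a", "b"}, {"c", "d"})

    def test_star_tree_has_no_splits(self):
        assert backbone_splits(star(6)) == set()

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_binary_tree_has_n_minus_3_splits(self, n):
        tree = simulate_yule_tree(n, 1.0, seed=n)
        assert len(backbone_splits(tree)) == n - 3


class TestCheckConstraint:
    def test_tree_satisfies_its_own_backbone(self):
        tree = simulate_yule_tree(10, 1.0, seed=1)
        backbone = tree.restrict(sorted(tree.leaf_names())[:6])
        ok, violated = check_constraint(tree, backbone)
        assert ok and violated == []

    def test_conflicting_quartet_reported(self):
        backbone = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        tree = parse_newick("((a:1,c:1):1,(b:1,d:1):1);")
        ok, violated = check_constraint(tree, backbone)
        assert not ok
        assert len(violated) == 1


class TestOlsFit:
    def test_recovers_additive_branch_lengths(self):
        tree = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.05);")
        dm = path_distances(tree)
        fitted = ols_fit(tree, dm)
        assert path_distances(fitted)["a", "c"] == pytest.approx(0.5, abs=1e-9)
        for node, orig in zip(fitted.root.postorder(), tree.root.postorder()):
            if node.length is not None:
                assert node.length == pytest.approx(orig.length, abs=1e-9)


class TestConstrainedBuild:
    def test_no_extra_taxa_returns_backbone_topology(self):
        backbone = simulate_yule_tree(8, 1.0, seed=9)
        dm = path_distances(backbone)
        out = constrained_build(backbone, dm)
        assert tree_splits(out) == tree_splits(backbone)
        assert sorted(out.leaf_names()) == sorted(backbone.leaf_names())

    def test_insertion_edge_matches_exhaustive_ols_oracle(self):
        """The chosen attachment edge minimises OLS tree length over all edges."""
        true = simulate_yule_tree(5, 1.0, seed=21)
        names = sorted(true.leaf_names())
        backbone = true.restrict(names[:4])
        dm = path_distances(true)
        out = constrained_build(backbone, dm)

        extra = names[4]
        best_total, best_splits = None, None
        work = backbone.unrooted()
        edge_nodes = [
            n for n in work.root.postorder() if n.parent is not None
        ]
        for edge in edge_nodes:
            trial = work.copy()
            trial_edges = [
                n for n in trial.root.postorder() if n.parent is not None
            ]
            target = trial_edges[edge_nodes.index(edge)]
            junction = Node()
            parent = target.parent
            slot = parent.children.index(target)
            parent.children[slot] = junction
            junction.parent = parent
            junction.children = [target]
            target.parent = junction
            junction.add(Node(name=extra))
            total = ols_total_bruteforce(trial.root, dm)
            if best_total is None or total < best_total - 1e-12:
                best_total = total
                best_splits = tree_splits(PhyloTree(trial.root))
        assert tree_splits(out) == best_splits

    def test_additive_distances_recover_true_topology(self):
        """ME insertion plus constrained NNI is exact on additive distances."""
        true = simulate_yule_tree(12, 1.0, seed=5)
        backbone = true.restrict(sorted(true.leaf_names())[:6])
        dm = path_distances(true)
        out = constrained_build(backbone, dm)
        assert tree_splits(out) == tree_splits(true)
        ok, _ = check_constraint(out, backbone)
        assert ok

    def test_output_is_deterministic(self):
        true = simulate_yule_tree(9, 1.0, seed=13)
        backbone = true.restrict(sorted(true.leaf_names())[:5])
        dm = path_distances(true)
        assert to_newick(constrained_build(backbone, dm)) == to_newick(
            constrained_build(backbone, dm)
        )

    def test_missing_backbone_taxon_is_error(self):
        backbone = simulate_yule_tree(5, 1.0, seed=2)
        dm = path_distances(backbone)
        sub = dm.filter([i for i in dm.ids if i != backbone.leaf_names()[0]])
        with pytest.raises(ValueError, match="missing backbone"):
            constrained_build(backbone, sub)

    def test_constraint_enforced_against_contradicting_distances(self):
        """Even when distances favour another topology, backbone splits survive."""
        backbone = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        conflicting = parse_newick(
            "(((a:0.1,c:0.1):0.4,(b:0.1,d:0.1):0.4):0.1,(e:0.3,f:0.3):0.1);"
        )
        dm = path_distances(conflicting)
        out = constrained_build(backbone, dm)
        ok, violated = check_constraint(out, backbone)
        assert ok and violated == []
        assert sorted(out.leaf_names()) == ["a", "b", "c", "d", "e", "f"]
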