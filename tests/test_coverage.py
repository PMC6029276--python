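from fractions import Fraction

import pytest

from divcover.coverage import (
    CladeRecord,
    annotated_newick,
    collapse_clusters,
    root_on_outgroup,
    sequenced_fraction,
    summarize,
)
from divcover.dereplicate import ClusterSet, OtuCluster
from divcover.trees import parse_newick, to_newick


def clusters_for(otus: dict[str, bool]) -> ClusterSet:
    return ClusterSet(
        clusters=[
            OtuCluster(representative_id=o, member_ids=[o], genome_backed=flag)
            for o, flag in otus.items()
        ]
    )


class TestRooting:
    def test_outgroup_pair_becomes_first_child(self):
        tree = parse_newick("((o1:1,o2:1):2,a:1,b:1);")
        rooted = root_on_outgroup(tree, {"o1", "o2"})
        assert rooted.rooted
        first, second = rooted.root.children
        assert sorted(l.name for l in first.leaves()) == ["o1", "o2"]
        assert sorted(l.name for l in second.leaves()) == ["a", "b"]
        # midpoint rooting on the subtending edge
        assert first.length == pytest.approx(1.0)
        assert second.length == pytest.approx(1.0)

    def test_non_monophyletic_outgroup_is_error(self):
        tree = parse_newick("((o1:1,o2:1):2,a:1,b:1);")
        with pytest.raises(ValueError, match="intruding"):
            root_on_outgroup(tree, {"o1", "a"})

    def test_outgroup_covering_all_leaves_is_error(self):
        tree = parse_newick("(a:1,b:1,c:1);")
        with pytest.raises(ValueError, match="nothing left"):
            root_on_outgroup(tree, {"a", "b", "c"})

    def test_ingroup_mrca_excludes_every_outgroup_leaf(self, small_result, small_bundle):
        rooted = small_result.rooted_tree
        outgroup = set(small_bundle.outgroup_ids) & set(rooted.leaf_names())
        first, second = rooted.root.children
        sides = [
            {l.name for l in first.leaves()},
            {l.name for l in second.leaves()},
        ]
        assert outgroup in sides
        ingroup_side = sides[0] if sides[1] == outgroup else sides[1]
        assert not (ingroup_side & outgroup)


class TestCollapseClusters:
    def test_clean_subtree_is_monophyletic(self):
        tree = parse_newick("(((x1:1,x2:1):1,(y1:1,y2:1):1):1,o:3);")
        rooted = root_on_outgroup(tree, {"o"})
        groups = collapse_clusters(
            rooted, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}, outgroup={"o"}
        )
        assert [(g[0], g[2]) for g in groups] == [("X", True), ("Y", True)]

    def test_interleaved_labels_flagged_paraphyletic(self):
        tree = parse_newick("(((x1:1,y1:1):1,(x2:1,y2:1):1):1,o:3);")
        rooted = root_on_outgroup(tree, {"o"})
        groups = collapse_clusters(
            rooted, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}, outgroup={"o"}
        )
        assert [(g[0], g[2]) for g in groups] == [("X", False), ("Y", False)]

    def test_unlabeled_ingroup_otu_is_error(self):
        tree = parse_newick("((x1:1,x2:1):1,o:3);")
        rooted = root_on_outgroup(tree, {"o"})
        with pytest.raises(ValueError, match="x2"):
            collapse_clusters(rooted, {"x1": "X"}, outgroup={"o"})

    def test_otu_sets_partition_the_ingroup(self):
        tree = parse_newick("(((x1:1,x2:1):1,(y1:1,y2:1):1):1,o:3);")
        rooted = root_on_outgroup(tree, {"o"})
        groups = collapse_clusters(
            rooted, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}, outgroup={"o"}
        )
        assert sum(len(g[1]) for g in groups) == 4


class TestSequencedFraction:
    def test_zero_genomes_is_unsequenced(self):
        cs = clusters_for({f"o{i}": False for i in range(10)})
        record = sequenced_fraction([f"o{i}" for i in range(10)], cs, label="C")
        assert record.fraction == 0
        assert record.status == "unsequenced"

    def test_one_in_nine_is_sequenced(self):
        otus = {f"o{i}": i == 0 for i in range(9)}
        record = sequenced_fraction(list(otus), clusters_for(otus), label="B")
        assert record.fraction == Fraction(1, 9)
        assert float(record.fraction) == pytest.approx(0.111, abs=5e-4)
        assert record.status == "sequenced"

    def test_fully_sequenced_clade(self):
        otus = {f"o{i}": True for i in range(4)}
        record = sequenced_fraction(list(otus), clusters_for(otus), label="A")
        assert record.fraction == 1

    def test_boundary_is_strict(self):
        exactly = sequenced_fraction(
            [f"o{i}" for i in range(100)],
            clusters_for({f"o{i}": i == 0 for i in range(100)}),
        )
        assert exactly.fraction == Fraction(1, 100)
        assert exactly.status == "sequenced"  # 0.01 is NOT < 0.01
        below = sequenced_fraction(
            [f"o{i}" for i in range(101)],
            clusters_for({f"o{i}": i == 0 for i in range(101)}),
        )
        assert below.status == "unsequenced"  # 1/101 < 1%

    def test_empty_otu_set_is_error(self):
        with pytest.raises(ValueError):
            sequenced_fraction([], clusters_for({"o": True}))


class TestSummarize:
    def _record(self, label, n, k):
        return CladeRecord(
            cluster_label=label,
            n_otus=n,
            n_genome_backed_otus=k,
            fraction=Fraction(k, n),
            status="unsequenced" if Fraction(k, n) < Fraction(1, 100) else "sequenced",
            monophyletic=True,
        )

    def test_summary_over_sequenced_only(self):
        clades = [
            self._record("a", 10, 0),
            self._record("b", 10, 0),
            self._record("c", 10, 5),
        ]
        report = summarize(clades)
        assert report.n_unsequenced == 2
        assert report.summary_over_sequenced == (0.5, 0.5, 0.0)

    def test_all_unsequenced_gives_no_summary(self):
        report = summarize([self._record("a", 10, 0)])
        assert report.n_unsequenced == 1
        assert report.summary_over_sequenced is None

    def test_iqr_uses_linear_interpolation(self):
        clades = [self._record(str(i), 10, k) for i, k in enumerate((1, 2, 3, 4))]
        report = summarize(clades)
        mn, med, iqr = report.summary_over_sequenced
        assert mn == pytest.approx(0.1)
        assert med == pytest.approx(0.25)
        # linear-interpolation quantiles: Q1 = 0.175, Q3 = 0.325
        assert iqr == pytest.approx(0.15)


class TestAnnotatedNewick:
    def test_bracket_annotation_round_trips(self):
        tree = parse_newick("(((x1:1,x2:1):1,(y1:1,y2:1):1):1,o:3);")
        rooted = root_on_outgroup(tree, {"o"})
        groups = collapse_clusters(
            rooted, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}, outgroup={"o"}
        )
        clades = [
            sequenced_fraction(
                otus,
                clusters_for({"x1": True, "x2": False, "y1": False, "y2": False}),
                label=label,
                monophyletic=mono,
            )
            for label, otus, mono in groups
        ]
        text = annotated_newick(rooted, clades, {g[0]: g[1] for g in groups})
        assert "'X [2/1/0.500]'" in text
        assert "'Y [2/0/0.000]'" in text
        parse_newick(text)  # the annotated output remains valid newick
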