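import numpy as np
import pytest

from divcover.dereplicate import (
    greedy_cluster,
    pairwise_identity,
    promote_genome_representatives,
)
from divcover.io import SeqRecord

from _oracles import oracle_greedy
from conftest import mutate, random_sequence, small_config


def rec(rid, seq, source=None, accession=None):
    return SeqRecord(id=rid, sequence=seq, source=source, genome_accession=accession)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = random_sequence(rng, 100)
        r = pairwise_identity(s, s)
        assert r.identity == 1.0
        assert r.cov_shorter == 1.0 and r.cov_longer == 1.0

    def test_three_substitutions_give_097(self, rng):
        s = random_sequence(rng, 100)
        other = list(s)
        for i in (10, 50, 90):
            other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
        r = pairwise_identity(s, "".join(other))
        assert r.identity == pytest.approx(0.97)

    def test_exact_prefix_fails_on_coverage_not_identity(self, rng):
        s = random_sequence(rng, 100)
        r = pairwise_identity(s, s[:80])
        assert r.identity == 1.0
        assert r.cov_shorter == 1.0
        assert r.cov_longer == pytest.approx(0.8)
        # the coverage gate on the longer sequence is what a caller
        # would use to reject fragments; the default 0.0 lets them in
        assert not r.passes(0.975, 0.9, 0.9)
        assert r.passes(0.975, 0.9, 0.0)

    def test_n_never_counts_as_match(self):
        r = pairwise_identity("AAANAAA", "AAANAAA")
        assert r.identity == pytest.approx(6 / 7)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestGreedyCluster:
    def test_single_record_single_cluster(self):
        cs = greedy_cluster([rec("a", "ACGTACGT")])
        assert len(cs) == 1
        assert cs.clusters[0].representative_id == "a"

    def test_threshold_splits_at_975(self, rng):
        s = random_sequence(rng, 1200)
        near = mutate_at_positions(s, 10, rng)
        far = mutate_at_positions(s, 50, rng)
        one = greedy_cluster([rec("a", s), rec("b", near)])
        two = greedy_cluster([rec("a", s), rec("b", far)])
        assert len(one) == 1  # identity ~0.992 >= 0.975
        assert len(two) == 2  # identity ~0.958 < 0.975

    def test_partition_property(self, small_bundle):
        records = small_bundle.all_records()
        cs = greedy_cluster(records)
        assert cs.member_ids() == {r.id for r in records}

    def test_every_member_passes_gates_against_representative(self, small_bundle):
        records = small_bundle.all_records()
        cs = greedy_cluster(records)
        by_id = {r.id: r for r in records}
        for cluster in cs.clusters:
            rep = by_id[cluster.representative_id]
            for mid in cluster.member_ids:
                r = pairwise_identity(by_id[mid].sequence, rep.sequence)
                assert r.passes(0.975, 0.9, 0.0)

    def test_cluster_count_monotone_in_threshold(self, rng):
        records = []
        for fam in range(4):
            base = random_sequence(rng, 250)
            for i in range(3):
                records.append(rec(f"f{fam}m{i}", mutate(rng, base, 0.02 * i)))
        counts = [
            len(greedy_cluster(records, threshold=t))
            for t in (0.90, 0.95, 0.975, 0.99)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        """Greedy clustering equals an independent reimplementation."""
        records = _random_instance(np.random.default_rng(seed))
        got = greedy_cluster(records)
        expected = oracle_greedy(records)
        got_view = [
            (c.representative_id, sorted(c.member_ids)) for c in got.clusters
        ]
        assert got_view == expected

    def test_recovers_true_species_partition(self, small_bundle):
        """Within-species <1% and between-species >10% divergence separate cleanly."""
        from sklearn.metrics import adjusted_rand_score

        records = small_bundle.all_records()
        cs = greedy_cluster(records)
        truth_of = {
            rid: sp
            for sp, rids in small_bundle.truth.true_partition.items()
            for rid in rids
        }
        ids = sorted(r.id for r in records)
        got_of = {m: i for i, c in enumerate(cs.clusters) for m in c.member_ids}
        ari = adjusted_rand_score(
            [truth_of[i] for i in ids], [got_of[i] for i in ids]
        )
        assert ari == 1.0


class TestPromotion:
    def test_genome_member_becomes_representative(self):
        cs = greedy_cluster(
            [
                rec("r1", "ACGTACGTACGT", source="reference"),
                rec("g1", "ACGTACGTACGT", source="genome",
                    accession="GCA_0000001.1"),
            ]
        )
        assert cs.clusters[0].representative_id == "g1"  # 'g1' < 'r1' founds it
        promoted, n = promote_genome_representatives(
            cs,
            [
                rec("r1", "ACGTACGTACGT", source="reference"),
                rec("g1", "ACGTACGTACGT", source="genome",
                    accession="GCA_0000001.1"),
            ],
        )
        assert n == 0  # already genome-backed representative

    def test_reference_representative_replaced(self):
        records = [
            rec("a1", "ACGTACGTACGT", source="reference"),
            rec("z9", "ACGTACGTACGT", source="genome", accession="GCA_0000001.1"),
        ]
        cs = greedy_cluster(records)
        assert cs.clusters[0].representative_id == "a1"
        promoted, n = promote_genome_representatives(cs, records)
        assert n == 1
        assert promoted.clusters[0].representative_id == "z9"
        assert sorted(promoted.clusters[0].member_ids) == ["a1", "z9"]

    def test_replacement_count_matches_direct_count(self, small_bundle):
        records = small_bundle.all_records()
        cs = greedy_cluster(records)
        by_id = {r.id: r for r in records}
        expected = sum(
            1
            for c in cs.clusters
            if any(by_id[m].source == "genome" for m in c.member_ids)
            and by_id[c.representative_id].source != "genome"
        )
        _, n = promote_genome_representatives(cs, records)
        assert n == expected


def mutate_at_positions(s, k, rng):
    out = list(s)
    for i in rng.choice(len(s), size=k, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


def _random_instance(rng) -> list[SeqRecord]:
    """<= 8 sequences: mutated families, fragments, and unrelated noise."""
    records = []
    n = int(rng.integers(2, 9))
    base = "".join(rng.choice(list("ACGT"), int(rng.integers(60, 110))))
    for i in range(n):
        kind = rng.integers(4)
        if kind == 0:
            seq = _mut(base, 0.01, rng)
        elif kind == 1:
            seq = _mut(base, 0.2, rng)
        elif kind == 2:
            seq = _mut(base, 0.01, rng)[: int(0.7 * len(base))]
        else:
            seq = "".join(rng.choice(list("ACGT"), int(rng.integers(60, 110))))
        records.append(SeqRecord(id=f"q{i}", sequence=seq))
    return records


def _mut(s, p, rng):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)
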