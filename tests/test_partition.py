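"""Pretrain / Seen / Unseen partitioning contracts."""

from collections import Counter

import pytest

from barcodelm.partition import PartitionConfig, assign_partitions, split_seen

from conftest import make_record


def species_of(records, ids):
    by_id = {r.record_id: r for r in records}
    return {by_id[i].species for i in ids}


class TestPartitionConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PartitionConfig(split_fractions=(0.5, 0.4, 0.2))

    def test_rare_threshold_bounded_by_seen_min(self):
        with pytest.raises(ValueError, match="rare"):
            PartitionConfig(seen_min_per_species=10, unseen_rare_threshold=15)


class TestAssignPartitions:
    def test_abundant_species_capped_at_fifty(self, species_corpus):
        records = species_corpus({("G1", "G1_a"): 60})
        assignment = assign_partitions(records, PartitionConfig(seed=3))
        counts = assignment.counts()
        n_seen = counts["seen_train"] + counts["seen_val"] + counts["seen_test"]
        assert n_seen == 50
        assert counts["pretrain"] == 10

    def test_twenty_record_species_fully_seen(self, species_corpus):
        records = species_corpus({("G1", "G1_a"): 20})
        assignment = assign_partitions(records, PartitionConfig(seed=3))
        assert assignment.counts()["pretrain"] == 0

    def test_minimum_seen_species_count_is_twenty(self, species_corpus):
        counts = {("G1", f"G1_s{c}"): c for c in (5, 10, 19, 20, 21)}
        records = species_corpus(counts)
        assignment = assign_partitions(records, PartitionConfig(seed=0))
        seen_ids = [
            rid
            for rid, lab in assignment.labels.items()
            if lab.startswith("seen_")
        ]
        seen_species = species_of(records, seen_ids)
        assert seen_species == {"G1_s20", "G1_s21"}

    def test_record_without_species_goes_to_pretrain(self, species_corpus, rng):
        records = species_corpus({("G1", "G1_a"): 25})
        from conftest import random_dna

        genus_only = make_record("genusonly", random_dna(rng, 300), genus="G1")
        assignment = assign_partitions(records + [genus_only], PartitionConfig(seed=1))
        assert assignment.labels["genusonly"] == "pretrain"

    def test_rare_species_in_seen_genus_goes_to_unseen(self, species_corpus):
        records = species_corpus({("G1", "G1_a"): 30, ("G1", "G1_rare"): 5})
        assignment = assign_partitions(records, PartitionConfig(seed=1))
        unseen_species = species_of(records, assignment.ids("unseen"))
        assert unseen_species == {"G1_rare"}

    def test_rare_species_outside_seen_genus_goes_to_pretrain(self, species_corpus):
        records = species_corpus({("G1", "G1_a"): 30, ("G2", "G2_rare"): 5})
        assignment = assign_partitions(records, PartitionConfig(seed=1))
        assert assignment.counts()["unseen"] == 0
        assert species_of(records, assignment.ids("pretrain")) == {"G2_rare"}

    def test_unseen_per_genus_cap(self, species_corpus):
        counts = {("G1", "G1_big"): 30}
        counts.update({("G1", f"G1_r{i:02d}"): 3 for i in range(30)})
        records = species_corpus(counts)
        assignment = assign_partitions(records, PartitionConfig(seed=5))
        unseen = assignment.ids("unseen")
        assert len(unseen) == 20  # 90 candidates capped at 20 per genus

    def test_no_qualifying_species_raises(self, species_corpus):
        records = species_corpus({("G1", "G1_a"): 5})
        with pytest.raises(ValueError, match="seen_min_per_species=20"):
            assign_partitions(records, PartitionConfig())

    def test_partition_invariants(self, species_corpus):
        counts = {}
        for g in range(4):
            counts[(f"G{g}", f"G{g}_big")] = 25 + 10 * g
            counts[(f"G{g}", f"G{g}_huge")] = 70
            counts[(f"G{g}", f"G{g}_rare")] = 4
        counts[("Gx", "Gx_rareonly")] = 6
        records = species_corpus(counts)
        assignment = assign_partitions(records, PartitionConfig(seed=11))
        labels = assignment.labels
        # exactly one label per record, full coverage
        assert set(labels) == {r.record_id for r in records}
        by_id = {r.record_id: r for r in records}
        seen_sp = Counter()
        unseen_genus = Counter()
        for rid, lab in labels.items():
            if lab.startswith("seen_"):
                seen_sp[by_id[rid].species] += 1
            elif lab == "unseen":
                unseen_genus[by_id[rid].genus] += 1
        assert all(20 <= c <= 50 for c in seen_sp.values())
        assert all(c <= 20 for c in unseen_genus.values())
        seen_ids = [r for r, l in labels.items() if l.startswith("seen_")]
        assert species_of(records, seen_ids).isdisjoint(
            species_of(records, assignment.ids("unseen"))
        )
        seen_genera = {by_id[r].genus for r in seen_ids}
        assert set(unseen_genus) <= seen_genera
        # summary agrees with labels
        assert assignment.summary["unseen"]["records"] == len(assignment.ids("unseen"))

    def test_seed_reproducibility(self, species_corpus):
        counts = {("G1", "G1_a"): 80, ("G1", "G1_r"): 6, ("G2", "G2_b"): 33}
        records = species_corpus(counts)
        a = assign_partitions(records, PartitionConfig(seed=42))
        b = assign_partitions(records, PartitionConfig(seed=42))
        c = assign_partitions(records, PartitionConfig(seed=43))
        assert a.labels == b.labels
        assert a.labels != c.labels  # the 80->50 subsample should differ


class TestSplitSeen:
    def test_exact_proportions_100(self, species_corpus):
        records = species_corpus({("G", "G_s"): 100})
        labels = split_seen(records, seed=0)
        counts = Counter(labels.values())
        assert counts == {"seen_train": 70, "seen_test": 20, "seen_val": 10}

    def test_exact_proportions_20(self, species_corpus):
        records = species_corpus({("G", "G_s"): 20})
        counts = Counter(split_seen(records, seed=0).values())
        assert counts == {"seen_train": 14, "seen_test": 4, "seen_val": 2}

    def test_stratified_per_species(self, species_corpus):
        records = species_corpus({("G", "G_a"): 30, ("G", "G_b"): 40})
        labels = split_seen(records, seed=1)
        by_id = {r.record_id: r for r in records}
        per_species = {}
        for rid, lab in labels.items():
            per_species.setdefault(by_id[rid].species, Counter())[lab] += 1
        assert per_species["G_a"] == {"seen_train": 21, "seen_test": 6, "seen_val": 3}
        assert per_species["G_b"] == {"seen_train": 28, "seen_test": 8, "seen_val": 4}

    def test_determinism(self, species_corpus):
        records = species_corpus({("G", "G_a"): 37})
        assert split_seen(records, seed=9) == split_seen(records, seed=9)

    def test_bad_fractions(self, species_corpus):
        records = species_corpus({("G", "G_a"): 20})
        with pytest.raises(ValueError, match="sum to 1"):
            split_seen(records, fractions=(0.6, 0.2, 0.1))
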