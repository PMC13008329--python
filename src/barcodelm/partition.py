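"""Pretrain / Seen / Unseen partitioning of a cleaned barcode corpus.

The Seen partition holds well-represented, species-labeled taxa for
supervised (closed-world) evaluation: each admitted species has at least
20 and at most 50 barcodes (over-abundant species are subsampled, surplus
goes to Pretrain). The Unseen partition holds "rare" species — fewer than
20 barcodes corpus-wide — restricted to genera that also occur in Seen, at
most 20 barcodes per genus, for open-world evaluation. Everything else,
including records without a species label, goes to Pretrain.

Seen is further split per species into train/test/val at 70/20/10.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from barcodelm.records import BarcodeRecord

PARTITION_LABELS = ("pretrain", "seen_train", "seen_val", "seen_test", "unseen")


@dataclass(frozen=True)
class PartitionConfig:
    seen_min_per_species: int = 20
    seen_max_per_species: int = 50
    unseen_rare_threshold: int = 20   # species with fewer barcodes are "rare"
    unseen_max_per_genus: int = 20
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)  # train, test, val
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split_fractions must sum to 1, got {self.split_fractions}")
        if self.unseen_rare_threshold > self.seen_min_per_species:
            raise ValueError(
                "unseen_rare_threshold must not exceed seen_min_per_species "
                "(rare species can never qualify for Seen)"
            )


@dataclass
class PartitionAssignment:
    """record_id -> partition label, with per-partition summary counts."""

    labels: dict[str, str]
    summary: dict[str, dict[str, int]] = field(default_factory=dict)

    def ids(self, label: str) -> list[str]:
        return [rid for rid, lab in self.labels.items() if lab == label]

    def counts(self) -> Counter:
        return Counter(self.labels.values())


def _summarize(
    records: Sequence[BarcodeRecord], labels: dict[str, str]
) -> dict[str, dict[str, int]]:
    by_label: dict[str, list[BarcodeRecord]] = defaultdict(list)
    for rec in records:
        by_label[labels[rec.record_id]].append(rec)
    summary = {}
    for label in PARTITION_LABELS:
        recs = by_label.get(label, [])
        summary[label] = {
            "records": len(recs),
            "species": len({r.species for r in recs if r.species}),
            "genera": len({r.genus for r in recs if r.genus}),
        }
    return summary


def split_seen(
    seen_records: Sequence[BarcodeRecord],
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> dict[str, str]:
    """Stratified per-species 70/20/10 train/test/val split of Seen records.

    Per species with n records, train receives round(f_train * n), test
    round(f_test * n), and the remainder goes to val (largest-remainder
    style rounding on the first two fractions). Assignment within a species
    is a seeded uniform shuffle, so reruns with the same seed are identical.

    Returns record_id -> {"seen_train", "seen_test", "seen_val"}.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    f_train, f_test, _ = fractions
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[BarcodeRecord]] = defaultdict(list)
    for rec in seen_records:
        if rec.species is None:
            raise ValueError(f"Seen record {rec.record_id!r} lacks a species label")
        by_species[rec.species].append(rec)
    labels: dict[str, str] = {}
    for species in sorted(by_species):
        recs = by_species[species]
        order = rng.permutation(len(recs))
        n = len(recs)
        n_train = int(round(f_train * n))
        n_test = int(round(f_test * n))
        n_test = min(n_test, n - n_train)
        for pos, j in enumerate(order):
            if pos < n_train:
                lab = "seen_train"
            elif pos < n_train + n_test:
                lab = "seen_test"
            else:
                lab = "seen_val"
            labels[recs[j].record_id] = lab
    return labels


def assign_partitions(
    records: Sequence[BarcodeRecord], config: PartitionConfig | None = None
) -> PartitionAssignment:
    """Assign every record to exactly one of the five partition labels.

    Records must already be cleaned and deduplicated. The procedure:

    1. Seen candidates: species-labeled species with corpus count >=
       ``seen_min_per_species``. Species above ``seen_max_per_species`` are
       uniformly subsampled (seeded) down to the cap; surplus records go to
       Pretrain. The Seen set is then split per species 70/20/10.
    2. Unseen: records of species-labeled rare species (corpus count <
       ``unseen_rare_threshold``) whose genus occurs among Seen genera,
       subsampled to at most ``unseen_max_per_genus`` records per genus;
       surplus to Pretrain. Rare species in genera absent from Seen go to
       Pretrain, preserving the property that every Unseen genus also
       occurs in Seen.
    3. Everything else (including records without a species label) ->
       Pretrain.
    """
    config = config or PartitionConfig()
    rng = np.random.default_rng(config.seed)

    species_count: Counter = Counter(r.species for r in records if r.species)
    seen_species = {
        sp for sp, c in species_count.items() if c >= config.seen_min_per_species
    }
    if not seen_species:
        raise ValueError(
            "no species qualifies for the Seen partition: every species has "
            f"fewer than seen_min_per_species={config.seen_min_per_species} barcodes"
        )

    by_species: dict[str, list[BarcodeRecord]] = defaultdict(list)
    for rec in records:
        if rec.species:
            by_species[rec.species].append(rec)

    labels: dict[str, str] = {rec.record_id: "pretrain" for rec in records}

    seen_records: list[BarcodeRecord] = []
    for species in sorted(seen_species):
        recs = by_species[species]
        if len(recs) > config.seen_max_per_species:
            pick = rng.choice(len(recs), size=config.seen_max_per_species, replace=False)
            recs = [recs[i] for i in sorted(pick)]
        seen_records.extend(recs)
    seen_genera = {r.genus for r in seen_records if r.genus}

    rare_by_genus: dict[str, list[BarcodeRecord]] = defaultdict(list)
    for species, count in species_count.items():
        if species in seen_species or count >= config.unseen_rare_threshold:
            continue
        for rec in by_species[species]:
            if rec.genus in seen_genera:
                rare_by_genus[rec.genus].append(rec)
    unseen_records: list[BarcodeRecord] = []
    for genus in sorted(rare_by_genus):
        recs = rare_by_genus[genus]
        if len(recs) > config.unseen_max_per_genus:
            pick = rng.choice(len(recs), size=config.unseen_max_per_genus, replace=False)
            recs = [recs[i] for i in sorted(pick)]
        unseen_records.extend(recs)

    for rec in unseen_records:
        labels[rec.record_id] = "unseen"
    # seeded sub-splits of Seen; derive the split seed from the config seed
    seen_labels = split_seen(seen_records, config.split_fractions, seed=config.seed + 1)
    labels.update(seen_labels)

    assignment = PartitionAssignment(labels)
    assignment.summary = _summarize(records, labels)
    return assignment
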