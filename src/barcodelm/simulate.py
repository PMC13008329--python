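"""Synthetic barcode corpora with a planted taxonomic hierarchy.

Each order gets a uniform-random ~658-nt root sequence; genus roots derive
from the order root by i.i.d. per-site substitution at rate ``mu_genus``,
species roots from genus roots at ``mu_species``, and individual specimens
from species roots at ``mu_individual``. Because the rates are ordered
(mu_genus > mu_species > mu_individual), expected Hamming distance within
a species is smaller than within a genus, which is smaller than across
genera — the rank-ordered signal every probe in the package relies on.
Substitutions are uniform over the three alternative bases; there is no
transition/transversion bias, codon structure or indel process (an
optional single-indel flag exists for robustness tests).

Per-species specimen counts follow a truncated power law, producing both
well-represented species (eligible for the Seen partition) and rare ones
(candidates for Unseen), mimicking the long-tailed abundance distribution
of real barcode reference libraries. Ambiguity characters (N) are injected
i.i.d. per site. BIN labels default to one BIN per species; a
``bin_split_rate`` fractures some species into two BINs so that zero-shot
clustering is exercised below species granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from barcodelm.partition import PartitionAssignment, PartitionConfig, assign_partitions
from barcodelm.records import BarcodeRecord, preprocess

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    n_orders: int = 3
    genera_per_order: int = 4
    species_per_genus: int = 4
    sequence_length: int = 658
    mu_genus: float = 0.15        # order root -> genus root, per site
    mu_species: float = 0.03      # genus root -> species root, per site
    mu_individual: float = 0.005  # species root -> specimen, per site
    ambiguity_rate: float = 0.005  # per-site probability of N
    abundance_exponent: float = 1.3  # power-law exponent of species counts
    max_count: int = 60           # cap of the abundance law
    min_count: int = 1
    bin_split_rate: float = 0.0   # fraction of species fractured into 2 BINs
    indel_rate: float = 0.0       # per-specimen probability of one 1-nt indel
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_genus", "mu_species", "mu_individual", "ambiguity_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")
        if not self.mu_genus >= self.mu_species >= self.mu_individual:
            raise ValueError(
                "hierarchical signal requires mu_genus >= mu_species >= mu_individual"
            )
        if self.n_orders * self.genera_per_order * self.species_per_genus == 0:
            raise ValueError("configuration yields zero species")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at ``rate``, uniform over the 3 other bases."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    if hit.size:
        # shift by 1..3 in base space: always lands on a different base
        cur = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return out


def _sample_counts(
    n_species: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    support = np.arange(config.min_count, config.max_count + 1)
    weights = support.astype(float) ** (-config.abundance_exponent)
    weights /= weights.sum()
    return rng.choice(support, size=n_species, p=weights)


def generate(config: SimConfig) -> list[BarcodeRecord]:
    """Generate specimens with ground-truth taxonomy and BIN labels.

    Byte-identical across runs for a fixed config (single seeded RNG).
    """
    rng = np.random.default_rng(config.seed)
    records: list[BarcodeRecord] = []
    L = config.sequence_length
    n_species_total = (
        config.n_orders * config.genera_per_order * config.species_per_genus
    )
    counts = _sample_counts(n_species_total, config, rng)
    species_idx = 0
    for o in range(config.n_orders):
        order_name = f"Order{o:02d}"
        order_root = rng.choice(_BASES, size=L)
        for g in range(config.genera_per_order):
            genus_name = f"{order_name}_Genus{g:02d}"
            genus_root = _mutate(order_root, config.mu_genus, rng)
            for s in range(config.species_per_genus):
                species_name = f"{genus_name}_sp{s:02d}"
                species_root = _mutate(genus_root, config.mu_species, rng)
                split_bin = rng.random() < config.bin_split_rate
                for i in range(counts[species_idx]):
                    seq = _mutate(species_root, config.mu_individual, rng)
                    chars = seq.copy()
                    amb = rng.random(L) < config.ambiguity_rate
                    chars[amb] = "N"
                    sequence = "".join(chars)
                    if config.indel_rate > 0 and rng.random() < config.indel_rate:
                        pos = int(rng.integers(0, len(sequence)))
                        if rng.random() < 0.5:
                            sequence = sequence[:pos] + sequence[pos + 1 :]
                        else:
                            base = str(rng.choice(_BASES))
                            sequence = sequence[:pos] + base + sequence[pos:]
                    bin_label = species_name
                    if split_bin and i % 2 == 1:
                        bin_label = species_name + "_binB"
                    records.append(
                        BarcodeRecord(
                            record_id=f"{species_name}_i{i:03d}",
                            sequence=sequence,
                            taxonomy={
                                "phylum": "Arthropoda",
                                "class": "Insecta",
                                "order": order_name,
                                "family": f"{order_name}_Family{g:02d}",
                                "genus": genus_name,
                                "species": species_name,
                            },
                            bin_label=bin_label,
                        )
                    )
                species_idx += 1
    return records


def make_eval_fixture(
    config: SimConfig, partition_config: PartitionConfig | None = None
) -> tuple[list[BarcodeRecord], PartitionAssignment]:
    """generate -> clean -> filter -> deduplicate -> assign_partitions.

    Returns the cleaned records and their partition assignment; ground
    truth for probe scoring lives on the records themselves (taxonomy and
    BIN labels). Warns if the Unseen partition comes out empty.
    """
    raw = generate(config)
    cleaned, _ = preprocess(raw)
    assignment = assign_partitions(cleaned, partition_config)
    if assignment.summary["unseen"]["records"] == 0:
        warnings.warn(
            "Unseen partition is empty: no rare species fall in Seen genera",
            stacklevel=2,
        )
    return cleaned, assignment


def records_by_label(
    records: Sequence[BarcodeRecord], assignment: PartitionAssignment, label: str
) -> list[BarcodeRecord]:
    """Convenience selector: the records carrying one partition label."""
    return [r for r in records if assignment.labels[r.record_id] == label]
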