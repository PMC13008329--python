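import numpy as np
import pytest

from barcodelm.records import BarcodeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    record_id: str,
    sequence: str,
    genus: str | None = None,
    species: str | None = None,
    bin_label: str | None = None,
) -> BarcodeRecord:
    taxonomy = {}
    if genus:
        taxonomy["genus"] = genus
    if species:
        taxonomy["species"] = species
    return BarcodeRecord(record_id, sequence, taxonomy, bin_label)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def species_corpus(rng):
    """Records for species with prescribed per-species counts.

    Returns a factory: given {(genus, species): count}, produce records with
    distinct random sequences (no accidental duplicates).
    """

    def build(counts: dict[tuple[str, str], int]) -> list[BarcodeRecord]:
        records = []
        i = 0
        for (genus, species), count in counts.items():
            for _ in range(count):
                records.append(
                    make_record(f"r{i:05d}", random_dna(rng, 300), genus, species)
                )
                i += 1
        return records

    return build
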