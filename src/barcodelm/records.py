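"""Barcode record I/O, cleaning and filtering.

A barcode record is one specimen: an identifier, a COI nucleotide sequence,
a (possibly incomplete) taxonomic annotation from phylum down to species,
and an optional Barcode Index Number (BIN) label.

Cleaning follows the standard practice for BOLD-style barcode exports:
every non-ACGT symbol (IUPAC ambiguity codes, RNA ``U``, alignment gaps
``-``/``.``) is uniformly replaced by ``N``, trailing runs of ``N`` are
truncated, and sequences shorter than 200 bp or with more than 50% ``N``
are excluded. Duplicate sequences are removed, keeping the first occurrence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

RANKS = ("phylum", "class", "order", "family", "genus", "species")

TSV_COLUMNS = (
    "processid",
    "sequence",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "bin_uri",
)

_ACGT = frozenset("ACGT")

MIN_LENGTH = 200          # sequences below 200 bp are excluded
MAX_N_FRACTION = 0.5      # sequences with over 50% N are excluded


class ParseError(ValueError):
    """Malformed input file (bad header, inconsistent row, bad rank data)."""


class AllAmbiguousSequenceError(ValueError):
    """Cleaning removed every character: the raw sequence had no A/C/G/T."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: sequence plus taxonomy and optional BIN label.

    ``taxonomy`` maps rank name -> taxon name for the ranks present; ranks
    may be absent from any level downward, but a named species requires a
    named genus (partitioning is genus-aware).
    """

    record_id: str
    sequence: str
    taxonomy: dict[str, str] = field(default_factory=dict)
    bin_label: str | None = None

    def rank(self, name: str) -> str | None:
        return self.taxonomy.get(name)

    @property
    def species(self) -> str | None:
        return self.taxonomy.get("species")

    @property
    def genus(self) -> str | None:
        return self.taxonomy.get("genus")

    def with_sequence(self, sequence: str) -> "BarcodeRecord":
        return BarcodeRecord(self.record_id, sequence, dict(self.taxonomy), self.bin_label)


@dataclass
class CleaningReport:
    """Counts of records dropped per preprocessing rule."""

    n_input: int = 0
    dropped_blank: int = 0
    dropped_all_ambiguous: int = 0
    dropped_short: int = 0
    dropped_high_n: int = 0
    dropped_duplicate: int = 0
    n_output: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _check_taxonomy(taxonomy: dict[str, str], record_id: str, where: str) -> None:
    if taxonomy.get("species") and not taxonomy.get("genus"):
        raise ParseError(
            f"{where}: record {record_id!r} has a species label but no genus; "
            "rank-consistent taxonomy is required"
        )


def _read_tsv(path: Path) -> Iterator[tuple[BarcodeRecord | None, bool]]:
    """Yield (record, was_blank) per non-empty row."""
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return
        missing = [c for c in ("processid", "sequence") if c not in header]
        if missing:
            raise ParseError(f"{path}: line 1: header lacks required columns {missing}")
        idx = {name: header.index(name) for name in header}
        for lineno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            record_id = row[idx["processid"]].strip()
            sequence = row[idx["sequence"]].strip()
            if not sequence:
                yield None, True
                continue
            taxonomy = {}
            for rank in RANKS:
                if rank in idx and row[idx[rank]].strip():
                    taxonomy[rank] = row[idx[rank]].strip()
            _check_taxonomy(taxonomy, record_id, f"{path}: line {lineno}")
            bin_label = row[idx["bin_uri"]].strip() or None if "bin_uri" in idx else None
            yield BarcodeRecord(record_id, sequence, taxonomy, bin_label), False


def _read_fasta(path: Path) -> Iterator[tuple[BarcodeRecord | None, bool]]:
    for entry in SeqIO.parse(str(path), "fasta"):
        sequence = str(entry.seq).strip()
        taxonomy: dict[str, str] = {}
        bin_label = None
        # description = "<id> key=value key=value ..."
        for token in entry.description.split()[1:]:
            if "=" not in token:
                raise ParseError(
                    f"{path}: entry {entry.id!r}: malformed header annotation {token!r} "
                    "(expected key=value)"
                )
            key, value = token.split("=", 1)
            key = key.lower()
            if key in RANKS:
                taxonomy[key] = value
            elif key in ("bin", "bin_uri"):
                bin_label = value
        _check_taxonomy(taxonomy, entry.id, str(path))
        if not sequence:
            yield None, True
        else:
            yield BarcodeRecord(entry.id, sequence, taxonomy, bin_label), False


def read_records(
    path: str | Path, format: str = "tsv"
) -> tuple[list[BarcodeRecord], int]:
    """Read barcode records from a TSV table or annotated FASTA.

    Raw sequences are preserved verbatim; cleaning is a separate step.
    Rows/entries with a blank sequence are dropped and counted.

    Returns
    -------
    records, n_blank_dropped
    """
    path = Path(path)
    if format == "tsv":
        rows = _read_tsv(path)
    elif format == "fasta":
        rows = _read_fasta(path)
    else:
        raise ValueError(f"unknown format {format!r}: expected 'tsv' or 'fasta'")
    records: list[BarcodeRecord] = []
    n_blank = 0
    for record, was_blank in rows:
        if was_blank:
            n_blank += 1
        else:
            assert record is not None
            records.append(record)
    return records, n_blank


def write_records_tsv(records: Iterable[BarcodeRecord], path: str | Path) -> None:
    """Write records in the canonical 9-column TSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.record_id, rec.sequence]
                + [rec.taxonomy.get(rank, "") for rank in RANKS]
                + [rec.bin_label or ""]
            )


def clean_sequence(raw: str) -> str:
    """Uppercase, replace every non-ACGT symbol by ``N``, strip trailing ``N``.

    Ambiguity codes, ``U``, gap symbols ``-``/``.`` and anything else outside
    {A,C,G,T} all become ``N``; leading and internal ``N`` runs are retained.

    Raises
    ------
    AllAmbiguousSequenceError
        If nothing remains (the raw sequence contained no A/C/G/T).
    """
    upper = raw.upper()
    cleaned = "".join(c if c in _ACGT else "N" for c in upper).rstrip("N")
    if not cleaned:
        raise AllAmbiguousSequenceError(
            "sequence contains no unambiguous nucleotides after cleaning"
        )
    return cleaned


def passes_filters(cleaned: str) -> bool:
    """Length/ambiguity filter on an already-cleaned sequence.

    Retained iff length >= 200 and the N fraction is <= 50%. Both boundaries
    are inclusive on the keep side: a 200-bp sequence and a sequence with
    exactly half its sites ambiguous are retained.
    """
    n = len(cleaned)
    if n < MIN_LENGTH:
        return False
    return cleaned.count("N") / n <= MAX_N_FRACTION


def deduplicate(records: Sequence[BarcodeRecord]) -> tuple[list[BarcodeRecord], int]:
    """Keep one record per distinct cleaned sequence string.

    The duplicate key is the sequence alone (not sequence + taxonomy); the
    first occurrence in input order wins, so the result is deterministic
    given input order. Returns (kept_records, n_removed).
    """
    seen: set[str] = set()
    kept: list[BarcodeRecord] = []
    for rec in records:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        kept.append(rec)
    return kept, len(records) - len(kept)


def preprocess(
    records: Sequence[BarcodeRecord], n_blank_dropped: int = 0
) -> tuple[list[BarcodeRecord], CleaningReport]:
    """Run clean -> filter -> deduplicate over raw records, with a report."""
    report = CleaningReport(n_input=len(records) + n_blank_dropped)
    report.dropped_blank = n_blank_dropped
    cleaned: list[BarcodeRecord] = []
    for rec in records:
        try:
            seq = clean_sequence(rec.sequence)
        except AllAmbiguousSequenceError:
            report.dropped_all_ambiguous += 1
            continue
        if len(seq) < MIN_LENGTH:
            report.dropped_short += 1
            continue
        if not passes_filters(seq):
            report.dropped_high_n += 1
            continue
        cleaned.append(rec.with_sequence(seq))
    kept, n_dup = deduplicate(cleaned)
    report.dropped_duplicate = n_dup
    report.n_output = len(kept)
    return kept, report
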