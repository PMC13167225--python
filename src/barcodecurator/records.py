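"""Core containers for barcode specimens and dataset input/output.

A barcode reference library is modelled as a :class:`RecordSet`: an ordered
collection of :class:`BarcodeRecord` objects, each pairing an aligned (or
alignable) COI-5P nucleotide sequence with its specimen metadata — species
label, optional BIN (Barcode Index Number) label, and provenance fields.
This mirrors the shape of a BOLD dataset export: a FASTA file plus a
tab-separated metadata table keyed on the record id.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BarcodeRecord",
    "RecordSet",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "METADATA_COLUMNS",
]

#: IUPAC nucleotide alphabet accepted in sequences, plus the gap symbol.
IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")

#: Canonical metadata column names; `column_map` in read_dataset may rename.
METADATA_COLUMNS = ("record_id", "species_label", "bin_label", "country", "project")


class DatasetError(ValueError):
    """Raised for malformed or inconsistent dataset input."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen: identifier, taxonomy labels, sequence, provenance."""

    record_id: str
    species_label: str
    sequence: str
    bin_label: str | None = None
    country: str | None = None
    project: str | None = None
    marker: str = "COI-5P"

    def __post_init__(self) -> None:
        if not self.record_id:
            raise DatasetError("record_id must be non-empty")
        if not self.sequence:
            raise DatasetError(f"{self.record_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - IUPAC_NUCLEOTIDES
        if bad:
            raise DatasetError(
                f"{self.record_id}: non-IUPAC symbols in sequence: {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        """Sequence with alignment gaps removed."""
        return self.sequence.replace("-", "")

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")

    def with_sequence(self, sequence: str) -> "BarcodeRecord":
        return replace(self, sequence=sequence)


class RecordSet:
    """Ordered collection of uniquely identified barcode records.

    ``aligned`` asserts that all sequences have equal length, i.e. columns
    are homologous sites; it is set by :func:`barcodecurator.filters.check_alignment`
    or trusted from the constructor.
    """

    def __init__(self, records: Iterable[BarcodeRecord], aligned: bool = False):
        self.records: list[BarcodeRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise DatasetError(f"duplicate record_id: {rec.record_id}")
            seen.add(rec.record_id)
        if aligned and self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                raise DatasetError(
                    f"aligned=True but sequence lengths differ: {sorted(lengths)}"
                )
        self.aligned = aligned

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "RecordSet":
        keep = set(ids)
        return RecordSet((r for r in self.records if r.record_id in keep),
                         aligned=self.aligned)

    def species_of(self) -> dict[str, str]:
        """record_id -> species_label mapping."""
        return {r.record_id: r.species_label for r in self.records}

    def bins_of(self) -> dict[str, str | None]:
        return {r.record_id: r.bin_label for r in self.records}

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "record_id": r.record_id,
                "species_label": r.species_label,
                "bin_label": r.bin_label,
                "country": r.country,
                "project": r.project,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def read_dataset(
    fasta_path: str | Path,
    metadata_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> RecordSet:
    """Read a FASTA + metadata TSV pair into a :class:`RecordSet`.

    Every FASTA entry must resolve to a metadata row via ``record_id``.
    ``column_map`` translates non-canonical column headers, e.g.
    ``{"processid": "record_id", "species_name": "species_label"}``.

    Raises
    ------
    DatasetError
        On duplicate ids, FASTA entries absent from the metadata table, or a
        missing ``species_label`` column. Records with an *empty* species
        label are kept but flagged on stderr, never silently dropped.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, encoding="utf-8")
    if column_map:
        meta = meta.rename(columns=dict(column_map))
    if "record_id" not in meta.columns:
        raise DatasetError("metadata table lacks a 'record_id' column")
    if "species_label" not in meta.columns:
        raise DatasetError("metadata table lacks a 'species_label' column")
    if meta["record_id"].duplicated().any():
        dups = meta.loc[meta["record_id"].duplicated(), "record_id"].tolist()
        raise DatasetError(f"duplicate ids in metadata: {dups}")
    meta = meta.set_index("record_id")

    def cell(row: pd.Series, col: str) -> str | None:
        if col not in row or pd.isna(row[col]) or row[col] == "":
            return None
        return str(row[col])

    records: list[BarcodeRecord] = []
    orphans: list[str] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise DatasetError(f"duplicate id in FASTA: {rid}")
        seen.add(rid)
        if rid not in meta.index:
            orphans.append(rid)
            continue
        row = meta.loc[rid]
        species = cell(row, "species_label")
        if species is None:
            print(f"warning: {rid}: missing species_label", file=sys.stderr)
            species = "UNIDENTIFIED"
        records.append(
            BarcodeRecord(
                record_id=rid,
                species_label=species,
                sequence=str(entry.seq).upper(),
                bin_label=cell(row, "bin_label"),
                country=cell(row, "country"),
                project=cell(row, "project"),
            )
        )
    if orphans:
        raise DatasetError(
            f"{len(orphans)} FASTA entries absent from metadata: {orphans[:10]}"
        )
    return RecordSet(records, aligned=False)


def write_dataset(rs: RecordSet, fasta_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write a RecordSet back to FASTA + metadata TSV (the read_dataset dialect)."""
    with open(fasta_path, "w") as fh:
        for rec in rs:
            fh.write(f">{rec.record_id}\n{rec.sequence}\n")
    rs.metadata_frame().to_csv(metadata_path, sep="\t", index=False)
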