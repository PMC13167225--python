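"""Sequence quality filters for barcode library construction.

Three filters mirror standard reference-library curation practice for the
COI-5P marker:

* a length window (default 500–658 bp, inclusive, measured on ungapped
  nucleotides) that admits partial but still diagnostic barcodes;
* a stop-codon screen under the invertebrate mitochondrial genetic code
  (NCBI translation table 5), the primary defence against NUMTs — nuclear
  pseudogene copies of COI, which are typically frame-disrupted;
* a curation exclusion list, the hook by which expert review (e.g. voucher
  re-examination flagging contaminations or misidentifications) removes
  records without the tool ever deleting anything on its own.

Every filter returns the surviving :class:`~barcodecurator.records.RecordSet`
together with a :class:`FilterReport` audit row set, so the provenance of
each removal is preserved.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Data import CodonTable

from .records import BarcodeRecord, DatasetError, RecordSet

__all__ = [
    "FilterReport",
    "filter_by_length",
    "translate",
    "count_stops",
    "screen_stop_codons",
    "apply_exclusion_list",
    "check_alignment",
    "write_filter_reports",
]

# Invertebrate mitochondrial code: stops are TAA/TAG; AGA/AGG encode Ser
# and TGA encodes Trp, unlike the standard code.
_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_FORWARD = dict(_TABLE5.forward_table)
_STOPS = frozenset(_TABLE5.stop_codons)


@dataclass
class FilterReport:
    """Audit trail for one filter rule: counts plus per-record reasons."""

    rule: str
    n_in: int
    n_kept: int
    n_removed: int
    removed: list[tuple[str, str]] = field(default_factory=list)
    #: rule-specific extras, e.g. chosen reading frame per kept record
    details: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_kept + self.n_removed == self.n_in
        assert len(self.removed) == self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.rule, rid, reason) for rid, reason in self.removed],
            columns=["rule", "record_id", "reason"],
        )


def filter_by_length(
    rs: RecordSet, min_len: int = 500, max_len: int = 658
) -> tuple[RecordSet, FilterReport]:
    """Keep records whose ungapped length lies in [min_len, max_len].

    Bounds are inclusive; gaps are alignment artifacts and never count
    toward length.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept, removed = [], []
    for rec in rs:
        n = rec.ungapped_length
        if min_len <= n <= max_len:
            kept.append(rec)
        else:
            side = "short" if n < min_len else "long"
            removed.append((rec.record_id, f"length {n} {side} of [{min_len},{max_len}]"))
    report = FilterReport("length", len(rs), len(kept), len(removed), removed)
    return RecordSet(kept, aligned=rs.aligned), report


def translate(sequence: str, frame_offset: int = 0) -> str:
    """Translate an ungapped nucleotide string under NCBI table 5.

    Codons containing any symbol outside {A,C,G,T} translate to ``X`` and
    never count as stops; the trailing partial codon is ignored.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = sequence.upper()
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _FORWARD:
            out.append(_FORWARD[codon])
        elif codon in _STOPS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


def count_stops(sequence: str, frame_offset: int) -> int:
    return translate(sequence, frame_offset).count("*")


def screen_stop_codons(rs: RecordSet) -> tuple[RecordSet, FilterReport]:
    """Remove records whose translation contains stop codons in every frame.

    The reading frame of a BOLD-style export is not recorded, so each
    ungapped sequence is translated at all three offsets and kept iff at
    least one frame is stop-free. The report's ``details['frames']`` maps
    each kept record to its minimal-stop (i.e. stop-free, lowest-offset)
    frame.
    """
    kept, removed = [], []
    frames: dict[str, int] = {}
    for rec in rs:
        stops = [count_stops(rec.ungapped, f) for f in (0, 1, 2)]
        best = min(range(3), key=lambda f: (stops[f], f))
        if stops[best] == 0:
            kept.append(rec)
            frames[rec.record_id] = best
        else:
            removed.append(
                (rec.record_id, f"stop codons in all frames (per-frame: {stops})")
            )
    report = FilterReport(
        "stop_codons", len(rs), len(kept), len(removed), removed,
        details={"frames": frames},
    )
    return RecordSet(kept, aligned=rs.aligned), report


def apply_exclusion_list(
    rs: RecordSet, excluded_ids: Iterable[str]
) -> tuple[RecordSet, FilterReport]:
    """Remove records named on a curation exclusion list.

    Unknown ids are warned about, never fatal — the list is typically
    written by hand during expert review.
    """
    excluded = set(excluded_ids)
    present = set(rs.ids)
    for rid in sorted(excluded - present):
        print(f"warning: exclusion list id not in dataset: {rid}", file=sys.stderr)
    kept, removed = [], []
    for rec in rs:
        if rec.record_id in excluded:
            removed.append((rec.record_id, "curation"))
        else:
            kept.append(rec)
    report = FilterReport("curation", len(rs), len(kept), len(removed), removed)
    return RecordSet(kept, aligned=rs.aligned), report


def check_alignment(rs: RecordSet) -> RecordSet:
    """Assert that all sequences are the same length and mark the set aligned.

    This package does not align: inputs are expected pre-aligned (e.g. by
    the repository's own aligner). Unequal lengths are an error instructing
    the user to supply aligned input.
    """
    if len(rs) == 0:
        raise DatasetError("no records: cannot check alignment of an empty set")
    lengths = sorted({len(r.sequence) for r in rs})
    if len(lengths) > 1:
        raise DatasetError(
            f"sequences are not aligned (lengths {lengths}); "
            "supply pre-aligned input"
        )
    return RecordSet(rs.records, aligned=True)


def write_filter_reports(reports: Iterable[FilterReport], path: str | Path) -> None:
    """Concatenate reports into one TSV: rule, record_id, reason."""
    frames = [r.to_frame() for r in reports]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["rule", "record_id", "reason"])
    )
    out.to_csv(path, sep="\t", index=False)
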