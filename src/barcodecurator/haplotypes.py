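"""Haplotype collapsing and richness-vs-sampling-effort analysis.

A haplotype is an exact-match equivalence class over aligned sequences.
Records carrying ambiguous bases (IUPAC degeneracies, N) or gaps are
excluded from haplotype counting — an ambiguous base makes exact identity
undecidable — but still count toward sampling effort (``n_records``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from scipy import stats

from .records import RecordSet

__all__ = [
    "HaplotypeTable",
    "RichnessCorrelation",
    "usable_records",
    "count_haplotypes",
    "richness_vs_effort",
]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class HaplotypeTable:
    """Per-group haplotype accounting.

    For each group (species, or the single pseudo-group ``__all__``):
    ``n_records`` counts all records carrying the label (sampling effort),
    ``n_usable`` those free of gaps/ambiguities, ``n_haplotypes`` the
    distinct usable sequences, and ``members`` maps each haplotype string
    to its record ids.
    """

    n_records: dict[str, int]
    n_usable: dict[str, int]
    n_haplotypes: dict[str, int]
    members: dict[str, dict[str, list[str]]]

    @property
    def total_haplotypes(self) -> int:
        return sum(self.n_haplotypes.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": g,
                "n_records": self.n_records[g],
                "n_usable": self.n_usable[g],
                "n_haplotypes": self.n_haplotypes[g],
            }
            for g in sorted(self.n_records)
        ]
        return pd.DataFrame(rows, columns=["species", "n_records", "n_usable",
                                           "n_haplotypes"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RichnessCorrelation:
    """Pearson correlation between per-species record and haplotype counts."""

    r: float
    n: int
    p_value: float


def usable_records(rs: RecordSet) -> RecordSet:
    """Records whose aligned sequence contains only unambiguous A/C/G/T."""
    if not rs.aligned:
        raise ValueError("usable_records requires an aligned RecordSet")
    keep = [r for r in rs if set(r.sequence) <= _UNAMBIGUOUS]
    return RecordSet(keep, aligned=True)


def count_haplotypes(
    rs: RecordSet, group_by: Literal["species", "all"] = "species"
) -> HaplotypeTable:
    """Collapse usable records into exact-match haplotypes per group.

    Haplotype identity is exact equality of the full aligned string; the
    ambiguity-bearing records excluded by :func:`usable_records` still
    count in ``n_records``.
    """
    if not rs.aligned:
        raise ValueError("count_haplotypes requires an aligned RecordSet")
    usable = {r.record_id for r in usable_records(rs)}

    def group_of(rec) -> str:
        return rec.species_label if group_by == "species" else "__all__"

    n_records: dict[str, int] = {}
    n_usable: dict[str, int] = {}
    members: dict[str, dict[str, list[str]]] = {}
    for rec in rs:
        g = group_of(rec)
        n_records[g] = n_records.get(g, 0) + 1
        members.setdefault(g, {})
        if rec.record_id in usable:
            n_usable[g] = n_usable.get(g, 0) + 1
            members[g].setdefault(rec.sequence, []).append(rec.record_id)
    for g in n_records:
        n_usable.setdefault(g, 0)
    n_haplotypes = {g: len(members[g]) for g in members}
    return HaplotypeTable(n_records, n_usable, n_haplotypes, members)


def richness_vs_effort(table: HaplotypeTable) -> RichnessCorrelation:
    """Pearson r between sampling effort and haplotype count across species.

    Effort is ``n_records``; the two-sided p-value comes from the exact
    t-transform of r. Requires at least three species and non-zero variance
    in both variables.
    """
    species = sorted(table.n_records)
    x = [table.n_records[s] for s in species]
    y = [table.n_haplotypes[s] for s in species]
    if len(species) < 3:
        raise ValueError(f"need >=3 species for a correlation, got {len(species)}")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in effort or richness: r undefined")
    res = stats.pearsonr(x, y)
    return RichnessCorrelation(r=float(res.statistic), n=len(species),
                               p_value=float(res.pvalue))
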