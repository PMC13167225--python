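"""BIN (Barcode Index Number) concordance with species labels.

BINs are algorithmically defined sequence clusters consumed here as
metadata labels. Each BIN is classified as:

* ``singleton`` — exactly one record (concordance unassessable);
* ``concordant`` — two or more records, all carrying the same species label;
* ``discordant`` — two or more records spanning several species labels.

Singleton takes precedence: a one-record BIN is never called concordant.
The three classes partition all distinct BIN labels. Records lacking a
species label inside a BIN count toward its size but not its species set,
and are surfaced as ``has_unassigned_records`` rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import RecordSet

__all__ = ["BINReport", "bin_concordance", "species_bin_summary"]

#: species labels treated as "no identification"
_UNIDENTIFIED = {"", "UNIDENTIFIED"}


@dataclass
class BINReport:
    """Per-BIN classification plus dataset-level tallies."""

    bins: pd.DataFrame  # bin_label, n_records, n_species, species_list, class
    n_bins: int
    n_concordant: int
    n_discordant: int
    n_singleton: int
    n_records_without_bin: int

    def percentages(self) -> dict[str, float]:
        """Class shares over distinct BINs, as percents."""
        if self.n_bins == 0:
            return {"concordant": 0.0, "discordant": 0.0, "singleton": 0.0}
        return {
            "concordant": round(100.0 * self.n_concordant / self.n_bins, 2),
            "discordant": round(100.0 * self.n_discordant / self.n_bins, 2),
            "singleton": round(100.0 * self.n_singleton / self.n_bins, 2),
        }

    def write(self, path: str | Path) -> None:
        self.bins.to_csv(path, sep="\t", index=False)


def bin_concordance(rs: RecordSet) -> BINReport:
    """Classify every distinct BIN label in the record set."""
    per_bin: dict[str, dict] = {}
    without_bin = 0
    for rec in rs:
        if rec.bin_label is None:
            without_bin += 1
            continue
        slot = per_bin.setdefault(
            rec.bin_label,
            {"n_records": 0, "species": set(), "unassigned": False},
        )
        slot["n_records"] += 1
        if rec.species_label in _UNIDENTIFIED:
            slot["unassigned"] = True
        else:
            slot["species"].add(rec.species_label)

    rows = []
    counts = {"concordant": 0, "discordant": 0, "singleton": 0}
    for label in sorted(per_bin):
        slot = per_bin[label]
        if slot["n_records"] == 1:
            cls = "singleton"
        elif len(slot["species"]) <= 1:
            cls = "concordant"
        else:
            cls = "discordant"
        counts[cls] += 1
        rows.append(
            {
                "bin_label": label,
                "n_records": slot["n_records"],
                "n_species": len(slot["species"]),
                "species_list": ";".join(sorted(slot["species"])),
                "class": cls,
                "has_unassigned_records": slot["unassigned"],
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["bin_label", "n_records", "n_species", "species_list",
                 "class", "has_unassigned_records"],
    )
    return BINReport(
        bins=frame,
        n_bins=len(per_bin),
        n_concordant=counts["concordant"],
        n_discordant=counts["discordant"],
        n_singleton=counts["singleton"],
        n_records_without_bin=without_bin,
    )


def species_bin_summary(rs: RecordSet) -> pd.DataFrame:
    """Per-species BIN multiplicity: how many distinct BINs each species spans.

    Columns: species, n_records, n_bins, bins_list, has_unbinned_records.
    Species whose records all lack a BIN report ``n_bins = 0``.
    """
    per_species: dict[str, dict] = {}
    for rec in rs:
        if rec.species_label in _UNIDENTIFIED:
            continue
        slot = per_species.setdefault(
            rec.species_label, {"n_records": 0, "bins": set(), "unbinned": False}
        )
        slot["n_records"] += 1
        if rec.bin_label is None:
            slot["unbinned"] = True
        else:
            slot["bins"].add(rec.bin_label)
    rows = [
        {
            "species": sp,
            "n_records": slot["n_records"],
            "n_bins": len(slot["bins"]),
            "bins_list": ";".join(sorted(slot["bins"])),
            "has_unbinned_records": slot["unbinned"],
        }
        for sp, slot in sorted(per_species.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "n_records", "n_bins", "bins_list",
                 "has_unbinned_records"],
    )
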