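"""Uncorrected p-distances with pairwise deletion, and per-group statistics.

The distance between two aligned sequences is the proportion of mismatching
sites among sites where *both* sequences carry an unambiguous A/C/G/T
(pairwise deletion of gaps and ambiguities). No multiple-hit correction is
applied: identification performance in barcode libraries is conventionally
summarised on raw p-distances.

Two per-group statistics drive the barcode-gap diagnostics:

* ``intra_dmax`` — the maximum distance among records sharing a group label
  (species or BIN); undefined (NA) for singleton groups;
* ``Dmin_NN`` — the minimum distance from any record of the group to any
  record outside it; the outside group attaining it is the nearest
  neighbor.

A species is *distance-anomalous* when its nearest neighbor is less than a
threshold (default 2%) divergent, or when ``Dmin_NN < intra_dmax`` (a
barcode-gap violation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import RecordSet

__all__ = [
    "DistanceMatrix",
    "GroupDistanceSummary",
    "DistributionSummary",
    "p_distance",
    "distance_matrix",
    "group_dmax",
    "nearest_neighbor",
    "group_summaries",
    "anomaly_flags",
    "distribution_summaries",
    "write_phylip",
    "write_summary_table",
]

# A/C/G/T -> 0..3; every other symbol (gaps, IUPAC ambiguity) -> 4 = excluded.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected distance between two equal-length aligned sequences.

    Returns ``(proportion, n_compared_sites)``. With zero comparable sites
    the pair is incomparable and the proportion is NaN — never 0.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal aligned lengths: {len(a)} vs {len(b)}")
    ea, eb = _encode(a), _encode(b)
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        return (math.nan, 0)
    mism = int(((ea != eb) & valid).sum())
    return (mism / n, n)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with per-pair site counts.

    ``d[i, j]`` is a proportion in [0, 1], NaN where the pair shares no
    comparable site; ``sites[i, j]`` counts the compared sites.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.d.shape == (n, n) and self.sites.shape == (n, n)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def incomparable_pairs(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        mask = np.isnan(self.d[iu, ju])
        return [(self.ids[a], self.ids[b]) for a, b in zip(iu[mask], ju[mask])]

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        index = {rid: k for k, rid in enumerate(self.ids)}
        keep = [index[rid] for rid in ids]
        sel = np.ix_(keep, keep)
        return DistanceMatrix([self.ids[k] for k in keep],
                              self.d[sel].copy(), self.sites[sel].copy())


def distance_matrix(rs: RecordSet) -> DistanceMatrix:
    """All-pairs p-distance matrix of an aligned RecordSet (n >= 2)."""
    if not rs.aligned:
        raise ValueError("distance_matrix requires an aligned RecordSet")
    n = len(rs)
    if n < 2:
        raise ValueError(f"need at least 2 records, got {n}")
    enc = np.stack([_encode(r.sequence) for r in rs])
    ok = enc < 4
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, ok.sum(axis=1))
    for i in range(n - 1):
        valid = ok[i] & ok[i + 1 :]
        ns = valid.sum(axis=1)
        mism = ((enc[i] != enc[i + 1 :]) & valid).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(ns > 0, mism / np.maximum(ns, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
        sites[i, i + 1 :] = ns
        sites[i + 1 :, i] = ns
    return DistanceMatrix(list(rs.ids), d, sites)


def _group_indices(dm: DistanceMatrix,
                   grouping: Mapping[str, str]) -> dict[str, np.ndarray]:
    missing = [rid for rid in dm.ids if rid not in grouping]
    if missing:
        raise ValueError(f"grouping not total over matrix ids, missing {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for k, rid in enumerate(dm.ids):
        groups.setdefault(grouping[rid], []).append(k)
    return {g: np.array(ix) for g, ix in groups.items()}


def group_dmax(dm: DistanceMatrix,
               grouping: Mapping[str, str]) -> dict[str, float | None]:
    """Maximum within-group distance per group, in percent; NA for singletons.

    Incomparable (NaN) pairs are skipped; a multi-member group whose pairs
    are all incomparable also reports NA.
    """
    out: dict[str, float | None] = {}
    for g, ix in _group_indices(dm, grouping).items():
        if len(ix) < 2:
            out[g] = None
            continue
        block = dm.d[np.ix_(ix, ix)]
        iu, ju = np.triu_indices(len(ix), k=1)
        vals = block[iu, ju]
        vals = vals[~np.isnan(vals)]
        out[g] = float(vals.max()) * 100.0 if len(vals) else None
    return out


def nearest_neighbor(
    dm: DistanceMatrix, grouping: Mapping[str, str]
) -> dict[str, tuple[str, float, list[str]]]:
    """Per group: (nearest-neighbor group, Dmin_NN in percent, tied groups).

    Dmin_NN is the minimum distance from any member to any non-member.
    Ties are broken lexicographically on group label; all groups attaining
    the minimum are listed third.
    """
    groups = _group_indices(dm, grouping)
    if len(groups) < 2:
        raise ValueError("nearest_neighbor needs at least 2 groups")
    labels = sorted(groups)
    out: dict[str, tuple[str, float, list[str]]] = {}
    for g in labels:
        ix = groups[g]
        best: dict[str, float] = {}
        for h in labels:
            if h == g:
                continue
            block = dm.d[np.ix_(ix, groups[h])]
            vals = block[~np.isnan(block)]
            if len(vals):
                best[h] = float(vals.min())
        if not best:
            raise ValueError(f"group {g}: no comparable inter-group pair")
        dmin = min(best.values())
        tied = sorted(h for h, v in best.items() if v == dmin)
        out[g] = (tied[0], dmin * 100.0, tied)
    return out


@dataclass
class GroupDistanceSummary:
    """One row of the anomaly table: a group and its gap statistics."""

    group_id: str
    n: int
    intra_dmax: float | None  # percent, NA for singletons
    nn_group: str
    dmin_nn: float  # percent
    nn_ties: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    monophyly_status: str | None = None

    @property
    def anomalous(self) -> bool:
        return bool(self.flags)


def group_summaries(
    dm: DistanceMatrix, grouping: Mapping[str, str]
) -> list[GroupDistanceSummary]:
    """Combine intra_dmax and nearest-neighbor statistics per group."""
    dmax = group_dmax(dm, grouping)
    nn = nearest_neighbor(dm, grouping)
    sizes: dict[str, int] = {}
    for rid in dm.ids:
        sizes[grouping[rid]] = sizes.get(grouping[rid], 0) + 1
    return [
        GroupDistanceSummary(
            group_id=g, n=sizes[g], intra_dmax=dmax[g],
            nn_group=nn[g][0], dmin_nn=nn[g][1], nn_ties=nn[g][2],
        )
        for g in sorted(sizes)
    ]


def anomaly_flags(
    summaries: Iterable[GroupDistanceSummary], threshold_percent: float = 2.0
) -> list[GroupDistanceSummary]:
    """Flag groups with a too-close nearest neighbor or a barcode-gap violation.

    ``NN_below_threshold``: Dmin_NN < threshold (percent).
    ``gap_violation``: Dmin_NN < intra_dmax (only defined for n >= 2).
    Returns the flagged subset; flags are set in place on the summaries.
    """
    flagged = []
    for s in summaries:
        if s.dmin_nn < threshold_percent:
            s.flags.add("NN_below_threshold")
        if s.intra_dmax is not None and s.dmin_nn < s.intra_dmax:
            s.flags.add("gap_violation")
        if s.flags:
            flagged.append(s)
    return flagged


@dataclass(frozen=True)
class DistributionSummary:
    """Five-number-plus-mean summary of a per-group statistic, in percent."""

    category: str
    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float


def _summarise(category: str, values: list[float]) -> DistributionSummary:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # type-7 interpolation
    return DistributionSummary(category, len(arr), float(arr.min()), float(q1),
                               float(med), float(q3), float(arr.max()),
                               float(arr.mean()))


def distribution_summaries(
    dm: DistanceMatrix,
    grouping_species: Mapping[str, str],
    grouping_bin: Mapping[str, str] | None = None,
) -> list[DistributionSummary]:
    """Quartile summaries of intra_dmax and Dmin_NN per grouping (NA dropped).

    Mirrors a violin/box summary of within- versus between-group distances
    for species and, when BIN labels are available, for BINs.
    """
    out: list[DistributionSummary] = []
    groupings = [("species", grouping_species)]
    if grouping_bin is not None:
        groupings.append(("bin", grouping_bin))
    for name, grouping in groupings:
        dmax = [v for v in group_dmax(dm, grouping).values() if v is not None]
        nn = [v[1] for v in nearest_neighbor(dm, grouping).values()]
        if dmax:
            out.append(_summarise(f"{name}_dmax", dmax))
        out.append(_summarise(f"{name}_dmin_nn", nn))
    return out


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the matrix in square PHYLIP distance format (NaN as -1)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for i, rid in enumerate(dm.ids):
            row = " ".join(
                f"{-1.0 if math.isnan(v) else v:.6f}" for v in dm.d[i]
            )
            fh.write(f"{rid}  {row}\n")


def write_summary_table(
    summaries: Iterable[GroupDistanceSummary], path: str | Path
) -> None:
    """Anomaly-table TSV: group, max intra-group distance, NN, Dmin_NN, flags."""
    rows = [
        {
            "species": s.group_id,
            "n": s.n,
            "max_intra_sp": "NA" if s.intra_dmax is None else f"{s.intra_dmax:.2f}",
            "nearest_neighbor": s.nn_group,
            "distance_to_nn": f"{s.dmin_nn:.2f}",
            "flags": ";".join(sorted(s.flags)) or "none",
            "monophyly_status": s.monophyly_status or "NA",
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
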