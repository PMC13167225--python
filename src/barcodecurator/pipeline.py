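"""End-to-end two-pass curation workflow.

One *pass* chains the whole analysis: quality filters → haplotype
accounting → distance statistics → tree (supplied newick, or an internal
neighbor-joining fallback) → monophyly assessment → BIN concordance →
anomaly and intruder reports. The tool never deletes records on its own:
pass 1 produces advisory reports, the user writes an exclusion list after
review, and pass 2 re-runs the identical chain on the reduced set so that
non-monophyly cases caused by operational errors can be confirmed as
resolved. The bundle keeps both passes plus a diff of monophyly statuses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

from . import bins as bins_mod
from . import distances as dist_mod
from . import filters as filt_mod
from . import haplotypes as hap_mod
from . import monophyly as mono_mod
from .records import RecordSet, read_dataset

__all__ = ["PipelineConfig", "PassResult", "CurationBundle", "run_pass",
           "run_curation", "write_reports"]


@dataclass
class PipelineConfig:
    """Configuration of a curation run (flat key-value semantics)."""

    fasta: str | Path
    metadata: str | Path
    tree: str | Path | None = None
    exclusion_list: str | Path | None = None
    min_len: int = 500
    max_len: int = 658
    threshold_percent: float = 2.0
    rooting: str = "as-read"  # or "midpoint"
    outdir: str | Path = "curation_out"
    column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.threshold_percent <= 0:
            raise ValueError("threshold_percent must be > 0")
        if self.min_len > self.max_len:
            raise ValueError("invalid length bounds")
        if self.rooting not in ("as-read", "midpoint"):
            raise ValueError(f"unknown rooting mode {self.rooting!r}")


@dataclass
class PassResult:
    """All artifacts of one pass of the curation chain."""

    records: RecordSet
    filter_reports: list[filt_mod.FilterReport]
    haplotypes: hap_mod.HaplotypeTable
    richness: hap_mod.RichnessCorrelation | None
    dm: dist_mod.DistanceMatrix
    summaries: list[dist_mod.GroupDistanceSummary]
    flagged: list[dist_mod.GroupDistanceSummary]
    monophyly: dict[str, mono_mod.MonophylyResult]
    intruders: pd.DataFrame
    bin_report: bins_mod.BINReport
    species_bins: pd.DataFrame
    distributions: list[dist_mod.DistributionSummary]
    tree: dendropy.Tree

    @property
    def n_non_monophyletic(self) -> int:
        return sum(r.status == "non_monophyletic" for r in self.monophyly.values())

    def manifest(self) -> dict:
        # full-length = ungapped length equals the full alignment span
        aln_len = max((len(r.sequence) for r in self.records), default=0)
        species = {r.species_label for r in self.records}
        counts = {
            "n_sequences": len(self.records),
            "n_full_length": sum(
                1 for r in self.records if r.ungapped_length == aln_len
            ),
            "n_species": len(species),
            "n_haplotypes": self.haplotypes.total_haplotypes,
            "n_bins": self.bin_report.n_bins,
            "n_bins_concordant": self.bin_report.n_concordant,
            "n_bins_discordant": self.bin_report.n_discordant,
            "n_bins_singleton": self.bin_report.n_singleton,
            "n_species_flagged": len(self.flagged),
            "n_species_non_monophyletic": self.n_non_monophyletic,
        }
        counts["pct_full_length"] = (
            round(100.0 * counts["n_full_length"] / counts["n_sequences"], 2)
            if counts["n_sequences"] else 0.0
        )
        counts["pct_bins_concordant"] = self.bin_report.percentages()["concordant"]
        if self.richness is not None:
            counts["richness_pearson_r"] = round(self.richness.r, 4)
            counts["richness_p_value"] = self.richness.p_value
        return counts


@dataclass
class CurationBundle:
    pass1: PassResult
    pass2: PassResult | None
    status_diff: pd.DataFrame
    config: PipelineConfig | None = None


def _grouping_or_none(rs: RecordSet) -> dict[str, str] | None:
    binned = {r.record_id: r.bin_label for r in rs if r.bin_label is not None}
    if len(set(binned.values())) < 2:
        return None
    return binned


def run_pass(
    rs_raw: RecordSet,
    tree: dendropy.Tree | None = None,
    min_len: int = 500,
    max_len: int = 658,
    threshold_percent: float = 2.0,
    rooting: str = "as-read",
    exclusion: Iterable[str] = (),
) -> PassResult:
    """Run the full analysis chain once on a raw record set."""
    rs, rep_len = filt_mod.filter_by_length(rs_raw, min_len, max_len)
    rs, rep_stop = filt_mod.screen_stop_codons(rs)
    rs, rep_cur = filt_mod.apply_exclusion_list(rs, exclusion)
    rs = filt_mod.check_alignment(rs)
    reports = [rep_len, rep_stop, rep_cur]

    haplo = hap_mod.count_haplotypes(rs, "species")
    try:
        richness = hap_mod.richness_vs_effort(haplo)
    except ValueError:
        richness = None

    dm = dist_mod.distance_matrix(rs)
    species_grouping = rs.species_of()
    summaries = dist_mod.group_summaries(dm, species_grouping)
    flagged = dist_mod.anomaly_flags(summaries, threshold_percent)

    if tree is None:
        tree_used = mono_mod.nj_tree(dm)
    else:
        tree_used = tree
    if rooting == "midpoint":
        tree_used = mono_mod.midpoint_root(tree_used)

    tip_to_taxon, _unresolved = mono_mod.map_tips_to_taxa(
        tree_used, metadata=species_grouping
    )
    # tips excluded upstream of this pass are ignored on a supplied tree
    present = set(rs.ids)

    def tip_known(label: str) -> bool:
        prefix = label.partition(".")[0]
        return label in present or prefix in present

    tip_to_taxon = {t: x for t, x in tip_to_taxon.items() if tip_known(t)} \
        if tree is not None else tip_to_taxon
    mono = mono_mod.assess_monophyly(tree_used, tip_to_taxon)
    by_group = {s.group_id: s for s in summaries}
    for taxon, res in mono.items():
        if taxon in by_group:
            by_group[taxon].monophyly_status = res.status
    intruders = mono_mod.intruder_report(tree_used, tip_to_taxon, mono)

    bin_report = bins_mod.bin_concordance(rs)
    species_bins = bins_mod.species_bin_summary(rs)
    distributions = dist_mod.distribution_summaries(dm, species_grouping)
    bin_grouping = _grouping_or_none(rs)
    if bin_grouping is not None:
        # records without a BIN label are dropped from the BIN-level view
        dm_binned = (dm.submatrix(sorted(bin_grouping))
                     if len(bin_grouping) < len(rs) else dm)
        distributions += [
            dist_mod.DistributionSummary(
                d.category.replace("species", "bin"), d.n, d.min, d.q1,
                d.median, d.q3, d.max, d.mean,
            )
            for d in dist_mod.distribution_summaries(
                dm_binned, {k: bin_grouping[k] for k in dm_binned.ids}
            )
        ]

    return PassResult(
        records=rs, filter_reports=reports, haplotypes=haplo,
        richness=richness, dm=dm, summaries=summaries, flagged=flagged,
        monophyly=mono, intruders=intruders, bin_report=bin_report,
        species_bins=species_bins, distributions=distributions,
        tree=tree_used,
    )


def _status_diff(p1: PassResult, p2: PassResult | None) -> pd.DataFrame:
    if p2 is None:
        return pd.DataFrame(columns=["taxon", "pass1", "pass2"])
    rows = []
    taxa = sorted(set(p1.monophyly) | set(p2.monophyly))
    for t in taxa:
        s1 = p1.monophyly[t].status if t in p1.monophyly else "absent"
        s2 = p2.monophyly[t].status if t in p2.monophyly else "absent"
        if s1 != s2:
            rows.append({"taxon": t, "pass1": s1, "pass2": s2})
    return pd.DataFrame(rows, columns=["taxon", "pass1", "pass2"])


def run_curation(
    cfg: PipelineConfig, rs_raw: RecordSet | None = None
) -> CurationBundle:
    """Two-pass curation: analyse, apply the user's exclusion list, re-analyse.

    With no exclusion list pass 2 is skipped (the diff is then empty).
    ``rs_raw`` short-circuits dataset reading for programmatic use.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rs_raw is None:
        rs_raw = read_dataset(cfg.fasta, cfg.metadata, cfg.column_map)
    tree = None
    if cfg.tree is not None:
        tree = mono_mod.parse_newick(Path(cfg.tree).read_text())

    common = dict(min_len=cfg.min_len, max_len=cfg.max_len,
                  threshold_percent=cfg.threshold_percent, rooting=cfg.rooting)
    pass1 = run_pass(rs_raw, tree=tree, **common)
    pass2 = None
    if cfg.exclusion_list is not None:
        excluded = [
            line.strip() for line in Path(cfg.exclusion_list).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        tree2 = mono_mod.parse_newick(Path(cfg.tree).read_text()) \
            if cfg.tree is not None else None
        pass2 = run_pass(rs_raw, tree=tree2, exclusion=excluded, **common)
    return CurationBundle(pass1, pass2, _status_diff(pass1, pass2), cfg)


def _write_pass(p: PassResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    filt_mod.write_filter_reports(p.filter_reports, outdir / "filter_report.tsv")
    p.haplotypes.write(outdir / "haplotype_table.tsv")
    dist_mod.write_summary_table(p.summaries, outdir / "distance_summary.tsv")
    dist_mod.write_summary_table(p.flagged, outdir / "anomaly_table.tsv")
    mono_mod.write_monophyly_report(p.monophyly, outdir / "monophyly_report.tsv")
    p.intruders.to_csv(outdir / "intruder_report.tsv", sep="\t", index=False)
    p.bin_report.write(outdir / "bin_report.tsv")
    p.species_bins.to_csv(outdir / "species_bin_summary.tsv", sep="\t", index=False)
    pd.DataFrame([vars(d) for d in p.distributions]).to_csv(
        outdir / "distribution_summaries.tsv", sep="\t", index=False
    )
    mono_mod.write_newick(p.tree, outdir / "tree.nwk")
    species_rows = p.haplotypes.to_frame().rename(
        columns={"n_records": "n_barcodes"}
    )[["species", "n_barcodes"]]
    species_rows.to_csv(outdir / "species_summary.tsv", sep="\t", index=False)


def write_reports(bundle: CurationBundle, outdir: str | Path) -> Path:
    """Write both passes' TSV reports plus a JSON manifest; returns outdir."""
    if bundle is None or bundle.pass1 is None:
        raise ValueError("empty bundle: nothing to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_pass(bundle.pass1, outdir / "pass1")
    manifest: dict = {"pass1": bundle.pass1.manifest()}
    if bundle.pass2 is not None:
        _write_pass(bundle.pass2, outdir / "pass2")
        manifest["pass2"] = bundle.pass2.manifest()
    bundle.status_diff.to_csv(outdir / "monophyly_status_diff.tsv",
                              sep="\t", index=False)
    if bundle.config is not None:
        manifest["parameters"] = {
            "min_len": bundle.config.min_len,
            "max_len": bundle.config.max_len,
            "threshold_percent": bundle.config.threshold_percent,
            "rooting": bundle.config.rooting,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
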