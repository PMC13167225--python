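"""Synthetic barcode libraries with known structure and injected errors.

Real curation inputs (the pre-filter record pool, the identity of every
mislabelled voucher) are never published, so every pipeline stage here is
exercised against generated libraries where the truth is known exactly.

The generative model is deliberately minimal but structured like a barcode
dataset:

* a random rooted species tree (requested sister pairs are honoured as
  cherries) with Jukes–Cantor-style substitutions — each branch carries a
  Poisson number of substitutions, each replacing a site with a uniformly
  chosen different base — produces one ancestral (modal) haplotype per
  species with a controlled interspecific divergence scale;
* individuals are a star-shaped cloud around their species ancestor: each
  record adds a Poisson(θ) number of substitutions (θ in expected sites per
  individual, default 2), yielding haplotype richness that grows with
  sampling effort;
* substitutions that would create a stop codon in reading frame 0 are
  redrawn, emulating purifying selection on a protein-coding marker — so
  clean records always keep a stop-free frame and stop-codon screening
  is a sound NUMT detector;
* operational error processes are injected per record with configured
  probabilities: label swaps (misidentification), cross-species
  contamination, NUMT-like frame-disrupted copies carrying in-frame stops
  in every frame, sub-length fragments, ambiguity-riddled reads, and
  cross-species haplotype sharing for designated sister pairs.

Every record's true species and injected error class are recorded in a
:class:`TruthTable` for parameter-recovery testing. All randomness flows
through one seeded generator: identical seed, identical library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .records import BarcodeRecord, RecordSet

__all__ = ["SimConfig", "TruthTable", "simulate_ancestors",
           "simulate_individuals", "inject_errors", "simulate_library",
           "write_library"]

_BASES = "ACGT"
_STOPS_F0 = {"TAA", "TAG"}  # invertebrate mitochondrial stops


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic library.

    ``inter_divergence`` is the expected substitutions per site separating
    a sister pair; non-sister splits are deeper by ``deep_multiplier``.
    ``intra_theta`` is the expected number of substituted *sites* per
    individual relative to its species ancestor. ``n_per_species`` is
    ``("fixed", n)``, ``("uniform", lo, hi)`` or ``("ztnb", mean, sd)``
    (zero-truncated negative binomial, the skewed per-species sampling
    depth typical of reference libraries: default mean 24, SD 30.73).
    Error rates are per-record probabilities of each injected class.
    """

    n_species: int
    sister_pairs: tuple[tuple[int, int], ...] = ()
    seq_length: int = 658
    inter_divergence: float = 0.10
    deep_multiplier: float = 2.0
    intra_theta: float = 2.0
    n_per_species: tuple = ("ztnb", 24.0, 30.73)
    mislabel_rate: float = 0.0
    contamination_rate: float = 0.0
    numt_rate: float = 0.0
    short_rate: float = 0.0
    ambiguity_rate: float = 0.0
    share_pairs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.seq_length < 60:
            raise ValueError("seq_length must be >= 60")
        rates = (self.mislabel_rate, self.contamination_rate, self.numt_rate,
                 self.short_rate, self.ambiguity_rate)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("error rates must lie in [0, 1]")
        if sum(rates) > 1.0:
            raise ValueError("error rates must sum to <= 1 (one class per record)")
        for pair in self.sister_pairs + self.share_pairs:
            a, b = pair
            if not (0 <= a < self.n_species and 0 <= b < self.n_species) or a == b:
                raise ValueError(f"invalid species pair {pair}")

    def species_name(self, index: int) -> str:
        return f"Synthosoma sp{index + 1:03d}"

    def bin_name(self, index: int) -> str:
        return f"BIN:S{index + 1:03d}"


@dataclass
class TruthTable:
    """Ground truth of a synthetic library.

    ``table`` has one row per record: record_id, true_species,
    observed_species, error_class in {none, mislabel, contamination, numt,
    short, ambiguous, shared_haplotype}. ``shared_pairs`` lists the species
    pairs across which a haplotype was copied.
    """

    table: pd.DataFrame
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)

    def ids_with(self, error_class: str) -> set[str]:
        mask = self.table["error_class"] == error_class
        return set(self.table.loc[mask, "record_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _random_stopfree_sequence(length: int, rng: np.random.Generator) -> str:
    seq = list(rng.choice(list(_BASES), size=length))
    for i in range(0, length - 2, 3):
        while "".join(seq[i : i + 3]) in _STOPS_F0:
            seq[i + 2] = _BASES[rng.integers(4)]
    return "".join(seq)


def _substitute(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    """Replace seq[pos] with a different base, avoiding frame-0 stops."""
    options = [b for b in _BASES if b != seq[pos]]
    rng.shuffle(options)
    codon_start = (pos // 3) * 3
    for base in options:
        old = seq[pos]
        seq[pos] = base
        codon = "".join(seq[codon_start : codon_start + 3])
        if len(codon) < 3 or codon not in _STOPS_F0:
            return
        seq[pos] = old
    # every alternative creates a stop (cannot happen for single-site edits
    # of a stop-free codon, but keep the site unchanged as a safe fallback)


def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in rng.integers(0, len(chars), size=n_subs):
        _substitute(chars, int(pos), rng)
    return "".join(chars)


def simulate_ancestors(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """One ancestral sequence per species, evolved down a species tree.

    Declared sister pairs are cherries at expected divergence
    ``inter_divergence`` (substitutions per site, before multiple-hit
    overlap); every other species pair sits at ``inter_divergence *
    deep_multiplier``, so declared sisters are strictly each other's
    nearest neighbours in expectation.
    """
    if cfg.deep_multiplier < 1.0:
        raise ValueError("deep_multiplier must be >= 1")
    root = _random_stopfree_sequence(cfg.seq_length, rng)
    half_sister = cfg.inter_divergence / 2.0
    half_deep = cfg.inter_divergence * cfg.deep_multiplier / 2.0

    def evolve(seq: str, branch_rate: float) -> str:
        n = int(rng.poisson(branch_rate * cfg.seq_length))
        return _mutate(seq, n, rng)

    # star-of-cherries: each sister pair hangs off a pair ancestor placed
    # half_deep - half_sister below the root; unpaired species hang directly
    # at half_deep. Expected divergence is then exactly inter_divergence
    # within a sister pair and inter_divergence * deep_multiplier otherwise.
    paired = {i for pair in cfg.sister_pairs for i in pair}
    ancestors: dict[str, str] = {}
    for a, b in cfg.sister_pairs:
        pair_anc = evolve(root, half_deep - half_sister)
        ancestors[cfg.species_name(a)] = evolve(pair_anc, half_sister)
        ancestors[cfg.species_name(b)] = evolve(pair_anc, half_sister)
    for i in range(cfg.n_species):
        if i not in paired:
            ancestors[cfg.species_name(i)] = evolve(root, half_deep)
    return {name: ancestors[name]
            for name in (cfg.species_name(i) for i in range(cfg.n_species))}


def _draw_n(cfg: SimConfig, rng: np.random.Generator) -> int:
    kind = cfg.n_per_species[0]
    if kind == "fixed":
        return int(cfg.n_per_species[1])
    if kind == "uniform":
        lo, hi = cfg.n_per_species[1:3]
        return int(rng.integers(lo, hi + 1))
    if kind == "ztnb":
        mean, sd = float(cfg.n_per_species[1]), float(cfg.n_per_species[2])
        var = sd * sd
        if var <= mean:
            raise ValueError("ztnb requires sd^2 > mean")
        p = mean / var
        r = mean * mean / (var - mean)
        while True:
            n = int(rng.negative_binomial(r, p))
            if n > 0:
                return n
    raise ValueError(f"unknown n_per_species spec: {cfg.n_per_species!r}")


def simulate_individuals(
    ancestors: dict[str, str], cfg: SimConfig, rng: np.random.Generator
) -> tuple[RecordSet, TruthTable]:
    """Sample individuals as Poisson(θ) mutation clouds around each ancestor."""
    records: list[BarcodeRecord] = []
    rows = []
    counter = 0
    for sp_index in range(cfg.n_species):
        species = cfg.species_name(sp_index)
        anc = ancestors[species]
        for _ in range(_draw_n(cfg, rng)):
            counter += 1
            rid = f"SYN{counter:05d}"
            seq = _mutate(anc, int(rng.poisson(cfg.intra_theta)), rng)
            records.append(
                BarcodeRecord(
                    record_id=rid, species_label=species, sequence=seq,
                    bin_label=cfg.bin_name(sp_index), country="Synthetica",
                    project="SIM",
                )
            )
            rows.append({"record_id": rid, "true_species": species,
                         "observed_species": species, "error_class": "none"})
    truth = TruthTable(pd.DataFrame(rows))
    return RecordSet(records, aligned=True), truth


def _force_all_frame_stops(seq: str, rng: np.random.Generator) -> str:
    """Guarantee >=1 TAA stop in each of the three reading frames."""
    chars = list(seq)
    for frame in range(3):
        starts = range(frame, len(chars) - 2, 3)
        if any("".join(chars[i : i + 3]) in _STOPS_F0 for i in starts):
            continue
        pos = int(rng.choice(list(starts)))
        chars[pos : pos + 3] = "TAA"
    return "".join(chars)


def inject_errors(
    rs: RecordSet, truth: TruthTable, cfg: SimConfig, rng: np.random.Generator
) -> tuple[RecordSet, TruthTable]:
    """Apply the configured per-record error processes.

    Each record receives at most one error class, drawn from the configured
    rates; haplotype sharing then copies one clean haplotype across each
    designated species pair. All sequences are re-padded with trailing gaps
    to the alignment length, so the output stays aligned.
    """
    records = {r.record_id: r for r in rs}
    table = truth.table.set_index("record_id", drop=False)
    species_names = [cfg.species_name(i) for i in range(cfg.n_species)]
    by_species: dict[str, list[str]] = {}
    for rec in rs:
        by_species.setdefault(rec.species_label, []).append(rec.record_id)

    classes = ["mislabel", "contamination", "numt", "short", "ambiguous"]
    rates = np.array([cfg.mislabel_rate, cfg.contamination_rate, cfg.numt_rate,
                      cfg.short_rate, cfg.ambiguity_rate])
    edges = np.cumsum(rates)
    aln_len = len(next(iter(rs)).sequence) if len(rs) else cfg.seq_length

    def pad(seq: str) -> str:
        return seq + "-" * (aln_len - len(seq))

    n_eligible = 0
    for rid in list(records):
        u = rng.random()
        k = int(np.searchsorted(edges, u, side="right"))
        if k >= len(classes):
            continue
        n_eligible += 1
        cls = classes[k]
        rec = records[rid]
        true_sp = table.at[rid, "true_species"]
        if cls == "mislabel":
            others = [s for s in species_names if s != true_sp]
            new_sp = others[int(rng.integers(len(others)))]
            records[rid] = replace(rec, species_label=new_sp)
            table.at[rid, "observed_species"] = new_sp
        elif cls == "contamination":
            donors = [
                r for sp, ids in by_species.items() if sp != true_sp
                for r in ids
                if table.at[r, "error_class"] == "none" and r != rid
            ]
            if not donors:
                continue
            donor = records[donors[int(rng.integers(len(donors)))]]
            records[rid] = replace(rec, sequence=donor.sequence,
                                   bin_label=donor.bin_label)
        elif cls == "numt":
            ungapped = rec.ungapped
            cut = int(rng.integers(len(ungapped)))
            shifted = ungapped[:cut] + ungapped[cut + 1 :]
            records[rid] = replace(rec,
                                   sequence=pad(_force_all_frame_stops(shifted, rng)))
        elif cls == "short":
            new_len = int(rng.integers(300, 500))
            records[rid] = replace(rec, sequence=pad(rec.ungapped[:new_len]))
        elif cls == "ambiguous":
            chars = list(rec.sequence)
            hit = rng.random(len(chars)) < 0.02
            if not hit.any():
                hit[int(rng.integers(len(chars)))] = True
            for i in np.flatnonzero(hit):
                if chars[i] != "-":
                    chars[i] = "N"
            records[rid] = replace(rec, sequence="".join(chars))
        table.at[rid, "error_class"] = cls

    shared_pairs: list[tuple[str, str]] = []
    for a, b in cfg.share_pairs:
        sp_a, sp_b = cfg.species_name(a), cfg.species_name(b)
        clean_a = [r for r in by_species.get(sp_a, ())
                   if table.at[r, "error_class"] == "none"]
        clean_b = [r for r in by_species.get(sp_b, ())
                   if table.at[r, "error_class"] == "none"]
        if not clean_a or not clean_b:
            continue
        donor = records[clean_a[int(rng.integers(len(clean_a)))]]
        target = clean_b[int(rng.integers(len(clean_b)))]
        records[target] = replace(records[target], sequence=donor.sequence)
        table.at[target, "error_class"] = "shared_haplotype"
        shared_pairs.append((sp_a, sp_b))

    out = RecordSet([records[r.record_id] for r in rs], aligned=True)
    new_truth = TruthTable(table.reset_index(drop=True), shared_pairs)
    return out, new_truth


def simulate_library(cfg: SimConfig) -> tuple[RecordSet, TruthTable]:
    """Ancestors -> individuals -> error injection, under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    ancestors = simulate_ancestors(cfg, rng)
    rs, truth = simulate_individuals(ancestors, cfg, rng)
    return inject_errors(rs, truth, cfg, rng)


def write_library(rs: RecordSet, truth: TruthTable, cfg: SimConfig,
                  outdir: str | Path) -> None:
    """Emit FASTA + metadata TSV (reader dialect), truth TSV, and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .records import write_dataset

    write_dataset(rs, outdir / "library.fasta", outdir / "metadata.tsv")
    truth.write(outdir / "truth.tsv")
    with open(outdir / "sim_config.txt", "w") as fh:
        for key, value in vars(cfg).items():
            fh.write(f"{key}\t{value!r}\n")
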