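"""Shared fixtures: tiny hand-built record sets and seeded synthetic libraries."""

from __future__ import annotations

import pytest

from barcodecurator.records import BarcodeRecord, RecordSet
from barcodecurator.simulate import SimConfig, simulate_library

# The synthetic study conditions: 40 species x 20 individuals with one
# sister pair sharing a haplotype and low-rate operational errors.
STUDY_CONFIG = SimConfig(
    n_species=40,
    sister_pairs=((0, 1),),
    n_per_species=("fixed", 20),
    mislabel_rate=0.02,
    contamination_rate=0.01,
    numt_rate=0.03,
    short_rate=0.02,
    share_pairs=((0, 1),),
    seed=7,
)

# Error-free, well-separated library for the no-anomaly invariants.
CLEAN_CONFIG = SimConfig(n_species=15, n_per_species=("fixed", 8), seed=11)


def make_records(*rows, aligned=True) -> RecordSet:
    """rows: (record_id, species, sequence[, bin_label]) tuples."""
    recs = []
    for row in rows:
        rid, species, seq = row[:3]
        bin_label = row[3] if len(row) > 3 else None
        recs.append(BarcodeRecord(record_id=rid, species_label=species,
                                  sequence=seq, bin_label=bin_label))
    return RecordSet(recs, aligned=aligned)


@pytest.fixture(scope="session")
def study_library():
    return simulate_library(STUDY_CONFIG)


@pytest.fixture(scope="session")
def study_pass1(study_library):
    from barcodecurator.pipeline import run_pass

    rs, _truth = study_library
    return run_pass(rs)


@pytest.fixture(scope="session")
def study_pass2(study_library):
    """Second curation pass after excluding the true mislabelled records."""
    from barcodecurator.pipeline import run_pass

    rs, truth = study_library
    return run_pass(rs, exclusion=sorted(truth.ids_with("mislabel")))


@pytest.fixture(scope="session")
def clean_library():
    return simulate_library(CLEAN_CONFIG)
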