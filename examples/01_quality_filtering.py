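"""Quality-filter a barcode library: length window and stop-codon screen.

Builds a small synthetic COI-5P library with injected NUMT-like sequences
(frame-disrupted, stops in every reading frame) and sub-length fragments,
then applies the two sequence quality filters and prints the audit trail.
"""

from barcodecurator import filter_by_length, screen_stop_codons
from barcodecurator.simulate import SimConfig, simulate_library

cfg = SimConfig(n_species=10, n_per_species=("fixed", 10),
                numt_rate=0.05, short_rate=0.05, seed=1)
rs, truth = simulate_library(cfg)
print(f"simulated {len(rs)} records for {cfg.n_species} species")

rs, length_report = filter_by_length(rs, min_len=500, max_len=658)
print(f"length filter [500, 658]: kept {length_report.n_kept}, "
      f"removed {length_report.n_removed}")

rs, stop_report = screen_stop_codons(rs)
print(f"stop-codon screen (mito code, 3 frames): kept {stop_report.n_kept}, "
      f"removed {stop_report.n_removed}")

# the truth table tells us what the filters should have caught
print(f"injected: {len(truth.ids_with('short'))} short, "
      f"{len(truth.ids_with('numt'))} NUMT-like")
caught = {rid for rid, _ in length_report.removed + stop_report.removed}
expected = truth.ids_with("short") | truth.ids_with("numt")
print(f"filters recovered the injected errors exactly: {caught == expected}")
# Every removal is listed with its reason; nothing is dropped silently.
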