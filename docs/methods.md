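# Methods

This note documents the models, conventions and numerical choices behind
`barcodecurator`, in the order data flows through the pipeline.

## Quality filtering

**Length window.** Records are kept when their *ungapped* length lies in
the inclusive window [500, 658] bp. Gaps are alignment artifacts, not
sequence, so they never count toward length. The bounds correspond to the
standard animal barcode fragment: 658 bp is the full COI-5P amplicon and
500 bp is the conventional floor below which a partial barcode loses
diagnostic value. Both bounds are parameters.

**Stop-codon screen.** Translation uses the invertebrate mitochondrial
genetic code (NCBI table 5), the correct code for insect COI: TAA/TAG are
the only stops, TGA encodes tryptophan and AGA/AGG encode serine. Because
BOLD-style exports do not record the reading frame, each ungapped sequence
is translated at all three offsets and kept iff at least one frame is
stop-free; the stop-free frame with the lowest offset is reported. This
convention avoids false removals from frame mis-specification at the cost
of retaining a pseudogene whose disruption happens to leave one frame
clean. Codons containing any symbol outside {A,C,G,T} translate to `X` and
never count as stops: an ambiguous base is missing evidence, not evidence
of disruption.

**Exclusion list.** Expert curation is represented as a user-supplied list
of record ids. The tool never removes records on its own authority;
suggestions from the monophyly stage only become removals when a curator
writes them into the list. Unknown ids warn rather than fail, since the
list is typically hand-edited.

Every filter emits a report that partitions its input exactly into kept
and removed (with per-record reasons), so the full provenance of the final
dataset is reconstructible.

## Distances and the barcode gap

Distances are uncorrected p-distances: the proportion of mismatching sites
among sites where both sequences carry an unambiguous A/C/G/T (*pairwise*
deletion, which preserves information in ragged 500–658 bp data better
than complete-column deletion). No substitution-model correction is
applied; barcode-gap diagnostics conventionally operate on raw
proportions. A pair with zero comparable sites is marked incomparable
(NaN), never distance 0, and is excluded from group minima/maxima.

Per group (species, or BIN), two statistics are derived:

* `intra_dmax` — the maximum within-group distance; undefined (NA) for
  singletons, which have no within-group pair;
* `Dmin_NN` — the minimum distance from any member to any non-member; the
  outside group attaining it is the nearest neighbor. Ties are broken
  lexicographically on the group label, with all tied groups listed.

A species is **distance-anomalous** when `Dmin_NN` falls below a threshold
(default 2%, a conventional congeneric-divergence floor for COI; a
parameter here) or when `Dmin_NN < intra_dmax` — a barcode-gap violation,
meaning some conspecific pair is further apart than the closest
heterospecific pair. Distances are stored as proportions and reported as
percents with two decimals. Distribution summaries (min, quartiles,
median, max, mean of the per-group `intra_dmax` and `Dmin_NN` value sets)
use numpy's default linear (type-7) quantile interpolation so they are
reproducible bit-for-bit.

## Monophyly and the curation loop

Trees are consumed as newick (labels preserved verbatim; composite
`ProcessID.Taxon_name` tip labels are split at the first dot, with a
metadata mapping taking precedence when both resolve). Assessment is
performed on the tree **rooted as read**: a taxon with ≥2 tips is
monophyletic iff the MRCA of its tips has no descendant tip of another
taxon; 1-tip taxa are singletons (never counted non-monophyletic) and
0-tip taxa are absent. A midpoint-rooting helper is provided, with the
caveat that status can differ between rootings. Support values are parsed
and carried but play no role in status: the call is purely topological.

For each non-monophyletic taxon the intruder report lists the foreign tips
under its MRCA and a **minimal removal set**. The removal set is computed
exactly: any removal that restores monophyly is fully determined by the
clade that will host the surviving members — every foreign tip inside that
clade and every member outside it must go — so minimising
(foreign-inside + members-outside) over all nodes of the tree, one linear
pass of subtree counts, yields the true minimum. (A greedy single-tip
search was considered and rejected: when two or more mislabelled members
stray into different clades, removing one stray does not shrink the MRCA,
so a greedy intruder-count objective degenerates into removing most of the
tree.) Ties prefer the clade keeping more members, then the shallower
node. The suggestions are advisory; the two-pass pipeline re-runs the
identical chain after the curator's exclusion list is applied and diffs
the statuses, so persistent non-monophyly can be attributed to biology
(haplotype sharing, introgression, incomplete lineage sorting) rather than
operational error.

When no external tree is supplied, a neighbor-joining tree is built from
the distance matrix. NJ is implemented with a deterministic tie-break
(lowest row/column index pair of the Q-criterion minimum), keeps negative
branch lengths as computed, and reproduces additive matrices exactly
(verified against patristic distances and, for topology, against an
independent NJ implementation). NJ is a fallback for self-contained
analyses, not a substitute for proper likelihood inference on real data;
incomparable pairs are an error directing the user to supply a tree.

## BIN concordance

BIN labels are operational taxonomic units assigned upstream and consumed
as metadata; the package never re-clusters. A BIN with one record is a
*singleton* (concordance unassessable — singleton takes precedence, a
1-record BIN is never "concordant"); with ≥2 records and one species
label, *concordant*; with ≥2 species labels, *discordant*. The three
classes partition all distinct BINs, and percentages are computed over the
distinct-BIN count with two decimals. Records lacking a species label
count toward BIN size but not its species set, and are flagged rather than
guessed. The per-species view reports BIN multiplicity (how many BINs a
species spans) and species lacking any BIN.

## Synthetic library generator

The generator exists because real curation inputs — the pre-filter record
pool and the identity of every bad record — are never published, so
ground-truth validation requires simulation. It emulates the statistical
structure the pipeline assumes, not a full evolutionary model:

* **Species structure.** A star-of-cherries species tree: declared sister
  pairs are cherries whose members sit at an expected `inter_divergence`
  substitutions/site from each other (default 0.10, a typical congeneric
  COI scale); all other species pairs sit at `inter_divergence ×
  deep_multiplier` (default ×2). This realises exactly the two divergence
  scales the downstream statistics consume; no deeper tree shape is
  modelled.
* **Substitutions** are Jukes–Cantor style: a Poisson number per branch,
  each replacing a uniformly chosen site with a uniformly chosen different
  base. Substitutions that would create a frame-0 stop codon are redrawn —
  purifying selection on a protein-coding marker — so clean records always
  retain a stop-free frame and the stop-codon screen is a sound NUMT
  detector within the model.
* **Individuals** form a star-shaped cloud: each record adds Poisson(θ)
  substitutions to its species ancestor (θ in expected sites per record,
  default 2). There is no within-species coalescent; the star model is
  sufficient to produce haplotype-richness gradients and barcode gaps, but
  it understates haplotype autocorrelation and geographic structure — a
  documented limitation of what passing tests show about real data.
* **Sampling depth** per species defaults to a zero-truncated negative
  binomial with mean 24 and SD 30.73, the skewed depth profile typical of
  reference libraries (a handful of deeply sampled species, many
  singletons), so richness-versus-effort analyses behave realistically.
* **Error processes**, each a per-record probability, at most one class
  per record: *mislabel* (species label swapped, sequence untouched),
  *contamination* (sequence replaced by a copy from another species' clean
  record, BIN following the sequence), *NUMT* (1-bp deletion, then a TAA
  written into any still-clean frame, guaranteeing stops in all three
  frames at ungapped length 657 — so NUMTs are caught by the stop screen,
  never the length filter), *short* (3′ truncation to 300–499 bp — caught
  by the length filter, never the stop screen), *ambiguous* (≈2% of sites
  overwritten with N, at least one). Haplotype *sharing* then copies one
  clean haplotype across each designated sister pair, which forces
  `Dmin_NN = 0` for both species and non-monophyly on any distance-based
  tree. BIN labels equal the true (sequence-source) species, so every
  mislabel makes a BIN discordant.

All randomness flows through a single `numpy` generator seeded from the
configuration: identical seed, byte-identical library.

## Problem sizes and validation

The package's own validation runs entirely on synthetic data: an
error-injection study of 40 species × 20 individuals (mislabel 2%,
contamination 1%, NUMT 3%, short 2%, one sharing pair) through the full
two-pass chain, and a 50-species richness study under the default
negative-binomial depth. These sizes exercise every code path, including
an 800-tip NJ tree and MRCA queries, while keeping a full run in tens of
seconds. Against the truth table, the length filter and stop screen each
recover their injected class with recall and precision 1.0, all mislabels
surface in intruder reports, and excluding them in pass 2 reduces the
non-monophyletic count; an error-free configuration yields zero anomalies,
full monophyly and fully concordant multi-record BINs. Distance matrices
are checked element-wise against a naive site-enumeration oracle, NJ
against additive-matrix exactness and an independent implementation,
monophyly against an independent tree library, and removal sets against
exhaustive enumeration on small trees.

## Known limitations

* The pipeline assumes pre-aligned input (equal-length sequences); it
  checks alignment but does not align.
* Sequence-based NUMT detection is limited to stop codons; NUMTs with an
  intact frame pass the screen and are only catchable through tree
  inspection, which is left to the curator.
* The monophyly verdict depends on the rooting of the supplied tree.
* The synthetic generator's star model omits coalescent structure,
  recombination-free linkage effects, rate variation among sites and
  lineages, and alignment error.
* The 2% anomaly threshold is a convention, not an inference; taxa with
  genuinely shallow divergence will always be flagged.
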