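# Methods

`superbarcode` evaluates how well DNA barcoding datasets — from short
standard plastid markers up to whole plastomes and the complete nrDNA
cistron ("super-barcodes" or "barcode 2.0") — discriminate species in a
densely sampled genus. This note records the models, conventions and
numerical choices behind every statistic the package prints.

## Data model and input conventions

Alignments are read from aligned FASTA plus a TSV sample map
(`sample_id`, `species`, optional `section`, `provenance`). Sequences are
uppercase-normalized; `U` → `T`; the gap dialects `.` and `?` → `-`;
IUPAC ambiguity codes are preserved in the matrix and every statistic
declares its own treatment of them (below). Infraspecific taxa (e.g.
"X. y var. z") are treated as the species unit: the full label string is
the unit of discrimination. Column coordinates are 0-based half-open
internally and 1-based inclusive in all TSV output. Newick supports are
accepted as internal-node labels in both the `)87:` and `)0.87:`
dialects; when every support in a tree is ≤ 1 they are rescaled ×100.

## Alignment feature statistics

A column is **variable** when ≥ 2 distinct unambiguous bases (A/C/G/T)
occur among its rows and **parsimony-informative** when ≥ 2 distinct
unambiguous bases each occur in ≥ 2 rows. Variation carried only by gaps
or ambiguity codes does not count — the convention of the common
population-genetics desktop tools this table is meant to be comparable
with, declared here rather than inferred. **Haplotypes** are counted
after removing every column containing any gap or ambiguity in any row
(site exclusion), then counting distinct row strings; if every column is
removed the count degenerates to 1 with a warning. **GC content** is
(#G+#C)/(#A+#C+#G+#T) with gaps/ambiguities in neither numerator nor
denominator. Reported percentages use two-decimal half-up rounding.

## Nucleotide diversity and hotspots

π is the average over all unordered sample pairs of (differences /
comparable sites), where a site is comparable for a pair when both rows
carry an unambiguous base. The per-pair denominator (rather than the
alignment length) keeps the statistic stable in gap-rich spacer regions;
pairs with no comparable site are skipped (all pairs skipped is an
error). Note the pair-average convention means duplicating every row
changes π by the known pair-count factor; permutation of rows never does.

The sliding-window profile uses 600 bp windows at 100 bp steps
(defaults), with windows at starts 0, step, 2·step, … while the start is
inside the alignment; terminal truncated windows are kept but flagged
partial and excluded from region peaks, avoiding short-window variance
spikes. A named region (annotation track, non-overlapping) is called a
**hypervariable hotspot** when its crest — the maximum π among full
windows whose midpoint falls inside the region — strictly exceeds 0.020
and its aligned length strictly exceeds 600 bp. Hotspots are reported in
descending crest order. Window coordinates refer to alignment columns,
not ungapped positions of any reference.

## Distances and distance-based discrimination

The K2P distance separates transitions (A↔G, C↔T; proportion P) from
transversions (proportion Q) over the pair's comparable columns:

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

Pairwise deletion is the default (per-pair comparable columns); complete
deletion is available by flag. Ambiguity codes are excluded outright — no
fractional matching — for determinism. A non-positive log argument
(saturation) raises an error naming the pair instead of clamping to
infinity; the bootstrap falls back to raw differences for the affected
replicate and counts the event. Raw differences are integer counts of
differing comparable columns.

A multi-individual species is **successfully identified** by the
distance method when its minimum interspecific distance strictly exceeds
its maximum intraspecific distance (a tie fails; "larger than" is
strict). Singleton species are not evaluated but do serve as potential
nearest neighbors. Dataset-level statistics:

* **resolution** — 100 × successes / multi-individual species, half-up
  to two decimals;
* **zero-K2P species count** — multi-individual species whose minimum
  interspecific K2P distance is exactly 0 (these necessarily fail);
* **zero-K2P pair count** — unordered species pairs, singletons
  included, whose minimum between-species K2P distance is 0;
* **AMID** — mean (and range) over multi-individual species of each
  species' minimum interspecific raw difference count, a dataset's
  budget of usable interspecific variation.

`resolution_vs_zero_k2p` fits an OLS line of resolution on the zero-K2P
count (≥ 3 datasets; constant response returns slope 0, r 0, p 1;
constant predictor is an error).

On printed-table percentages: success counts are integers and exact;
two-decimal percentages of n/21 are reported under the single half-up
rule even where legacy tables mix rounding conventions, so 19/21 prints
as 90.48.

## Tree-based discrimination

Internal edges with bootstrap support below the threshold (default 50)
are contracted to polytomies first; missing supports count as below
threshold with a warning. A species is then monophyletic iff some edge
separates exactly its individuals from every other leaf — a bipartition
criterion, so verdicts are stable under rerooting; outgroup leaves, when
given, are pruned beforehand. The support reported for a success is that
of the edge adjacent to the species clade (when the tree is rooted and
the clade and its complement are both root children, the clade's own
edge wins). A two-individual species whose samples are sister below the
threshold fails, by construction of the collapse step.

Support histograms over successes use the bins =100, [90,100), [65,90),
<65. Dataset comparison returns the species gained/lost between two
verdict tables plus paired supports for shared successes.

Representative selection (one sample per species for downstream
inter-section analyses) applies, in order: singleton and monophyletic
species keep their samples; individuals outside their section's dominant
clade (the largest section-pure bipartition side — "pure" meaning every
leaf in it belongs to the section) are excluded as strays; own-provenance
samples are preferred over downloaded ones; remaining ties break on
lexicographic sample id. A species whose every individual is a stray is
flagged and keeps its first sample by id.

Two-tree (e.g. cytonuclear) comparison reports shared bipartitions, the
Robinson–Foulds distance on the support-collapsed trees, and conflicts:
pairs of bipartitions, each supported ≥ 50 in its own tree, that are
incompatible (all four intersection cells non-empty). At species or
section level, multi-member groups are collapsed to one leaf only where
monophyletic in *both* trees; other groups are excluded and reported
rather than forced into a placement. Fewer than four shared leaves is an
error.

## Neighbor joining and bootstrap

The in-repo tree builder is classical neighbor joining (Q criterion),
provided so the tree-based method runs without external phylogenetics
tools; externally inferred ML trees are accepted as first-class inputs
wherever a tree is consumed. Ties in Q break on the first row-major
minimal pair, making the topology deterministic. Negative branch lengths
are clamped to zero with the remainder shifted to the sibling edge,
preserving the joined pair's summed length. Supports come from a
nonparametric bootstrap over columns: site patterns are compressed once,
each replicate draws a multinomial reweighting, rebuilds the matrix and
the NJ tree, and each original-tree bipartition is scored by its
replicate frequency × 100. Everything is driven by one named seed,
recorded on the returned tree.

## Synthetic study generator

The generator emulates the emulated study's sampling design: 55 species,
83 samples, 21 multi-individual species (16×2 + 3×3 + 2×4) and 34
singletons, grouped into 13 sections; multi-individual status is spread
over species by a seeded permutation. Defaults for what the design does
not fix were chosen once as a realistic genus-level setting and are
documented here:

* marker lengths 20 000 / 4 000 / 700 bp (plastome-like, nrDNA-like,
  ITS-like; the plastome-like marker is a scaled-down stand-in for a
  ~130 kb alignment, sized so that multi-seed recovery suites run in
  minutes), with per-marker rate multipliers (1, 1, 3) so the short
  nuclear marker is proportionally more variable, as ITS is;
* `interspecific_scale` 0.05 expected substitutions/site per unit tree
  path, `intraspecific_scale` 0.002 expected within-species pairwise
  divergence — a 25× separation, comfortably inside the ≥ 10× default
  regime;
* transition/transversion rate-class ratio 1.5 (κ = 3, typical for
  plastid DNA); base composition uniform with a configurable GC target.

The species tree is a pure-birth (Yule) tree rescaled to unit depth,
with two guards: a floor on inter-event waiting times and a terminal
stem guaranteeing the youngest split sits ≥ 20% of the depth before the
present. The stem is what makes the configured inter/intra scale *ratio*
a realized divergence ratio for every species pair (minimum interspecific
divergence 2 × 0.2 × `interspecific_scale` = 10× the default
intraspecific scale); without it a radiation can place two species
arbitrarily close and no scale ratio separates them. Genuinely
indistinguishable species are modeled explicitly instead, through:

* **capture events** — a sample's sequence on the designated (plastid)
  markers is replaced by a near-copy (intraspecific-scale perturbation)
  of a donor species' haplotype, reproducing chloroplast capture:
  deterministic per (seed, event, marker) and idempotent;
* **ILS pairs** — a fraction of one species' individuals receive an
  exact copy of another species' haplotype, planting a zero-distance
  species pair.

Sequences evolve down the tree under the two-rate (ts/tv) continuous
Markov model whose closed-form transition probabilities match the K2P
estimator's assumptions, so estimator consistency is directly testable:
the expected K2P distance between two samples equals their path length
times the scale. Individuals sit on terminal branches of half the
intraspecific scale.

What the generator does **not** emulate: indels and alignment error
(gaps appear in real data, not in generated data), coalescent gene-tree
heterogeneity (ILS is modeled as haplotype sharing, not as a
multispecies-coalescent process), rate variation across sites, and base
compositional heterogeneity across lineages. Tests passing on this
generator therefore validate the *evaluation machinery* (statistics,
verdicts, bootstrap, planted failure modes), not robustness to
real-data artifacts like misalignment.

## Orchestration

`run_study` evaluates a TOML-configured list of datasets (single or
concatenated FASTAs; tree per dataset either a supplied newick or
"njboot"), writing features, distance reports, tree reports, pairwise
gained/lost comparisons, and a JSON run log carrying the package
version, seed and thresholds, so every printed percentage is auditable.
A failing dataset is recorded and skipped without aborting the others. A
degenerate resolution-vs-zero-K2P regression (no variance in the
predictor, as happens when every dataset is fully resolved) is logged as
a note, not a failure.

## Problem sizes used by the validation suite

The shipped suite and the reproduction script run: 100 random small
alignments (≤ 12 × 300) against brute-force oracles; 50 (suite) / 20
(script) random additive matrices of 5–12 taxa for NJ consistency; the
default 55-species scenario across 20 seeds with 100 bootstrap
replicates for parameter recovery; and single-seed capture/ILS
phenocopy runs. These sizes were chosen so the whole battery completes
in a few minutes on one core while keeping every estimate's Monte-Carlo
error far below the margins being asserted.

## Known limitations

* Bootstrap supports from NJ are not comparable to ML rapid-bootstrap
  values on real data; the package treats any supported tree as input
  and makes no claim of equivalence.
* `zero-K2P` statistics test exact equality with 0, which is the
  definition (shared haplotypes), not a numerical tolerance; distances
  computed from identical sequences are exactly 0 in floating point.
* The hotspot caller requires an annotation track; it does not discover
  region boundaries.
* K2P saturation aborts a matrix rather than degrading silently; for
  saturated datasets use raw differences.
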