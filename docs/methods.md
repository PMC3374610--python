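# Methods

This note records the models, conventions and numerical choices behind
`annocompare`, and what the synthetic-data suite does and does not show.

## Data model

A dataset is an ordered list of annotation records in a fixed 17-column
tab-delimited layout (`peptide_id ... weight`). Records are immutable and
validated on construction: accession patterns (`GO:\d{7}`, `K\d{5}`, dotted
EC numbers with `-` wildcards), weight ≥ 0, BLAST percent-identity and
coverage in [0, 1], peptide ids unique within a dataset. Conventions the
format itself leaves open were fixed as follows:

* **Multi-valued cells.** One entity can carry several GO/EC/KO
  assignments; cells in `go_id` / `ec_id` / `ko_id` join values with `'||'`.
* **Missing values.** `''`, `N/A`, `NA` and the literal token `median`
  (printed by read-based pipelines that summarise per-gene BLAST statistics)
  all map to missing.
* **Weight default.** A missing or absent weight is 1, so unweighted data
  degenerates to counting and both paths share one implementation.
* **Parsing strictness.** Strict by default — silently dropping rows
  corrupts abundance sums. Lenient mode skips invalid rows with a logged
  warning but still refuses misaligned column counts.
* **Filter tags.** Rows tagged in the `filter` column (e.g. `repeat`) are
  kept and exposed as a queryable field rather than dropped at load time.

Pooling concatenates datasets and namespaces peptide ids by their source
library, so pooled total weight is exactly the sum of member totals.

## Hierarchies and rollup

* **Taxonomy.** Pipe-delimited node/name dumps; single root, orphan and
  cycle checks at load. Rollup at a named rank returns the unique ancestor
  at that rank or the reserved `unresolved` bucket when the lineage lacks
  it (including records annotated at a rank coarser than the requested
  one — the alternative, keeping them at their coarser rank, would break
  the partition property). This makes rank rollup a partition of records,
  so weight conservation is exact and testable.
* **Ontology.** OBO files are parsed with `obonet`; only `is_a` edges are
  kept. A term maps to its *minimal* slim ancestors (itself when it is a
  slim term): a slim ancestor is discarded when another slim ancestor of
  the term lies strictly below it. Set semantics per record — a record
  whose GO terms reach the same slim term along several paths contributes
  its weight once.
* **Pathways.** The KO→pathway map is many-to-many and rollup is
  deliberately non-conservative: a KO in *k* pathways contributes its full
  weight to each of the *k* buckets, matching pathway-map semantics.
  Pathway-level relative frequencies may therefore sum past 1.
* **EC classes.** `ec_level` truncates to 1–4 components and pads with `-`
  (`1.2.4.1` at level 2 → `1.2.-.-`).

## Abundance

Absolute frequency of a feature is the sum of weights of records carrying
it after rollup; relative frequency divides by the sum of *all* weights of
the dataset passed in — i.e. the post-filter total when summarising a
filtered dataset (a pre-filter denominator can be passed explicitly).
Records lacking the attribute accumulate in `unassigned`; both reserved
buckets are always computed and can be suppressed at export. Multi-valued
attributes contribute full weight to each distinct value (no splitting),
consistent with pathway semantics. Accumulation follows record order and
export sorts feature keys, so TSV output is reproducible byte for byte.

## Distances, clustering, ordination

Distances are computed on relative-abundance rows by default (heatmaps are
drawn on relative values); absolute mode is a flag.

* Morisita–Horn: `1 − 2Σx_iy_i / ((Σx_i²/X² + Σy_i²/Y²)·X·Y)`. The
  ecological literature carries more than one denominator variant; this
  form is implemented and its range/invariance properties are verified
  (0 on identical, 1 on disjoint profiles, invariance under proportional
  scaling of either profile) rather than claiming numeric equality with
  any particular legacy implementation. It is not a metric (no triangle
  inequality); Bray–Curtis, Jaccard and Euclidean are, and the suite
  checks the axioms accordingly. The denominator is grouped as
  `(da+db)·(X·Y)` so the value is bitwise symmetric in its arguments.
* UPGMA (average linkage) maintains between-cluster means with the
  Lance–Williams update; candidate ties break on the lexicographically
  smallest member labels, so dendrograms and their Newick exports are
  deterministic. Newick branch lengths are parent−child height
  differences; cutting at height *h* severs every merge above *h* (cut at
  or above the root: one cluster; below every merge: singletons).
* Classical (Torgerson) MDS eigendecomposes the double-centred squared
  distance matrix; negative eigenvalues — expected for non-Euclidean
  inputs such as Morisita–Horn — are truncated at zero with a warning,
  and axis signs are fixed by making the first nonzero loading positive.

## Statistical tests

Both tests operate on per-sample relative abundances (each sample
normalised by its own total), since samples of very different depths are
not comparable on raw sums.

* **Wilcoxon rank-sum**: exact null enumeration when the pooled sample
  size is ≤ 12 and tie-free, otherwise the normal approximation with tie
  and continuity corrections (both selectable). Identical pooled values
  give p = 1.
* **Metastats-style permutation test**: Welch *t* per feature;
  permutation p = `(1 + #{|t*| ≥ |t|}) / (B + 1)` (add-one, so p is never
  zero and never below `1/(B+1)`); default B = 10 000. Features whose
  pooled count across both groups is at most 8 (the conventional sparse
  cutoff, configurable) are tested instead with Fisher's exact test on
  the pooled 2×2 table. The 95% CI on the mean difference is
  normal-theory (`diff ± z·SE_Welch`) — a percentile-bootstrap CI would
  be a reasonable alternative; the normal CI was chosen for determinism
  and cost. Within-group sample order is canonicalised (lexicographic row
  sort) before permuting, so p-values depend only on (data, seed, B), not
  on input row order. Zero variance in both groups with equal means gives
  p = 1 and a degenerate CI.
* **Multiplicity**: Bonferroni, `min(1, m·p)` with *m* the number of
  features present in either group after filtering.
* Group summaries report medians of relative abundance as percentages and
  their A/B ratio (∞ when the B median is 0; even-sized groups use the
  mean of the middle two order statistics).

## Synthetic data

The fixture module generates everything the tests need: the exact
100-entry dynamic-weighting example; ranked taxonomies with a designated
chordate-analog subtree ("Chordatoid", taxon 31) so host-removal filters
are exercisable; a 12-term ontology with a 3-term slim (including a
two-slim-parent term and a diamond); a many-to-many KO→pathway map; and
habitat-structured dataset families from a Dirichlet-multinomial model:

* each habitat has a centroid composition over KO features (Dirichlet
  draw, with a `sparsity` fraction of features zeroed per habitat) and a
  tenfold phylum emphasis in its taxon profile;
* each sample draws its composition from `Dirichlet(concentration ×
  centroid)` and allocates records multinomially; record weights are
  log-normal (μ = 0, σ = 0.5); a `host_fraction` of records (default 5%)
  come from the chordate-analog subtree with no functional annotation;
* `concentration = inf` is a zero-noise mode (deterministic
  largest-remainder allocation, unit weights) in which same-habitat
  samples are exact replicas.

Two regimes serve two kinds of study. *Clustering* fixtures use
independent habitat centroids (concentration 50 — per-feature share CV
around 60%), so habitats differ everywhere and dendrogram/ordination
recovery is the question. *Differential-abundance* fixtures use
`shared_centroid=True`: all groups share one baseline composition and
differ only by planted fold-changes, so false positives are measurable. A
planted effect can pin its pre-fold baseline share (otherwise the share is
whatever the centroid draw produced, which can be arbitrarily small and
makes "a 2-fold shift" ill-defined). The power fixture used in the
acceptance suite plants a 2-fold shift on a 5%-share feature in a
20-vs-20 design at concentration 200 (within-group CV of the share ≈ 30%,
a moderate-dispersion setting at which this design has essentially full
power after Bonferroni correction).

What the generator does **not** emulate: read-level simulation, real
pipeline weighting (weights are drawn, not derived from alignments),
phylogenetic correlation between features, compositional coupling between
taxonomy and function beyond the shared per-record draw, or the scale of
real surveys (hundreds of samples, millions of records). Green tests
therefore demonstrate correctness of the computations and recovery under
the stated generative model, not performance on real microbiome data.

## Problem sizes in the test suite

The suite runs at desk scale by design: dataset families of 4–40 samples ×
120–300 records; 1000 random query/dataset pairs for the query-engine
oracle; UPGMA cross-checked against a naive reference on matrices up to
n = 7 and against an independent library implementation; null calibration
with 2000 features in a 20-vs-20 design at B = 1000 permutations. The full
suite completes in well under a minute.

## Known limitations

* Query language: no range queries, fuzzy matching, boosts or relevance
  scoring; `com_name` matching is case-insensitive substring, which may be
  broader than tokenised full-text search.
* Ontology handling is `is_a`-only; merged/deleted taxonomy nodes are not
  resolved.
* Only average linkage is provided (the clustering used throughout the
  intended workflows); no FDR control (Bonferroni only); two-group tests
  only.
* The in-memory store is the database: no persistence layer beyond the
  TSV round-trip.
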