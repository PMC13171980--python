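# Methods

## Scope and data model

`studymatcher` operates on MGnify-style inputs: wide tab-separated
abundance tables (taxon lineage or GO term rows, one integer-count column
per Run/Assembly ID), an OBO 1.2 ontology, and a study catalog mapping
each study to its samples and text metadata. Internally everything is a
long-format sparse count table (`CountTable`; zero cells are never
stored, so "fraction of samples containing a term" is plain record
presence), an acyclic child→parent term hierarchy (`OntologyDAG`, is_a
edges only — whether other edge types such as part_of should participate
in count propagation is genuinely unsettled, and is_a is the conservative
choice), and fixed-axis relative-abundance matrices (`ProfileMatrix`,
each sample vector sums to 1 within 1e-9).

Linked abstracts shared by 16 or more studies are blanked at catalog
load: such texts are resource boilerplate, not study-specific signal, and
would bias text-based relatedness. Applying the rule once at load keeps a
single source of truth for every downstream consumer.

## Profile pipelines

**Taxonomic.** Lineages are truncated at the genus rank (the `g__` token;
records without one are dropped — they cannot be attributed), counts
summed per (genus, sample), then two quality filters: records with fewer
than `min_reads = 30` reads are removed (sequencing noise, index bleed
operate per record, hence the per-(genus, sample) scope), and samples
with fewer than `min_genera = 10` distinct genera are excluded (failed
libraries). Both thresholds are strict ("fewer than"), so boundary values
survive. Order is fixed: aggregate → count filter → richness filter →
normalize; filtering species-level rows before aggregation would
double-penalize genera split across many species.

**Functional.** Raw term counts are propagated to every distinct
ancestor with set semantics — in a diamond, a leaf's reads reach the
shared ancestor once, not once per path. Frequencies are computed on the
backtracked table (propagation precedes filtering in the workflow).
Local frequency = fraction of the sample's backtracked reads on the
term; global frequency = fraction of samples containing the term. Terms
with global frequency strictly above `global_max = 0.75` are removed
everywhere (generic functions); remaining records with local frequency
strictly below `local_min = 0.01` are removed from that sample only (the
definition is per-sample, so the filter is too). TF-IDF ranks survivors:
TF is the mean local frequency over samples where the term is present
(the per-sample definition needs an aggregation rule; the mean is the
least structure-committing choice), IDF is the natural log of total
samples over samples containing the term (the base only rescales scores
and leaves the rank order, which is all pruning consumes, unchanged).
Ties are broken lexicographically by term id so runs are reproducible.
Greedy pruning scans the ranking and keeps a term iff it is
hierarchically unrelated (neither descendant nor ancestor) to every
already-kept term; the resulting curated set is an antichain — it never
contains a nested pair — which is the property the whole step exists to
deliver. Counts restricted to the curated set are renormalized per
sample; a sample retaining no curated term is dropped with a warning,
not an error.

A `threshold_grid_report` utility tabulates, for candidate
(global, local) threshold pairs, how many terms die as generic vs
uninformative and what remains — the accounting a threshold choice is
based on. No automatic threshold selection is attempted.

## Similarity metrics

Cosine similarity (in [0, 1] for nonnegative abundances), Euclidean
distance, and Jensen–Shannon divergence with log base 2 so its range is
[0, 1] bits (needed for a common 0–1 similarity axis). All-vs-all
matrices compute the n(n−1)/2 unique pairs vectorized (scikit-learn for
cosine, scipy `cdist` otherwise; the base-e Jensen–Shannon distance is
squared and divided by ln 2), are symmetrized exactly, and carry their
orientation. Distances convert to similarities only for ranking-free
consumers (aggregation, plotting): JSD d ↦ 1−d, Euclidean d ↦ 1/(1+d),
both strictly monotone. Retrieval ranking always uses the native metric
orientation, so no result depends on the transform. Degenerate inputs
raise: zero-norm vectors (cosine undefined), non-normalized inputs to
JSD, samples with zero totals.

## Noise-injection robustness benchmark

One ratio r ∈ (0, 1] controls both the affected fraction and the depth
factor: ⌊r × subset⌋ seeded-uniformly chosen samples are resampled from
Multinomial(round(r × depth), p = original relative abundances); the
rest are copied unchanged. Only affected samples serve as queries
(unaffected copies would self-match trivially); candidates are all
originals of the evaluation subset. Rank = 1 + number of candidates
scoring strictly better than the true original — the optimistic
information-retrieval tie convention — and a query is a top-k hit iff
rank ≤ k. All metrics see the same noisy realization per ratio, so
differences are attributable to the metrics.

The synthetic conditions for this benchmark
(`retrieval_benchmark_config`) use 30 studies × 7 samples (210 samples,
filling the 200-sample evaluation subset), 150 genera, within-study
Dirichlet concentration 5000 and sequencing depth 1500. The rationale:
retrieval is only informative when nearest neighbors sit at distances
comparable to the injected noise (tight replicates), and the mechanism
that separates metrics — norm distortion of sparse, shallowly resampled
count vectors, which cosine normalizes away and Euclidean does not —
requires a feature-rich axis at shallow depth. The paired count filter
is 3 reads, preserving the default pipeline's relative detection limit
(30/20,000 = 0.15%) at this depth. At the default deep-sequencing
conditions every metric retrieves perfectly and the benchmark shows
nothing.

## Study-level aggregation

For studies X and Y: X→Y is the mean over samples of X of their maximum
similarity to any sample of Y; the study score is max(X→Y, Y→X). Both
directional means are retained as provenance — their asymmetry flags
partial overlap. Aggregation refuses distance-oriented matrices ("maximum
similarity" inverts silently for distances; convert first). Catalog
samples missing from the matrix are dropped from their study with a
warning; studies losing all samples are excluded. The within-study
diagonal is the X→X value (1 for cosine).

## Text relatedness

The prompt embeds a fixed core question with four category definitions
(high / medium / low / no) followed by both studies' title, description,
biome lineage and surviving abstract, and requests a JSON response with
`explanation` and `relatedness` fields. The surrounding instruction text
is this package's own wording. Parsing is tolerant of prose around the
JSON object; the prompt's label "no" normalizes to the analysis category
"none"; anything else outside the four labels is a parse error carrying
the raw text. Each pair is evaluated exactly three times; the modal
category wins, and a 1/1/1 split falls back to the ordinal median on
none < low < medium < high (three runs over four categories can split,
and the median respects the ordinal scale; the applied rule is recorded
per verdict). A backend call failing twice records an error verdict
rather than aborting the batch.

The backend contract is a pure `prompt text → response text` callable.
The shipped `MockBiomeBackend` is deterministic: it reads the two biome
lineages out of the prompt and maps shared lineage depth below the root
(≥3 / 2 / 1 / 0) to high / medium / low / no — the same correspondence
the category definitions describe. A real model server is an optional
adapter and never a test dependency; sampling controls pass through
opaquely.

## Statistics

Kruskal–Wallis (scipy, tie-corrected) over the four category
distributions per similarity type and run; then, per type and run, three
two-sided Mann–Whitney U tests comparing each of high / medium / low
against the pooled other two. "None" is excluded from the post-hoc
tests: it is far larger than the other categories and would dominate any
pool. Sidedness is a design choice (two-sided, the non-committal
default); scipy's exact method is used for small tie-free samples and
the tie-corrected normal approximation otherwise. The resulting 18 raw
p-values (3 categories × 3 runs × 2 similarity types) are
Benjamini–Hochberg-adjusted jointly as one family (statsmodels
step-up; the per-type 9-test family is the plausible alternative — the
joint family is the more conservative reading). The violin export is a
long (pair, category, similarity, type) table with per-category
n/median/quartiles; biome stratification keeps pairs where both studies'
colon-delimited lineage starts with the given prefix. Plot rendering is
a thin seaborn layer over the exported table; the tested surface is the
table.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
dataset:

* **Biomes on a lineage tree.** Up to eight template lineages
  (host-associated / environmental / engineered branches, three levels
  below the root). The genus axis is partitioned into disjoint
  contiguous blocks, one per lineage-tree node; a biome's base
  composition is a weighted sum of the block compositions along its path
  (weights 0.20 / 0.25 / 0.25 / 0.30 from root to leaf). Genus sharing
  between biomes is therefore exactly their shared lineage, so
  compositional similarity is graded by lineage distance by
  construction, and every level's signal is strong enough to survive the
  default frequency filters. `cross_biome_overlap` (default 0.15) mixes
  the cosmopolitan root block into every biome; at 1.0 all biomes
  collapse onto one composition.
* **Studies and samples.** A study composition is
  Dirichlet(3c × base); each sample is Multinomial(depth,
  Dirichlet(c × study)) with c = `dirichlet_concentration` (default 60)
  and depth = `sequencing_depth` (default 20,000 reads) — the same
  multinomial family the noise benchmark uses, so benchmark noise is
  statistically commensurate with biological variation. Sample totals
  equal the depth exactly. A fifth of genera are emitted as two
  species-level lineage rows to exercise genus aggregation.
* **Functional redundancy.** One global genus→term loading matrix sends
  30% of every genus's functional output to a shared housekeeping core
  of leaf terms and the rest to a window of the leaf-term axis that
  slides with the genus index. Distinct taxa thus load onto overlapping
  term sets, and cross-biome functional similarity exceeds cross-biome
  taxonomic similarity on raw profiles by construction. Functional
  counts are an independent multinomial draw at the same depth.
* **Ontology.** A shallow rooted hierarchy (root, broad branches,
  narrow branches, leaves in contiguous runs, ~10% of terms with a
  second parent) — enough structure for set-semantics backtracking and
  antichain pruning to be non-trivial.
* **Texts.** Titles/descriptions/abstracts are templated from a
  per-lineage-token keyword vocabulary: same-biome studies share their
  whole vocabulary, unrelated branches share no domain keyword. Filler
  phrases come from a neutral study-design pool.
* **Ground truth.** Pair relatedness is the shared lineage depth below
  root mapped to none/low/medium/high — the same map the mock backend
  applies, which is what makes end-to-end recovery testable.

What the generator does **not** emulate: sequencing error, chimeras,
primer/extraction/platform bias, uneven real-world depths, the long
rare-taxon tail beyond the allocated blocks, inter-study metadata
quality variation, and real language. Passing tests therefore show the
pipeline's logic is correct and its statistical behavior is as designed
under a controlled generative model; they do not certify performance on
real MGnify data or with a real language model.

Default sizes (6 biomes × 2 studies × 5 samples; 60 genera; 48 GO
terms) keep a full run in seconds on one CPU while leaving all four
relatedness categories populated (6 / 8 / 16 / 36 pairs). At this pair
count the Kruskal–Wallis tests are decisively significant, but some
one-vs-rest post-hoc tests are not after correction — a power
limitation of desk scale, not a property of the method.

## Numerical and reproducibility choices

* Profile sum tolerance 1e-9; similarity-matrix symmetry enforced
  exactly by averaging with the transpose; matrix symmetry validated at
  1e-12.
* `round(ratio × total)` uses Python banker's rounding; a downsample
  whose new total is 0 returns the all-zero vector and the sample drops
  out of profile space (flagged, not fatal).
* The pipeline splits per-stage seeds from one master seed via a fixed
  BLAKE2 derivation (all seeds < 2³¹), so stages re-run independently
  yet reproducibly; identical config + seed reproduces every artifact
  byte for byte (manifest checksums verify this).
* Backtracking is an exploded merge over precomputed ancestor sets;
  ancestor/descendant sets are cached per ontology instance.

## Limitations

Nearest-neighbor aggregation can overestimate relatedness when only a
small sample subset matches; the retained directional means are the
diagnostic. The local-frequency threshold couples to sequencing depth
through the backtracked denominator — at depths far from the default,
the 1% cut changes meaning. LSU and SSU tables are processed as separate
datasets end to end and never merged. The framework is a prioritization
tool: conflicting semantic and compositional signals are observations to
inspect, not errors to suppress.
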