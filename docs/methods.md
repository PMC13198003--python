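# Methods

## Model

`phdms` treats a multi-resolution clustering sweep as a filtered graph and
reads tissue structure off its 0-dimensional persistent homology.

**Input.** A spot set *X* (N spots with 2-D coordinates in the tissue's
units) and K ≥ 2 partitions of *X*, ordered fine → coarse. The package
never looks at expression values or embeddings; the partitions are the
interface, so any upstream spatial-domain method can be used. A thin
adapter (`cluster_sweep`) is provided for the common case of Leiden
community detection on a kNN graph of a per-spot embedding, with a default
schedule of 8 uniformly spaced resolutions from 0.95 down to 0.15 and a
single seed shared across scales.

**Filtration.** One vertex per cluster per scale, entering at value 0.
For each pair of clusters at *consecutive* scales with non-empty
intersection, an edge weighted by the containment dissimilarity
(1 − |A∩B|/|A|, A the finer cluster) or the Jaccard dissimilarity
(1 − |A∩B|/|A∪B|). Containment is the default and suits largely nested
sweeps; Jaccard is selectable for tissues without nested anatomy (tumors).
Weights are ratios of integer counts; IEEE division of equal rationals is
exact, so ties are exact and no epsilon is used in comparisons.

Zero-overlap pairs (weight exactly 1) are not materialized. An edge at the
terminal filtration value cannot change any death below it, and components
alive at the end get lifetime 1 by convention either way, so the
sparsification is semantics-preserving; it also makes the edge count
O(spots·K) instead of quadratic in clusters. Spots reachable only through
such a pair would receive coreness 1 − 1 = 0, which is exactly what the
absent edge yields.

**Persistence.** Edges are processed in increasing weight, ties broken by
the deterministic key (source scale, source label, target label). All
vertices are born at 0, so the classical elder rule is ambiguous; the class
containing the smallest (scale, label) key survives each merge. The dying
class is snapshotted *immediately before* death: its member clusters are
those merged strictly earlier, and its internal edges are those with both
endpoints inside and weight strictly below the death value. After death a
feature no longer exists; snapshotting at death keeps coreness consistent
with the component's lifetime. Survivors get death = ∞, lifetime 1, and
keep all their internal edges. Weight-0 merges produce zero-persistence
points; they are kept in the diagram (they are needed for the
component-count identity used in testing) but excluded from default domain
reporting, since they carry no cross-scale information.

**Coreness.** For component *D*, a spot's raw coreness is one minus the
smallest weight among *D*'s internal edges whose endpoint-union contains
the spot, and 0 for uncovered spots. Normalisation is min–max over the
support only: taking the min over all of *X* would pin it at 0 for every
domain smaller than the tissue and the rescaling would never act. A
constant field normalises to 1. Singleton components (no internal edge)
get coreness 1 on their lone cluster — the vanishing-overlap limit — so
every reported component remains plottable; the default `min_clusters = 2`
hides them unless requested.

**Heterogeneity.** h(x) = Σ p_i · c̄_{D_i}(x) over the reported domains,
with lifetimes clamped to 1. Low where a spot sits in one stable domain
(plus its ancestors), high where it is claimed by many persistent domains.

**Ranking.** Domains are ranked by lifetime × support size (descending,
ties to the lower component id), defaulting to the top 25. Weighting by
size keeps tiny immortal outliers from crowding out structurally important
domains. The product form is this package's choice of size weighting.

## Evaluation metrics

**Spatial 2-Wasserstein.** A multiscale domain is converted to a
probability distribution by normalising c̄ to unit sum; a binary domain
gets the uniform distribution on its members. W₂ is the square root of the
minimal expected squared Euclidean cost over couplings, solved *exactly* as
a transportation LP with the HiGHS solver on the distributions' supports
(one redundant marginal constraint dropped). No entropic regularisation is
used, so reported distances are exact in coordinate units; supports larger
than `subsample_threshold` (default 5,000 spots) are uniformly subsampled
with a seeded generator first. `match_to_truth` scans candidates in
decreasing support-overlap order and stops at an exact match (W₂ = 0 is
unbeatable); this changes running time, never the result.

**Generalized NMI.** Columns are domains, entries normalised coreness.
Rows are normalised to sum to 1; spots with an all-zero row in either
matrix carry no membership information and are dropped from both, with N
set to the retained count (binary partitions have no zero rows, so the
classical arithmetic-mean NMI is recovered exactly — verified against an
independent implementation to 1e−10). Natural logarithms throughout with
0·ln(·) = 0; a degenerate pair whose mean entropy is 0 returns 0 with a
warning. Subset selection is greedy forward search; exhaustive search is
exponential and the greedy result is guaranteed at least as good as any
single domain. Because dropped rows shrink N, an addition that leaves the
NMI unchanged is still accepted when it covers new spots; without this the
search can stop before covering the tissue even when perfect candidates
remain.

**Best single scale.** For baselines, the sweep scale whose cluster count
is nearest the number of annotated domains, ties to the finer scale.

## Synthetic tissues

`generate_hierarchy` plants a nested seeded-Voronoi hierarchy on a square
grid with unit spacing (default 32×32, 2 levels, branching 2): level 1
splits the grid into `branching` domains, each deeper level splits every
parent into up to `branching` children inside it, so refinement is strict.
Voronoi cells give irregular, varied domain shapes rather than rings or
rectangles. The frontier mask flags spots within one grid step
(8-neighbourhood) of a differing label at any level.

`degrade_to_clusterings` observes each level at `scales_per_level`
consecutive scales (default 2, so K = 4 with the defaults) with
pseudo-resolutions on the standard 0.95 → 0.15 grid. At every scale,
independently, each frontier spot flips to a uniformly chosen spatially
adjacent domain of that level with probability ρ (default 0.05); interior
spots never flip. Noise is redrawn per scale, so two observations of the
same level differ at the frontier — the mechanism that produces
sub-maximal frontier coreness. At ρ = 0 the sequence is perfectly nested:
every materialized containment weight is exactly 0, Jaccard child→parent
weights equal 1 − |child|/|parent|, and every planted domain is the
support of some persistent component (finite deaths land exactly on those
size ratios).

**What the generator does not emulate.** Real sweeps change cluster count
gradually rather than in level jumps; real label noise is spatially
correlated and not confined to a fixed frontier band; there is no
expression noise, dropout, or segmentation error, and domains are
contiguous by construction. Passing the recovery tests therefore shows the
pipeline's correctness on its own model of multiscale structure, not
performance on real tissue.

A caveat worth knowing: with duplicated scales and small ρ, the raw
coreness inside large components is nearly constant (differences of order
of the duplicate-edge weights), so min–max normalisation amplifies that
small spread. The frontier-vs-interior heterogeneity contrast is
consequently noisy at ρ = 0.1 for a single fixed hierarchy and is assessed
as a mean over independently drawn simulations (hierarchy and noise both
seeded per replicate); it is clearly positive in expectation and grows with
ρ.

## Numerical and design choices

- Deterministic total orders everywhere (edge tie key, elder key, component
  ids in death order, ranking tie-break) make repeated runs byte-identical.
- Problem sizes in tests and in the acceptance script: random persistence
  graphs ≤ 30 nodes / 60 edges (where brute-force component counting is an
  exact oracle), Wasserstein triples on 10-point supports, planted grids of
  32² spots with 10 replicates per noise level.
- Label codes are arbitrary: partitions are re-encoded to dense integers in
  first-appearance order on input, and all overlap computation buckets
  spots by (finer, coarser) label pair — labels are never compared across
  scales.
- Scale ordering: column order is authoritative (fine → coarse); a
  non-monotone cluster count only warns, since real sweeps can be
  non-monotone.
- Degenerate inputs: empty finer cluster (containment) and two empty sets
  (Jaccard) are errors; empty coreness support is an error; an
  all-zero-row NMI pair returns 0 with a warning.

## Limitations

- Only 0-dimensional homology: merge structure, not loops or voids.
- Coreness is cluster-granular — all spots of a cluster covered by the same
  minimal edge share a value.
- The exact OT solve is O((n·m) LP) and is meant for desk-scale supports;
  very large tissues rely on the seeded subsampling.
- Greedy subset selection has no global-optimality guarantee.
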