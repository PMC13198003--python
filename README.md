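# phdms — persistent multiscale spatial domains

Spatial-transcriptomics segmentation methods (GraphST, SCAN-IT, Banksy,
SpaGCN, BayesSpace, …) partition a tissue into disjoint spatial domains at a
user-chosen resolution. Tissue organisation is not single-scale: a cortex
contains layers, layers contain subfields, and tumor frontiers mix malignant
and healthy cells. Practitioners sweep the resolution parameter and reconcile
the partitions by eye.

`phdms` makes that reconciliation systematic. It consumes an ordered
sequence of clusterings of one spot set (fine → coarse) and applies
0-dimensional persistent homology to a cluster-overlap filtration,
producing **multiscale domains** — groups of clusters that keep reappearing
across scales — together with a per-spot **coreness** score (stable core vs
unstable frontier) and a per-spot **heterogeneity** score (how many
persistent domains claim each spot). It is clustering-method agnostic: any
upstream pipeline that yields labels at several resolutions can feed it.

## Method

Index the *j*-th cluster at scale *k_i* as *C_{i,j}*. Every cluster becomes
a vertex (filtration value 0); clusters at consecutive scales that share
spots are joined by an edge weighted by either the containment
dissimilarity

&nbsp;&nbsp;&nbsp;&nbsp;*f_C* = 1 − |C_{i,j} ∩ C_{i+1,l}| / |C_{i,j}|

(for largely nested sweeps) or the Jaccard dissimilarity

&nbsp;&nbsp;&nbsp;&nbsp;*f_J* = 1 − |C_{i,j} ∩ C_{i+1,l}| / |C_{i,j} ∪ C_{i+1,l}|

(for arbitrary sweeps). Adding edges in increasing weight order and tracking
connected components with a union-find structure yields a persistence
diagram; each component *D* with lifetime *p* (death − birth, clamped to 1
for components that never die) is a multiscale domain. A spot *x* covered by
an internal edge of *D* has coreness

&nbsp;&nbsp;&nbsp;&nbsp;*c_D*(x) = 1 − min { f([C_{i,j}, C_{i+1,l}]) : x ∈ C_{i,j} ∪ C_{i+1,l} },

min–max normalised over the domain's support to *c̄_D*; the heterogeneity
score is h(x) = Σ_i p_i · c̄_{D_i}(x). Two evaluation metrics for soft,
overlapping domains are included: an exact spatial 2-Wasserstein distance
between coreness distributions (in coordinate units, e.g. microns) and a
generalized NMI that reduces to classical arithmetic-mean NMI on binary
partitions.

## Worked example

Plant a two-level nested tissue on a 32×32 grid (two coarse Voronoi domains,
each split in two), observe each level at two scales with 5 % frontier label
noise, and fit:

```python
from phdms import MultiscaleDomainModel, generate_hierarchy, degrade_to_clusterings

h = generate_hierarchy(grid_side=32, n_levels=2, branching=2, seed=0)
seq = degrade_to_clusterings(h, scales_per_level=2, rho=0.05, seed=0)
results = MultiscaleDomainModel(seq, index_kind="jaccard").fit(min_clusters=1)
print(results.summary())
```

```
Multiscale spatial domains (0-D persistence on a cluster filtration)
====================================================================
spots: 1024   scales: 4 (clusters per scale: [4, 4, 2, 2])
filtration: 12 cluster nodes, 21 overlap edges (jaccard index)
diagram: 12 points, 1 immortal components
reported domains: 12 (min_lifetime=0.0, min_clusters=1)

  id    death  lifetime  clusters  support     score
------------------------------------------------------
  11      inf    1.0000        12     1024    1024.0
  10   0.9942    0.9942         6      879     873.9
   6   0.2277    0.2277         2      876     199.5
   9   0.7774    0.7774         2      198     153.9
   7   0.4052    0.4052         2      154      62.4
   8   0.6225    0.6225         2       59      36.7
   ...
```

The immortal component (id 11) is the whole tissue; domain 10 (lifetime
0.994) is one planted coarse domain, which the noise almost never bridges to
the other; domains 9, 7, 8 are planted fine domains, whose deaths equal the
child/parent size ratio at which they merge into their parent. Benchmarking
against the planted coarse annotation:

```python
subset, nmi = results.select_best_subset(h.truth_annotation(0))
# best subset vs coarse truth: domains [0, 8], NMI = 0.984
```

and at zero noise every planted domain is recovered exactly
(per-truth-domain 2-Wasserstein distance 0.0).

The same pipeline runs from the shell on delimited tables
(`spot_id,x,y` plus a label matrix with one column per scale):

```bash
phdms simulate --grid-side 32 --rho 0.05 --output-dir sim/
phdms run --spots sim/spots.csv --labels sim/labels.csv --index-kind jaccard --output-dir out/
phdms metrics --spots sim/spots.csv --labels sim/labels.csv --truth sim/truth.csv --index-kind jaccard
phdms at --spots sim/spots.csv --labels sim/labels.csv --x 10 --y 20
```

`out/` then holds `diagram.csv`, `coreness.csv`, `heterogeneity.csv`, one
coreness map per reported domain, and the persistence diagram image.

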