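# screscale

Integration of single-cell RNA-seq datasets across platforms by
**composition-aware per-gene re-scaling**.

## The problem

Cell atlases profile tissues on several scRNA-seq platforms — plate-based
full-length chemistry (deep read counts) and droplet-based chemistry
(shallow UMI counts).  Standard preprocessing scales every gene to unit
variance within each dataset.  A gene's variance, however, depends on the
dataset's cell-type composition: for a two-type mixture with proportions
`p, 1−p` and type-mean separation `δ`, the between-type component is
`p(1−p)·δ²`.  Two datasets containing the same types in different
proportions therefore divide the same gene by different standard
deviations, and after scaling, cells of the same type disagree across
datasets — naive concatenation puts them in separate clusters.

This package corrects exactly that distortion, for analysts integrating
cross-platform or cross-tissue scRNA-seq data who want an integrated
**expression matrix** (not just a latent embedding) with each dataset's
internal structure untouched.

## The method

For two datasets (the larger one is the *anchor*):

1. log-normalize (`ln(1 + X_ij/libsize_j · 10⁴)`), scale each gene to unit
   sample variance, select highly variable genes shared by both datasets;
2. cluster each dataset on its PC scores (SNN graph, Jaccard weights,
   modularity communities);
3. align anchor clusters to query clusters in a joint PC space: accept the
   nearest of the five closest query clusters `b` satisfying
   `‖Z̄_a − Z̄_b‖² < Q₀.₇₅(‖Z_{b,i} − Z̄_b‖²)`; clusters left unaligned are
   retried after subsampling the over-represented side to the matched
   proportion `n′ = ⌊p(N−n)/(1−p)⌋` and re-scaling on a scratch copy;
4. subsample the aligned clusters so both datasets contain the same types
   in the same proportions, compute per-gene standard deviations
   `s_j = sd(Y_ij)` on each subset, and divide each **full** dataset by its
   own factors;
5. concatenate.  Clustering resolutions are chosen by grid search over
   `[0.1, 2]²`, minimizing the mixing metric; if re-scaling never beats
   direct concatenation, the baseline is returned — which is why datasets
   with no shared cell types are never forced to mix.

The toolkit also provides kNN label transfer with per-cell match scores,
sequential integration of three or more datasets, the four standard
integration metrics (mixing, local structure, ASW, ARI), and a synthetic
multi-platform data generator.  See `docs/methods.md` for assumptions,
parameter meanings and limitations.

## Worked example

Two synthetic datasets share two cell types, but one is 50/50 and the other
80/20, with a 3× sequencing-depth difference:

```python
import numpy as np
import screscale as sc

cfg = sc.scenario("skewed_composition", n_cells=(600, 600), seed=0)
datasets, truth = sc.simulate_pair(cfg)
run = sc.RunConfig(resolution_step=0.3, seed=0)
result = sc.integrate_pair(datasets[0], datasets[1], run)

print(f"baseline used: {result.baseline_used}")
print(f"chosen resolutions (anchor, query): {result.chosen_resolutions}")
print(f"aligned cluster pairs: {result.alignment.pairs}")
print(f"mixing metric (re-scaled): {result.mixing_score:.2f}")
ratio = result.factors.s_anchor / result.factors.s_query
print(f"median factor ratio s_anchor/s_query: {np.median(ratio):.3f}")
```

prints

```
baseline used: False
chosen resolutions (anchor, query): (1.6, 1.9)
aligned cluster pairs: [(0, 1), (1, 5), (2, 0), (3, 3)]
mixing metric (re-scaled): 11.05
median factor ratio s_anchor/s_query: 0.996
```

Every anchor cluster aligned to a query cluster and re-scaling was kept
(`baseline used: False`).  The mixing metric of the integrated embedding is
11.05 — essentially the ≈10 a perfectly interleaved pair of equal batches
scores, and far below the 16.74 of naive concatenation of the same data.
The median per-gene factor ratio of 0.996 says the two datasets needed no
global correction — the correction is concentrated in the
composition-distorted genes.  Clustering the integrated embedding recovers
the two ground-truth types exactly (adjusted Rand index 1.0).

The same pipeline is available from the shell:

```bash
screscale simulate --scenario skewed_composition --out sim/ --seed 0
screscale integrate sim/plate sim/droplet --out run/ --coarse --seed 0
screscale evaluate --bundle run/ --annotations sim/truth.csv --out metrics.json
screscale transfer --bundle run/ --annotations sim/plate_annotations.csv --out labels.csv
```

`integrate` accepts 10x-style MTX directories or dense CSV/TSV matrices and
writes the integrated matrix, per-cell metadata, PC scores, a JSON run
report (alignment table, factors summary, full search trace) and a
provenance record.

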