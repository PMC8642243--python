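# cytoref

Design and interpret flow-cytometry experiments against single-cell
proteo-genomic reference atlases.

Single-cell assays that co-measure transcriptomes and surface proteins
(antibody-derived tags, ADTs) yield richly annotated cell atlases, but
routine work — sorting, screening, diagnostics — still runs on
conventional cytometers measuring a dozen markers. `cytoref` bridges the
two: it projects cytometry events onto an annotated atlas, derives and
scores gating schemes directly from atlas data, and tests for cell-type
abundance changes between donor groups. It is aimed at computational
immunologists and cytometrists who have (or simulate) an annotated
cells × antibody reference and want to exploit it from Python.

## What it computes

**Nearest rank neighbors (NRN) projection.** ADT counts and fluorescence
intensities live on incomparable scales, but their per-marker rank
orderings are comparable. For each shared marker, expression is mapped to
[0, 1] by ranks — (rank − 1)/(n − 1), average ranks on ties — separately
within reference and query. Each event's k = 4 nearest reference cells
under cosine distance, d(a, b) = 1 − a·b/(‖a‖‖b‖), supply a majority-vote
cell-type label and the mean of their 2-D embedding and pseudotime
positions. The mean pairwise Euclidean distance of the neighbors in the
reference's latent factor space is an *inconsistency score*: events whose
neighbors scatter across unrelated states exceed a user threshold and are
flagged. Because ranks are invariant under any strictly increasing
transform, the projection is unaffected by logicle/arcsinh display
transforms or monotone instrument response.

**Automated gating design.** Three scheme families over marker thresholds,
each scored by purity Pr = TP/(TP+FP) and recall Rc = TP/(TP+FN):

* *decision trees* (CART, Gini impurity) on continuous expression or on
  Otsu-binarized indicators, pruned until at most `max_markers` distinct
  markers remain;
* *hypergate-style hyperrectangles*: coordinate ascent over candidate
  min/max bounds at observed values maximizing
  F_β = (1+β²)·Pr·Rc / (β²·Pr + Rc), with per-channel contributions
  (F_β lost when a channel's bounds are removed) used to respect a marker
  budget;
* *expert schemes*: ordered (marker, ±) predicates resolved sequentially,
  with the Otsu threshold recomputed on the retained events at each step,
  mirroring manual gating.

**Otsu thresholding.** Marker positivity is called at the histogram bin
edge maximizing the between-class variance ω₀ω₁(μ₀−μ₁)² (256 equal-width
bins by default, computed per sample); values strictly above the
threshold are "positive".

**Marker statistics.** Plug-in mutual information (nats, equal-count
bins) between pseudotime and expression; log2 fold change between the
first and last 10% of a trajectory; intragate dissimilarity = 1 − mean
pairwise Pearson correlation of within-gate expression profiles.

**Abundance model comparison.** Per-individual target counts k_i out of
gate totals n_i are modelled as Binomial(n_i, q) with Beta(1, 1) priors
under three sharing structures — M0: one q for all; M1: q per group;
M2: q per individual — and compared by the leave-one-out log predictive
density. Conjugacy makes each held-out predictive an exact
beta-binomial, so elpd_loo = Σᵢ ln p(kᵢ | data₋ᵢ) is computed
analytically; LOO-IC = −2·elpd_loo.

A seeded synthetic-data module (`cytoref.simulate`) generates branching
trajectory atlases with negative-binomial ADT counts, distorted
cytometry queries and grouped binomial abundance tables, so the whole
toolkit runs with no external data.

## Worked example

```python
import numpy as np
import cytoref as cr

config = cr.default_config()          # 6 populations, 3 branches, 20 markers
in_atlas = ["Erythroid", "Blymph", "Tcell", "NK"]

atlas, _ = cr.generate_reference(config, seed=1, include_types=in_atlas)
query, labels = cr.generate_query(config, 2000, seed=2, include_types=in_atlas)

result = cr.project(query, atlas, k=4, inconsistency_threshold=8.0)
print(np.mean(result.transferred_label == labels))   # 0.998
print(np.median(result.inconsistency))               # 0.562

absent, _ = cr.generate_query(config, 500, seed=3, include_types=["Myeloid"])
print(np.median(cr.project(absent, atlas, k=4).inconsistency))  # 2.375
```

The query is measured through an asinh instrument distortion plus noise,
yet 99.8% of events receive their true generating label — rank
normalization removes the distortion entirely. Events simulated from a
population *absent* from the atlas have a four-fold higher median
inconsistency (2.375 vs 0.562): their four nearest reference cells come
from unrelated states far apart in latent space, which is exactly what
the score is designed to flag.

The `examples/` directory holds one short script per capability
(thresholding, trajectory statistics, projection, gating design,
abundance testing); each prints its numbers with a note on what they
mean. A `cytoref` command-line tool exposes the same steps
(`simulate`, `threshold`, `stats`, `project`, `gate-fit`, `gate-eval`,
`abundance`) for file-based pipelines.

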