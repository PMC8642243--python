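# Methods

This note documents the models and procedures implemented in `cytoref`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Normalization

Antibody-tag (ADT) counts are normalized per cell with a centered
log-ratio transform: out[c, f] = ln(x[c, f] + 1) − mean_f ln(x[c, ·] + 1).
The +1 pseudocount keeps zeros finite; centering across *features within
a cell* absorbs cell-wise capture efficiency and unspecific binding
background, and guarantees every output row has mean exactly zero. Cells
with all-zero counts map to zero rows with a warning rather than an
error, since droplet data routinely contains empty rows and downstream
rank-based steps handle them gracefully. Gene counts use standard depth
normalization, ln(1 + s·x/total) with s = 10,000.

## Otsu thresholding

Marker positivity is called at the histogram bin edge maximizing the
between-class variance ω₀ω₁(μ₀−μ₁)², with class masses and means taken
from an equal-width histogram over [min, max]. Defaults and choices:

* **Bins**: 256 equal-width bins (configurable). Enough resolution for
  continuous normalized expression while keeping the exhaustive candidate
  set small.
* **Tie-break**: the smallest maximizing edge. Edges preceded by an empty
  bin induce the same partition as a smaller edge and are excluded from
  the candidate set, so the tie-break is decided by the partition, not by
  floating-point noise between mathematically equal variances.
* **Positivity** is *strictly greater* than the threshold, making the
  all-at-threshold case unambiguous (nobody positive).
* Thresholds are computed per sample by default (background levels differ
  between samples); a pooled mode exists for single-sample data.
* Constant distributions are an error — there is no threshold to find.

## Marker statistics

**Mutual information** between pseudotime and expression uses the
plug-in estimator on a B × B joint histogram of equal-count (quantile)
bins per axis, natural logarithm, B = 8 by default. Quantile bins make
the estimate invariant to monotone transforms of either axis and give
the exact value ln(B) in the deterministic equal-count case. The plug-in
estimator is upward-biased by roughly (B−1)²/(2n) nats; no bias
correction is applied (at the sizes used here, n ≥ 1,000, the bias is
below 0.025 nats) and a warning flags n < 5B. Whether equal-width or
equal-count bins are preferable was an open choice; equal-count was
selected for the transform invariance and the exact deterministic case,
and the bin count is exposed.

**Trajectory log fold change** compares cells in the bottom and top 10%
pseudotime-quantile windows: log2((mean_end + 1)/(mean_start + 1)), with
a pseudocount of 1 on the normalized scale stabilizing near-zero means.
The 10% edge windows are a bias/variance compromise: narrower windows
track the endpoints better but average fewer cells.

**Intragate dissimilarity** is 1 − the mean Pearson correlation over all
unordered pairs of within-gate cells (profiles are the concatenated
normalized features), ranging 0 (identical profiles) to 2 (perfectly
anti-correlated). Cells with constant profiles have undefined
correlations; they are excluded with a warning, and fewer than two valid
cells is an error.

## NRN projection

Given a query of events × markers and a reference atlas sharing ≥ 2
antibody marker names:

1. both matrices are restricted to the shared markers;
2. each marker is rank-normalized *within its own dataset*:
   (rank − 1)/(n − 1) with average ranks on ties, so the minimum maps to
   exactly 0 and the maximum to exactly 1. The mapping is invariant to
   any strictly increasing per-marker transform, which is what makes ADT
   counts and transformed fluorescence comparable; heavy ties at the
   transform floor are handled deterministically by average ranks;
3. each event's k = 4 nearest reference cells by cosine distance are
   found; distance ties at rank k are broken by atlas cell order
   (stable sort) for reproducibility;
4. the transferred label is the neighbors' majority vote, ties broken by
   the nearest neighbor; embedding coordinates are the arithmetic mean of
   the neighbors' rows; pseudotime is averaged over the neighbors with a
   defined value and undefined if none has one;
5. the inconsistency score is the mean pairwise Euclidean distance of
   the neighbors' latent-space rows (a centroid-distance mode is
   available); events with score above the threshold are flagged as not
   kept.

The default threshold of 8 is meaningful only on a particular latent
scaling and is documented as data-dependent; a quantile mode
(`auto_threshold_quantile`) drops the top q% least consistent events
regardless of scale. k = 4 follows the convention of small-neighborhood
label transfer: large enough for a majority vote and a non-trivial
scatter estimate, small enough to respect fine-grained states.

## Gating design

**Decision trees** are CART (Gini impurity, binary axis-aligned splits,
greedy growth) via scikit-learn, with `min_leaf` = 20 events per leaf by
default and cost-complexity pruning. The surface-marker budget is
enforced by raising the complexity penalty along the pruning path until
at most `max_markers` distinct markers remain — simple, deterministic,
and monotone (a smaller budget never uses more markers). The
Otsu-binarized variant thresholds each marker once and fits the tree on the
0/1 indicators; the resulting splits are mapped back to the continuous
thresholds so the scheme applies directly to expression data. Note that
for *fully grown* trees, continuous splits are a superset of the
binarized ones and training purity can only be equal or higher; for
pruned greedy trees this dominance is not guaranteed.

**Hyperrectangles** maximize F_β of purity and recall (β = 1 by
default, weighing both equally). The optimizer is coordinate ascent:
sweep channels in order; for each channel and side (min, then max),
evaluate every candidate bound at an observed value of that channel —
plus the "no bound" candidate, which lets the ascent also *relax* a
bound — against the current bounds on the other channels, and accept the
best strictly improving candidate immediately. Convergence is a full
sweep with no accepted move; every accepted move increases F_β, which is
asserted at run time. Bounds are inclusive (min: ≥, max: ≤) so a bound
placed at an observed value keeps that event. The channel contribution
of a marker is F_β(gate) − F_β(gate with that marker's bounds removed),
computed without re-optimization; under a marker budget the top
contributing channels are retained and the ascent re-runs on that
subset. Contributions are *marginal* quantities: when several channels
exclude the same off-target events, each one's marginal contribution is
small, and aggressive budgets can discard an informative channel in
favor of redundant ones — the budgeted fit is re-optimized, but only
over the retained subset. Equivalence to the original hypergate
implementation's move schedule is not claimed; the ascent contract and
rectangle recovery are the tested surface.

**Expert schemes** apply ordered (marker, ±) predicates sequentially.
The Otsu threshold for each step is recomputed on the events retained so
far — mirroring how a manual gater re-draws each gate within the
previous one — with a fixed-threshold mode available. A retained set
that becomes degenerate for Otsu (fewer than two distinct values) is an
error reporting the step index. Note the two modes genuinely differ:
under recomputation, "A+ then A−" keeps the lower part of the upper
class, whereas under fixed thresholds it is empty.

**Balanced downsampling** (equal per-class sizes, seeded, without
replacement) is provided for tree training so abundant populations do
not dominate the impurity criterion. A CD34 partition helper
(normalized expression > 0.95 by default) mirrors the common practice
of designing progenitor gates inside the sorted CD34⁺ compartment.

## Abundance model comparison

Counts k_i of a target cell type out of gate totals n_i per individual
i, with group labels C(i), are modelled as k_i ~ Binomial(n_i, q) with
Beta(1, 1) priors on q under three sharing structures: M0 (one shared
q), M1 (one q per group), M2 (one q per individual). Models are scored
by the leave-one-out log predictive density. Because the Beta prior is
conjugate, the held-out predictive is an exact beta-binomial:

* M0: p(k_i | data₋ᵢ) = BetaBin(k_i; n_i, 1 + Σ_{j≠i} k_j, 1 + Σ_{j≠i}(n_j − k_j))
* M1: the same with sums over j ≠ i in individual i's group,
* M2: nothing is shared, so the predictive is the prior predictive,
  uniform over 0..n_i, giving elpd_loo = −Σ ln(n_i + 1) exactly.

elpd_loo = Σ lpd_i and LOO-IC = −2·elpd_loo. Computing the criterion
analytically (rather than by importance-sampling posterior draws)
removes all sampling noise from the comparison; the beta-binomial pmf is
evaluated in log-gamma arithmetic for numerical stability. The preferred
model is the elpd argmax with no standard-error gating, but the
pointwise standard error of Δelpd versus M0 is reported so users can
judge the strength of evidence. A group reduced to a single member
during hold-out falls back to the prior predictive with a warning.

## Synthetic data

The generator produces the structures the methods assume, at desk scale,
fully reproducible from an integer seed.

* **Reference atlas**: the default configuration has 3,000 cells, 20
  markers and 6 populations — a stem/progenitor root differentiating
  along erythroid, myeloid and B-lymphoid branches (pseudotime uniform on
  each type's sub-interval, marker means interpolated piecewise-linearly
  between the branch members' means) plus two off-trajectory mature
  populations. ADT counts are negative binomial with mean
  size_factor × profile mean and size (dispersion) 2 — strong
  overdispersion typical of antibody tags — with lognormal cell size
  factors (σ = 0.25). The normalized layer is the CLR transform of those
  counts. The latent space is an analytic population-indicator layout
  (scale 3, Gaussian jitter σ = 0.15) with a pseudotime coordinate; the
  2-D embedding is a deterministic angular-arm layout. Using analytic
  coordinates instead of a learned factor model keeps tests
  deterministic and dependency-free while preserving the property the
  inconsistency score needs: unrelated states are far apart, adjacent
  trajectory states are close.
* **Cytometry query**: events are drawn from the same populations;
  intensity = distortion(mean × lognormal biological noise, CV 0.2) +
  Gaussian measurement noise (σ = 0.05), with a strictly increasing
  per-marker instrument distortion (asinh with cofactor 5 by default;
  affine and power responses available). Biological noise is
  multiplicative to keep the pre-distortion signal positive on the power
  and asinh domains.
* **Abundance tables**: k_i ~ Binomial(n_i, q) with q shared (M0), per
  group (M1: 5% vs 50% across 2 × 4 individuals with n_i = 1,000 by
  default), or per individual drawn from Beta(1, 1) (M2).

What the generator does **not** emulate: RNA/ADT joint factor structure,
doublets, ambient background, batch effects beyond the per-marker
distortion, spillover/compensation artifacts, or non-monotone instrument
response. Passing tests therefore demonstrate correctness of the
algorithms under monotone distortion, overdispersed counts and grouped
binomial sampling — not robustness to those excluded artifacts.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
3,000-cell atlases, 2,000-event queries, 50-cell brute-force kNN oracle
instances, 200 simulation replicates per abundance regime, and a 10⁶-draw
Monte-Carlo check of the analytic leave-one-out densities. All
randomness flows through explicit integer seeds (numpy `default_rng`);
projection, gating and simulation outputs are bit-reproducible under a
fixed seed.

## Known limitations

* The inconsistency threshold default (8) is only meaningful relative to
  the latent scaling of a given atlas; prefer the quantile mode when the
  scaling is unknown.
* Hypergate channel contributions are marginal and can undervalue
  informative channels in the presence of redundancy (see above).
* The plug-in MI estimator is biased upward at small n; compare markers
  at equal n.
* Expert-scheme evaluation recomputes thresholds per step; published
  schemes calibrated with fixed global thresholds should use the
  fixed-threshold mode.
* FCS files are not parsed; queries enter as CSV intensity tables with
  display transforms applied upstream (the rank-based projection is
  invariant to them in any case).
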