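# Methods

`symptomnet` estimates and validates regularized partial-correlation
("symptom") networks from ordinal questionnaire data. This note documents
the statistical model, the conventions and defaults each stage uses, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## Model

Observed construct scores are treated as (discretized) views of a latent
multivariate normal **z** ~ N(0, Σ). The object of inference is the
precision matrix Θ = Σ⁻¹: its off-diagonal zeros encode conditional
independence, and the edge weights of the network are the partial
correlations

    w_ij = −Θ_ij / √(Θ_ii Θ_jj),

the association between nodes i and j controlling for all other nodes.

### Scale scoring

Construct scores are item sums, not means (the positive/negative
perfectionism subscales are conventionally reported on the 20–100 sum
scale, and summation is applied uniformly). Default battery: positive and
negative perfectionism (20 items each, 1–5), cognitive flexibility (20
items, 1–7), rumination (22 items, 1–4), procrastination (16 items; the
instrument's standard 4-point response format is the default and is
configurable in the schema, since forms in circulation differ). No
instrument in the default battery declares reverse-keyed items; the schema
supports them for forms that do. Missing data default to listwise deletion
per construct; person-mean imputation is available. A negative
perfectionism sum ≥ 69 is flagged as indicating negative-perfectionism
tendencies.

### Association matrix

The network nodes are by default the five construct totals (item-level
networks are also supported). The pairwise association method follows a
policy keyed to the data type, because full polychoric maximum likelihood
on sum scores with 50–80 observed categories is numerically fragile:

* both variables integer-coded with ≤ `max_categories` (default 10)
  levels → **polychoric**, two-step: thresholds fixed at marginal
  inverse-normal estimates, then a bounded 1-D likelihood search for ρ on
  [−0.999, 0.999] (tolerance 1e-8). Bivariate-normal rectangle
  probabilities come from an Owen's-T-based CDF (absolute accuracy ~1e-14,
  cross-checked against scipy's solver); cells are floored at 1e-12 in the
  log-likelihood.
* both variables continuous → **Pearson**;
* anything else (notably sum scores) → **Spearman**;
* optionally, all many-category variables can be binned into deciles and
  treated polychorically throughout.

The per-pair method is recorded in a JSON sidecar. If the assembled matrix
is indefinite it is projected to the nearest correlation matrix
(eigenvalue clipping, tolerance 1e-8) and flagged `psd_repaired`.

### Sparse network estimation

The precision matrix maximizes the L1-penalized Gaussian log-likelihood
(diagonal unpenalized) via block coordinate-descent graphical lasso,
warm-started along a descending grid of 100 log-spaced penalties from
λ_max = max|S_ij| down to λ_max/100. λ is selected by the Extended BIC
with γ = 0.5, the de-facto standard in psychometric network analysis; ties
go to the sparser model. Both γ and the grid are configurable, and the
manifest records them as this package's defaults, not as any study's
choice. Convergence: maximum elementwise change in the working covariance
< 1e-4 (configurable), at most 10,000 sweeps; edge weights below 1e-10
after back-transform are stored as exact zeros.

A caveat documented by simulation during development: with the likelihood
evaluated at the penalized estimate, EBIC keeps one or two very weak
spurious edges at large n (the known specificity decay of EBIC-glasso).
Recovery tests therefore assert sensitivity and weight accuracy, not exact
support identity.

### Distances, centrality, paths

The travel cost of an edge is d_ij = 1/|w_ij| (absent edges are infinitely
far; negative edges enter through their absolute value, as is standard in
this literature — sign is preserved only in expected influence and
visualization). Geodesics come from Dijkstra's algorithm.

Conventions, all recorded in the report manifest:

* **closeness** is the inverse of the *summed* geodesic distances (the
  inverse-average convention differs only by the factor p−1, which
  z-scoring removes); disconnected nodes sum over their reachable set, and
  isolated nodes get closeness 0.
* **betweenness** (node and edge) uses integer counts over a single
  selected geodesic per unordered node pair. Ties between equal-length
  geodesics — a measure-zero event for continuous weights but constructible
  in tests — are broken deterministically toward the lexicographically
  smallest node sequence, computed from the smaller-indexed endpoint. A
  pair whose geodesic is its own direct edge contributes 1 to that edge.
  Fractional (Brandes) counting over all geodesics is available as an
  option.
* **z-scores** use the population standard deviation (ddof = 0).

### Stability

* **Edge bootstrap**: B (default 1000) nonparametric resamples of
  participants; the full estimation (correlation → glasso with λ
  re-selected) is re-run per resample. Default intervals are quantiles
  shifted by the bootstrap bias estimate — the bootstrap mean minus the
  sample's *unpenalized* partial correlation, which is the parameter of the
  empirical world the resamples live in. Without that shift the intervals
  inherit the lasso shrinkage and sit systematically below strong edges
  (measured coverage of a true 0.4 edge at n = 2000: ~86% raw percentile
  vs ~95% corrected). The correction applies only to edges selected in at
  least half the resamples; where selection dominates, the raw quantiles
  already carry the relevant uncertainty and shifting a point mass at zero
  would be meaningless. Raw percentile intervals remain available.
* **Case-dropping bootstrap**: drop proportions 0.1–0.7 in steps of 0.1,
  B (default 250) subsamples per proportion without replacement, network
  re-estimated, and each centrality index correlated with its full-sample
  values. Correlations that are undefined (a constant index, e.g.
  betweenness all zero) are recorded as NaN and counted as failures.
* **CS coefficient**: the largest drop proportion such that at every
  proportion up to and including it, at least `confidence` (default 0.95)
  of the correlations are ≥ `cor_threshold` (default 0.7) — the
  established convention behind the "CS above 0.50 preferred, 0.25
  minimum" reading. The cumulative rule prevents non-monotone curves from
  inflating the CS.

### Network comparison test

Two-group permutation test with full re-estimation inside every
permutation. Statistics: absolute global-strength difference, maximum
absolute edge difference (structure), and per-edge absolute differences
with Holm correction (configurable). Designs: independent (pooled labels
reshuffled) and paired (per-participant swap with probability 1/2).
P-values use the add-one rule, so the smallest attainable p is
1/(iterations+1). Permuted samples with a degenerate (constant) variable
are rejected and redrawn, with the count reported. Within the comparison
and bootstrap loops the correlation step is Pearson or Spearman (chosen
automatically: Spearman for integer-coded data); polychoric estimation is
not offered there, both for speed and because sum-score nodes fall under
the Spearman policy anyway.

### Layout and reports

Fruchterman–Reingold with attraction proportional to |w_ij|, repulsion
k²/d with k = √(area/p), 500 iterations, linear cooling, seeded initial
positions, normalized to the unit square. Edges are drawn for every
nonzero weight (no visual cutoff), colored by sign (blue positive, red
negative) with stroke width proportional to |w|. Report bundles are
byte-stable under a fixed master seed: JSON is written sorted, SVG
metadata carries no timestamp and the SVG id hash salt is pinned. Stage
wall times appear on the console logger only; the bundled run log records
stages, seeds and warnings.

## Synthetic data generator

Ground truths are precision matrices with a requested sparsity pattern
(chain, hub, random, custom) and unit diagonal; if a pattern is not
positive definite the diagonal is inflated minimally, and the stored truth
weights are always the exact partial correlations of the final matrix.
Data are multivariate-normal draws from the implied correlation,
discretized through equiprobable thresholds (a skewed-threshold option
exists for robustness checks).

The study-shaped emulator generates n = 207 participants on the 98-item
battery: construct latents from a 5-node truth, items as
loading·latent + √(1−loading²)·noise with a default loading of 0.65
(a typical questionnaire item loading), discretized into each
instrument's category range. Its default truth uses moderate partial
correlations (0.15–0.40): a strong negative-perfectionism/rumination tie,
weaker procrastination links, an all-negative cognitive-flexibility node,
and a weakly attached positive-perfectionism node. These magnitudes are
illustrative — chosen once to qualitatively reproduce the pattern such
batteries report — not estimates from any dataset.

What the emulator does **not** reproduce: item-level residual
correlations (local dependence), skewed response distributions,
differential loadings across items, missingness mechanisms, and sampling
designs. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
their violation.

## Problem sizes used in validation

The validation suite and the acceptance script run at deliberately chosen
reduced sizes: bootstrap B = 250–1000 and permutation counts of 500 with
50–200 replications (a production analysis would use the conventional
10,000 iterations; the implementation accepts any count). Oracle
equivalence checks use exhaustive path enumeration up to p = 6 and 50–100
random instances. At these sizes the measured quantities are: graph-metric
oracle agreement 100%, polychoric recovery of ρ = 0.5 within ±0.05 at
n = 5000, chain-truth edge-weight correlation ≥ 0.99 at n = 2000,
edge-CI coverage ≈ 95%, NCT type-I error ≈ 0.05 and single-edge power
100% — each recomputed, not quoted, by `scripts/acceptance.py` and the
acceptance tests.

## Known limitations

* Polychoric estimation is two-step, not full-information ML, and offers
  no missing-data likelihood; polyserial correlations are out of scope.
* EBIC-glasso's selection behavior at large n (see above) means exact
  support recovery is not guaranteed even asymptotically with γ = 0.5.
* The CS coefficient is reported with its defining threshold/confidence
  parameters; no confidence interval is constructed around it.
* Betweenness on small, near-saturated networks is frequently constant
  (all zeros), making its case-dropping stability undefined; the report
  shows NaN rather than a fabricated correlation.
* The NCT assumes exchangeability under the null; with severely unequal
  group sizes or non-PSD permuted samples, rejected-permutation counts
  should be inspected.
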