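# Methods

## Coordinate model of the tissue

All coordinates are micrometres in a right-handed x–y plane and all
distances are Euclidean. The tissue model has three reference structures:
a basal-membrane polyline (the base of the villi), segmented villus labels
per cell (an input, never recomputed from images), and the per-cell typing
that identifies epithelial cells. The three axes are pure functions of these
inputs:

* **Longitudinal** — the cell is projected onto the basal polyline
  (per-segment orthogonal projection via shapely's `line_locate_point`) and
  reported as the arc-length fraction of the projection point, clipped to
  [0, 1]. Invariant to rigid motions applied jointly to cells and polyline.
* **Crypt–villus (geometric)** — raw value is the distance to the nearest
  point of the basal polyline; z-scored within each villus using the
  *population* standard deviation. Villi with one cell or with s.d. below
  `sd_floor` (default 1e-9) get z = 0 (with a warning) rather than NaN, so
  degenerate villi do not poison downstream screens. A per-sample min–max
  rescale of the z-scores to [0, 1] is provided for display and as the IMAP
  x coordinate. Cells outside any villus (e.g. muscularis) have no
  geometric value and are excluded from villus-relative analyses.
* **Crypt–villus (predicted)** — for samples whose morphology does not
  support the geometric construction. The feature space is a 15-factor
  non-negative matrix factorization (sklearn NMF, `nndsvda` init, fixed
  seed) of the neighbourhood matrix `N[cell, gene]` = summed counts of the
  cell's 10 nearest neighbours, with neighbour candidates restricted to
  epithelial and stromal types so the embedding is insensitive to shifting
  immune composition across infection states; self is excluded from its own
  neighbourhood. The factor→axis map is a pluggable regressor with
  fit/predict semantics; the default is a 10-NN regressor on the factor
  space — deterministic and dependency-light — since downstream stages
  consume only the contract (factors in, smoothed axis out), not any
  particular architecture. Predictions are smoothed by averaging over each
  cell's 150 nearest *spatial* neighbours (including itself; `smoothing_k=1`
  is the identity). Held-out error metrics from a 20 % label split are
  returned with the predictions.
* **Epithelial** — mean distance to the 5 nearest epithelial cells divided
  by the mean distance to the 5 nearest cells of any type, both
  self-excluded. Because the any-type candidate pool contains the epithelial
  pool and both use the same k, the ratio is ≥ 1, with equality when the
  cell's immediate neighbourhood is purely epithelial. The ratio is z-scored
  over the sample and clipped at +3 z-units (the clip aligns the scale
  between the intra-villus and basal regions; only an upper clip is applied
  because the lower tail is the well-behaved epithelial side). Duplicate
  coordinates are handled by flooring the denominator at 1e-12 with a
  warning. For the human-style variant the neighbourhood count (30) is
  exposed as separate knobs for the epithelial-and-stromal pool because
  "30 nearest" is ambiguous between 30 total and 30 each.

k-NN queries throughout use scipy's cKDTree and exclude the query cell
itself; exact distance ties inherit the tree's deterministic ordering, and
nearest-nucleus assignment ties go to the lower-indexed centroid.

## IMAPs

IMAP coordinates are `(crypt_villus_display, asinh(epithelial_clipped / w))`
with width `w = 0.5` z-units. The biexponential family is realized as
asinh because it is the standard invertible choice — linear near 0,
logarithmic in the tails — and the width parameter is the only degree of
freedom that matters at display scale. Whether the x axis uses the z-scored
or display-rescaled crypt–villus value is configurable; display-rescaled is
the default to match figure colouring conventions.

Density fields are Gaussian KDEs with weights normalized to sum to one, so
all-equal weights reproduce the unweighted estimate exactly. Rule-based
bandwidths (Scott's rule by default) go through `scipy.stats.gaussian_kde`;
a *scalar* bandwidth is interpreted as the absolute standard deviation of an
isotropic kernel and evaluated directly, because scipy treats scalars as
covariance multipliers and cannot handle the degenerate weighted clouds
that hand-set-bandwidth toys produce. Gene-weighted IMAPs use raw counts as
weights; signature-weighted IMAPs square the enrichment scores to counter
the bias from the physical density of the scored population.

Gates are simple polygons in IMAP coordinates; membership is
boundary-inclusive (`shapely.covers`) and overlaps resolve by declaration
order. Gate fractions are reported per population over gates plus the
`none` bucket and sum to one.

Signature scores are rank-based: genes are ranked per cell by descending
count with average ranks for ties and truncated at `max_rank` (default
1500); the signature's rank-sum, shifted by its minimum n(n+1)/2, is
normalized by the maximum attainable shifted rank-sum
`n·max_rank − n(n+1)/2`. This maps a signature occupying the top n ranks to
exactly 1 and one entirely beyond `max_rank` to exactly 0, is bounded in
[0, 1], and is monotone in any signature gene's count.

## Screens, trends and group statistics

The gradient screen takes raw counts by default (Spearman is invariant to
per-gene monotone transforms, and rank correlation on raw counts matches
the screen's intent; normalized input is available as an option). Genes
must be detected (count > 0) in at least 5 % of the subset — boundary
inclusive. Spearman uses average ranks; p-values use the large-sample t
approximation; zero-variance genes get an undefined ρ and class `none`.
The |ρ| > 0.05 classification threshold is an arbitrary display convention
retained as the default and exposed as a parameter.

Convolved trends average counts over windows of exactly `window` cells
sorted by axis value, centred where possible and clamped (shifted inward)
at the edges, so `window=1` returns the sorted raw counts and `window=n`
the constant global mean.

Additive-model trends are penalized cubic B-splines: quantile interior
knots (default 8), a second-difference coefficient penalty, and the penalty
weight chosen by generalized cross-validation over a log-spaced grid
(1e-8 … 1e6). The system is solved as an augmented least-squares problem
for conditioning. Linear signals lie (numerically) in the penalty null
space and are reproduced to ~1e-6; constant fits z-scale to an all-zero
curve by a tolerance rule rather than amplifying float noise.

Rank-sum differential expression (for building spatial signatures) uses
Mann–Whitney U on log-normalized counts — per-cell scaling to the median
total count, then log1p — with `method="auto"`, so small tie-free groups
get the exact enumeration p-value and larger groups the tie-corrected
asymptotic one, followed by Benjamini–Hochberg adjustment. Genes are
ordered by the signed standardized statistic so the top-n list reads
"highest in group A first".

Perturbation group comparisons use Welch (unequal-variance) two-sided
t-tests — the robust default when only "two-sample t-test" is specified —
with BH correction within each pairwise comparison and significance tiers
at 0.05/0.01/0.001. The perturbed-cell caller is a pure function of its
five inputs (marker sum on *raw* counts, barcode detection, cluster
membership, contaminant count, dominant channel); cells whose barcode
channels tie are flagged `ambiguous` and never assigned.

## Proximity statistics

The default spatial graph is symmetrized 6-NN — an explicit, reproducible
contract rather than an external package's default neighbourhood; Delaunay
and fixed-radius graphs are available, with degenerate Delaunay inputs
falling back to k-NN with a warning. Interaction scores are raw symmetric
edge tallies by type pair, averaged across replicates. "Normalized score
above 0.1" is interpreted as max-normalization to [0, 1] (the top-fraction-
of-connections reading); row normalization is reserved for heat maps. Both
variants are always emitted. Nearest-type distances are self-excluded;
expression–distance correlations are computed per sample and averaged, with
negative ρ meaning higher expression near the target type. The KS
similarity cut-off D = 0.08 is retained as the default flag threshold.

## The synthetic generator

The generator emulates, in a flat (unrolled) layout, exactly the features
the analyses depend on: a straight basal membrane at y = 0 (the axes are
defined relative to it, so the rolled geometry would only add registration
complexity), a muscularis band below, and a row of half-ellipse villi
(default 10 villi, 300 µm tall, 80 µm wide, 20 µm apart; 160 epithelial +
260 lamina propria + 80 muscularis cells per villus ≈ 5,000 cells per
sample — sizes chosen so per-villus statistics are stable while a full
sample simulates in seconds). Epithelial cells sit exactly on the lining
(true epithelial distance 0), lamina propria cells fill a slightly shrunken
interior, muscularis cells fill the band. Crypts are not modelled as
separate invaginations: the lining reaches y = 0 at the villus edges, so
the crypt region is simply the low crypt–villus band and `crypt_depth`
provides its gating semantics.

True axes are exact functions of placement (no noise): longitudinal = x
over total length, crypt–villus = height over villus height, epithelial
distance = distance to the lining. Counts follow
`Poisson(exp(b0 + b_cv·cv + b_epi·epi + b_long·long))` per gene with
optional cell-type restriction; a negative-binomial option exists for
overdispersion robustness. The default 38-gene panel mirrors the biology it
stands in for: villus-tip and crypt epithelial gradients (Apoa4, Ada vs
Olfm4, Lgr5), CD8 effector/progenitor gradients (Gzmb, Gzma, Itgae vs
Tcf7, Slamf6), chemokines low in the villus (Cxcl9/10), markers
(Cd8a/Cd8b1/Cd3e at baseline log 8, high enough that a true CD8 cell
essentially never fails the marker-sum filter), Muc2 in goblet cells, eight
exactly-null genes, and three silent barcode landing genes (Muc5ac,
Neurog3, Fer1l6).

The perturbation scenario assigns disjoint pools of CD8 T cells to each
sgRNA (default 10 % each), adds `1 + Poisson` landing-gene counts scaled by
the 7- or 8-site barcode, optionally contaminates a fraction of goblet
cells with spurious landing-gene counts (the bleed-over failure mode the
Muc2 filter exists for), and can resample one sgRNA population into the
upper villus band to give gate-enrichment tests a known displacement.
Expression is drawn before that positional shift, so shifted cells'
gradient genes reflect their pre-shift position; tests of the shift use
positions only, which are exact.

What the generator does *not* emulate: segmentation errors, probe chemistry
and optical crowding, cell-shape anisotropy, villus curvature and the
rolled ("Swiss-roll") geometry, batch effects beyond seed-level replicates.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated noise model, not robustness to real-data
segmentation artifacts.

## Determinism and numerics

Every stochastic step takes an explicit seed (numpy `default_rng`); the
pipeline writes all numeric outputs with fixed `%.10g` formatting, so
identical seed and configuration give byte-identical files. QC boundaries
follow the strict-removal reading (n < 8 nuclear, n < 20 or n > 800 total
are removed; 8/20/800 are kept) and the filter is idempotent. Bin-to-cell
aggregation assigns a bin to the mask containing its centre (boundary
inclusive, first mask in declaration order on overlap), conserving counts
for bins in exactly one mask.

## Known limitations

* The geometric crypt–villus axis requires villus labels; without them only
  the predicted variant is available.
* The longitudinal axis assumes the basal polyline is traced in anatomical
  order; for rolled sections the restriction of nearest-neighbour candidates
  to the inner side of the roll is not implemented (flat geometry makes it
  moot here) and is recorded as a caveat for real rolled inputs.
* The GCV grid for the spline penalty is fixed; pathological designs fall
  back to heavy smoothing with a warning rather than failing.
* Interaction scores are raw contact tallies (with normalizations), not
  permutation-based enrichment z-scores, which are deliberately out of
  scope.
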