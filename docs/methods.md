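# Methods

## Model

The package treats an image window as carrying two coupled kinds of
uncertainty.  Gray-level *imprecision* is modeled by a fuzzy c-partition of
the intensities: fuzzy c-means (FCM) minimizes
J_m(U, V) = Σᵢ Σₖ u_ik^m (xᵢ − v_k)² under the row-stochastic constraint
Σₖ u_ik = 1, so every pixel belongs to every intensity cluster with a grade
u_ik ∈ [0, 1].  *Spatial* uncertainty is modeled by indicator kriging:
thresholding the memberships of cluster k at a level α gives a binary
indicator field, and the kriged estimate F̂(u) = Σⱼ wⱼ i(uⱼ) at a pixel is a
non-parametric estimate of the probability that the pixel belongs to the
cluster at that grade, conditional on its K nearest coded neighbors.

The two are combined through the probability calculus of fuzzy events: a
fuzzy event's probability is the expectation of its membership function, and
its entropy with respect to a discrete distribution P = (p₁, …, p_n) is

    H(μ; P) = − Σᵢ μ(xᵢ) pᵢ log₂ pᵢ ,   0·log 0 := 0 .

Here μ is the FCM membership of one cluster and P is the kriged probability
field normalized over the window (pᵢ = F̂ᵢ / Σⱼ F̂ⱼ).  One entropy per
(cluster, α) pair, cluster-major with α ascending, forms the window's
feature vector.  Ordinary kriging gives the PEFI1 variant; universal kriging
with a polynomial drift gives PEFI2, which tolerates a locally varying mean
(non-stationarity) in the indicator field.

## Assumptions

- Images are single-channel with gray levels rescaled to [0, 1]; clustering
  runs on the scalar intensities only, never on pixel coordinates.
- The indicator field is second-order stationary within a window (OK) or
  stationary after removal of a low-degree polynomial trend in the pixel
  coordinates (UK).
- The variogram is isotropic: lags are binned by Euclidean distance
  regardless of direction.
- Within-window estimation is leave-one-out: every pixel of a fully
  observed window is treated as unsampled and predicted from its K nearest
  other pixels.  This makes the feature a descriptor of spatial
  predictability rather than an interpolator.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `c` | 3 (2 for two-phase images) | intensity clusters; roughly the number of gray-level groups present |
| `m` | 2.0 | FCM fuzzifier; >1, larger is fuzzier |
| `alphas` | 0.5, 0.6, 0.7, 0.8, 0.9 | membership level cuts; values above 0.5 code "more possible than not" |
| `k_neighbors` (K) | 5 (7 supported) | kriging neighbors per pixel |
| `n_lags` | 10 | variogram lag bins, width 1 pixel, bin b = ((b−0.5), (b+0.5)] |
| `drift_degree` | 1 | UK drift basis: 0 = {1} (≡ OK), 1 = {1, r, c}, 2 = {1, r, c, r², rc, c²} |
| `window_shape` | 53×60 | scan window; any shape with > K pixels works |
| `tol`, `max_iter` | 1e-5, 300 | FCM stop: max absolute membership change, iteration cap |

FCM initialization is a seeded uniform random membership matrix, row
normalized; the seed is a required argument of every feature call, so
identical inputs and seeds give bitwise-identical features.

## Numerical choices

- **Membership update.** Standard alternating optimization: centers are the
  m-weighted means, memberships the inverse-distance ratios with exponent
  2/(m−1).  A pixel within 1e-15 of a center gets crisp membership (the
  limit of the update); coincident centers raise an error before any
  division.  Clusters are always relabeled so centers ascend, keeping
  feature positions comparable across windows.
- **Variogram evaluation between bins.** No parametric model is fitted.
  Semivariance at arbitrary distance is linearly interpolated between
  populated lag centers, anchored at γ(0) = 0, and held constant beyond the
  last populated lag.  Bins without pairs carry NaN and are skipped.
- **Variogram computation.** Pairs are enumerated by integer (Δrow, Δcol)
  offsets, which visits exactly the set of unordered pixel pairs an
  all-pairs loop would visit but in O(#offsets · #pixels) time.
- **Kriging solves.** One linear solve per *unique neighbor-offset
  pattern*: because the variogram-based OK/UK systems depend on coordinates
  only through differences (the polynomial drift span is translation
  invariant), all pixels sharing a neighbor geometry share their weights.
  A 32×32 window with K = 5 needs ~a dozen solves instead of 1024.  Exactly
  singular or rank-deficient systems fall back to a least-squares
  pseudo-solution; every fallback is counted and logged with the tag
  `singular-kriging`, and window scanning never aborts.
- **Clamping.** Kriging weights can be negative, so estimates are clipped to
  [0, 1].  No cross-α order-relation correction is applied beyond this.
- **Degenerate cuts.** A constant indicator field short-circuits to that
  constant (an all-ones field kriges to 1 because weights sum to 1; an
  all-zeros field yields zero mass and entropy 0 by the 0·log 0 convention).
- **Ties.** Kriging neighbors are the K nearest by Euclidean distance with
  ties broken by row-major scan order; k-NN distance ties follow
  training-set order and vote ties go to the tied class with the nearest
  member; equidistant prototypes resolve to the lowest class index.
- **Prototype covariance.** Mahalanobis matching uses the pooled
  within-class covariance (scatter / (n − Q)) with a ridge of
  1e-6 · trace/d (1e-6 when the scatter vanishes) so the metric stays
  defined on degenerate training sets.
- **Feature tables.** CSVs are written with `%.17g` and read with
  round-trip float parsing, so a written matrix re-reads bit-identically;
  every artifact embeds a hash of the generating configuration and
  mismatched train/test hashes are refused unless overridden.

## Design decisions

- **What the distribution P is.** Turning kriged per-pixel values into the
  distribution entering the entropy is underdetermined; this package
  normalizes F̂ over the window's pixels, treating the window as the sample
  space of the fuzzy event.  Log base 2 is used; any other base rescales
  all features uniformly and cannot change a distance-based decision.
- **Per-window fitting.** Both the FCM partition and the indicator
  variogram are computed from the window being described, not globally, so
  each feature vector is self-contained and windows can be processed
  independently.
- **Window labeling.** For detection-style ground truth, a window
  overlapping a target object at all counts as a positive sample; this
  favors sensitivity, leaving precise localization to a downstream step.
- **Monte-Carlo evaluation.** Stratified 50/50 train/test splits, 10
  seeded repetitions by default; reported metrics are means over splits.

## Synthetic benchmark

Real reference data for this feature family (FIB-SEM organelle scans,
clinical CT) are not redistributable, so the package ships a generator of
labeled textures.  The default benchmark is two `binary-mosaic` classes:
seeded Gaussian noise blurred at correlation scale 1 (fine) or 6 (coarse)
pixels, thresholded at the field median into equal areas of gray levels 0.2
and 0.8, plus additive noise of sd 0.05.  The median split forces the two
classes to share their marginal intensity histogram exactly (up to noise),
so nothing but spatial structure separates them — precisely the signal the
entropy feature is built to capture.  The benchmark uses 40 windows of
32×32 per class, c = 2, α ∈ {0.5, …, 0.9}, K = 5, 10 lags, degree-1 drift
for PEFI2, Euclidean prototype matching and 10 Monte-Carlo splits; these
sizes keep a full run at a few seconds on one CPU.

What passing the benchmark shows — and what it does not: synthetic mosaics
are stationary, noise is iid Gaussian, and class differences are purely in
correlation length.  Real micrographs add illumination gradients,
structured noise, multi-scale texture and boundary effects that the
benchmark does not emulate; results on it validate the machinery, not
field performance.

## Limitations

- Single-channel 2-D images only; 3-D stacks must be processed slice-wise.
- No parametric variogram fit; with very small windows the experimental
  variogram is noisy and the interpolated γ may be rough.
- No order-relation correction across α levels beyond clamping, so kriged
  probabilities are not guaranteed monotone in α pixel-wise.
- FCM converges to a local optimum; with the seeded random initialization
  two runs with different seeds may differ on near-degenerate inputs.
- The entropy features are window-level descriptors; the package does not
  produce per-pixel segmentation maps.
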