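# Methods

This note records the detector's model, its tunable parameters, the
numerical conventions the implementation fixes where the method itself is
silent, what the synthetic data emulate, and the known limitations.

## Detection model

The detector assumes targets that are approximately circular, ring-
textured, and of roughly known size: a "reference" target fills a 45×45 px
patch (ring radius ≈ 15 px), and targets in test images are scaled copies
within 0.5–1.5× of that reference. Both stages share one dense-SIFT
bag-of-words representation; neither stage is rotation-invariant (rings
are rotationally self-similar, so this costs little for this target
class), and brightness robustness comes from gradient-based descriptors
with per-descriptor L2 normalization rather than from photometric
calibration.

Localization is an exemplar-voting generalized Hough scheme: matched
feature pairs (same visual word) vote for the implied target centroid
under each candidate scale, with the vote weighted by the word's
discriminative capability d(k) = α(k)/δ(k). Identification re-represents
each candidate crop globally (LLC codes, max-pooled) and filters it with
a linear SVM. The two stages use the local geometry and the global
appearance of the same training patches, respectively.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| grid_size | 16 px | descriptor grid side; 4×4 subgrids of 4×4 px |
| grid_step | 2 px | dense-lattice spacing; 225 descriptors per 45×45 patch |
| patch_w, patch_h | 45 px | canonical training-patch geometry |
| K | 400 | visual words; K-means on all training-patch descriptors |
| M, N | 50, 200 | query / background training patches |
| scales | 0.5:0.1:1.5 | 11 scale factors searched during voting |
| γ | 0.2 | threshold on the [0,1]-normalized final voting map |
| C (LLC) | 5 | local-base size for candidate encoding |
| SVM C grid | 2⁻⁸…2⁸ | chosen by seeded 5-fold stratified CV, ties → smaller C |
| NMS IoU | 0.5 | overlap above which a lower-vote candidate is dropped |
| NMS containment | 0.8 | intersection/min-area above which a nested candidate is dropped |

## Numerical conventions

* **Gradients**: central differences in the interior, one-sided at image
  borders; zero-magnitude pixels report orientation 0.
* **Orientation binning**: bin centers at 0°, 45°, …, 315°; every
  gradient's magnitude is split linearly between its two nearest centers
  (exact-center gradients land wholly in one bin). Unnormalized descriptor
  mass therefore equals the summed gradient magnitude over the grid.
* **Grid centers**: `origin + (grid_size − 1)//2` per axis, used both for
  descriptor locations and query-patch centroids.
* **Vote rounding**: vote coordinates are rounded half-up per axis;
  votes landing outside the image are discarded (counted in the map's
  `n_discarded`).
* **Scale fusion ties**: per-pixel argmax over scales breaks ties toward
  the smallest scale (deterministic, biases to tighter boxes).
* **d(k) regularization**: d = α/(δ + ε) with ε = 1e−12, so words absent
  from every background patch get a very large but finite weight. The
  voting map then spans many orders of magnitude; all downstream use is
  through the min-max-normalized map, which is invariant to that scale.
* **Candidate corners**: the ceiling/floor corner expressions are
  evaluated after rounding to 9 decimals, so the binary representation of
  scale factors such as 0.7 cannot shift a corner off its exact-rational
  value.
* **LLC**: the sum-to-one constrained least squares over the C nearest
  words (ties in the nearest-word ranking break by index) is solved via
  the shifted covariance system with ridge λ = 1e−6·trace/C; coefficients
  are renormalized to sum exactly 1. Pooled descriptors are L2-normalized,
  following standard LLC practice.
* **SVM**: trained with a deterministic SMO solver; the stored model is
  the explicit (w, b) of the linear decision function, so scoring is a dot
  product and reruns are bit-reproducible.
* **Matching**: boxes use 0-based inclusive corners (area = (Δx+1)(Δy+1)),
  the same α₀ definition serves NMS and evaluation, and detections claim
  ground-truth boxes greedily in descending score, one-to-one.
* **LAMR**: the MR-FPPI curve is read as a step function (miss rate of the
  largest achieved FPPI ≤ each of the nine reference FPPIs; 1.0 left of
  the curve). The nine samples are aggregated by geometric mean with miss
  rates floored at 1e−10; an arithmetic mode is available
  (`log_average_miss_rate(..., mode="arithmetic")`) since the convention
  is not universal.

## Non-maximum suppression

Suppression is greedy in descending vote value and removes a candidate
that either overlaps a kept one with α₀ > 0.5 **or** is contained in /
contains a kept one with intersection over the smaller area > 0.8. The
second criterion is required by the scale search: the same target is
proposed at several scale factors, and two concentric square boxes at
scales s₁ < s₂ have α₀ = (s₁/s₂)², which falls below any reasonable IoU
threshold once the scales differ by more than √2. Containment directly
expresses "these candidates contain the same target" while leaving
genuinely adjacent targets (whose boxes overlap only partially) alone.

## Synthetic scenes

The generator emulates the image regime the detector is designed for, not
a specific microscope:

* **targets** — Gaussian annuli A·exp(−(r−R)²/2σ_r²), radius 8–22 px
  (so the ground-truth box, side 45·R/15 rounded to odd, spans the whole
  0.5–1.5 scale search), amplitude 150 over a baseline of 20;
* **confounders** — filled Gaussian discs, partial arcs (< 180°, hence
  never a closed ring) and clusters of small blobs, at ring-like
  amplitudes, emulating endosome-like background structures;
* **background** — a spatially correlated granular field (Gaussian-
  filtered white noise, correlation length 2.5 px, amplitude 12) emulating
  cytoplasmic autofluorescence, plus additive Gaussian sensor noise
  (σ = 5; an optional signal-dependent term is off by default). The
  granular field matters statistically: on flat backgrounds the
  between-class similarity δ(k) degenerates to zero for most words and
  the d(k) weighting loses meaning, which real cytoplasm never exhibits;
* **training sets** — query patches are the ground-truth crops of planted
  rings resampled to 45×45 (so every query shows a ring at the reference
  radius); background patches combine confounder crops and object-free
  crops whose sizes are drawn from the ring-box side distribution and
  resampled identically, so resampling smoothing cannot become a spurious
  class signature.

What passing on these scenes does **not** show: robustness to uneven
illumination, depth-defocused or overlapping organelles, non-Gaussian
camera noise, or ring shapes far from circular — none of which the
generator produces.

## Problem sizes

The self-contained experiment used by the test suite and by
`scripts/acceptance.py` runs 20 scenes of 320×320 px (8 rings + 8
confounders each, minimum center separation 52 px), trains on the first 4
scenes and tests on 16. Four training scenes contain 32 rings, so the
experiment uses M = 32 query patches with N = 200 background patches; all
other parameters keep their defaults. The scene-size and M choices keep a
full train-plus-detect cycle around half a minute on one CPU while every
stage still operates well inside its intended regime; the generator's
default 512×512 geometry behaves equivalently.

## Known limitations

* The voting map's per-pixel optimal scale is reliable near strong peaks
  but noisy elsewhere; candidate boxes inherit that noise and the
  containment rule in NMS is what keeps duplicate scale proposals in
  check.
* Words with δ(k) = 0 dominate the raw (pre-normalization) voting map by
  many orders of magnitude; this is intentional under the d(k) definition
  but means absolute vote values are not comparable across trained models.
* The SVM sees only centered, correctly scaled training patches; it is
  not trained against off-center or mis-scaled crops, so localization
  errors can propagate to identification.
* Confidence scores are signed SVM margins, monotone for ranking (and
  hence for MR-FPPI sweeps) but not calibrated probabilities.
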