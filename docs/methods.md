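# Methods

This note documents the models, numerical schemes and design choices behind
`cytonuclei`, and states what the synthetic test bed does and does not show.

## Problem setting

Pap-stained cytology slides of pleural effusion show three intensity strata:
dark nuclei, intermediate cytoplasm (and blood cells), and a bright
background. All twelve segmenters exploit this single cue — darkness — and
return a binary nuclei mask. None of them attempts to split touching or
overlapping nuclei; a connected predicted region counts as one nucleus, and
the same convention is applied to the ground truth.

## Synthetic scenes

`synthetic.generate_scene` renders, per nucleus, a rotated ellipse at the
nucleus intensity with a brighter elliptical cytoplasm halo, on a constant
bright background, then adds i.i.d. Gaussian noise and quantizes to uint8.
Defaults (all configurable): 256×256 px, 8 nuclei of which 2 abnormal,
background 220, cytoplasm 180, normal nuclei ≈70, abnormal nuclei ≈50
(±5 jitter each), noise σ = 8, nucleus half-axes 6.5–12 px. Abnormal nuclei
are sampled to have at least 1.5× the scene's mean normal-nucleus area, which
is what the abnormal-detection statistic keys on. Rasterization is center-in:
a pixel belongs to an ellipse iff its center satisfies the ellipse
inequality; the ground-truth label image is written before noise, so the
ground truth is pixel-exact by construction.

Placement is rejection sampling; when overlap is disallowed, cytoplasm
footprints padded by a 10 px clearance must stay disjoint (larger nuclei are
placed first). The clearance guarantees ≥ 28 px between nucleus boundaries,
so the closing radius used in postprocessing cannot merge neighbours. When
overlap is allowed, later nuclei overwrite earlier labels on contested
pixels and the mask is the union.

`standard_degraded_fixture` models the acquisition defects that motivate the
preprocessing stage: stain contrast reduced to 0.3 of nominal, an
uneven-illumination ramp spanning the full dynamic range, 300 single-pixel
dark impulses (debris), and Gaussian noise σ = 8. Two properties are
deliberate: impulse noise is what separates the median filter from linear
filters in PSNR, and the broad-global/narrow-local histogram structure is
what separates tile-wise CLAHE from global equalization in CII — a global
map cannot add contrast to an image whose histogram is already uniform.

What the scenes do **not** emulate: chromatin texture, staining variation
within a nucleus, out-of-focus blur, densely packed or overlapping cell
clusters, and realistic debris morphology. Passing the recovery tests shows
the machinery is implemented correctly and the parameter defaults are
coherent; it does not predict accuracy on clinical images.

## Preprocessing

All images are 2-D float arrays on [0, 255]; every windowed operation uses
reflect padding and outputs are clipped back to [0, 255].

* Grayscale: fixed luminance weights (0.299, 0.587, 0.114).
* Resize: bilinear; the full-scan working resolution is 1052×1052 (a plain
  resize that changes aspect ratio; cropping is not applied).
* Filters (window 3 default): median and mean are the scipy rank/uniform
  filters; Gaussian uses σ = window/6; the Laplacian "filter" sharpens
  (input − Laplacian) so its output is PSNR-comparable; the Wiener filter is
  the locally adaptive form with the noise power estimated as the mean local
  variance.
* Enhancers: global histogram equalization uses the classic 256-bin CDF map
  with cdf-min normalization (occupied extremes map to 0 and 255; constant
  images pass through). Intensity adjustment is a linear stretch saturating
  1% at each tail. CLAHE uses an 8×8 tile grid, 256 bins, clip limit 0.01 of
  the tile pixel count (via scikit-image).
* PSNR returns +inf for identical images (valid limiting case). CII is the
  ratio of mean sliding-3×3 (max−min)/(max+min+1e−6); two zero-contrast
  images give CII = 1 by convention.

## Global thresholding

A threshold t ∈ [0, 254] splits the 256-bin normalized histogram into
classes {0..t} and {t+1..255}; `apply_threshold` marks intensity ≤ t as
foreground. Each criterion is a pure function of (histogram, t); one shared
optimizer evaluates all 255 candidates exhaustively. Ties — including
floating near-ties within 1e−9 relative — break to the smallest t.
Degenerate histograms (< 2 occupied bins, or no admissible split for the
minimum-error criterion) raise instead of returning an arbitrary level.

Isodata is the one iterative selector: t ← (μ_below + μ_above)/2 from the
global mean, stopping when the update moves < 0.5 gray levels; an empty
class's mean is taken as t itself to keep the map total. The continuous
fixed point is rounded to the neighbouring integer with the smaller
midpoint residual; because the midpoint map jumps at occupied bins, the
integer residual can reach ~0.9 gray levels and tests assert < 1.

The fuzzy-entropy criterion uses a distance-to-class-mean membership
μ(g) = 1/(1 + |g − m_class|/C) with C the occupied gray-level range, scored
by the Shannon fuzzy entropy −μlnμ − (1−μ)ln(1−μ); the membership form is
isolated so it can be swapped. The cross-entropy criterion shifts
intensities by +1 for log-domain safety. Adaptive thresholding honours an
even window (12) by anchoring it top-left of the center pixel; the offset
default of 5 gray levels prevents noise-driven foreground in flat
background; a window covering the whole image degenerates to the global
mean rule.

## Clustering

Feature space is 1-D normalized intensity only — the dark/bright dichotomy
is the signal, and deterministic behaviour matters more than spatial
smoothing here (regularization is the postprocessing stage's job).

* k-means (k = 2): Lloyd iterations from fixed percentile initialization
  (25th/75th; evenly spaced for k > 2), convergence at center movement
  < 1e−4 or 300 iterations. Deterministic by design — random initialization
  is a known failure mode and makes tests inexact.
* Fuzzy c-means (c = 2, m = 2): standard alternating updates of the
  memberships and centers minimizing J_m; pixels exactly on a center get
  full membership; defuzzification by maximum membership.
* Mean shift: flat kernel of bandwidth 0.2 on [0, 1] intensity, run over
  the 256-bin weighted histogram rather than per pixel — identical for
  intensity features at 8-bit quantization and orders of magnitude faster.
  Converged positions within bandwidth/2 merge into modes; pixels inherit
  their bin's mode; a single surviving mode yields an empty mask.

The nuclei cluster is always the one with the smallest center/mode.

## Chan–Vese active contour

Level-set gradient descent on the regularized two-phase energy
E = μ·Σ|∇H(φ)| + λ₁ΣH(φ)(I−c₁)² + λ₂Σ(1−H(φ))(I−c₂)², with
H(φ) = (1 + tanh(φ/ε))/2, ε = 1. Defaults: μ = 0.2 (normalized units),
λ₁ = λ₂ = 1, max 500 iterations. φ starts as the signed distance of the
initialization mask — by default the Otsu mask, which is already "close to
the nuclei" — clamped to ±3 in place of reinitialization.

Three numerical choices are load-bearing:

* the tanh Heaviside's exponentially saturating tails keep the
  Heaviside-weighted region means essentially uncontaminated by the far
  field even at the small clamp (an arctan-style regularization decays only
  quadratically: with a small clamp it pollutes the region means, with a
  large clamp its delta freezes the far field);
* c₁, c₂ are recomputed each iteration as the H-weighted means — the exact
  minimizers of E at fixed φ — so the mean update can only lower E;
* the time step (trial dt = 2) is accepted through a backtracking line
  search on E at fixed means, making the recorded energy sequence
  non-increasing by construction.

Stopping follows three conditions: iteration budget, energy change below
tol (1e−8 relative), or a contour that stops moving (max |Δφ| < 1e−4); a
constant image has zero region force everywhere and stops after one
iteration. The small clamp also sets the evolution pace: a pixel k levels
below zero needs ~k/(dt·δ·force) updates to flip, so an undersized
initialization grows over hundreds of iterations — short budgets
undersegment, and Dice increases monotonically with the budget. Foreground
polarity (nuclei = darker region) is resolved after convergence.

## Continuous min cut

The two-label cut is relaxed to u ∈ [0, 1] minimizing
α∫|∇u| + ∫u(I−c_fg)² + (1−u)(I−c_bg)², with region constants from the
deterministic k = 2 intensity clustering (darker = foreground) and the TV
term smoothed as √(|∇u|² + β²), β = 1e−2. The solver is projected gradient
descent from the pointwise nearest-mean indicator with a backtracking line
search (initial trial step = the `step` parameter, default 0.3, admissible
(0.3, 3)); each iteration additionally offers the two constant labelings as
candidate moves. This keeps the primal energy non-increasing at every
accepted move — a tested contract — while still reaching the TV-dominant
limit, where the true minimizer is a constant labeling that small-step
descent alone cannot reach in bounded iterations. Limits behave exactly:
α = 0 returns nearest-mean classification unchanged, and α ≥ 10³ collapses
to a single label. The final mask is u ≥ 0.5.

A primal-dual splitting would converge faster per iteration but its primal
energy is not monotone, which would sacrifice the descent guarantee for
speed that is not needed at these image sizes.

## Postprocessing

Spurious regions (debris, blood cells) are smaller than true nuclei, so the
chain is: drop 8-connected components with area strictly below P, then open
with a disk of radius 5, then close with a disk of radius 12 (opening feeds
into closing). P = 1500 px is defined at the 1052×1052 working resolution
and rescaled by the image-area ratio (≈ 89 px at 256×256) so the filter is
resolution-invariant; the structuring element contains offsets with
i² + j² ≤ R². The strict "< P removed, = P kept" boundary is tested at
1499/1501.

## Evaluation

Pixel metrics follow the standard confusion-count formulas, with explicit
degenerate conventions (precision/recall 0 when their denominator is 0;
vacuously perfect predictions score 1 on the overlap metrics) centralized
in one function so aggregates never contain silent NaNs. Per-image metrics
are macro-averaged per method; detection is pooled: NDR = detected nuclei /
all nuclei across images, where detected means the predicted mask covers
strictly more than τ = 0.6 of the nucleus's pixels, and the abnormal NDR
restricts the pool to abnormal nuclei (NaN when there are none). NDR is
recall-only by design; spurious predicted regions are penalized by the
pixel metrics. CSV reports print Dice in percent; JSON keeps fractions.

## Problem sizes used in tests

Unit and acceptance tests run at 256×256 (scenes) and 128×128 (disk
fixtures) with 8 nuclei per scene; the synthetic recovery check uses 20
seeded scenes per method. These sizes exercise every code path, keep the
area filter well above the speckle scale, and make the whole suite run in a
couple of minutes on one CPU.

## Known limitations

* No overlap splitting: touching nuclei merge into one region (by design;
  watershed/concavity splitting composes downstream).
* Global thresholds assume an at-least-bimodal histogram; on images where
  cytoplasm mass dominates, entropy-family criteria can place the cut
  between cytoplasm and background (visible as low Dice for maximum-entropy
  and minimum-error on some synthetic scenes — and as their lower ranking
  on real data).
* Adaptive thresholding is a local rim detector at these nucleus sizes: its
  window (12) sits inside most nuclei, so interiors are not flagged and its
  Dice is poor. It is included as a comparison baseline, faithfully.
* The CII definition (ratio of mean local Michelson contrast) is one of
  several reasonable choices and is isolated in a single function.
* Chan–Vese's iteration budget trades accuracy for time; the default 500 is
  sized to the 256×256 test scale.
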