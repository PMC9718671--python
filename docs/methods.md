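# Methods

## Model and estimator

A diffraction-limited spot is modeled as an axis-aligned Gaussian
intensity profile. For a radially symmetric profile, the image gradient
at any point aims at the spot center, so in the noise-free limit all
gradient lines intersect in one point. With noise they do not, and the
center is defined as the weighted least-squares point

    p_c = argmin_p  Σ_k w_k d_k(p)²,

where d_k is the Euclidean distance from p to the line through the
dual-grid position p_k with direction ∇I(p_k). Because each d_k² is a
quadratic form, the minimizer solves the normal equations

    [ Σ_k w_k (I − û_k û_kᵀ) ] p_c = Σ_k w_k (I − û_k û_kᵀ) p_k ,

a closed-form n-dimensional solution (n = 2 or 3 here); no iteration or
initialization is involved. The system is declared degenerate when the
smallest eigenvalue of the normal matrix is below 1e-10 times the
largest (all lines near-parallel).

**Gradients.** Gradients are computed per 2ⁿ-pixel cell by separable
convolution: an unnormalized difference (+1, −1) along the derivative
axis and an averaging kernel (1/2, 1/2) along every other axis. The
gradient lives at the cell center, a half-integer "dual grid" position.
A radius-r support patch — (2r+1)ⁿ pixels, mirror-extended at image
borders — yields (2r)ⁿ gradients; the default r = 3 gives a 7×7×7 patch
and 216 gradients in 3D. Any global positive rescaling of the gradients
cancels in the fit; the kernel normalization only fixes testable values.

**Weights.** w_k = |g_k|² by default (computed after anisotropy
scaling). Squared-magnitude weighting suppresses the near-zero gradients
of flat background, and in a Gaussian spot the strong gradients near the
peak flank are also the ones whose directions noise perturbs least.
`uniform` and `magnitude` schemes are available for comparison;
gradients with magnitude < 1e-12 are dropped before normalization.

**Anisotropy.** 3D PSFs are elongated along z. Instead of resampling the
image, point positions are multiplied by the scale vector s = (1, 1, a)
and gradients by s⁻¹; the fit runs in the scaled (isotropic) space and
the center maps back by s⁻¹. The convention: a multiplies axial
coordinates, so a < 1 compresses an elongated PSF to isotropy and
σ_axial = σ_lateral / a (a = 0.5 for σ_z = 2σ_xy). Fitting pre-scaled
inputs with a = 1 and fitting raw inputs with factor a agree to 1e-9
(property-tested), which is exactly why explicit rescaling is
unnecessary. The factor is global per dataset; `estimate_anisotropy`
measures it by fitting free-sigma axis-aligned Gaussians (amplitude,
offset, center, per-axis sigma, bounded away from degenerate values)
around the brightest ≤ 100 DoG seeds and taking the median of
(mean lateral sigma / axial sigma). Fits pinned to a sigma bound are
discarded; fewer than `n_spots_min` (default 10) usable fits is an
error, and the estimate is invariant to global intensity scaling.

## Seeding

Difference of Gaussians, `G(σ_vec) ∗ I − G(k σ_vec) ∗ I` with k = 1.6
(the classic Laplacian-of-Gaussian approximation), σ_vec =
(σ, σ, σ/a) so the axial blob scale matches the lateral one, mirror
boundary handling, and Gaussian kernels truncated at 4σ. Seeds are
strict local maxima over the full 3ⁿ−1 neighborhood with response ≥
threshold; plateaus are not maxima (the 0.5-px redundancy filter catches
any residual duplicates), and seeds sit strictly inside the image
because the full neighborhood must exist. σ and the threshold are the
two parameters a user tunes to the spot size and brightness of their
data; `grid_search` automates the choice on simulated or annotated
scenes.

## RANSAC consensus

Given the gradient field of one seed, two gradients are drawn, their
minimal-model center computed (midpoint of mutual closest approach of
the two lines in scaled space), and gradients with point-to-line
distance d_k < ε count as inliers. Sampling repeats under the standard
adaptive bound N = ⌈log(1−confidence)/log(1−w²)⌉ with w the best inlier
fraction so far (confidence 0.99), capped at `max_iterations` = 1000;
samples are drawn in vectorized batches of 64. The best consensus (most
inliers, ties by smaller mean residual) is refit with the weighted
normal equations, inliers are re-selected once against the refit center,
and the final refit on that set is reported with only the gradients
within ε of it; fewer than `min_inliers` (default 30, roughly one
seventh of the 216 default gradients) yields no spot. ε defaults to
0.5 px in scaled space.

Multi-consensus mode repeats the whole search after removing each
accepted set's inliers from the candidate pool, stopping at the first
failure; this separates spot pairs (~3 px apart) that the seed detector
merged. Mixed gradients between two close spots can occasionally form a
small extra consensus between them — gradient cross-talk is not
modeled — so multi-consensus trades a few ghost detections for the
ability to resolve pairs.

Determinism: every candidate gets its own generator seeded from
(global seed, seed position) via `numpy.random.SeedSequence`. Because
the seed does not involve the block, the detection table is bitwise
identical for every block layout — a deliberately stronger contract than
per-block seeding, under which different layouts traverse candidates in
different orders.

## Block-wise execution

`plan_blocks` tiles the image with half-open interiors [lo, hi) that
cover it exactly once; a block owns the seeds whose integer DoG-maximum
position lies in its interior (decidable before localization, so
sub-pixel shifts cannot double-report). Each block reads its interior
expanded per axis by the DoG kernel radius + 1 (maxima test) + the
support radius, clamped at the image bounds with mirror extension, so
every owned seed sees exactly the pixels a whole-image run would use.
Peak resident pixels per block are bounded by that read region
(asserted with an instrumented lazy reader in the tests). Blocks are
processed sequentially; the computation is embarrassingly parallel
across blocks by construction. Zarr stores are read lazily per block;
TIFFs are loaded whole.

Intensity interpolation and the Gaussian refit do all floating-point
arithmetic in global coordinates (the block enters only through exact
integer index offsets), which is what makes even the measured
intensities bitwise layout-independent.

## Post-processing

* **Redundancy filter:** greedy, priority = (more inliers, higher
  intensity, lexicographically smaller position); keeps a subset with
  all pairwise distances ≥ 0.5 px. Idempotent.
* **Intensity:** n-linear interpolation at the sub-pixel center, or a
  least-squares refit of amplitude A and offset B of a Gaussian with
  center and sigmas fixed (σ, σ, σ/a) over the pixels touched by the
  inlier cells, reporting A + B; a singular refit falls back to
  interpolation with a logged warning. Fixing the center keeps the
  radial-symmetry localization authoritative.
* **Mask filter:** a spot is inside iff the mask pixel at its rounded
  coordinates (nearest integer, half away from zero — consistent with
  pixel-center coordinates) is nonzero; a 2D mask applies to every z.
* Fitted centers farther than r + 0.5 px (per axis) from their seed are
  discarded: a consensus that wanders outside its own support region is
  not a localization of that seed's spot.

## Simulator

`simulate_scene` emulates the photon-counting physics of a spot image:
uniform random positions, brightnesses from a normal distribution
(clamped at 1 photon), expected counts I_pred = baseline + Σ spots
brightness·exp(−Σ_d (x_d−c_d)²/2σ_d²) evaluated at pixel centers,
per-pixel Poisson draws with mean I_pred, plus additive Gaussian read
noise. Pair mode places anchor points uniformly and partners at an exact
separation in a uniformly random direction (both in bounds).

Defaults: 256×256×32 volume, 30 spots, σ_lateral = σ_axial = 1.5 px,
peak brightness 500 ± 100 photons, baseline 10, read noise sd 5 — a
bright, well-sampled smFISH-like regime in which localization is
shot-noise-limited. Ground-truth centers keep a 3 px margin (the default
support radius) from the volume faces: a spot whose peak pixel lies on
a face has no full maxima neighborhood and is undetectable by
construction, and the benchmark is meant to measure the localizer, not
boundary truncation.

Not emulated: real PSF shapes (Airy rings, Gibson–Lanni axial
asymmetry), camera gain/offset maps and clipping, structured background,
spot motion or blinking. Passing benchmarks on these scenes therefore
demonstrates the estimator's geometric accuracy and robustness under
Poisson + Gaussian noise, not performance under optical aberrations or
strong autofluorescence — for real data the background-plane correction
and parameter tuning (σ, threshold, ε) carry that weight.

## Benchmark conventions

Matching is one-to-one, greedy by ascending distance with a 3 px
default radius (an optimal linear-assignment mode exists for sensitivity
checks). F1 = 2TP/(2TP+FP+FN). The "precision" diagnostic is the mean
signed per-dimension offset of matched pairs; `correct_offset` subtracts
it, the standard remedy for coordinate-convention disagreements between
tools. Localization error is the mean Euclidean distance of matched
pairs; in noise sweeps it is only aggregated at levels where F1 ≥ 0.5,
because with a handful of surviving detections the statistic is
selection-biased toward the brightest spots. Noise sweeps use a paired
design: the same Poisson-only base scenes with fresh Gaussian noise per
level, so level-to-level differences reflect the detector's noise
response rather than scene variation. Aggregation across scenes is an
unweighted mean.

## Problem sizes used in tests and the acceptance script

End-to-end checks use the 256×256×32 / 30-spot standard scene (3
seeds), 100-spot scenes for anisotropy estimation, 50 pair scenes at
64×64×32, 50 outlier-robustness trials on rendered single spots, and
5-level noise sweeps with 3 paired scenes per level at 128×128×32 —
sizes at which every statistic in the suite is stable across seeds while
the whole suite runs in about a minute.

## Known limitations

* The dual-grid finite-difference gradient of a Gaussian is slightly
  nonlinear in the offset (a tanh in the offset over 2σ²), leaving a
  noise-free localization bias of up to ~2.5e-3 px at σ = 1.5–2 with
  r = 3 (≤ 1e-3 at σ = 1); negligible against shot noise in practice.
* Axial localization of anisotropic spots is less efficient than the
  isotropic equivalent beyond the σ_z/σ_xy factor itself: at fixed peak
  brightness the axial gradient SNR drops while the cubic support
  truncates the axial tails. On σ_z = 2σ_xy scenes the corrected axial
  error is ~0.03–0.05 px versus ~0.012–0.017 px isotropic (and ~0.6–0.8
  px uncorrected).
* Multi-consensus does not model gradient cross-talk between close
  spots; ghost consensus between a pair is possible (see RANSAC above).
* The anisotropy estimator assumes bright, isolated spots; heavily
  overlapping spots bias the elliptical fits.
* Block-wise processing is sequential in-process; distribution across
  machines is out of scope (the per-block contract is designed for it).
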