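# radsym

Sub-pixel detection of diffraction-limited fluorescent spots in 2D/3D
microscopy images — the kind produced by smFISH, spatial transcriptomics
and spatial genomics experiments, where every mRNA molecule appears as a
PSF-sized blob a few pixels across. `radsym` is for microscopists and
image-analysis pipelines that need accurate spot coordinates (and spot
counts) from such images, including volumes too large to hold in memory.

## Method

A bright, radially symmetric spot has the property that its image
gradients all point at its center. `radsym` localizes each spot as the
least-squares intersection point of gradient lines:

1. **Seeding.** Candidate locations are strict local maxima of a
   difference-of-Gaussians filter, `G(σ)∗I − G(kσ)∗I`, above a threshold.
2. **Gradients.** Around each seed a (2r+1)ⁿ support patch is read
   (default r = 3, a 7×7×7 patch in 3D) and one finite-difference
   gradient is computed per 2ⁿ-pixel cell on the dual grid of
   half-integer positions — (2r)ⁿ = 216 gradients in 3D. An optional
   plane fit to the patch boundary removes non-uniform background.
3. **Consensus (RANSAC).** Two gradients are drawn at random, their
   lines intersected, and the gradients whose lines pass within ε of
   that point are counted. The largest consensus wins, and the center
   is refit on all inliers; spots need at least `min_inliers` (default
   30) supporting gradients, which rejects noise and hot pixels.
   Multi-consensus mode repeats the search on the leftover gradients to
   split spot pairs the seed detector merged.
4. **Center fit.** The center p<sub>c</sub> minimizes
   Σₖ wₖ d(p<sub>c</sub>, line(pₖ, ∇I(pₖ)))² and solves the normal
   equations `[Σ wₖ (I − ûₖûₖᵀ)] p = Σ wₖ (I − ûₖûₖᵀ) pₖ` in closed
   form. Axially elongated PSFs are handled without resampling by
   scaling positions with s = (1, 1, a) and gradients with s⁻¹; the
   global factor a (σ_z = σ_xy / a) can be estimated from the image
   itself via elliptical Gaussian fits around bright spots.
5. **Post-processing.** Detections closer than 0.5 px are de-duplicated,
   intensities are measured by n-linear interpolation (or a Gaussian
   amplitude refit over the inlier pixels), and a binary mask can
   classify spots (e.g. nuclear vs cytoplasmic).

Large chunked volumes (zarr) are processed block-wise: blocks own the
seeds in disjoint half-open interiors and read only a fixed halo around
them. Per-candidate RNG seeds derive from the seed position, so the
detection table is *bitwise identical for every block layout*.

Pixels are point measurements: pixel centers sit at integer coordinates
and the first pixel of the first slice is (0.0, 0.0, 0.0). Detections
are written as CSV with header `x,y,z,t,c,intensity`.

The package also ships the benchmark machinery used to validate it: a
ground-truth simulator (Gaussian PSF → Poisson shot noise → Gaussian
read noise, plus a close-pair mode) and matching/metrics code (F1 score,
per-axis signed offsets, Euclidean localization error, parameter grid
search, noise sweeps).

## Worked example

```python
from radsym import (RunConfig, SimulationParams, detect_spots,
                    match_detections, simulate_scene, spots_to_array)

scene = simulate_scene(SimulationParams(n_spots=30, rng_seed=1))
spots = detect_spots(scene.image, RunConfig(threshold=20.0))
result = match_detections(scene.truth_positions(), spots_to_array(spots), 3.0)
print(result.f1, result.mean_euclidean_error)
```

Running `python examples/01_detect_and_benchmark.py` (the same
computation with reporting) prints:

```
detected 30 spots / 30 simulated
F1 = 1.000  (tp=30 fp=0 fn=0)
mean localization error = 0.0244 px
per-axis offset (x,y,z) = [ 0.0032   0.00218 -0.00039]
```

Every simulated spot was found exactly once (F1 = 1: no false positives
or negatives); matched detections sit 0.024 px from the true centers on
average, and the per-axis mean signed offsets near zero show the
coordinate conventions of detector and simulator agree. The other
scripts in `examples/` demonstrate anisotropy estimation/correction,
close-pair separation by multi-consensus RANSAC, lazy block-wise
processing of a zarr store, and the noise sweep.

A command-line interface wraps the same pipeline:

```sh
radsym simulate --shape 256,256,32 --n-spots 30 --seed 1 \
    --out scene.tif --truth truth.csv
radsym detect scene.tif spots.csv --threshold 20
radsym benchmark --truth truth.csv --detections spots.csv
```

## Documentation

`docs/methods.md` describes the model, the estimator, parameter
defaults, what the simulator does and does not emulate, numerical
conventions, and known limitations.
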