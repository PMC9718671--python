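"""Detect spots in a simulated smFISH-like volume and score the result.

Simulates a 256 x 256 x 32 stack with 30 diffraction-limited spots
(Gaussian PSF, Poisson shot noise, Gaussian read noise), runs the full
detector (DoG seeding -> gradient extraction -> RANSAC -> radial-symmetry
fit), and compares the detections with the ground truth.
"""

import numpy as np

from radsym import (RunConfig, SimulationParams, detect_spots,
                    match_detections, simulate_scene, spots_to_array)

scene = simulate_scene(SimulationParams(n_spots=30, rng_seed=1))
config = RunConfig(threshold=20.0)  # DoG threshold matched to spot brightness
spots = detect_spots(scene.image, config)

result = match_detections(scene.truth_positions(), spots_to_array(spots), 3.0)
print(f"detected {len(spots)} spots / {len(scene.truth)} simulated")
print(f"F1 = {result.f1:.3f}  (tp={result.tp} fp={result.fp} fn={result.fn})")
print(f"mean localization error = {result.mean_euclidean_error:.4f} px")
print(f"per-axis offset (x,y,z) = {np.round(result.per_axis_offset, 5)}")
print("\nfirst three detections (x, y, z, intensity, inliers):")
for s in spots[:3]:
    x, y, z = s.position
    print(f"  {x:8.3f} {y:8.3f} {z:7.3f}   {s.intensity:8.1f}   {s.n_inliers}")

# F1 = 1.0 means every simulated spot was found exactly once; the mean
# error of a few hundredths of a pixel is the sub-pixel localization
# accuracy of the gradient-intersection fit at this noise level.
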