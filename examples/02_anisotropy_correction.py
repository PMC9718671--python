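"""Estimate the axial anisotropy factor and see what correcting it buys.

3D microscopy PSFs are elongated along z.  The detector compensates by
scaling point positions by s = (1, 1, a) and gradients by 1/s inside the
fit — no image resampling.  The factor a can be estimated from the data:
elliptical Gaussian fits around bright spots give a = mean lateral sigma
over axial sigma.
"""

from radsym import (DogParams, RunConfig, SimulationParams, estimate_anisotropy,
                    evaluate_scene, simulate_scene)

# sigma_z = 2 sigma_xy, i.e. true anisotropy factor a = 0.5
scene = simulate_scene(SimulationParams(n_spots=100, sigma_axial=3.0,
                                        rng_seed=2))

a_hat = estimate_anisotropy(scene.image, DogParams(sigma=1.5, threshold=20.0))
print(f"estimated anisotropy factor a = {a_hat:.3f}  (true 0.5)")

for a, label in ((1.0, "uncorrected (a=1.0)"), (round(a_hat, 3), "corrected")):
    res = evaluate_scene(scene, RunConfig(threshold=20.0, anisotropy=a))
    axial = res.matches["dz"].abs().mean()
    print(f"{label:22s} F1 = {res.f1:.3f}   mean |dz| = {axial:.4f} px")

# The uncorrected fit mislocalizes along z by over half a pixel; with the
# data-driven factor the axial error drops to a few hundredths of a pixel.
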