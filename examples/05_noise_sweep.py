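"""How detection accuracy and localization error respond to image noise.

Renders noise-free (Poisson-only) base scenes, adds increasing Gaussian
read noise to the same bases, and runs the detector at each level —
a paired sweep isolating the noise response from scene-to-scene
variation.
"""

from radsym import RunConfig, SimulationParams, noise_sweep

table = noise_sweep(
    noise_levels=[0.0, 25.0, 50.0, 100.0, 200.0],
    scenes_per_level=3,
    base_params=SimulationParams(shape=(128, 128, 32), n_spots=30),
    config=RunConfig(threshold=20.0),
    seed=5,
)
print(table.to_string(index=False))

# F1 stays near 1 until the read noise becomes comparable to the spot
# amplitude, then collapses; the localization error of matched spots
# grows monotonically with the noise level.
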