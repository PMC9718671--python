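import numpy as np
import pandas as pd
import pytest

from radsym.gradients import compute_gradients, extract_patch
from radsym.simulate import SimulationParams, render_expected


def render_spot(center, sigma_lateral=1.5, sigma_axial=None, shape=(33, 33, 33),
                brightness=1000.0, baseline=0.0):
    """Noise-free rendered Gaussian spot (internal axis order)."""
    center = np.asarray(center, dtype=float)
    params = SimulationParams(
        shape=shape, n_spots=1, noise_sd=0.0, baseline=baseline,
        sigma_lateral=sigma_lateral,
        sigma_axial=sigma_axial if sigma_axial is not None else sigma_lateral,
    )
    cols = ["x", "y", "z"][: len(shape)]
    truth = pd.DataFrame([dict(zip(cols, center), brightness=brightness)])
    return render_expected(params, truth)


def spot_gradient_field(center, sigma_lateral=1.5, sigma_axial=None,
                        radius=3, shape=(33, 33, 33), brightness=1000.0):
    """Gradient field of the patch around the peak of a clean rendered spot."""
    img = render_spot(center, sigma_lateral, sigma_axial, shape, brightness)
    peak = np.unravel_index(np.argmax(img), img.shape)
    return compute_gradients(extract_patch(img, peak, radius))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
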