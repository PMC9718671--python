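"""Ground-truth scene simulator for localization benchmarks.

Spot positions are drawn uniformly in the volume, each spot gets a
brightness from a normal distribution, the expected photon count per
pixel is an axis-aligned Gaussian PSF evaluated at the pixel centers,
pixel values are Poisson draws with that mean (shot noise), and
Gaussian read noise is added on top.  A close-pair mode places pairs of
spots at exact separations to probe two-spot resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

TRUTH_COLUMNS = ("x", "y", "z", "brightness")

#: PSF support cutoff when rendering, in units of sigma
RENDER_TRUNCATE = 6.0


@dataclass(frozen=True)
class PairMode:
    """Close-pair layout: for each separation (pixels), place
    ``pairs_per_separation`` pairs at exactly that Euclidean distance."""

    separations: Tuple[float, ...]
    pairs_per_separation: int = 10


@dataclass(frozen=True)
class SimulationParams:
    """Scene parameters.

    shape : image extents (x, y[, z]); 256 x 256 x 32 is the benchmark size
    n_spots : number of spots (ignored in pair mode)
    brightness_mean/sd : normal distribution of spot peak brightness
        (expected photons at the spot center above baseline)
    sigma_lateral/axial : Gaussian PSF extents in pixels
    noise_sd : additive Gaussian (read) noise standard deviation
    baseline : constant background photon rate
    margin : minimum distance of true centers from the volume faces, in
        pixels; keeps the full PSF peak inside the field of view so the
        benchmark measures the localizer rather than boundary clipping
    rng_seed : generator seed; same params + seed give a bit-identical scene
    """

    shape: Tuple[int, ...] = (256, 256, 32)
    n_spots: int = 30
    brightness_mean: float = 500.0
    brightness_sd: float = 100.0
    sigma_lateral: float = 1.5
    sigma_axial: float = 1.5
    noise_sd: float = 5.0
    baseline: float = 10.0
    margin: float = 3.0
    rng_seed: int = 0
    pair_mode: Optional[PairMode] = None

    def __post_init__(self):
        if any(s < 8 for s in self.shape):
            raise ValueError("all extents must be >= 8")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.sigma_lateral <= 0 or self.sigma_axial <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def sigma_vector(self) -> np.ndarray:
        s = np.full(self.ndim, self.sigma_lateral, dtype=float)
        if self.ndim == 3:
            s[2] = self.sigma_axial
        return s


@dataclass
class SimulatedScene:
    """A rendered noisy image plus the ground truth that produced it."""

    image: np.ndarray
    truth: pd.DataFrame
    params: SimulationParams

    def truth_positions(self) -> np.ndarray:
        cols = ["x", "y", "z"][: self.params.ndim]
        return self.truth[cols].to_numpy(dtype=float)


def render_expected(params: SimulationParams, truth: pd.DataFrame) -> np.ndarray:
    """Noise-free expected photon count I_pred.

    baseline + sum over spots of brightness * exp(-sum_d (x_d - c_d)^2 /
    (2 sigma_d^2)), evaluated at pixel centers (integer coordinates).
    """
    shape = params.shape
    n = params.ndim
    sig = params.sigma_vector()
    image = np.full(shape, float(params.baseline))
    cols = ["x", "y", "z"][:n]
    for _, row in truth.iterrows():
        c = np.array([row[col] for col in cols], dtype=float)
        if np.any(c < 0) or np.any(c > np.asarray(shape) - 1):
            raise ValueError(f"truth position {c} outside image bounds")
        lo = np.maximum(np.floor(c - RENDER_TRUNCATE * sig).astype(int), 0)
        hi = np.minimum(np.ceil(c + RENDER_TRUNCATE * sig).astype(int) + 1,
                        shape)
        grids = np.meshgrid(*[np.arange(l, h, dtype=float)
                              for l, h in zip(lo, hi)], indexing="ij")
        expo = sum(((g - c[d]) / sig[d]) ** 2 for d, g in enumerate(grids))
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        image[box] += float(row["brightness"]) * np.exp(-0.5 * expo)
    return image


def _uniform_positions(rng: np.random.Generator, params: SimulationParams,
                       n: int) -> np.ndarray:
    lo = params.margin
    hi = np.asarray(params.shape, dtype=float) - 1 - params.margin
    if np.any(hi <= lo):
        raise ValueError("margin leaves no room for spot positions")
    return rng.uniform(lo, hi, size=(n, params.ndim))


def _pair_positions(rng: np.random.Generator, params: SimulationParams
                    ) -> np.ndarray:
    pm = params.pair_mode
    lo = params.margin
    hi = np.asarray(params.shape, dtype=float) - 1 - params.margin
    rows = []
    for sep in pm.separations:
        for _ in range(pm.pairs_per_separation):
            while True:
                anchor = rng.uniform(lo, hi, size=params.ndim)
                direction = rng.normal(size=params.ndim)
                nrm = np.linalg.norm(direction)
                if nrm < 1e-9:
                    continue
                partner = anchor + sep * direction / nrm
                if np.all(partner >= lo) and np.all(partner <= hi):
                    rows.append(anchor)
                    rows.append(partner)
                    break
    return np.asarray(rows)


def simulate_scene(params: SimulationParams) -> SimulatedScene:
    """Draw a scene: truth table plus Poisson + Gaussian noisy image.

    Brightnesses are clamped at a small positive floor.  Deterministic
    given ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    if params.pair_mode is not None:
        positions = _pair_positions(rng, params)
    else:
        positions = _uniform_positions(rng, params, params.n_spots)
    n = len(positions)
    brightness = np.maximum(
        rng.normal(params.brightness_mean, params.brightness_sd, size=n), 1.0)
    cols = ["x", "y", "z"][: params.ndim]
    truth = pd.DataFrame(positions, columns=cols)
    if params.ndim == 2:
        truth["z"] = 0.0
        truth = truth[["x", "y", "z"]]
    truth["brightness"] = brightness
    expected = render_expected(params, truth)
    image = rng.poisson(expected).astype(np.float64)
    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=image.shape)
    return SimulatedScene(image=image, truth=truth, params=params)


def write_truth(truth: pd.DataFrame, path: str) -> None:
    """Write the ground-truth table as CSV with header x,y,z,brightness."""
    truth.to_csv(path, index=False, float_format="%.6f",
                 columns=list(TRUTH_COLUMNS))


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
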