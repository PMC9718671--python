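"""Difference-of-Gaussians seeding.

Candidate spot locations (seeds) are strict local maxima of the
band-pass response ``G(sigma) * I - G(k * sigma) * I`` above a
user threshold.  ``sigma`` matches the lateral spot extent; the axial
sigma is divided by the anisotropy factor ``a`` so axially elongated
PSFs produce blobs of comparable scale along every axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

GAUSS_TRUNCATE = 4.0  # kernel support in units of sigma


@dataclass(frozen=True)
class DogParams:
    """Parameters of the difference-of-Gaussians seed detector.

    sigma : lateral spot scale in pixels (> 0)
    k : ratio of the second Gaussian's sigma to the first (> 1);
        1.6 is the classic Laplacian-of-Gaussian approximation
    threshold : minimum DoG response at an accepted maximum (>= 0)
    anisotropy : axial scale factor a (> 0); axial sigma = sigma / a
    """

    sigma: float = 1.5
    k: float = 1.6
    threshold: float = 0.007
    anisotropy: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.k <= 1:
            raise ValueError("k must be > 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be > 0")

    def sigma_vector(self, ndim: int) -> np.ndarray:
        """Per-axis sigma ``(sigma, sigma[, sigma / a])``."""
        s = np.full(ndim, self.sigma, dtype=float)
        if ndim == 3:
            s[2] = self.sigma / self.anisotropy
        return s

    def kernel_radii(self, ndim: int) -> np.ndarray:
        """Support radius per axis of the wider (k·sigma) Gaussian."""
        return (GAUSS_TRUNCATE * self.k * self.sigma_vector(ndim) + 0.5).astype(int)


@dataclass(frozen=True)
class Seed:
    """An integer-coordinate candidate location with its DoG response."""

    position: Tuple[int, ...]
    dog_value: float


def dog_filter(data: np.ndarray, params: DogParams) -> np.ndarray:
    """Band-pass filter ``G(sigma)*I - G(k·sigma)*I`` (bright spots positive).

    Boundaries are mirror-extended.  Raises if the kernel of the wider
    Gaussian does not fit inside the image.
    """
    data = np.asarray(data, dtype=np.float64)
    sig = params.sigma_vector(data.ndim)
    radii = params.kernel_radii(data.ndim)
    if np.any(radii > np.asarray(data.shape)):
        raise ValueError(
            f"DoG kernel (radii {tuple(radii)}) exceeds image shape {data.shape}"
        )
    narrow = ndimage.gaussian_filter(data, sig, mode="mirror",
                                     truncate=GAUSS_TRUNCATE)
    wide = ndimage.gaussian_filter(data, params.k * sig, mode="mirror",
                                   truncate=GAUSS_TRUNCATE)
    return narrow - wide


def find_seeds(dog: np.ndarray, threshold: float) -> List[Seed]:
    """Strict local maxima of a DoG response above ``threshold``.

    A maximum must exceed all 3^n - 1 neighbours (plateaus are not
    maxima), so seeds are strictly inside the image.  Returned sorted
    lexicographically by position.
    """
    dog = np.asarray(dog, dtype=np.float64)
    n = dog.ndim
    core = tuple(slice(1, s - 1) for s in dog.shape)
    center = dog[core]
    strict = center >= threshold
    for offset in np.ndindex(*(3,) * n):
        if all(o == 1 for o in offset):
            continue
        nb = dog[tuple(slice(o, o + s - 2) for o, s in zip(offset, dog.shape))]
        strict &= center > nb
        if not strict.any():
            break
    idx = np.argwhere(strict) + 1
    order = np.lexsort(tuple(idx[:, d] for d in reversed(range(n))))
    return [Seed(tuple(int(v) for v in idx[i]), float(dog[tuple(idx[i])]))
            for i in order]


def detect_seeds(data: np.ndarray, params: DogParams) -> List[Seed]:
    """Convenience: DoG filter then threshold local maxima."""
    return find_seeds(dog_filter(data, params), params.threshold)
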