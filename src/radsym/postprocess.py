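"""From accepted centers to final spots.

Covers the redundancy filter (detections at least ``min_separation``
pixels apart), intensity measurement (n-linear interpolation or a
Gaussian amplitude refit over the supporting pixels), binary-mask
classification, and data-driven estimation of the global axial
anisotropy factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, spatial

from .dog import DogParams, detect_seeds
from .gradients import GradientField, extract_patch

logger = logging.getLogger(__name__)


@dataclass
class Spot:
    """A final sub-pixel detection.

    position : sub-pixel coordinates in pixel units, (x, y[, z])
    intensity : measured intensity at the spot
    n_inliers : consensus size (0 when RANSAC is off)
    mean_residual : average point-to-line distance of the inliers
    block_id : id of the block that produced the spot
    seed : the integer DoG seed the spot came from
    """

    position: np.ndarray
    intensity: float = float("nan")
    n_inliers: int = 0
    mean_residual: float = 0.0
    block_id: int = 0
    seed: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


def redundancy_filter(spots: Sequence[Spot], min_separation: float = 0.5
                      ) -> List[Spot]:
    """Keep a subset with all pairwise distances >= ``min_separation``.

    Conflicts are resolved greedily by priority: higher inlier count,
    then higher intensity, then lexicographically smaller position.
    Idempotent.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    if not spots or min_separation == 0:
        return list(spots)

    def priority(s: Spot):
        inten = s.intensity if np.isfinite(s.intensity) else -np.inf
        return (-s.n_inliers, -inten, tuple(s.position))

    order = sorted(range(len(spots)), key=lambda i: priority(spots[i]))
    positions = np.stack([spots[i].position for i in order])
    tree = spatial.cKDTree(positions)
    kept_rank = np.full(len(order), -1, dtype=int)  # rank among kept, -1 = undecided
    kept: List[int] = []
    for rank, row in enumerate(range(len(order))):
        neighbors = tree.query_ball_point(positions[row], min_separation)
        # distances are < min_separation only if strictly closer; equality keeps both
        conflict = any(
            kept_rank[j] >= 0 and j != row
            and np.linalg.norm(positions[j] - positions[row]) < min_separation
            for j in neighbors
        )
        if not conflict:
            kept_rank[row] = rank
            kept.append(order[row])
    return [spots[i] for i in sorted(kept)]


def _interpolate(data: np.ndarray, position: np.ndarray,
                 origin: np.ndarray) -> float:
    """n-linear interpolation at a global position.

    ``origin`` is the integer global coordinate of ``data[0, ...]``.
    All float arithmetic uses global coordinates only, so the result is
    bitwise independent of how the image was cut into blocks.
    """
    pos = np.asarray(position, dtype=float)
    local = pos - origin
    if np.any(local < 0) or np.any(local > np.asarray(data.shape) - 1):
        raise ValueError(f"position {pos} outside data bounds")
    lo = np.floor(pos).astype(int)
    frac = pos - lo  # exact: global-coordinate arithmetic only
    n = data.ndim
    value = 0.0
    for offset in np.ndindex(*(2,) * n):
        idx = np.minimum(lo + offset - origin.astype(int),
                         np.asarray(data.shape) - 1)
        w = 1.0
        for d in range(n):
            w *= frac[d] if offset[d] else 1.0 - frac[d]
        value += w * data[tuple(idx)]
    return float(value)


def _inlier_pixels(positions: np.ndarray, shape) -> np.ndarray:
    """Integer pixels touched by dual-grid cells at half-integer positions."""
    n = positions.shape[1]
    lo = np.floor(positions).astype(int)
    offsets = np.stack(np.meshgrid(*([[0, 1]] * n), indexing="ij"),
                       axis=-1).reshape(-1, n)
    pix = (lo[:, None, :] + offsets[None, :, :]).reshape(-1, n)
    pix = np.unique(pix, axis=0)
    inside = np.all((pix >= 0) & (pix < np.asarray(shape)), axis=1)
    return pix[inside]


def measure_intensity(data: np.ndarray, spot: Spot, mode: str = "interpolate",
                      inliers: Optional[GradientField] = None,
                      sigma: float = 1.5, anisotropy: float = 1.0,
                      origin: Optional[np.ndarray] = None) -> float:
    """Intensity at a spot's sub-pixel position.

    mode="interpolate": n-linear interpolation of the image.
    mode="gauss_refit": least-squares fit of amplitude A and offset B of
    a Gaussian with center fixed at the spot position and per-axis sigma
    fixed at (sigma, sigma, sigma/anisotropy), over the pixels touched
    by the inlier gradient cells; returns the model value A + B at the
    center.  A singular refit falls back to interpolation.

    ``origin`` (integer global coordinate of ``data[0, ...]``, default
    zero) lets block-wise callers pass positions in global coordinates.
    """
    n = data.ndim
    origin = np.zeros(n) if origin is None else np.asarray(origin, dtype=float)
    if mode == "interpolate":
        return _interpolate(data, spot.position, origin)
    if mode != "gauss_refit":
        raise ValueError(f"unknown intensity mode {mode!r}")
    if inliers is None or len(inliers) == 0:
        raise ValueError("gauss_refit requires the inlier gradients")
    pix = _inlier_pixels(inliers.positions - origin, data.shape)
    sig = np.full(n, sigma, dtype=float)
    if n == 3:
        sig[2] = sigma / anisotropy
    delta = (pix + origin - spot.position) / sig
    g = np.exp(-0.5 * np.sum(delta * delta, axis=1))
    design = np.column_stack([g, np.ones(len(g))])
    gram = design.T @ design
    if len(g) < 2 or np.linalg.cond(gram) > 1e12:
        logger.warning("singular Gaussian refit at %s; falling back to "
                       "interpolation", spot.position)
        return _interpolate(data, spot.position, origin)
    coef, *_ = np.linalg.lstsq(design, data[tuple(pix.T)], rcond=None)
    a_amp, b_off = coef
    return float(a_amp + b_off)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.trunc(x + np.copysign(0.5, x)).astype(int)


def mask_filter(spots: Sequence[Spot], mask: np.ndarray
                ) -> Tuple[List[Spot], List[Spot]]:
    """Partition spots by a binary mask (nonzero = inside).

    A spot is inside iff the mask pixel at its rounded coordinates
    (half away from zero) is nonzero.  A 2D mask applies to every z
    slice of a 3D image.
    """
    mask = np.asarray(mask)
    inside: List[Spot] = []
    outside: List[Spot] = []
    for s in spots:
        pos = s.position
        if mask.ndim == 2 and pos.size == 3:
            pos = pos[:2]
        elif mask.ndim != pos.size:
            raise ValueError(
                f"mask of ndim {mask.ndim} cannot classify {pos.size}D spots"
            )
        idx = _round_half_away(pos)
        if np.any(idx < 0) or np.any(idx >= np.asarray(mask.shape)):
            outside.append(s)
            continue
        (inside if mask[tuple(idx)] else outside).append(s)
    return inside, outside


class AnisotropyEstimationError(RuntimeError):
    """Too few usable spots to estimate the anisotropy factor."""


def _fit_elliptical_gaussian(patch: np.ndarray):
    """Free-sigma axis-aligned Gaussian fit; returns per-axis sigmas or None."""
    n = patch.ndim
    side = patch.shape[0]
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in patch.shape],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1)
    vals = patch.ravel()
    b0 = float(np.percentile(vals, 10))
    a0 = float(vals.max() - b0)
    if a0 <= 0:
        return None
    c0 = np.full(n, (side - 1) / 2.0)
    s0 = np.full(n, max(side / 6.0, 1.0))
    p0 = np.concatenate([[a0, b0], c0, s0])

    def model(p):
        amp, off = p[0], p[1]
        c = p[2:2 + n]
        s = p[2 + n:]
        d = (coords - c) / s
        return off + amp * np.exp(-0.5 * np.sum(d * d, axis=1))

    lb = np.concatenate([[0.0, -np.inf], np.zeros(n), np.full(n, 0.2)])
    ub = np.concatenate([[np.inf, np.inf], np.full(n, side - 1.0),
                         np.full(n, side)])
    try:
        res = optimize.least_squares(lambda p: model(p) - vals, p0,
                                     bounds=(lb, ub), max_nfev=200)
    except ValueError:
        return None
    if not res.success and res.cost > 1e-3 * np.sum(vals ** 2):
        return None
    sigmas = res.x[2 + n:]
    # reject fits pinned to a bound (unresolved sigma)
    if np.any(sigmas <= 0.25) or np.any(sigmas >= side - 0.5):
        return None
    return sigmas


def estimate_anisotropy(data: np.ndarray, dog: DogParams,
                        n_spots_min: int = 10, max_spots: int = 100,
                        patch_radius: Optional[int] = None) -> float:
    """Estimate the global axial scale factor a from the image itself.

    Fits an axis-aligned elliptical Gaussian (free per-axis sigmas,
    center, amplitude, offset) around each of the brightest DoG seeds
    and returns the median of (mean lateral sigma / axial sigma).
    a = 1 for isotropic spots, a = 0.5 when sigma_z = 2 sigma_xy.
    Invariant to global intensity scaling.
    """
    if data.ndim != 3:
        raise ValueError("anisotropy estimation requires a 3D image")
    seeds = detect_seeds(data, dog)
    if not seeds:
        raise AnisotropyEstimationError("no seeds found (0 usable spots)")
    seeds = sorted(seeds, key=lambda s: -s.dog_value)[:max_spots]
    if patch_radius is None:
        patch_radius = max(5, int(np.ceil(3 * dog.sigma)))
    ratios = []
    for seed in seeds:
        patch = extract_patch(data, seed.position, patch_radius)
        sigmas = _fit_elliptical_gaussian(patch.values)
        if sigmas is None:
            continue
        ratios.append(float(0.5 * (sigmas[0] + sigmas[1]) / sigmas[2]))
    if len(ratios) < n_spots_min:
        raise AnisotropyEstimationError(
            f"only {len(ratios)} usable spot fits, need {n_spots_min}"
        )
    return float(np.median(ratios))
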