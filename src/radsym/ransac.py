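"""RANSAC consensus over gradient lines.

A spot candidate's gradient field usually contains gradients that do
not belong to the spot (noise, hot pixels, a second nearby spot).
RANSAC repeatedly samples the minimal model — two gradients — computes
their intersection, and counts how many other gradient lines pass
within a distance ``epsilon`` of it.  The largest consensus wins; the
final center is refit on all inliers.  Run iteratively with inlier
removal (multi-consensus), several spots hiding under one seed can be
separated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .gradients import GradientField
from .localize import (
    AnisotropyScale,
    CenterFit,
    DegenerateFitError,
    InsufficientDataError,
    fit_center,
    point_line_distances,
    _scaled_lines,
)

_PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class RansacParams:
    """Consensus parameters.

    epsilon : max point-to-line distance for an inlier, in pixels of
        the anisotropy-scaled space (> 0)
    min_inliers : minimum consensus size to accept a spot (>= 2);
        around 30 rejects random-noise consensus for the default
        radius-3 support region
    max_iterations : cap on sampling rounds
    confidence : target probability of having drawn an all-inlier pair;
        drives the adaptive iteration bound
    multi_consensus : extract several spots per candidate field
    rng_seed : seed of the sampling generator
    """

    epsilon: float = 0.5
    min_inliers: int = 30
    max_iterations: int = 1000
    confidence: float = 0.99
    multi_consensus: bool = False
    rng_seed: int = 0
    weight_scheme: str = "magnitude2"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_inliers < 2:
            raise ValueError("min_inliers must be >= 2")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ConsensusSet:
    """An accepted spot: inlier indices into the gradient field plus the
    center refit on those inliers.  All inliers lie within epsilon of
    the refit center."""

    inliers: np.ndarray
    center: CenterFit


def _two_line_center(p1, u1, p2, u2) -> Optional[np.ndarray]:
    """Midpoint of mutual closest approach of two lines in scaled space.

    Returns None for (numerically) parallel lines.  Equals the
    two-gradient least-squares fit with unit weights.
    """
    b = float(u1 @ u2)
    denom = 1.0 - b * b
    if denom < _PARALLEL_TOL:
        return None
    w0 = p1 - p2
    d = float(u1 @ w0)
    e = float(u2 @ w0)
    t1 = (b * e - d) / denom
    t2 = (e - b * d) / denom
    return 0.5 * (p1 + t1 * u1 + p2 + t2 * u2)


def _adaptive_bound(inlier_fraction: float, confidence: float, cap: int) -> int:
    """Standard RANSAC iteration bound for a 2-sample model."""
    w2 = inlier_fraction * inlier_fraction
    if w2 >= 1.0:
        return 1
    if w2 <= 0.0:
        return cap
    denom = math.log1p(-w2)
    if denom == 0.0:
        return cap
    n = math.ceil(math.log1p(-confidence) / denom)
    return int(min(max(n, 1), cap))


_BATCH = 64


def _consensus_search(pos, units, params: RansacParams,
                      rng: np.random.Generator):
    """Sample minimal 2-gradient models in batches; return the best
    inlier mask (largest consensus, ties by smaller mean residual) or
    None.  Deterministic given the generator state."""
    m = pos.shape[0]
    best_mask = None
    best_count = 0
    best_resid = np.inf
    bound = params.max_iterations
    done = 0
    while done < bound:
        batch = min(_BATCH, bound - done)
        done += batch
        a = rng.integers(0, m, size=batch)
        b = (a + 1 + rng.integers(0, m - 1, size=batch)) % m
        u1, u2 = units[a], units[b]
        p1, p2 = pos[a], pos[b]
        bdot = np.einsum("ij,ij->i", u1, u2)
        denom = 1.0 - bdot * bdot
        valid = denom > _PARALLEL_TOL
        denom = np.where(valid, denom, 1.0)
        w0 = p1 - p2
        dd = np.einsum("ij,ij->i", u1, w0)
        ee = np.einsum("ij,ij->i", u2, w0)
        t1 = (bdot * ee - dd) / denom
        t2 = (ee - bdot * dd) / denom
        centers = 0.5 * (p1 + t1[:, None] * u1 + p2 + t2[:, None] * u2)
        diff = centers[:, None, :] - pos[None, :, :]
        val = np.einsum("bmj,bmj->bm", diff, diff) \
            - np.einsum("bmj,mj->bm", diff, units) ** 2
        dist = np.sqrt(np.clip(val, 0.0, None))
        masks = dist < params.epsilon
        counts = np.where(valid, masks.sum(axis=1), 0)
        with np.errstate(invalid="ignore"):
            resids = np.where(counts > 0,
                              (dist * masks).sum(axis=1) / np.maximum(counts, 1),
                              np.inf)
        for i in range(batch):
            c = int(counts[i])
            if c < 2:
                continue
            r = float(resids[i])
            if c > best_count or (c == best_count and r < best_resid):
                best_mask, best_count, best_resid = masks[i], c, r
        if best_count:
            bound = min(bound, _adaptive_bound(best_count / m,
                                               params.confidence,
                                               params.max_iterations))
    return best_mask


def _refit(field: GradientField, scale: AnisotropyScale, candidate_idx,
           mask, params: RansacParams, pos, units) -> Optional[ConsensusSet]:
    """Refit on the consensus, re-select inliers once, refit again.

    Reported inliers all satisfy d_k < epsilon against the reported
    center; returns None if the final set falls below min_inliers.
    """
    s = scale.vector(field.positions.shape[1])
    try:
        fit1 = fit_center(field.subset(candidate_idx[mask]), scale,
                          weight_scheme=params.weight_scheme)
        d1 = point_line_distances(fit1.center * s, pos, units)
        mask2 = d1 < params.epsilon
        if int(mask2.sum()) < 2:
            return None
        fit2 = fit_center(field.subset(candidate_idx[mask2]), scale,
                          weight_scheme=params.weight_scheme)
    except (DegenerateFitError, InsufficientDataError):
        return None
    d2 = point_line_distances(fit2.center * s, pos, units)
    final_mask = mask2 & (d2 < params.epsilon)
    idx = candidate_idx[final_mask]
    if idx.size < params.min_inliers:
        return None
    fit = CenterFit(center=fit2.center, residuals=d2[final_mask],
                    used_count=int(idx.size))
    return ConsensusSet(inliers=idx, center=fit)


def ransac_single(field: GradientField,
                  scale: AnisotropyScale = AnisotropyScale(),
                  params: RansacParams = RansacParams(),
                  rng: Optional[np.random.Generator] = None
                  ) -> Optional[ConsensusSet]:
    """Find the largest consensus of gradients agreeing on one center.

    Returns None when no consensus of at least ``min_inliers`` exists.
    Deterministic given ``params.rng_seed`` (or an explicit ``rng``).
    """
    if len(field) == 0:
        return None
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    pos, units, _, kept = _scaled_lines(field, scale)
    if pos.shape[0] < max(2, params.min_inliers):
        return None
    mask = _consensus_search(pos, units, params, rng)
    if mask is None or int(mask.sum()) < params.min_inliers:
        return None
    return _refit(field, scale, kept, mask, params, pos, units)


def ransac_multi(field: GradientField,
                 scale: AnisotropyScale = AnisotropyScale(),
                 params: RansacParams = RansacParams(),
                 rng: Optional[np.random.Generator] = None
                 ) -> List[ConsensusSet]:
    """Iterated RANSAC: extract consensus sets until none remains.

    After each accepted set its inliers leave the candidate pool, so
    the returned sets are pairwise disjoint, in acceptance order.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    results: List[ConsensusSet] = []
    remaining = np.arange(len(field))
    while remaining.size >= params.min_inliers:
        sub = field.subset(remaining)
        hit = ransac_single(sub, scale, params, rng=rng)
        if hit is None:
            break
        results.append(ConsensusSet(inliers=remaining[hit.inliers],
                                    center=hit.center))
        keep = np.ones(remaining.size, dtype=bool)
        keep[hit.inliers] = False
        remaining = remaining[keep]
    return results
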