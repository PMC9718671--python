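"""Block-wise detection on (possibly lazy) volumes.

The image is tiled by half-open interior intervals that cover it
exactly once.  Each block owns the seeds whose integer DoG-maximum
position falls in its interior and reads an expanded region around it —
interior plus the DoG kernel support, one pixel for the maxima test and
the gradient-patch radius — so every owned seed is localized on exactly
the pixel values a whole-image run would use.  Per-candidate RANSAC
seeds derive from (global seed, seed position), not from the block, so
the detections are bit-identical for every block layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .dog import dog_filter, find_seeds
from .gradients import compute_gradients, extract_patch, subtract_background
from .io import ImageVolume
from .localize import (DegenerateFitError, InsufficientDataError,
                       fit_center)
from .postprocess import Spot, measure_intensity
from .ransac import ransac_multi, ransac_single

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Block:
    """One tile: half-open interior [lo, hi) in global pixel indices."""

    block_id: int
    lo: Tuple[int, ...]
    hi: Tuple[int, ...]

    def owns(self, position: Sequence[int]) -> bool:
        return all(l <= p < h for p, l, h in zip(position, self.lo, self.hi))


@dataclass(frozen=True)
class BlockGrid:
    """A tiling of the image by disjoint half-open interiors."""

    shape: Tuple[int, ...]
    block_size: Tuple[int, ...]
    blocks: Tuple[Block, ...]

    def __len__(self) -> int:
        return len(self.blocks)


def plan_blocks(shape: Sequence[int], block_size: Sequence[int]) -> BlockGrid:
    """Tile ``shape`` with blocks of at most ``block_size`` per axis.

    Interiors are half-open, disjoint, and cover the image exactly; the
    last block per axis may be smaller.  A block size larger than the
    image yields a single block.
    """
    shape = tuple(int(s) for s in shape)
    block_size = tuple(int(b) for b in block_size[:len(shape)])
    if len(block_size) != len(shape):
        raise ValueError("block_size must give one extent per image axis")
    if any(b < 8 for b in block_size):
        raise ValueError("block sizes must be >= 8 per axis")
    starts = [list(range(0, s, b)) for s, b in zip(shape, block_size)]
    blocks = []
    bid = 0
    for corner in np.ndindex(*[len(s) for s in starts]):
        lo = tuple(starts[d][corner[d]] for d in range(len(shape)))
        hi = tuple(min(l + b, s) for l, b, s in zip(lo, block_size, shape))
        blocks.append(Block(block_id=bid, lo=lo, hi=hi))
        bid += 1
    return BlockGrid(shape=shape, block_size=block_size, blocks=tuple(blocks))


def _read_margin(config: RunConfig, ndim: int) -> np.ndarray:
    """Per-axis halo so in-interior results equal a whole-image run."""
    radii = config.dog_params().kernel_radii(ndim)
    return radii + 1 + config.support_radius


def _read_block(image: ImageVolume, block: Block, margin: np.ndarray):
    """Expanded block with mirror extension beyond the image bounds.

    Returns (values, origin): origin is the global coordinate of
    values[0, 0, 0] (may be negative where mirrored).
    """
    shape = np.asarray(image.shape)
    want_lo = np.asarray(block.lo) - margin
    want_hi = np.asarray(block.hi) + margin
    lo = np.maximum(want_lo, 0)
    hi = np.minimum(want_hi, shape)
    values = image.region(lo, hi)
    pad = list(zip(lo - want_lo, want_hi - hi))
    if any(p != (0, 0) for p in pad):
        values = np.pad(values, pad, mode="reflect")
    return values, want_lo


def candidate_rng(global_seed: int, position: Sequence[int]) -> np.random.Generator:
    """Deterministic generator for one candidate, independent of blocks."""
    ss = np.random.SeedSequence((int(global_seed),) + tuple(int(p) for p in position))
    return np.random.default_rng(ss)


def _localize_candidate(values: np.ndarray, origin: np.ndarray,
                        seed_pos: Tuple[int, ...], dog_value: float,
                        config: RunConfig, block_id: int) -> List[Spot]:
    """Run gradients -> (RANSAC ->) radial-symmetry fit for one seed."""
    local = tuple(int(p - o) for p, o in zip(seed_pos, origin))
    patch = extract_patch(values, local, config.support_radius)
    patch = subtract_background(patch, config.background)
    field = compute_gradients(patch)
    # patch coordinates are block-local; shift dual-grid positions to global
    field.positions = field.positions + np.asarray(origin, dtype=float)
    scale = config.scale()
    spots: List[Spot] = []
    if config.ransac == "off":
        try:
            fit = fit_center(field, scale, weight_scheme=config.weight_scheme)
        except (DegenerateFitError, InsufficientDataError):
            return []
        hits = [(fit, None)]
    else:
        rng = candidate_rng(config.seed, seed_pos)
        params = config.ransac_params()
        if config.ransac == "multi":
            sets = ransac_multi(field, scale, params, rng=rng)
        else:
            one = ransac_single(field, scale, params, rng=rng)
            sets = [one] if one is not None else []
        hits = [(c.center, c) for c in sets]
    for fit, consensus in hits:
        center = fit.center
        if not np.all(np.isfinite(center)):
            continue
        if np.any(np.abs(center - np.asarray(seed_pos)) >
                  config.support_radius + 0.5):
            continue  # fit wandered outside its own support: not this seed's spot
        spot = Spot(position=center,
                    n_inliers=0 if consensus is None else len(consensus.inliers),
                    mean_residual=fit.mean_residual,
                    block_id=block_id, seed=tuple(seed_pos))
        inliers = None
        if config.intensity == "gauss_refit" and consensus is not None:
            inliers = field.subset(consensus.inliers)
        try:
            spot.intensity = measure_intensity(
                values, spot, mode=config.intensity, inliers=inliers,
                sigma=config.sigma, anisotropy=config.anisotropy,
                origin=origin)
        except ValueError:
            spot.intensity = float("nan")
        spots.append(spot)
    return spots


def detect_block(image: ImageVolume, block: Block, config: RunConfig) -> List[Spot]:
    """Detect and localize the spots owned by one block."""
    margin = _read_margin(config, image.ndim)
    values, origin = _read_block(image, block, margin)
    dog = dog_filter(values, config.dog_params())
    spots: List[Spot] = []
    shape = np.asarray(image.shape)
    for seed in find_seeds(dog, config.threshold):
        global_pos = tuple(int(p + o) for p, o in zip(seed.position, origin))
        if not block.owns(global_pos):
            continue
        if any(p < 1 or p > s - 2 for p, s in zip(global_pos, shape)):
            continue  # seeds need a full neighborhood inside the image
        spots.extend(_localize_candidate(values, origin, global_pos,
                                         seed.dog_value, config,
                                         block.block_id))
    logger.info("block %d %s..%s: %d spots", block.block_id, block.lo,
                block.hi, len(spots))
    return spots


def detect_blockwise(image: ImageVolume, grid: BlockGrid, config: RunConfig
                     ) -> List[Spot]:
    """Run detection over every block; concatenation is layout-invariant
    before the global redundancy filter (applied by the caller)."""
    spots: List[Spot] = []
    for block in grid.blocks:
        try:
            spots.extend(detect_block(image, block, config))
        except Exception as exc:  # noqa: BLE001 - annotate with block id
            raise RuntimeError(f"block {block.block_id} failed: {exc}") from exc
    return spots
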