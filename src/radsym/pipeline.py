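"""End-to-end detection: seeds -> gradients -> consensus fit -> spots."""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np

from .blockwise import detect_blockwise, plan_blocks
from .config import RunConfig
from .io import ImageVolume, from_array
from .postprocess import Spot, redundancy_filter

logger = logging.getLogger(__name__)


def _sort_spots(spots: List[Spot]) -> List[Spot]:
    return sorted(spots, key=lambda s: tuple(s.position))


def detect_spots(image, config: RunConfig = RunConfig(),
                 block_size: Optional[Sequence[int]] = None) -> List[Spot]:
    """Detect sub-pixel spots in a 2D/3D image.

    ``image`` is an :class:`ImageVolume` or a bare ndarray in internal
    (x, y[, z]) axis order.  Detection runs block-wise (a single block
    when the image fits one), results are redundancy-filtered globally
    and returned sorted by position.  Output is a pure function of
    (pixels, config): identical runs give identical spots for every
    block layout.
    """
    if not isinstance(image, ImageVolume):
        image = from_array(np.asarray(image, dtype=np.float64))
    bs = tuple(block_size) if block_size is not None else config.block_size
    grid = plan_blocks(image.shape, bs)
    spots = detect_blockwise(image, grid, config)
    n_raw = len(spots)
    spots = redundancy_filter(spots, config.min_separation)
    logger.info("detected %d spots (%d before redundancy filter)",
                len(spots), n_raw)
    return _sort_spots(spots)


def spots_to_array(spots: Sequence[Spot], ndim: int = 3) -> np.ndarray:
    """Spot positions as an (n, ndim) array (z = 0 appended for 2D)."""
    if not spots:
        return np.zeros((0, ndim))
    arr = np.stack([s.position for s in spots])
    if arr.shape[1] < ndim:
        arr = np.column_stack([arr, np.zeros(len(arr))])
    return arr
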