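"""Dual-grid image gradients in a local support patch.

Gradients are computed by separable convolution on the dual grid: for
every 2^n cell of adjacent pixels one gradient vector is produced at
the cell center (a half-integer position).  The component along axis d
is the unnormalized difference (+1 at the higher index, -1 at the
lower) along d combined with the averaging kernel (1/2, 1/2) along
every other axis.  A radius-r patch of side 2r+1 therefore yields
(2r)^n gradients — 216 for the default r = 3 in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class SupportPatch:
    """Intensity values in a (2r+1)^n box around a seed.

    center : integer seed position in global pixel coordinates
    radius : support-region radius r (>= 1)
    values : the (2r+1)^n intensity grid, internal (x, y[, z]) order,
        mirror-extended where the box leaves the image
    """

    center: Tuple[int, ...]
    radius: int
    values: np.ndarray

    def __post_init__(self):
        side = 2 * self.radius + 1
        if any(s != side for s in self.values.shape):
            raise ValueError(
                f"patch of radius {self.radius} must have side {side}, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("patch values must be finite")

    @property
    def origin(self) -> np.ndarray:
        """Global coordinate of the patch's first pixel."""
        return np.asarray(self.center, dtype=float) - self.radius


@dataclass
class GradientField:
    """Gradient vectors on the dual grid of a support patch.

    positions : (m, n) global dual-grid coordinates (integer + 0.5)
    vectors : (m, n) gradient vectors
    """

    positions: np.ndarray
    vectors: np.ndarray

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def subset(self, indices) -> "GradientField":
        return GradientField(self.positions[indices], self.vectors[indices])


def extract_patch(data: np.ndarray, center: Sequence[int], radius: int) -> SupportPatch:
    """Cut a (2r+1)^n box around ``center`` out of ``data``.

    Where the box leaves the array, values are mirror-extended (without
    repeating the edge pixel), matching the filter boundary handling.
    """
    center = tuple(int(c) for c in center)
    n = data.ndim
    lo = [c - radius for c in center]
    hi = [c + radius + 1 for c in center]
    pad_lo = [max(0, -l) for l in lo]
    pad_hi = [max(0, h - s) for h, s in zip(hi, data.shape)]
    sl = tuple(slice(max(0, l), min(h, s)) for l, h, s in zip(lo, hi, data.shape))
    block = data[sl]
    if any(pad_lo) or any(pad_hi):
        block = np.pad(block, list(zip(pad_lo, pad_hi)), mode="reflect")
    return SupportPatch(center=center, radius=radius,
                        values=np.asarray(block, dtype=np.float64))


def _cell_difference(values: np.ndarray, axis: int) -> np.ndarray:
    """Difference along ``axis``, (1/2, 1/2) average along all others."""
    out = values
    for d in range(values.ndim):
        lo = out.take(range(0, out.shape[d] - 1), axis=d)
        hi = out.take(range(1, out.shape[d]), axis=d)
        out = hi - lo if d == axis else 0.5 * (hi + lo)
    return out


def compute_gradients(patch: SupportPatch) -> GradientField:
    """One gradient per 2^n pixel cell, at the cell center.

    Gradients of a bright spot point toward its center.  The gradient
    count is (side - 1)^n = (2r)^n.
    """
    values = patch.values
    n = values.ndim
    if any(s < 2 for s in values.shape):
        raise ValueError("patch side must be >= 2 along every axis")
    comps = [_cell_difference(values, d) for d in range(n)]
    vectors = np.stack([c.reshape(-1) for c in comps], axis=1)
    side = values.shape[0] - 1
    grids = np.meshgrid(*[np.arange(s - 1) + 0.5 for s in values.shape],
                        indexing="ij")
    positions = np.stack([g.reshape(-1) for g in grids], axis=1)
    positions = positions + patch.origin
    return GradientField(positions=positions, vectors=vectors)


def _boundary_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for d in range(len(shape)):
        sl0 = [slice(None)] * len(shape)
        sl0[d] = 0
        mask[tuple(sl0)] = True
        sl0[d] = shape[d] - 1
        mask[tuple(sl0)] = True
    return mask


def subtract_background(patch: SupportPatch, mode: str = "none") -> SupportPatch:
    """Optionally remove a locally non-uniform fluorescence background.

    mode="none" returns the patch unchanged.  mode="plane" fits an
    affine function by least squares to the patch's boundary pixels
    only (the spot sits in the interior and would bias the fit) and
    subtracts it everywhere.
    """
    if mode == "none":
        return patch
    if mode != "plane":
        raise ValueError(f"unknown background mode {mode!r}")
    values = patch.values
    n = values.ndim
    mask = _boundary_mask(values.shape)
    coords = np.argwhere(mask).astype(float)
    design = np.column_stack([np.ones(len(coords)), coords])
    coef, *_ = np.linalg.lstsq(design, values[mask], rcond=None)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in values.shape],
                        indexing="ij")
    plane = coef[0] + sum(coef[1 + d] * grids[d] for d in range(n))
    return SupportPatch(center=patch.center, radius=patch.radius,
                        values=values - plane)
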