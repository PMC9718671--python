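"""Radial-symmetry localization: least-squares intersection of gradient lines.

In noise-free data the image gradients of a radially symmetric spot all
point at its center, so the center is the common intersection point of
the gradient lines.  With noise the lines no longer meet and the center
``p_c`` is defined as the minimizer of the weighted sum of squared
point-to-line distances

    sum_k  w_k * d_k^2,    d_k = dist(p_c, line(p_k, g_k)),

which has the closed-form normal equations

    [ sum_k w_k (I - u_k u_k^T) ] p_c = sum_k w_k (I - u_k u_k^T) p_k

with unit directions ``u_k = g_k / |g_k|``.  Axially elongated
(ellipsoidal) spots are handled without resampling the image: positions
are multiplied by a scale vector ``s = (1, 1, a)`` and gradients by its
inverse, the fit runs in the scaled (isotropic) space, and the center is
mapped back by ``s^-1``.  ``a < 1`` compresses an axially elongated PSF
to isotropy; equivalently ``sigma_axial = sigma_lateral / a``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gradients import GradientField

#: gradients shorter than this are dropped before direction normalization
MIN_GRADIENT_MAGNITUDE = 1e-12

#: smallest/largest eigenvalue ratio below which the normal matrix is singular
SINGULARITY_RATIO = 1e-10

WEIGHT_SCHEMES = ("uniform", "magnitude", "magnitude2")


class DegenerateFitError(ValueError):
    """All gradient lines are (numerically) parallel; no unique center."""


class InsufficientDataError(ValueError):
    """Fewer than two usable gradients."""


@dataclass(frozen=True)
class AnisotropyScale:
    """Global axial scale rendering the PSF isotropic.

    The factor ``a`` multiplies axial (z) coordinates; gradients receive
    the inverse.  ``a = 1`` is the isotropic (or 2D) case.
    """

    factor: float = 1.0

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("anisotropy factor must be > 0")

    def vector(self, ndim: int) -> np.ndarray:
        s = np.ones(ndim)
        if ndim == 3:
            s[2] = self.factor
        return s


@dataclass
class CenterFit:
    """Result of a radial-symmetry fit.

    center : sub-pixel coordinates in the original (unscaled) space
    residuals : per-gradient point-to-line distances in scaled space
    used_count : number of gradients that entered the fit
    """

    center: np.ndarray
    residuals: np.ndarray
    used_count: int

    @property
    def mean_residual(self) -> float:
        return float(np.mean(self.residuals)) if self.residuals.size else 0.0


def point_line_distance(q: Sequence[float], p: Sequence[float],
                        u: Sequence[float]) -> float:
    """Distance from point ``q`` to the line through ``p`` with unit
    direction ``u``: sqrt(|q-p|^2 - ((q-p)·u)^2), clamped at 0."""
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if norm < MIN_GRADIENT_MAGNITUDE:
        raise ValueError("direction vector has zero length")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    d = q - p
    val = d @ d - (d @ u) ** 2
    return float(np.sqrt(max(val, 0.0)))


def point_line_distances(q: np.ndarray, points: np.ndarray,
                         units: np.ndarray) -> np.ndarray:
    """Vectorized point-to-line distances for many lines at once."""
    d = q - points
    val = np.einsum("ij,ij->i", d, d) - np.einsum("ij,ij->i", d, units) ** 2
    return np.sqrt(np.clip(val, 0.0, None))


def gradient_weights(magnitudes: np.ndarray, scheme: str = "magnitude2") -> np.ndarray:
    """Per-gradient weights from (scaled-space) magnitudes."""
    if scheme == "uniform":
        return np.ones_like(magnitudes)
    if scheme == "magnitude":
        return magnitudes.copy()
    if scheme == "magnitude2":
        return magnitudes ** 2
    raise ValueError(f"unknown weight scheme {scheme!r}; use one of {WEIGHT_SCHEMES}")


def _scaled_lines(field: GradientField, scale: AnisotropyScale):
    """Scaled positions, unit directions and magnitudes of usable gradients.

    Positions are multiplied by s, gradients by s^-1; gradients with
    near-zero magnitude are dropped (their direction is undefined).
    Returns (positions, units, magnitudes, kept_indices).
    """
    n = field.positions.shape[1]
    s = scale.vector(n)
    pos = field.positions * s
    vec = field.vectors / s
    mags = np.linalg.norm(vec, axis=1)
    keep = mags > MIN_GRADIENT_MAGNITUDE
    units = vec[keep] / mags[keep, None]
    return pos[keep], units, mags[keep], np.flatnonzero(keep)


def fit_center(field: GradientField, scale: AnisotropyScale = AnisotropyScale(),
               weights: Optional[np.ndarray] = None,
               weight_scheme: str = "magnitude2") -> CenterFit:
    """Weighted least-squares intersection point of the gradient lines.

    ``weights`` overrides the magnitude-based scheme; zero-weight
    gradients never influence the result.  Raises
    :class:`InsufficientDataError` with < 2 usable gradients and
    :class:`DegenerateFitError` when all lines are parallel.
    """
    pos, units, mags, kept = _scaled_lines(field, scale)
    if weights is None:
        w = gradient_weights(mags, weight_scheme)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        w = weights[kept]
    usable = w > 0
    pos, units, w = pos[usable], units[usable], w[usable]
    m, n = pos.shape
    if m < 2:
        raise InsufficientDataError(f"need >= 2 usable gradients, have {m}")
    # A = sum w (I - u u^T);  b = A_k-weighted positions
    eye = np.eye(n)
    proj = eye[None, :, :] - units[:, :, None] * units[:, None, :]
    a_mat = np.einsum("k,kij->ij", w, proj)
    b = np.einsum("k,kij,kj->i", w, proj, pos)
    evals = np.linalg.eigvalsh(a_mat)
    if evals[0] < SINGULARITY_RATIO * evals[-1]:
        raise DegenerateFitError("gradient lines are parallel; center undefined")
    center_scaled = np.linalg.solve(a_mat, b)
    residuals = point_line_distances(center_scaled, pos, units)
    s = scale.vector(n)
    return CenterFit(center=center_scaled / s, residuals=residuals, used_count=m)


def minimal_center(field: GradientField, scale: AnisotropyScale = AnisotropyScale()
                   ) -> np.ndarray:
    """Center from exactly two gradient lines with unit weights.

    The midpoint of mutual closest approach in scaled space (the exact
    intersection when the lines meet), mapped back to unscaled space.
    """
    if len(field) != 2:
        raise ValueError("minimal_center requires exactly two gradients")
    fit = fit_center(field, scale, weights=np.ones(2))
    return fit.center
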