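import numpy as np
import pytest

from radsym.gradients import GradientField
from radsym.localize import (AnisotropyScale, DegenerateFitError,
                             InsufficientDataError, fit_center, minimal_center,
                             point_line_distance)
from tests.conftest import spot_gradient_field


def brute_force_center(field, scale, weights, span=4.0, levels=6, n=21):
    """Independent oracle: shrinking-grid minimizer of sum w_k d_k^2."""
    s = scale.vector(field.positions.shape[1])
    pos = field.positions * s
    vec = field.vectors / s
    mags = np.linalg.norm(vec, axis=1)
    keep = mags > 1e-12
    pos, units, w = pos[keep], vec[keep] / mags[keep, None], weights[keep]
    center = (w[:, None] * pos).sum(0) / w.sum()
    width = span
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, n) for c in center]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, len(center))
        diff = grid[:, None, :] - pos[None, :, :]
        d2 = np.einsum("gkj,gkj->gk", diff, diff) \
            - np.einsum("gkj,kj->gk", diff, units) ** 2
        cost = (d2 * w).sum(1)
        center = grid[np.argmin(cost)]
        width = 2 * width / (n - 1)
    return center / s, width


def test_point_line_distance_examples():
    assert point_line_distance((0, 0, 0), (1, 0, 0), (0, 1, 0)) == pytest.approx(1.0)
    assert point_line_distance((2, 3, 4), (0, 3, 4), (1, 0, 0)) == 0.0
    with pytest.raises(ValueError):
        point_line_distance((0, 0), (1, 1), (0, 0))


def test_point_line_distance_matches_line_sampling_oracle(rng):
    for _ in range(20):
        q, p = rng.normal(size=3), rng.normal(size=3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        t = np.linspace(-20, 20, 400001)
        brute = np.min(np.linalg.norm(q - (p + t[:, None] * u), axis=1))
        assert point_line_distance(q, p, u) == pytest.approx(brute, abs=1e-6)


def test_two_perpendicular_2d_lines_exact_intersection():
    field = GradientField(positions=np.array([[0.0, 1.0], [1.0, 0.0]]),
                          vectors=np.array([[0.0, -1.0], [-1.0, 0.0]]))
    fit = fit_center(field, weights=np.ones(2))
    np.testing.assert_allclose(fit.center, [0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)


def test_clean_gaussian_center_recovery():
    # sub-pixel center; bias of the dual-grid finite differences stays small
    center = np.array([31.30, 30.50, 15.70])
    field = spot_gradient_field(center, sigma_lateral=1.0, shape=(64, 64, 32))
    fit = fit_center(field)
    np.testing.assert_allclose(fit.center, center, atol=1e-3)
    # at the default sigma the residual discretization bias is still tiny
    field = spot_gradient_field(center, sigma_lateral=1.5, shape=(64, 64, 32))
    fit = fit_center(field)
    np.testing.assert_allclose(fit.center, center, atol=5e-3)


def test_anisotropic_gaussian_needs_matching_scale():
    center = np.array([31.30, 30.50, 15.70])
    field = spot_gradient_field(center, sigma_lateral=1.5, sigma_axial=3.0,
                                shape=(64, 64, 32))
    good = fit_center(field, AnisotropyScale(0.5))
    bad = fit_center(field, AnisotropyScale(1.0))
    np.testing.assert_allclose(good.center, center, atol=2e-2)
    assert abs(bad.center[2] - center[2]) > abs(good.center[2] - center[2])


def test_oracle_equivalence_random_fields(rng):
    for trial in range(30):
        ndim = 2 if trial % 2 else 3
        m = int(rng.integers(3, 13))
        pos = rng.uniform(0, 6, size=(m, ndim))
        target = rng.uniform(2, 4, size=ndim)
        vec = target - pos + rng.normal(0, 0.15, size=(m, ndim))
        field = GradientField(pos, vec)
        w = rng.uniform(0.1, 2.0, size=m)
        scale = AnisotropyScale(float(rng.uniform(0.5, 1.5)) if ndim == 3 else 1.0)
        try:
            fit = fit_center(field, scale, weights=w)
        except DegenerateFitError:
            continue
        oracle, res = brute_force_center(field, scale, w)
        np.testing.assert_allclose(fit.center, oracle, atol=max(4 * res, 1e-3))


def test_translation_equivariance(rng):
    field = spot_gradient_field((16.2, 15.7, 16.4))
    fit0 = fit_center(field)
    v = np.array([5.25, -3.5, 2.0])
    moved = GradientField(field.positions + v, field.vectors.copy())
    fit1 = fit_center(moved)
    np.testing.assert_allclose(fit1.center, fit0.center + v, atol=1e-9)


def test_rotation_equivariance_isotropic(rng):
    field = spot_gradient_field((16.2, 15.7, 16.4))
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    rotated = GradientField(field.positions @ rot.T, field.vectors @ rot.T)
    fit0 = fit_center(field)
    fit1 = fit_center(rotated)
    np.testing.assert_allclose(fit1.center, rot @ fit0.center, atol=1e-9)


def test_scale_consistency_prescaled_equals_scaled_fit():
    # fitting raw anisotropic data with factor a equals fitting
    # pre-scaled data with a = 1, after mapping back
    field = spot_gradient_field((16.3, 15.6, 16.1), sigma_lateral=1.5,
                                sigma_axial=3.0)
    a = 0.5
    s = np.array([1.0, 1.0, a])
    fit_raw = fit_center(field, AnisotropyScale(a))
    prescaled = GradientField(field.positions * s, field.vectors / s)
    fit_pre = fit_center(prescaled, AnisotropyScale(1.0))
    np.testing.assert_allclose(fit_pre.center / s, fit_raw.center, atol=1e-9)
    np.testing.assert_allclose(np.sort(fit_pre.residuals),
                               np.sort(fit_raw.residuals), atol=1e-9)


def test_zero_weight_gradients_have_no_influence(rng):
    field = spot_gradient_field((16.2, 15.7, 16.4))
    m = len(field)
    w = np.ones(m)
    w[::3] = 0.0
    fit_masked = fit_center(field, weights=w)
    keep = w > 0
    fit_subset = fit_center(field.subset(keep), weights=np.ones(keep.sum()))
    np.testing.assert_allclose(fit_masked.center, fit_subset.center, atol=1e-12)


def test_minimal_center_intersecting_and_skew_lines(rng):
    # intersecting lines -> exact intersection
    field = GradientField(np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]),
                          np.array([[0.0, -1.0, 0.0], [-1.0, 0.0, 0.0]]))
    np.testing.assert_allclose(minimal_center(field), [0, 0, 0], atol=1e-12)
    # skew lines -> brute-force grid-search oracle
    field = GradientField(np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 1.0]]),
                          np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    got = minimal_center(field)
    oracle, res = brute_force_center(field, AnisotropyScale(), np.ones(2),
                                     span=2.0, levels=5)
    np.testing.assert_allclose(got, oracle, atol=max(4 * res, 1e-4))


def test_degenerate_cases():
    same = GradientField(np.array([[0.0, 0.0], [1.0, 0.0]]),
                         np.array([[1.0, 0.0], [1.0, 0.0]]))
    with pytest.raises(DegenerateFitError):
        minimal_center(same)
    with pytest.raises(InsufficientDataError):
        fit_center(GradientField(np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]])))
    tiny = GradientField(np.random.default_rng(0).uniform(size=(5, 2)),
                         np.full((5, 2), 1e-15))
    with pytest.raises(InsufficientDataError):
        fit_center(tiny)


def test_anisotropy_scale_invariants():
    s = AnisotropyScale(0.5)
    v = s.vector(3)
    np.testing.assert_allclose(v * (1.0 / v), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        AnisotropyScale(0.0)
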