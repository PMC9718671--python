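import numpy as np
import pandas as pd
import pytest

from radsym.benchmark import (correct_offset, evaluate_scene, grid_search,
                              match_detections)
from radsym.config import RunConfig
from radsym.simulate import SimulationParams, simulate_scene


def _truth(n, rng, ndim=3, lo=5, hi=60):
    cols = ["x", "y", "z"][:ndim]
    return pd.DataFrame(rng.uniform(lo, hi, size=(n, ndim)), columns=cols)


def test_perfect_detections(rng):
    truth = _truth(20, rng)
    res = match_detections(truth, truth.to_numpy(), 3.0)
    assert (res.tp, res.fp, res.fn) == (20, 0, 0)
    assert res.f1 == 1.0
    assert res.mean_euclidean_error == 0.0
    np.testing.assert_allclose(res.per_axis_offset, 0.0)


def test_no_detections(rng):
    truth = _truth(7, rng)
    res = match_detections(truth, np.zeros((0, 3)), 3.0)
    assert res.f1 == 0.0 and res.fn == 7 and res.tp == 0


def test_f1_closed_form(rng):
    # 25 matched, 5 spurious detections, 5 missed truths
    truth = _truth(30, rng, lo=5, hi=200)
    det = truth.to_numpy()[:25] + 0.1
    det = np.vstack([det, rng.uniform(300, 400, size=(5, 3))])
    res = match_detections(truth, det, 3.0)
    assert (res.tp, res.fp, res.fn) == (25, 5, 5)
    assert res.f1 == pytest.approx(50 / 60)


def test_matching_is_one_to_one_and_respects_radius(rng):
    truth = _truth(50, rng, lo=5, hi=100)
    det = truth.to_numpy() + rng.normal(0, 0.3, size=(50, 3))
    res = match_detections(truth, det, max_distance=1.0)
    m = res.matches
    assert m["truth_index"].is_unique and m["detection_index"].is_unique
    assert (m["distance"] <= 1.0).all()


def test_f1_invariant_to_permutation(rng):
    truth = _truth(30, rng, lo=5, hi=100)
    det = truth.to_numpy() + rng.normal(0, 0.2, size=(30, 3))
    res1 = match_detections(truth, det, 3.0)
    res2 = match_detections(truth, det[rng.permutation(30)], 3.0)
    assert res1.f1 == res2.f1
    assert res1.mean_euclidean_error == pytest.approx(res2.mean_euclidean_error)


def test_error_bounds_offset_norm(rng):
    # Jensen: mean Euclidean error >= norm of the mean offset vector
    truth = _truth(100, rng, lo=5, hi=200)
    det = truth.to_numpy() + rng.normal(0.2, 0.3, size=(100, 3))
    res = match_detections(truth, det, 3.0)
    assert res.mean_euclidean_error >= np.linalg.norm(res.per_axis_offset) - 1e-12


def test_greedy_and_optimal_agree_on_easy_instances(rng):
    truth = _truth(20, rng, lo=5, hi=100)
    det = truth.to_numpy() + rng.normal(0, 0.05, size=(20, 3))
    g = match_detections(truth, det, 3.0, method="greedy")
    o = match_detections(truth, det, 3.0, method="optimal")
    assert g.tp == o.tp == 20


def test_correct_offset_removes_constant_shift(rng):
    truth = _truth(25, rng, lo=5, hi=100)
    det = truth.to_numpy() + np.array([0.5, 0.0, 0.0])
    res = match_detections(truth, det, 3.0)
    np.testing.assert_allclose(res.per_axis_offset, [0.5, 0, 0], atol=1e-9)
    corrected = correct_offset(res, det)
    np.testing.assert_allclose(corrected, truth.to_numpy(), atol=1e-9)
    res2 = match_detections(truth, corrected, 3.0)
    np.testing.assert_allclose(res2.per_axis_offset, 0.0, atol=1e-9)


def test_offset_shrinks_with_sample_size(rng):
    truth = _truth(1000, rng, lo=5, hi=500)
    det = truth.to_numpy() + rng.normal(0, 0.3, size=(1000, 3))
    res = match_detections(truth, det, 3.0)
    assert np.abs(res.per_axis_offset).max() < 0.05


def test_single_pair_correction_coincides():
    truth = pd.DataFrame([{"x": 10.0, "y": 11.0, "z": 12.0}])
    det = np.array([[10.4, 10.8, 12.1]])
    res = match_detections(truth, det, 3.0)
    corrected = correct_offset(res, det)
    np.testing.assert_allclose(corrected, truth.to_numpy(), atol=1e-12)


def test_correct_offset_requires_matches():
    truth = pd.DataFrame([{"x": 1.0, "y": 1.0, "z": 1.0}])
    res = match_detections(truth, np.zeros((0, 3)), 3.0)
    with pytest.raises(ValueError):
        correct_offset(res, np.zeros((0, 3)))


def test_grid_search_selects_generating_sigma():
    scenes = [simulate_scene(SimulationParams(shape=(96, 96, 24), n_spots=15,
                                              rng_seed=s)) for s in range(2)]
    table = grid_search(scenes, {"sigma": [1.5, 6.0]},
                        base_config=RunConfig(threshold=20.0))
    assert table.loc[0, "sigma"] == 1.5
    assert table.loc[0, "mean_f1"] > table.loc[1, "mean_f1"]


def test_grid_search_single_point_and_errors():
    scene = simulate_scene(SimulationParams(shape=(64, 64, 16), n_spots=5,
                                            rng_seed=0))
    table = grid_search([scene], {"sigma": [1.5]},
                        base_config=RunConfig(threshold=20.0))
    assert len(table) == 1
    with pytest.raises(ValueError):
        grid_search([], {"sigma": [1.5]})
    # an invalid grid point is recorded, not fatal
    table = grid_search([scene], {"sigma": [1.5, -1.0]},
                        base_config=RunConfig(threshold=20.0))
    assert (table["error_message"] != "").sum() == 1


def test_evaluate_scene_end_to_end():
    scene = simulate_scene(SimulationParams(shape=(96, 96, 24), n_spots=10,
                                            rng_seed=4))
    res = evaluate_scene(scene, RunConfig(threshold=20.0))
    assert res.f1 == 1.0
    assert res.mean_euclidean_error < 0.2
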