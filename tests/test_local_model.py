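"""Neighbour retrieval, local/global forests, evaluation metrics."""

import numpy as np
import pytest

import heliforge as hf
from heliforge.chem_space import encode, format_name, parse_name
from heliforge.chiroptics import PROPERTY_NAMES
from heliforge.dataset_io import Dataset
from heliforge.errors import DimensionError, InsufficientPoolError
from heliforge.local_model import (
    LocalForestRegressor,
    evaluate,
    fit_predict_local,
    mad_outliers,
    nearest_neighbours,
    weighted_distance,
)
from heliforge.synthetic_oracle import default_params, oracle_properties


class TestWeightedDistance:
    def test_identity(self):
        v = np.arange(16.0)
        assert weighted_distance(v, v) == 0.0

    def test_single_coordinate(self):
        a = np.zeros(16)
        b = np.zeros(16)
        b[4] = 0.78
        assert weighted_distance(a, b) == pytest.approx(0.78)

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.normal(size=(2, 16))
            w = rng.uniform(0.1, 2.0, 16)
            assert weighted_distance(a, b, w) == pytest.approx(weighted_distance(b, a, w))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            weighted_distance(np.zeros(16), np.zeros(15))

    def test_weights_scale_coordinates(self):
        a, b = np.zeros(2), np.array([1.0, 1.0])
        assert weighted_distance(a, b, [4.0, 0.0]) == pytest.approx(2.0)


class TestNearestNeighbours:
    def test_matches_brute_force(self, small_pool):
        q = small_pool.molecule(7)
        feats = small_pool.features()
        qv = encode(q)
        d = np.sqrt(((feats - qv) ** 2).sum(axis=1))
        brute = sorted(
            [(n, float(di)) for n, di in zip(small_pool.names, d)
             if n != format_name(q)],
            key=lambda t: (t[1], t[0]),
        )[:25]
        assert nearest_neighbours(q, small_pool, 25) == brute

    def test_query_excluded_from_own_neighbourhood(self, small_pool):
        q = small_pool.molecule(0)
        nn = nearest_neighbours(q, small_pool, len(small_pool) - 1)
        assert format_name(q) not in [n for n, _ in nn]

    def test_whole_pool_sorted(self, small_pool):
        q = parse_name("8-CCPh")  # not in the pool
        nn = nearest_neighbours(q, small_pool, len(small_pool))
        dists = [d for _, d in nn]
        assert dists == sorted(dists)

    def test_k_too_large(self, small_pool):
        with pytest.raises(InsufficientPoolError):
            nearest_neighbours(small_pool.molecule(0), small_pool, len(small_pool))


class TestLocalForest:
    def test_constant_targets_predict_constant(self, fast_forest):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 16))
        y = np.full((50, 2), 7.25)
        est = LocalForestRegressor(k=20, random_state=1, **fast_forest).fit(X, y)
        pred = est.predict(rng.normal(size=(3, 16)))
        assert np.allclose(pred, 7.25)

    def test_degenerate_neighbourhood_predicts_mean(self, fast_forest):
        X = np.zeros((10, 16))
        y = np.arange(10.0)[:, None]
        est = LocalForestRegressor(k=10, random_state=1, **fast_forest).fit(X, y)
        assert est.predict(np.zeros((1, 16)))[0, 0] == pytest.approx(np.mean(y))

    def test_deterministic_given_seed(self, small_pool, fast_forest):
        q = parse_name("2-CN_9-F")
        a = fit_predict_local(q, small_pool, k=40, seed=5, forest_params=fast_forest)
        b = fit_predict_local(q, small_pool, k=40, seed=5, forest_params=fast_forest)
        assert a == b

    def test_noiseless_linear_landscape_accuracy(self, noiseless_params):
        """On the smooth noiseless landscape the local model's MAE stays
        within the neighbourhood-scale property variation."""
        from heliforge.synthetic_oracle import generate_dataset

        ds = generate_dataset(800, family="EWG", max_subs=3,
                              params=noiseless_params, seed=17)
        train, test = hf.split(ds, 0.1, seed=17)
        errs = []
        for i in range(30):
            pred = fit_predict_local(
                test.molecule(i), train, k=60, seed=i,
                forest_params={"n_estimators": 60}, properties=["R_plus"],
            )["R_plus"]
            truth = test.record(i).R_plus
            errs.append(abs(pred - truth))
        assert np.mean(errs) < 60.0  # a small fraction of the ~1000-unit span

    def test_sklearn_get_set_params(self):
        est = LocalForestRegressor(k=10)
        assert est.get_params()["k"] == 10
        est.set_params(k=25)
        assert est.k == 25

    def test_g_prediction_clamped(self, fast_forest):
        # targets outside the physical range must not propagate to predictions
        gcol = PROPERTY_NAMES.index("g_abs")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 16))
        y = np.zeros((30, len(PROPERTY_NAMES)))
        y[:, gcol] = 5.0  # deliberately unphysical training values
        est = LocalForestRegressor(
            k=10, random_state=0, clamp={gcol: (-2.0, 2.0)}, **fast_forest
        ).fit(X, y)
        pred = est.predict(rng.normal(size=(2, 16)))
        assert np.all(pred[:, gcol] <= 2.0)


class TestEvaluate:
    def test_perfect_predictions(self):
        P = np.arange(10.0)
        rep = evaluate(P, P)
        m = rep.metrics["y0"]
        assert m["mae"] == 0.0 and m["rmse"] == 0.0 and m["outlier_fraction"] == 0.0

    def test_single_gross_outlier_flagged(self):
        truth = np.zeros(10)
        pred = np.zeros(10)
        pred[-1] = 100.0
        rep = evaluate(pred, truth)
        m = rep.metrics["y0"]
        assert m["outlier_fraction"] == pytest.approx(0.1)
        assert m["outlier_names"] == ["9"]

    def test_scaled_mad_rule_by_hand(self):
        rng = np.random.default_rng(8)
        r = rng.normal(size=200)
        mask = mad_outliers(r)
        med = np.median(r)
        mad = np.median(np.abs(r - med))
        expected = np.abs(r - med) > 2.5 * 1.4826 * mad
        assert np.array_equal(mask, expected)

    def test_mae_le_rmse_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=100)
        p = t + rng.normal(scale=0.5, size=100)
        r1 = evaluate(p, t).metrics["y0"]
        r2 = evaluate(p + 3.0, t + 3.0).metrics["y0"]
        assert r1["mae"] <= r1["rmse"]
        assert r1["mae"] == pytest.approx(r2["mae"])
        assert r1["rmse"] == pytest.approx(r2["rmse"])

    def test_length_checks(self):
        with pytest.raises(DimensionError):
            evaluate(np.zeros(3), np.zeros(4))
        with pytest.raises(DimensionError):
            evaluate(np.zeros(1), np.zeros(1))
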