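"""Boosted base model, leaf embedding, kNN applicability domain."""

import math

import numpy as np
import pytest

from cb2screen.model import (
    AdThresholdGrid,
    KnnIndex,
    PredictionResult,
    build_ad_grid,
    embed,
    predict,
    predict_batch,
    train_base_model,
)
from tests.conftest import TINY_GRID


def _linear_problem(n=60, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8))
    y = 7 + 1.5 * X[:, 0] - 0.8 * X[:, 1] + rng.normal(0, noise, n)
    return X, y


class TestTrainBaseModel:
    def test_learns_linear_signal(self):
        X, y = _linear_problem()
        m = train_base_model(X, y, param_grid=TINY_GRID, seed=0)
        pred = m.predict(X)
        r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 > 0.9

    def test_constant_target_raises(self):
        X, _ = _linear_problem()
        with pytest.raises(ValueError, match="degenerate"):
            train_base_model(X, np.full(len(X), 6.5), param_grid=TINY_GRID)

    def test_deterministic_given_seed(self):
        X, y = _linear_problem()
        m1 = train_base_model(X, y, param_grid=TINY_GRID, seed=3)
        m2 = train_base_model(X, y, param_grid=TINY_GRID, seed=3)
        assert m1.n_estimators_ == m2.n_estimators_
        assert np.array_equal(m1.predict(X), m2.predict(X))


class TestEmbed:
    def test_embedding_length_equals_tree_count(self):
        X, y = _linear_problem()
        m = train_base_model(X, y, param_grid=TINY_GRID, seed=0)
        emb = embed(m, X[0])
        assert emb.shape == (m.n_estimators_,)

    def test_leaf_value_sum_reproduces_prediction(self):
        """Per-tree leaf outputs must add up to the ensemble prediction."""
        X, y = _linear_problem()
        m = train_base_model(X, y, param_grid=TINY_GRID, seed=0)
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(10, X.shape[1]))
        emb = embed(m, Q)
        assert np.allclose(emb.sum(axis=1), m.predict(Q), atol=1e-9)

    def test_identical_rows_identical_embeddings(self):
        X, y = _linear_problem()
        m = train_base_model(X, y, param_grid=TINY_GRID, seed=0)
        emb = embed(m, np.stack([X[3], X[3]]))
        assert np.array_equal(emb[0], emb[1])
        assert np.linalg.norm(emb[0] - emb[1]) == 0.0

    def test_single_tree_ensemble_embeds_to_length_one(self):
        X, y = _linear_problem()
        grid = {"n_estimators": [1], "max_depth": [3], "learning_rate": [0.5]}
        m = train_base_model(X, y, param_grid=grid, seed=0)
        assert embed(m, X[0]).shape == (1,)


class TestAdGrid:
    def test_exactly_20_non_decreasing_thresholds(self):
        rng = np.random.default_rng(0)
        grid = build_ad_grid(rng.normal(size=(50, 6)))
        assert len(grid.thresholds) == 20
        assert (np.diff(grid.thresholds) >= 0).all()
        assert (grid.thresholds >= 0).all()

    def test_identical_points_give_zero_thresholds(self):
        grid = build_ad_grid(np.ones((10, 4)))
        assert np.all(grid.thresholds == 0.0)

    def test_collinear_points_match_hand_computation(self):
        # points at 0,1,2,3,4 on a line; max-3NN distances are {3,2,2,2,3}
        pts = np.arange(5.0).reshape(-1, 1)
        grid = build_ad_grid(pts, k=3)
        assert sorted(grid.max_knn_distances) == [2, 2, 2, 3, 3]
        assert grid.threshold_at(100.0) == 3.0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            build_ad_grid(np.zeros((3, 2)), k=3)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            AdThresholdGrid(np.array([1.0, 0.5] + [2.0] * 18), np.zeros(5))


class TestKnnOracle:
    def test_agrees_with_brute_force_on_random_instances(self):
        """Stable-tie kNN must match an independent per-point search."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            ref = rng.normal(size=(200, 5))
            queries = rng.normal(size=(20, 5))
            index = KnnIndex(ref, rng.uniform(4, 10, 200), [str(i) for i in range(200)])
            idx, dist = index.query(queries, k=3)
            for qi, q in enumerate(queries):
                d = [math.dist(q, r) for r in ref]
                expected = sorted(range(200), key=lambda j: (d[j], j))[:3]
                assert list(idx[qi]) == expected
                assert np.allclose(dist[qi], [d[j] for j in expected])

    def test_order_invariance_up_to_ties(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(80, 4))
        y = rng.uniform(4, 10, 80)
        perm = rng.permutation(80)
        q = rng.normal(size=(12, 4))
        i1 = KnnIndex(ref, y, [str(i) for i in range(80)])
        i2 = KnnIndex(ref[perm], y[perm], [str(i) for i in perm])
        _, d1 = i1.query(q)
        _, d2 = i2.query(q)
        assert np.allclose(d1, d2)


class TestPredict:
    def _setup(self):
        X, y = _linear_problem(80, seed=5)
        m = train_base_model(X, y, param_grid=TINY_GRID, seed=0)
        emb = embed(m, X)
        index = KnnIndex(emb, y, [f"K{i}" for i in range(len(y))])
        return X, y, m, index

    def test_query_equal_to_triplicated_training_point(self):
        X, y, m, _ = self._setup()
        emb_q = embed(m, X[0])
        index = KnnIndex(
            np.stack([emb_q] * 3), np.array([7.0, 7.0, 7.0]), ["a", "b", "c"]
        )
        r = predict(X[0], m, index, threshold=0.0)
        assert r.in_domain
        assert r.pki_pred == 7.0
        assert r.max_neighbor_distance == 0.0

    def test_zero_threshold_rejects_distinct_query(self):
        X, y, m, index = self._setup()
        q = X[0] + 100.0  # far outside training space
        r = predict(q, m, index, threshold=0.0)
        if r.max_neighbor_distance > 0:
            assert not r.in_domain
            assert r.pki_pred is None
        assert len(r.neighbor_ids) == 3

    def test_prediction_is_mean_of_neighbor_pki(self):
        X, y, m, _ = self._setup()
        emb_q = embed(m, X[0])
        index = KnnIndex(
            np.stack([emb_q, emb_q, emb_q]),
            np.array([6.0, 7.0, 8.0]),
            ["a", "b", "c"],
        )
        r = predict(X[0], m, index, threshold=1.0)
        assert r.pki_pred == pytest.approx(7.0)

    def test_negative_threshold_raises(self):
        X, y, m, index = self._setup()
        with pytest.raises(ValueError):
            predict(X[0], m, index, threshold=-0.1)

    def test_result_invariant_pred_iff_in_domain(self):
        with pytest.raises(ValueError):
            PredictionResult(6.5, False, 1.0, ("a", "b", "c"), 0.5)

    def test_in_domain_fraction_non_decreasing_in_threshold(self):
        X, y, m, index = self._setup()
        grid = build_ad_grid(index.embeddings)
        rng = np.random.default_rng(0)
        Q = X + rng.normal(0, 0.3, X.shape)
        pred, _, _ = predict_batch(embed(m, Q), index, grid.thresholds)
        coverage = np.isfinite(pred).mean(axis=0)
        assert (np.diff(coverage) >= 0).all()

    def test_training_set_in_domain_at_loosest_threshold(self):
        """Leave-self-out queries of the training set stay >= 95% in-domain
        at the 100th-percentile threshold."""
        X, y, m, index = self._setup()
        grid = build_ad_grid(index.embeddings)
        # leave-self-out max distances are exactly the grid's distribution
        frac = (grid.max_knn_distances <= grid.threshold_at(100.0)).mean()
        assert frac >= 0.95


class TestModelBundle:
    def test_save_load_roundtrip_preserves_predictions(
        self, trained_model, clean_dataset, tmp_path
    ):
        from rdkit import Chem

        from cb2screen.model import QsarModel

        trained_model.save(tmp_path / "bundle")
        loaded = QsarModel.load(tmp_path / "bundle")
        mol = Chem.MolFromSmiles(clean_dataset.smiles.iloc[5])
        r1 = trained_model.predict_one(mol, 100.0)
        r2 = loaded.predict_one(mol, 100.0)
        assert r1.pki_pred == pytest.approx(r2.pki_pred)
        assert r1.neighbor_ids == r2.neighbor_ids
        assert np.array_equal(
            trained_model.ad_grid.thresholds, loaded.ad_grid.thresholds
        )
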