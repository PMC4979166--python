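"""Base forests, the logistic combiner, and the stacked ensemble pipeline."""

import numpy as np
import pytest

from ipminer.classify import (
    IPMinerClassifier,
    combine,
    fit_stack,
    load_model,
    predict_pairs,
    save_model,
    train_base,
    train_ipminer,
)

from conftest import FAST_CONFIG


@pytest.fixture(scope="module")
def fitted(motif_matrix):
    X, y = motif_matrix
    return IPMinerClassifier(**FAST_CONFIG, random_state=17).fit(X, y)


class TestTrainBase:
    def test_separable_clusters_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (30, 5)), rng.normal(5, 0.1, (30, 5))])
        y = np.repeat([0, 1], 30)
        forest = train_base(X, y, n_trees=20, seed=1)
        assert (forest.predict(X) == y).all()

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.random((60, 8))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p1 = train_base(X, y, seed=3).predict_proba(X)
        p2 = train_base(X, y, seed=3).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_probabilities_valid(self):
        rng = np.random.default_rng(2)
        X = rng.random((40, 4))
        y = np.arange(40) % 2
        P = train_base(X, y, n_trees=10, seed=0).predict_proba(rng.random((10, 4)))
        assert np.all((P >= 0) & (P <= 1))
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            train_base(np.random.rand(10, 3), np.zeros(10), seed=0)


class TestCombine:
    def test_equal_weights_midpoint(self):
        # sigmoid(1.5) to 5 decimals
        out = combine(np.ones(3), 0.0, np.array([0.5, 0.5, 0.5]))
        assert out == pytest.approx(0.81757, abs=1e-5)

    def test_zero_weights_give_half(self):
        assert combine(np.zeros(3), 0.0, np.array([0.9, 0.1, 0.3])) == 0.5

    def test_equal_weights_rank_like_averaging(self):
        rng = np.random.default_rng(3)
        P = rng.random((50, 3))
        scores = combine(np.full(3, 2.0), 0.0, P)
        assert np.array_equal(np.argsort(scores), np.argsort(P.mean(axis=1)))

    def test_strictly_increasing_in_positive_weight_coordinates(self):
        w = np.array([1.0, 0.5, 2.0])
        p = np.array([0.3, 0.4, 0.5])
        base = combine(w, 0.1, p)
        for j in range(3):
            bumped = p.copy()
            bumped[j] += 0.05
            assert combine(w, 0.1, bumped) > base


class TestFitStack:
    def test_label_column_dominates(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 500)
        P = np.column_stack([y.astype(float), rng.random(500), rng.random(500)])
        # tiny jitter so the fit converges instead of diverging to infinity
        P[:, 0] = 0.9 * P[:, 0] + 0.05
        w, b = fit_stack(P, y)
        assert abs(w[0]) > abs(w[1]) and abs(w[0]) > abs(w[2])
        assert w[0] > 0

    def test_anti_predictive_column_gets_negative_weight(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 500)
        P = np.column_stack([0.9 * (1 - y) + 0.05, rng.random(500), rng.random(500)])
        w, _ = fit_stack(P, y)
        assert w[0] < 0

    def test_duplicated_columns_split_weight(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 400)
        col = 0.7 * y + 0.15 + rng.normal(0, 0.05, 400)
        noise = rng.random(400)
        w_single, _ = fit_stack(np.column_stack([col, noise, rng.random(400)]), y)
        w_dup, _ = fit_stack(np.column_stack([col, col, noise]), y)
        assert w_dup[0] + w_dup[1] == pytest.approx(w_single[0], rel=0.05)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_stack(np.random.rand(10, 3), np.ones(10))


class TestIPMinerClassifier:
    def test_fitted_surfaces(self, fitted):
        assert fitted.stack_w_.shape == (3,)
        assert set(fitted.base_classifiers_) == {"raw", "sda", "sda_ft"}
        assert fitted.protein_sda_.output_dim_ == 64
        assert fitted.rna_sda_.output_dim_ == 64

    def test_predictions_valid_and_thresholded(self, fitted, motif_matrix):
        X, _ = motif_matrix
        P = fitted.predict_proba(X[:20])
        assert np.all((P >= 0) & (P <= 1))
        assert np.allclose(P.sum(axis=1), 1.0)
        calls = fitted.predict(X[:20])
        assert np.array_equal(calls, (P[:, 1] >= 0.5).astype(int))

    def test_leakage_bookkeeping(self, fitted, motif_matrix):
        # every sample was scored by forests fitted on other folds only
        _, y = motif_matrix
        assert np.all(fitted.oof_fold_ids_ >= 0)
        assert fitted.oof_probs_.shape == (len(y), 3)
        # each fold holds out a contiguous stratified share
        counts = np.bincount(fitted.oof_fold_ids_)
        assert counts.sum() == len(y)
        assert counts.min() >= len(y) // FAST_CONFIG["stack_folds"] - 2

    def test_determinism_same_seed_same_model(self, motif_matrix):
        X, y = motif_matrix
        idx = np.r_[0:40, 160:200]  # balanced subset
        cfg = dict(FAST_CONFIG, pretrain_epochs=5, finetune_epochs=5)
        m1 = IPMinerClassifier(**cfg, random_state=3).fit(X[idx], y[idx])
        m2 = IPMinerClassifier(**cfg, random_state=3).fit(X[idx], y[idx])
        assert np.array_equal(m1.stack_w_, m2.stack_w_)
        assert np.array_equal(m1.predict_proba(X[80:100]), m2.predict_proba(X[80:100]))

    def test_positive_pairs_score_above_negative(self, fitted, motif_dataset):
        pairs, prot, rna = motif_dataset
        probs, calls = predict_pairs(fitted, pairs, prot, rna)
        y = np.array([p[2] for p in pairs])
        assert probs[y == 1].mean() > probs[y == 0].mean()
        assert np.all((probs >= 0) & (probs <= 1))

    def test_empty_pair_list(self, fitted, motif_dataset):
        _, prot, rna = motif_dataset
        probs, calls = predict_pairs(fitted, [], prot, rna)
        assert probs.shape == (0,) and calls.shape == (0,)

    def test_one_class_rejected(self, motif_matrix):
        X, _ = motif_matrix
        with pytest.raises(ValueError):
            IPMinerClassifier(**FAST_CONFIG).fit(X[:30], np.zeros(30))

    def test_unknown_mode_rejected(self, motif_matrix):
        X, y = motif_matrix
        idx = np.r_[0:15, 185:200]
        with pytest.raises(ValueError, match="mode"):
            IPMinerClassifier(mode="bogus").fit(X[idx], y[idx])

    def test_con_mode_single_stack(self, motif_matrix):
        X, y = motif_matrix
        idx = np.r_[0:50, 150:200]
        m = IPMinerClassifier(
            mode="con", architecture=(64, 32, 32), pretrain_epochs=5,
            finetune_epochs=5, batch_size=50, n_trees=20, stack_folds=3,
            random_state=1,
        ).fit(X[idx], y[idx])
        # one stacked network consuming the full 599-dim input
        assert m.sda_.layers_[0].in_dim == 599
        P = m.predict_proba(X[100:120])
        assert np.all((P >= 0) & (P <= 1))


class TestModelPersistence:
    def test_save_load_round_trip(self, fitted, motif_matrix, tmp_path):
        X, _ = motif_matrix
        save_model(fitted, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert np.array_equal(loaded.stack_w_, fitted.stack_w_)
        assert np.array_equal(
            loaded.predict_proba(X[:20]), fitted.predict_proba(X[:20])
        )

    def test_train_ipminer_from_pairs(self, motif_dataset, tmp_path):
        pairs, prot, rna = motif_dataset
        cfg = dict(FAST_CONFIG, pretrain_epochs=5, finetune_epochs=5,
                   random_state=2)
        model = train_ipminer(pairs[:60] + pairs[-60:], prot, rna, cfg)
        probs, calls = predict_pairs(model, pairs[:10], prot, rna)
        assert probs.shape == (10,)
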