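"""Parzen-window PNN: kernel sums, limits, bandwidth selection, persistence."""

import numpy as np
import pytest

import ftirclass as fc
from ftirclass.pnn import PNNModel, classify_batch


def _toy_features(rng, n_per_class=20, spread=0.3):
    centers = {"a": (0.0, 0.0), "b": (3.0, 0.0), "c": (0.0, 3.0)}
    X, y = [], []
    for name, c in centers.items():
        X.append(rng.normal(c, spread, size=(n_per_class, 2)))
        y += [name] * n_per_class
    return np.vstack(X), y


class TestFit:
    def test_stores_all_training_vectors_by_class(self):
        rng = np.random.default_rng(0)
        X, y = _toy_features(rng, n_per_class=60)
        m = fc.fit((X, y), sigma=1.0)
        assert m.M == 3
        assert m.n_k == (60, 60, 60)

    def test_single_sample_per_class_is_legal(self):
        m = fc.fit((np.array([[0.0], [1.0]]), ["a", "b"]), sigma=0.5)
        assert m.n_k == (1, 1)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(1)
        X, y = _toy_features(rng)
        a = fc.fit((X, y), sigma=0.7)
        b = fc.fit((X, y), sigma=0.7)
        for ca, cb in zip(a.centers, b.centers):
            np.testing.assert_array_equal(ca, cb)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fc.fit((np.array([[np.nan], [1.0]]), ["a", "b"]), sigma=1.0)
        with pytest.raises(ValueError):
            fc.fit((np.array([[0.0], [1.0]]), ["a", "a"]), sigma=1.0)
        with pytest.raises(ValueError):
            fc.fit((np.array([[0.0], [1.0]]), ["a", "b"]), sigma=0.0)


class TestPatternResponse:
    def test_kernel_peak_at_sole_centre(self):
        m = fc.fit((np.array([[0.2, 0.4], [5.0, 5.0]]), ["a", "b"]),
                   sigma=1.0, standardize=False)
        h = fc.pattern_response(m, np.array([0.2, 0.4]))
        assert h[0] == 1.0

    def test_hand_computed_gaussian_sum(self):
        # class A centres {0, 2}, sigma=1, x=1: H_A = 2 exp(-1/2)
        X = np.array([[0.0], [2.0], [10.0]])
        m = fc.fit((X, ["A", "A", "B"]), sigma=1.0, standardize=False)
        h = fc.pattern_response(m, np.array([1.0]))
        assert h[0] == pytest.approx(2.0 * np.exp(-0.5), abs=1e-9)

    def test_flat_kernel_limit_gives_counts(self):
        rng = np.random.default_rng(3)
        X, y = _toy_features(rng, n_per_class=7)
        m = fc.fit((X, y), sigma=1e6, standardize=False)
        np.testing.assert_allclose(fc.pattern_response(m, X[0]), [7.0, 7.0, 7.0],
                                   rtol=1e-9)

    def test_dimension_mismatch_rejected(self):
        m = fc.fit((np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"]), sigma=1.0)
        with pytest.raises(ValueError, match="dimension"):
            fc.pattern_response(m, np.array([1.0]))


class TestClassify:
    def test_concentrated_kernel_at_training_centre(self):
        rng = np.random.default_rng(4)
        X, y = _toy_features(rng)
        m = fc.fit((X, y), sigma=0.05)
        idx = y.index("b")
        pred = fc.classify(m, X[idx])
        assert pred.label == "b"
        assert pred.posteriors[m.class_names.index("b")] > 0.99

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, y = _toy_features(rng)
        m = fc.fit((X, y), sigma=0.5)
        for x in rng.normal(1.0, 2.0, size=(20, 2)):
            pred = fc.classify(m, x)
            assert abs(pred.posteriors.sum() - 1.0) <= 1e-12

    def test_sigma_to_zero_equals_nearest_neighbour(self):
        rng = np.random.default_rng(6)
        X, y = _toy_features(rng, n_per_class=30, spread=1.0)
        m = fc.fit((X, y), sigma=1e-6, standardize=False)
        queries = rng.normal(1.0, 2.0, size=(50, 2))
        for x in queries:
            nn = y[int(np.argmin(np.sum((X - x) ** 2, axis=1)))]
            assert fc.classify(m, x).label == nn

    def test_equidistant_tie_breaks_to_first_class(self):
        m = fc.fit((np.array([[-1.0], [1.0]]), ["first", "second"]),
                   sigma=1.0, standardize=False)
        pred = fc.classify(m, np.array([0.0]))
        assert pred.label == "first"
        np.testing.assert_allclose(pred.posteriors, [0.5, 0.5], atol=1e-12)

    def test_sigma_to_infinity_ties_to_class_order(self):
        rng = np.random.default_rng(7)
        X, y = _toy_features(rng)
        m = fc.fit((X, y), sigma=1e9, standardize=False)
        assert fc.classify(m, np.array([50.0, -20.0])).label == m.class_names[0]

    def test_scores_invariant_to_within_class_permutation(self):
        rng = np.random.default_rng(8)
        X, y = _toy_features(rng, n_per_class=10)
        m1 = fc.fit((X, y), sigma=0.8)
        perm = np.r_[rng.permutation(10), 10 + rng.permutation(10),
                     20 + rng.permutation(10)]
        m2 = fc.fit((X[perm], [y[i] for i in perm]), sigma=0.8)
        x = np.array([1.0, 1.0])
        np.testing.assert_allclose(fc.classify(m1, x).scores,
                                   fc.classify(m2, x).scores, rtol=1e-12)

    def test_duplicate_centre_never_decreases_output_under_fixed_weights(self):
        rng = np.random.default_rng(9)
        X, y = _toy_features(rng, n_per_class=5)
        base = fc.fit((X, y), sigma=0.7, standardize=False)
        unit = np.eye(3)
        m1 = PNNModel(base.class_names, base.centers, 0.7, unit, standardize=False)
        centers2 = [c.copy() for c in base.centers]
        centers2[1] = np.vstack([centers2[1], centers2[1][0]])
        m2 = PNNModel(base.class_names, centers2, 0.7, unit, standardize=False)
        for x in rng.normal(1.0, 2.0, size=(25, 2)):
            y1 = fc.classify(m1, x).scores[1]
            y2 = fc.classify(m2, x).scores[1]
            assert y2 >= y1 - 1e-12


class TestSelectSigma:
    def test_separable_classes_tie_to_smallest_candidate(self):
        rng = np.random.default_rng(10)
        X, y = _toy_features(rng, n_per_class=12, spread=0.05)
        s = fc.select_sigma((X, y), [0.5, 1.0, 2.0], folds=3, seed=0)
        assert s == 0.5

    def test_overlapping_classes_prefer_moderate_bandwidth(self):
        rng = np.random.default_rng(11)
        X, y = _toy_features(rng, n_per_class=24, spread=1.2)
        s = fc.select_sigma((X, y), [1e-9, 0.8, 1e9], folds=4, seed=0)
        assert s == 0.8

    def test_selection_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        X, y = _toy_features(rng, n_per_class=15, spread=1.0)
        runs = {fc.select_sigma((X, y), [0.3, 1.0, 3.0], folds=3, seed=5)
                for _ in range(3)}
        assert len(runs) == 1

    def test_validation(self):
        rng = np.random.default_rng(13)
        X, y = _toy_features(rng, n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            fc.select_sigma((X, y), [0.1, 1.0], folds=5)
        with pytest.raises(ValueError):
            fc.select_sigma((X, y), [0.1], folds=2)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(14)
        X, y = _toy_features(rng, n_per_class=8)
        m = fc.fit((X, y), sigma=0.6)
        fc.save_model(m, tmp_path / "model")
        back = fc.load_model(tmp_path / "model")
        assert back.class_names == m.class_names
        assert back.sigma == m.sigma
        assert back.n_k == m.n_k
        queries = rng.normal(1.0, 2.0, size=(20, 2))
        assert classify_batch(back, queries) == classify_batch(m, queries)
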