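import numpy as np
import pytest

from sitmap import (HipLocalization, PressureImage, SVMConfig, apply_standardizer,
                    cross_validate, extract_features, features_from_samples,
                    fit_standardizer, generate_scene, svm_grid_search, train_ova_svm)
from conftest import clean_scene_cfg


def _loc(left=(16, 10), right=(16, 22), caudal=(19, 16)):
    return HipLocalization(left_hip=left, right_hip=right, caudal=caudal,
                           angle_deg=0.0, variant_id=1, score=1.0)


def make_clusters(rng, n_per=25, spread=0.1):
    """Four well-separated Gaussian clusters in feature space."""
    centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
    labels = np.array(["upright", "lean_left", "lean_right", "lean_back"])
    X = np.vstack([c + rng.normal(0, spread, (n_per, 3)) for c in centers])
    y = np.repeat(labels, n_per)
    return X, y


class TestFeatureExtraction:
    def test_uniform_image_caudal_disc_counts_29_pixels(self):
        img = PressureImage(np.full((32, 32), 1 / 1024))
        f = extract_features(img, _loc())
        # 29 = number of integer pixels with center within 3 px (brute count)
        count = sum(1 for u in range(-3, 4) for v in range(-3, 4) if u * u + v * v <= 9)
        assert count == 29
        assert abs(f.f_caudal - 29 / 1024) < 1e-12

    def test_zero_image_gives_zero_features(self):
        f = extract_features(PressureImage(np.zeros((32, 32))), _loc())
        assert (f.f_left, f.f_right, f.f_caudal) == (0, 0, 0)

    def test_features_nonneg_and_bounded_by_total(self):
        s = generate_scene(clean_scene_cfg(seed=8, noise_sd=0.02))
        from sitmap import preprocess
        pre = preprocess(s.image)
        f = extract_features(pre, _loc(s.left_hip, s.right_hip))
        assert min(f.f_left, f.f_right, f.f_caudal) >= 0
        # discs may overlap, but each single feature is at most the total mass
        assert max(f.f_left, f.f_right, f.f_caudal) <= 1.0 + 1e-12

    def test_lean_left_scene_orders_features(self):
        s = generate_scene(clean_scene_cfg(posture="lean_left"))
        from sitmap import preprocess
        pre = preprocess(s.image)
        f = extract_features(pre, _loc(s.left_hip, s.right_hip))
        assert f.f_left > f.f_right

    def test_edge_disc_clips_to_zero_contribution(self):
        img = PressureImage(np.full((32, 32), 1 / 1024))
        f_center = extract_features(img, _loc()).f_left
        f_edge = extract_features(img, _loc(left=(0, 0))).f_left
        assert f_edge < f_center


class TestStandardization:
    def test_two_point_population_sd(self):
        stats = fit_standardizer(np.array([[0.0, 0, 0], [2.0, 2, 2]]))
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(stats.sd, 1.0)  # population sd
        z = apply_standardizer(stats, np.array([[0.0, 0, 0], [2.0, 2, 2]]))
        np.testing.assert_allclose(z, [[-1, -1, -1], [1, 1, 1]])

    def test_training_set_standardizes_to_zero_one(self, rng):
        X = rng.uniform(0, 1, (40, 3))
        z = apply_standardizer(fit_standardizer(X), X)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_moments_match_independent_sums(self, rng):
        X = rng.uniform(0, 5, (15, 3))
        stats = fit_standardizer(X)
        for i in range(3):
            m = sum(X[:, i]) / len(X)
            sd = (sum((x - m) ** 2 for x in X[:, i]) / len(X)) ** 0.5
            assert abs(stats.mean[i] - m) < 1e-12
            assert abs(stats.sd[i] - sd) < 1e-12

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="degenerate feature"):
            fit_standardizer(np.ones((10, 3)))


class TestSVM:
    def test_separable_clusters_fit_perfectly(self, rng):
        X, y = make_clusters(rng)
        stats = fit_standardizer(X)
        model = train_ova_svm(apply_standardizer(stats, X), y)
        assert (model.predict(apply_standardizer(stats, X)) == y).mean() == 1.0

    def test_table_parameters_accepted(self):
        cfg = SVMConfig(kernel="polynomial", C=1.3, beta=1.4, theta=0.8, degree=3)
        assert cfg._svc().kernel == "poly"
        SVMConfig(kernel="gaussian", C=0.2, gamma=2.0)
        SVMConfig(kernel="sigmoid", C=0.4, beta=0.2, theta=0.2)

    def test_duplicating_training_points_keeps_predictions(self, rng):
        X, y = make_clusters(rng, n_per=10)
        stats = fit_standardizer(X)
        Xz = apply_standardizer(stats, X)
        a = train_ova_svm(Xz, y).predict(Xz)
        b = train_ova_svm(np.vstack([Xz, Xz]), np.concatenate([y, y])).predict(Xz)
        assert (a == b).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_ova_svm(np.zeros((5, 3)), np.array(["upright"] * 5))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="unknown kernel"):
            SVMConfig(kernel="linear")


class TestCrossValidation:
    def test_separable_dataset_perfect_accuracy(self, rng):
        X, y = make_clusters(rng)
        res = cross_validate(X, y, folds=5, seed=0)
        assert res.mean_accuracy == 1.0

    def test_confusion_rows_sum_to_class_counts(self, rng):
        X, y = make_clusters(rng, n_per=12, spread=3.0)
        res = cross_validate(X, y, folds=4, seed=1)
        assert res.confusion.sum() == len(y)
        for i, lab in enumerate(res.labels):
            assert res.confusion[i].sum() == (y == lab).sum()
        trace_acc = res.confusion.trace() / res.confusion.sum()
        # pooled accuracy equals fold-weighted accuracy (equal fold sizes)
        assert abs(trace_acc - res.mean_accuracy) < 1e-9

    def test_same_seed_same_result(self, rng):
        X, y = make_clusters(rng, spread=2.0)
        a = cross_validate(X, y, seed=7)
        b = cross_validate(X, y, seed=7)
        assert a.fold_accuracies == b.fold_accuracies
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_mean_is_mean_of_folds(self, rng):
        X, y = make_clusters(rng, spread=2.0)
        res = cross_validate(X, y, seed=3)
        assert abs(res.mean_accuracy - np.mean(res.fold_accuracies)) < 1e-9

    def test_insufficient_class_samples_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array(["upright"] * 6 + ["lean_back"] * 2)
        with pytest.raises(ValueError, match="insufficient samples"):
            cross_validate(X, y, folds=5)


class TestGridSearch:
    def test_winner_matches_independent_maximization(self, rng):
        X, y = make_clusters(rng, n_per=15, spread=3.5)
        grid = {"C": [0.5, 1.3], "beta": [1.4], "theta": [0.8], "degree": [2, 3]}
        cfg, res = svm_grid_search(X, y, "polynomial", grid, folds=3, seed=0)

        best = None
        for C in grid["C"]:
            for d in grid["degree"]:
                r = cross_validate(X, y, SVMConfig("polynomial", C=C, beta=1.4,
                                                   theta=0.8, degree=d), folds=3, seed=0)
                if best is None or r.mean_accuracy > best[1]:
                    best = ((C, d), r.mean_accuracy)
        assert (cfg.C, cfg.degree) == best[0]
        assert res.mean_accuracy == best[1]

    def test_empty_grid_rejected(self, rng):
        X, y = make_clusters(rng, n_per=6)
        with pytest.raises(ValueError, match="empty grid"):
            svm_grid_search(X, y, "gaussian", {"C": []}, folds=2)


class TestEndToEnd:
    def test_pipeline_features_separate_postures(self, small_noisy_dataset, bank):
        X, y = features_from_samples(small_noisy_dataset, bank=bank)
        assert X.shape == (len(small_noisy_dataset), 3)
        res = cross_validate(X, y, SVMConfig(), folds=3, seed=0)
        assert res.mean_accuracy >= 0.7  # moderate noise, small n
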