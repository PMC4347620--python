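"""Texture descriptor registry, PCA reduction and the SVR pipeline."""

import numpy as np
import pytest

from beefmetrics.features import (
    COLOR_FEATURE_NAMES,
    FEATURE_NAMES,
    extract_color_features,
    extract_us_features,
    fit_pca,
    load_model,
    predict_imf,
    save_model,
    train_imf_model,
)


def feature(vec, name):
    return vec[FEATURE_NAMES.index(name)]


class TestUSFeatures:
    def test_registry_has_42_unique_names(self):
        assert len(FEATURE_NAMES) == 42
        assert len(set(FEATURE_NAMES)) == 42

    def test_vector_length_and_determinism(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 256, size=(80, 80)).astype(np.uint8)
        v1 = extract_us_features(patch)
        v2 = extract_us_features(patch)
        assert v1.shape == (42,)
        assert np.array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_constant_patch_degenerate_values(self):
        v = extract_us_features(np.full((80, 80), 77))
        assert feature(v, "gradient_mean_s1") == 0.0
        assert feature(v, "gradient_std_s1") == 0.0
        assert feature(v, "glcm_energy_0_1") == 1.0
        assert feature(v, "glcm_contrast_0_1") == 0.0
        for p in (20, 40, 60, 80):
            assert feature(v, f"hist_p{p}") == 77.0
        assert feature(v, "hist_skewness") == 0.0
        assert np.all(np.isfinite(v))

    def test_checkerboard_contrast_matches_pair_counting(self):
        cb = (np.indices((80, 80)).sum(axis=0) % 2 * 255).astype(np.uint8)
        v = extract_us_features(cb)
        codes = cb // 8
        # brute-force symmetric normalized pair counting, offset (0, 1)
        counts = np.zeros((32, 32))
        for r in range(80):
            for c in range(79):
                i, j = codes[r, c], codes[r, c + 1]
                counts[i, j] += 1
                counts[j, i] += 1
        counts /= counts.sum()
        ii, jj = np.mgrid[0:32, 0:32]
        expected = float((counts * (ii - jj) ** 2).sum())
        assert feature(v, "glcm_contrast_0_1") == pytest.approx(expected, abs=1e-9)

    def test_wrong_patch_size_rejected(self):
        with pytest.raises(ValueError):
            extract_us_features(np.zeros((64, 64)))


class TestColorFeatures:
    def test_uniform_region_channel_means(self):
        img = np.zeros((50, 60, 3), dtype=np.uint8)
        img[10:40, 10:50] = (120, 80, 40)
        mask = np.zeros((50, 60), dtype=bool)
        mask[10:40, 10:50] = True
        v = extract_color_features(img, mask)
        assert tuple(v[:3]) == (120.0, 80.0, 40.0)
        assert len(v) == len(COLOR_FEATURE_NAMES)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(60, 60, 3)).astype(np.uint8)
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:55, 5:55] = True
        assert np.array_equal(extract_color_features(img, mask),
                              extract_color_features(img, mask))

    def test_doubling_region_doubles_counts(self):
        rng = np.random.default_rng(2)
        tile = rng.integers(0, 256, size=(40, 40, 3)).astype(np.uint8)
        img1 = tile
        mask1 = np.ones((40, 40), dtype=bool)
        img2 = np.concatenate([tile, tile], axis=1)
        mask2 = np.ones((40, 80), dtype=bool)
        v1 = extract_color_features(img1, mask1)
        v2 = extract_color_features(img2, mask2)
        for c in range(3):
            assert v2[3 + c] == 2 * v1[3 + c]  # above-Otsu counts double
            assert v2[c] == pytest.approx(v1[c])  # means unchanged

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            extract_color_features(np.zeros((20, 20, 3), dtype=np.uint8),
                                   np.zeros((20, 20), dtype=bool))


class TestPCA:
    def test_rank3_data_concentrates_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 3)) @ rng.normal(size=(3, 42))
        X += 1e-3 * rng.normal(size=X.shape)
        model = fit_pca(X, k=10)
        assert model.explained_variance_ratio[:3].sum() >= 0.99

    def test_loadings_orthonormal_and_ratios_match_eigendecomposition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 42)) * rng.uniform(0.1, 5.0, size=42)
        model = fit_pca(X, k=10)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(10), atol=1e-8)
        # independent oracle: eigenvalues of the sample covariance
        cov = np.cov(X, rowvar=False, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expect = evals / evals.sum()
        assert np.allclose(model.explained_variance_ratio, expect[:10], atol=1e-8)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(5)
        X = rng.normal(loc=3.0, size=(60, 42))
        model = fit_pca(X, k=10)
        z = model.transform(X.mean(axis=0))
        assert np.allclose(z, 0.0, atol=1e-10)

    def test_rank_deficient_warns(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 42))
        with pytest.warns(UserWarning, match="rank"):
            model = fit_pca(X, k=10)
        assert np.all(model.explained_variance_ratio[2:] < 1e-10)


def _synthetic_feature_set(n=200, seed=0, noise=0.3):
    """Features carrying a latent scalar in a few columns, affine labels."""
    rng = np.random.default_rng(seed)
    latent = rng.uniform(0.5, 9.5, size=n)
    X = rng.normal(size=(n, 42))
    X[:, 5] += 2.0 * latent
    X[:, 17] += 0.5 * latent**1.1
    X[:, 30] -= latent
    y = 2.0 + 0.8 * latent + rng.normal(0, noise, size=n)
    return X, y, latent


class TestIMFModel:
    def test_synthetic_recovery(self):
        X, y, _ = _synthetic_feature_set(n=200, seed=1)
        tr = np.arange(140)
        te = np.arange(140, 200)
        model = train_imf_model(X[tr], y[tr])
        pred = predict_imf(model, X[te])
        ss_res = np.sum((pred - y[te]) ** 2)
        ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.8
        rmse = np.sqrt(np.mean((pred - y[te]) ** 2))
        assert rmse <= 2 * 0.3 + 0.3  # about twice the injected label noise

    def test_reduction_is_ten_components(self):
        X, y, _ = _synthetic_feature_set(n=60, seed=2)
        model = train_imf_model(X, y)
        assert model.pca.loadings.shape == (42, 10)

    def test_constant_labels_predict_constant(self):
        X, _, _ = _synthetic_feature_set(n=40, seed=3)
        with pytest.warns(UserWarning, match="constant"):
            model = train_imf_model(X, np.full(40, 3.0))
        pred = predict_imf(model, X[:5])
        assert np.all(np.abs(pred - 3.0) <= 1e-3)

    def test_unbounded_support_vectors_sit_on_tube(self):
        X, y, _ = _synthetic_feature_set(n=80, seed=4, noise=0.05)
        model = train_imf_model(X, y)
        Z = model._reduce(X)
        svr = model.svr
        pred = svr.predict(Z[svr.support_])
        resid = np.abs(pred - y[svr.support_])
        unbounded = np.abs(svr.dual_coef_.ravel()) < model.regularization - 1e-9
        if unbounded.any():
            assert np.all(resid[unbounded] <= svr.epsilon + model.tolerance + 1e-6)

    def test_prediction_deterministic_and_shape_checked(self):
        X, y, _ = _synthetic_feature_set(n=50, seed=5)
        model = train_imf_model(X, y)
        p1 = predict_imf(model, X[0])
        p2 = predict_imf(model, X[0])
        assert p1 == p2
        with pytest.raises(ValueError):
            predict_imf(model, X[0, :40])

    def test_serialization_round_trip(self, tmp_path):
        X, y, _ = _synthetic_feature_set(n=50, seed=6)
        model = train_imf_model(X, y)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.gamma == model.gamma
        assert loaded.tolerance == model.tolerance
        assert np.array_equal(predict_imf(loaded, X), predict_imf(model, X))

    def test_too_few_samples_rejected(self):
        X, y, _ = _synthetic_feature_set(n=10, seed=7)
        with pytest.raises(ValueError):
            train_imf_model(X, y)
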