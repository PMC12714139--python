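import numpy as np
import pytest

from planmet import ValidationError, cv_anova, pca, plsda_fit, q2_crossval
from planmet.multivariate import _nipals, _one_hot


def separated_classes(rng, n_per=20, m=50, distance=10.0):
    """Two Gaussian classes with centroids ``distance`` sds apart."""
    x = rng.normal(size=(2 * n_per, m))
    x[:n_per, :5] += distance / np.sqrt(5)
    labels = ["a"] * n_per + ["b"] * n_per
    return x, labels


class TestPca:
    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(15, 8))
        scores, loadings, r2x = pca(x, 4)
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        for k in range(4):
            sign = np.sign(loadings[:, k] @ vt[k])
            np.testing.assert_allclose(loadings[:, k], sign * vt[k],
                                       atol=1e-8)
            np.testing.assert_allclose(scores[:, k], sign * u[:, k] * s[k],
                                       atol=1e-8)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 6))
        _, _, r2x = pca(x, 3)
        sk = PCA(n_components=3).fit(x)
        np.testing.assert_allclose(r2x, sk.explained_variance_ratio_,
                                   atol=1e-10)

    def test_full_rank_variance_sums_to_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 6))
        _, _, r2x = pca(x, 6)
        assert r2x.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_samples_keep_loading_directions(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 5))
        _, load1, _ = pca(x, 2)
        _, load2, _ = pca(np.vstack([x, x]), 2)
        for k in range(2):
            cos = abs(load1[:, k] @ load2[:, k])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValidationError):
            pca(np.eye(4), 4)


class TestPlsda:
    def test_exact_recovery_single_latent_direction(self):
        """Y exactly linear in one latent X direction: R2Y = 1 at A = 1."""
        rng = np.random.default_rng(4)
        direction = rng.normal(size=30)
        # one latent value per class, so the centred one-hot Y is an exact
        # affine function of the latent score
        t = np.concatenate([np.full(10, 1.4), np.full(10, -0.6)])
        x = np.outer(t, direction)
        labels = ["hi"] * 10 + ["lo"] * 10
        model = plsda_fit(x, labels, n_components=1, cross_validate=False)
        assert model.r2y_cum == pytest.approx(1.0, abs=1e-6)

    def test_prediction_invariant_to_feature_order(self):
        rng = np.random.default_rng(5)
        x, labels = separated_classes(rng, n_per=8, m=12, distance=3)
        perm = rng.permutation(12)
        m1 = plsda_fit(x, labels, n_components=2, cross_validate=False)
        m2 = plsda_fit(x[:, perm], labels, n_components=2,
                       cross_validate=False)
        np.testing.assert_allclose(m1.predict(x), m2.predict(x[:, perm]),
                                   atol=1e-8)

    def test_full_rank_explains_all_x_variance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(8, 5))
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        model = plsda_fit(x, labels, n_components=5, cross_validate=False)
        assert model.r2x_cum == pytest.approx(1.0, abs=1e-9)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(7)
        x, labels = separated_classes(rng, n_per=10, m=20, distance=2)
        model = plsda_fit(x, labels, n_components=4, cross_validate=False)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            plsda_fit(np.eye(4), ["a"] * 4, n_components=1)

    def test_one_component_weights_proportional_to_covariance(self):
        """Single y column: the first PLS weight vector is cov(X, y)."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 10))
        y = (x[:, 0] + 0.5 * rng.normal(size=30))[:, None]
        xc, yc = x - x.mean(0), y - y.mean(0)
        fit = _nipals(xc, yc, 1)
        cov = xc.T @ yc[:, 0]
        cos = abs(fit["W"][:, 0] @ cov / np.linalg.norm(cov))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_first_weight_matches_sklearn_direction(self):
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(9)
        x, labels = separated_classes(rng, n_per=10, m=15, distance=3)
        model = plsda_fit(x, labels, n_components=1, cross_validate=False)
        y, _ = _one_hot(labels)
        sk = PLSRegression(n_components=1, scale=False).fit(x, y)
        w_sk = sk.x_weights_[:, 0]
        # per-column dominant direction agrees up to sign
        cos = abs(model.weights[:, 0] @ w_sk)
        assert cos == pytest.approx(1.0, abs=1e-6)


class TestCrossValidation:
    def test_q2_high_for_separated_classes(self):
        rng = np.random.default_rng(10)
        x, labels = separated_classes(rng)
        q2, press = q2_crossval(x, labels, 2, folds=7, seed=0)
        assert q2 > 0.8
        assert press.shape == (2,)

    def test_q2_low_under_permutation(self):
        rng = np.random.default_rng(11)
        x, labels = separated_classes(rng)
        q2s = [q2_crossval(x, rng.permutation(labels).tolist(), 1,
                           folds=7, seed=0)[0] for _ in range(100)]
        assert np.mean(q2s) <= 0.05

    def test_q2_not_above_r2y(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            x, labels = separated_classes(rng, n_per=12, m=20,
                                          distance=rng.uniform(0, 4))
            model = plsda_fit(x, labels, n_components=2, seed=1)
            assert model.q2_cum <= model.r2y_cum + 1e-9

    def test_leave_one_out_runs_and_is_finite(self):
        rng = np.random.default_rng(13)
        x, labels = separated_classes(rng, n_per=6, m=10, distance=3)
        q2, _ = q2_crossval(x, labels, 1, folds=len(labels), seed=0)
        assert np.isfinite(q2)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(14)
        x, labels = separated_classes(rng, n_per=10, m=15, distance=1)
        a = q2_crossval(x, labels, 2, folds=5, seed=42)
        b = q2_crossval(x, labels, 2, folds=5, seed=42)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_triggers_warning(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=(9, 5))
        labels = ["a"] * 3 + ["b"] * 6
        with pytest.warns(UserWarning, match="stratification relaxed"):
            q2_crossval(x, labels, 1, folds=5, seed=0)


class TestCvAnova:
    def test_press_equal_ssy_gives_p_one(self):
        f, p = cv_anova(2, press_total=10.0, ssy_total=10.0, n_samples=20)
        assert f == 0.0 and p == 1.0

    def test_separated_classes_highly_significant(self):
        rng = np.random.default_rng(16)
        x, labels = separated_classes(rng)
        model = plsda_fit(x, labels, n_components=2, seed=0)
        assert model.cv_anova_p < 1e-4

    def test_permutation_null_is_conservative(self):
        """Permuted labels reject at most at the nominal rate (the
        cross-validated F carries an atom at p = 1, making the test
        conservative rather than uniform)."""
        rng = np.random.default_rng(17)
        x, labels = separated_classes(rng)
        ps = []
        for _ in range(100):
            m = plsda_fit(x, rng.permutation(labels).tolist(),
                          n_components=1, seed=0)
            ps.append(m.cv_anova_p)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.07
        assert np.mean(np.asarray(ps) == 1.0) > 0.2

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValidationError):
            cv_anova(5, 1.0, 2.0, n_samples=6)


def test_auto_component_choice_capped_and_positive(small_design):
    from planmet import filter_features, log10_transform, uv_scale
    matrix, sheet, _pw, _truth = small_design
    scaled = uv_scale(log10_transform(filter_features(matrix)[0]))
    sub = scaled.sheet
    mask = (sub["genotype"] == "EY05103").to_numpy()
    model = plsda_fit(scaled.intensities[:, mask].T,
                      sub.loc[mask, "treatment"].tolist(),
                      n_components=None, folds=7, seed=0)
    assert 1 <= model.n_components <= 5
    assert model.q2_cum <= 1.0
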