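import numpy as np
import pytest

from pkqspr.latent import (
    cross_validate_q2,
    dmodx,
    fit_pca,
    fit_pls2,
    hotelling_outliers,
    pca_q2x,
    reduce_variables,
    select_n_components,
    vip_scores,
    weight_plot_data,
)


def autoscale(M):
    return (M - M.mean(0)) / M.std(0, ddof=1)


@pytest.fixture(scope="module")
def linear_xy():
    """Strong linear 2-response signal on 8 descriptors plus noise."""
    rng = np.random.default_rng(3)
    X = autoscale(rng.normal(size=(80, 8)))
    beta = np.zeros((8, 2))
    beta[0] = [1.0, -0.8]
    beta[1] = [0.6, 0.5]
    Y = autoscale(X @ beta + 0.1 * rng.normal(size=(80, 2)))
    return X, Y, beta


class TestPCA:
    def test_rank1_single_component_explains_all(self):
        t = np.linspace(-1, 1, 20)
        p = np.array([1.0, -2.0, 0.5])
        X = np.outer(t, p)
        model = fit_pca(X, 1)
        assert model.r2x_cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_first_loading_matches_svd(self):
        X = autoscale(np.random.default_rng(0).normal(size=(30, 6)))
        model = fit_pca(X, 2)
        _, _, vt = np.linalg.svd(X)
        v1 = vt[0]
        assert min(np.linalg.norm(model.loadings[:, 0] - v1), np.linalg.norm(model.loadings[:, 0] + v1)) < 1e-7

    def test_loadings_orthonormal_scores_orthogonal(self):
        X = autoscale(np.random.default_rng(1).normal(size=(40, 7)))
        model = fit_pca(X, 4)
        G = model.loadings.T @ model.loadings
        assert np.allclose(G, np.eye(4), atol=1e-8)
        S = model.scores.T @ model.scores
        assert np.abs(S - np.diag(np.diag(S))).max() < 1e-7
        assert np.all(np.diff(model.r2x_cum) >= 0)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.eye(3), 3)

    def test_q2x_positive_for_structured_data(self):
        rng = np.random.default_rng(2)
        T = rng.normal(size=(60, 2))
        P = rng.normal(size=(10, 2))
        X = T @ P.T + 0.1 * rng.normal(size=(60, 10))
        assert pca_q2x(autoscale(X), 2) > 0.5


class TestHotelling:
    def test_origin_not_flagged_and_injected_outlier_flagged(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 5))
        X[0] = 0.0  # center point
        X[1] = 10.0  # gross outlier, ~10 sigma on every axis
        model = fit_pca(autoscale(X), 2)
        flagged = hotelling_outliers(model, alpha=0.05)
        assert 1 in flagged
        assert 0 not in flagged

    def test_alpha_one_flags_everything(self):
        X = autoscale(np.random.default_rng(1).normal(size=(30, 4)))
        model = fit_pca(X, 2)
        assert len(hotelling_outliers(model, alpha=1.0)) == 30


class TestPLS2:
    def test_single_variable_single_response_is_ls_slope(self):
        rng = np.random.default_rng(0)
        x = autoscale(rng.normal(size=(50, 1)))
        y = autoscale(2.0 * x + 0.1 * rng.normal(size=(50, 1)))
        model = fit_pls2(x, y, 1)
        slope = float(np.linalg.lstsq(x, y, rcond=None)[0][0, 0])
        assert model.coef[0, 0] == pytest.approx(slope, abs=1e-10)

    def test_full_rank_equals_ols(self, linear_xy):
        X, Y, _ = linear_xy
        model = fit_pls2(X, Y, 8)
        B_ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        assert np.abs(model.coef - B_ols).max() < 1e-6

    def test_sign_recovery(self, linear_xy):
        X, Y, beta = linear_xy
        model = fit_pls2(X, Y, 3)
        nz = beta != 0
        assert np.array_equal(np.sign(model.coef[nz]), np.sign(beta[nz]))

    def test_structural_invariants(self, linear_xy):
        X, Y, _ = linear_xy
        model = fit_pls2(X, Y, 3)
        S = model.scores.T @ model.scores
        assert np.abs(S - np.diag(np.diag(S))).max() < 1e-8
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0)
        assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-8)
        # B = W* C' reproduces the training predictions T C'
        assert np.abs(X @ model.coef - model.scores @ model.y_loadings.T).max() < 1e-8

    def test_r2y_nondecreasing_in_components(self, linear_xy):
        X, Y, _ = linear_xy
        r2 = [fit_pls2(X, Y, a).r2y for a in range(1, 6)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_prediction_invariant_to_variable_order(self, linear_xy):
        X, Y, _ = linear_xy
        perm = np.random.default_rng(5).permutation(X.shape[1])
        m1 = fit_pls2(X, Y, 3)
        m2 = fit_pls2(X[:, perm], Y, 3)
        assert np.allclose(m1.predict(X), m2.predict(X[:, perm]), atol=1e-8)

    def test_agrees_with_reference_pls_implementation(self, linear_xy):
        """Cross-check: same predictions as an independent PLS implementation."""
        from sklearn.cross_decomposition import PLSRegression

        X, Y, _ = linear_xy
        ours = fit_pls2(X, Y, 3)
        ref = PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=10000).fit(X, Y)
        assert np.allclose(ours.predict(X), ref.predict(X), atol=1e-8)

    def test_degenerate_y_rejected(self):
        X = autoscale(np.random.default_rng(0).normal(size=(20, 3)))
        Y = np.zeros((20, 1))
        with pytest.raises(ValueError):
            fit_pls2(X, Y, 1)


class TestCrossValidation:
    def test_noise_free_signal_high_q2(self):
        rng = np.random.default_rng(3)
        X = autoscale(rng.normal(size=(200, 8)))
        beta = np.zeros((8, 2))
        beta[0] = [1.0, -0.8]
        beta[1] = [0.6, 0.5]
        Y = autoscale(X @ beta)
        res = cross_validate_q2(X, Y, 4, seed=0)
        assert res["pooled"] > 0.99
        assert np.all(res["per_response"] > 0.99)

    def test_independent_y_nonpositive_q2_in_expectation(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(50):
            X = autoscale(rng.normal(size=(30, 5)))
            Y = autoscale(rng.normal(size=(30, 2)))
            vals.append(cross_validate_q2(X, Y, 2, seed=0)["pooled"])
        assert np.mean(vals) <= 0

    def test_each_left_out_once(self, linear_xy):
        X, Y, _ = linear_xy
        res = cross_validate_q2(X, Y, 2, seed=1)
        assert not np.isnan(res["predictions"]).any()

    def test_fold_determinism(self, linear_xy):
        X, Y, _ = linear_xy
        a = cross_validate_q2(X, Y, 2, seed=3)["pooled"]
        b = cross_validate_q2(X, Y, 2, seed=3)["pooled"]
        assert a == b


class TestVIPAndDiagnostics:
    def test_informative_variable_has_max_vip(self):
        rng = np.random.default_rng(0)
        X = autoscale(rng.normal(size=(100, 10)))
        y = autoscale(X[:, [4]] + 0.05 * rng.normal(size=(100, 1)))
        model = fit_pls2(X, y, 2)
        assert int(np.argmax(model.vip)) == 4

    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(1)
        x = autoscale(rng.normal(size=(30, 1)))
        y = autoscale(x + 0.1 * rng.normal(size=(30, 1)))
        assert vip_scores(fit_pls2(x, y, 1))[0] == pytest.approx(1.0)

    def test_vip_equivariant_under_permutation(self):
        rng = np.random.default_rng(2)
        X = autoscale(rng.normal(size=(50, 6)))
        Y = autoscale(X[:, :2] @ np.array([[1.0], [0.5]]) + 0.1 * rng.normal(size=(50, 1)))
        perm = np.array([3, 0, 5, 1, 4, 2])
        v1 = fit_pls2(X, Y, 2).vip
        v2 = fit_pls2(X[:, perm], Y, 2).vip
        assert np.allclose(v1[perm], v2, atol=1e-8)

    def test_weight_plot_projections(self):
        """A descriptor built to track response 0 projects positively onto it."""
        rng = np.random.default_rng(3)
        y0 = rng.normal(size=200)
        y1 = rng.normal(size=200)
        X = autoscale(np.column_stack([y0 + 0.05 * rng.normal(size=200),
                                       -y0 + 0.05 * rng.normal(size=200),
                                       rng.normal(size=200)]))
        Y = autoscale(np.column_stack([y0, y1]))
        model = fit_pls2(X, Y, 2, response_names=("r0", "r1"), variable_names=["pos", "neg", "null"])
        df, responses = weight_plot_data(model)
        proj = df.set_index("variable")["proj_r0"]
        assert proj["pos"] > 0 > proj["neg"]
        assert abs(proj["null"]) < 0.5 * abs(proj["pos"])
        assert list(responses["response"]) == ["r0", "r1"]

    def test_weight_plot_needs_two_components(self, linear_xy):
        X, Y, _ = linear_xy
        with pytest.raises(ValueError):
            weight_plot_data(fit_pls2(X, Y, 1))

    def test_dmodx_mean_near_one_and_outlier_large(self, linear_xy):
        X, Y, _ = linear_xy
        model = fit_pls2(X, Y, 2)
        d_train = dmodx(model, X)
        assert d_train.mean() == pytest.approx(1.0, abs=0.25)
        X_off = X.copy()
        X_off[0] += 15.0 * np.ones(X.shape[1])
        assert dmodx(model, X_off)[0] > 5

    def test_in_plane_observation_zero_dmodx(self):
        rng = np.random.default_rng(4)
        T = rng.normal(size=(40, 2))
        P = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        X = T @ P.T
        y = autoscale(T[:, [0]])
        model = fit_pls2(X, y, 2)
        assert np.abs(dmodx(model, X)).max() < 1e-6


class TestVariableReduction:
    def test_noise_variables_removed(self):
        rng = np.random.default_rng(0)
        X_inf = rng.normal(size=(150, 4))
        X_noise = rng.normal(size=(150, 8))
        X = autoscale(np.hstack([X_inf, X_noise]))
        Y = autoscale(X_inf @ np.array([[1.0, -0.5], [0.8, 0.4], [-0.6, 0.9], [0.5, -0.7]])
                      + 0.1 * rng.normal(size=(150, 2)))
        names = [f"inf{j}" for j in range(4)] + [f"noise{j}" for j in range(8)]
        selected, model, audit = reduce_variables(X, Y, variable_names=names, vip_cutoff=0.8,
                                                  n_components=2, max_rounds=3, seed=0)
        assert set(f"inf{j}" for j in range(4)) <= set(selected)
        assert len([s for s in selected if s.startswith("noise")]) <= 2
        assert audit[0]["round"] == 0 and len(audit) >= 2

    def test_zero_cutoff_is_identity(self, linear_xy):
        X, Y, _ = linear_xy
        selected, _, _ = reduce_variables(X, Y, vip_cutoff=0.0, n_components=2, seed=0)
        assert len(selected) == X.shape[1]

    def test_component_selection_caps(self, linear_xy):
        X, Y, _ = linear_xy
        a = select_n_components(X, Y, max_components=10, seed=0)
        assert 1 <= a <= 10
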