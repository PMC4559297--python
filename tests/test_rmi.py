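"""Unit and property tests for the copula NN-graph multi-information estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dmi.rmi import (
    GammaTable,
    RenyiMultiInformation,
    calibrate_gamma,
    copula_transform,
    gaussian_copula_rmi,
    nn_graph_length,
    renyi_entropy,
    renyi_multi_information,
)


# ---------------------------------------------------------------- copula
class TestCopulaTransform:
    def test_simple_ranks(self):
        col = np.array([[3.1], [1.2], [2.0]])
        np.testing.assert_allclose(copula_transform(col)[:, 0], [3 / 3, 1 / 3, 2 / 3])

    def test_ties_share_maximum_rank(self):
        col = np.array([[1.0], [1.0], [2.0]])
        np.testing.assert_allclose(copula_transform(col)[:, 0], [2 / 3, 2 / 3, 3 / 3])

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda x: x**3, np.arctan, lambda x: 5 * x - 2]
    )
    def test_invariant_under_strictly_increasing_maps(self, transform):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        np.testing.assert_array_equal(
            copula_transform(X), copula_transform(transform(X))
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(3, 12), st.integers(2, 4)),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_column_structure(self, X):
        Z = copula_transform(X)
        n = X.shape[0]
        assert np.all((Z > 0) & (Z <= 1))
        # every column's maximum is exactly 1; values live on the grid k/n
        assert np.all(Z.max(axis=0) == 1.0)
        np.testing.assert_array_equal(np.round(Z * n), Z * n)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            copula_transform(np.empty((0, 3)))

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            copula_transform(X)


# ---------------------------------------------------------------- graph length
def brute_force_lp(X, neighbor_set, p):
    """Quadratic-loop oracle: all pairwise distances, sorted per point."""
    n = len(X)
    total = 0.0
    for i in range(n):
        d = np.sort(np.linalg.norm(X - X[i], axis=1))  # d[0] == 0 (self)
        total += sum(d[k] ** p for k in neighbor_set)
    return total


class TestNNGraphLength:
    def test_collinear_hand_example_single_neighbor(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        assert nn_graph_length(pts, {1}, p=1.0) == pytest.approx(4.0)

    def test_collinear_hand_example_two_neighbors(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        assert nn_graph_length(pts, {1, 2}, p=1.0) == pytest.approx(12.0)

    @pytest.mark.parametrize("n,d,S", [(50, 2, (1,)), (200, 3, (1, 2, 3)), (120, 5, (2, 4))])
    def test_matches_brute_force_oracle(self, n, d, S):
        rng = np.random.default_rng(n + d)
        X = rng.random((n, d))
        assert nn_graph_length(X, S, p=0.03) == pytest.approx(
            brute_force_lp(X, S, 0.03), rel=1e-10
        )

    def test_large_sample_tree_path_matches_brute_force(self):
        # n above the internal brute-force cutoff exercises the tree backend
        rng = np.random.default_rng(1)
        X = rng.random((900, 3))
        assert nn_graph_length(X, (1, 2), p=0.5) == pytest.approx(
            brute_force_lp(X, (1, 2), 0.5), rel=1e-9
        )

    def test_duplicate_points_warn_and_contribute_zero(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="duplicate"):
            total = nn_graph_length(pts, {1}, p=1.0)
        # the coincident pair contributes 0 + 0; only the third point's
        # nearest neighbor (distance 1) counts
        assert total == pytest.approx(1.0)

    def test_all_coincident_is_degenerate(self):
        pts = np.zeros((4, 2))
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValueError, match="degenerate"):
                nn_graph_length(pts, {1}, p=1.0)

    def test_neighbor_index_bounds(self):
        pts = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError):
            nn_graph_length(pts, {5}, p=1.0)
        with pytest.raises(ValueError):
            nn_graph_length(pts, set(), p=1.0)


# ---------------------------------------------------------------- calibration
class TestGammaCalibration:
    def test_gamma_positive_and_reproducible(self):
        g1 = calibrate_gamma(3, 0.03, (1,), n=500, reps=5, rng=np.random.default_rng(42))
        g2 = calibrate_gamma(3, 0.03, (1,), n=500, reps=5, rng=np.random.default_rng(42))
        assert g1 > 0
        assert g1 == g2

    def test_calibration_identity_on_uniform_sample(self):
        # entropy of a fresh uniform cube sample is ~0 within the replicate spread
        table = GammaTable(seed=0, reps=20)
        d, alpha = 3, 0.99
        p = d * (1 - alpha)
        n = 2000
        gamma = table.get_or_calibrate(d, p, (1, 2, 3), n, reference="uniform")
        sd = table.replicate_sd(d, p, (1, 2, 3), n, reference="uniform")
        X = np.random.default_rng(7).random((n, d))
        h = renyi_entropy(X, alpha, (1, 2, 3), gamma=gamma)
        assert abs(h) < 3 * (sd / gamma) / (1 - alpha)

    def test_neighbor_index_exceeding_calibration_n_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gamma(2, 0.02, (50,), n=40, reps=2)

    def test_table_roundtrip(self, tmp_path):
        table = GammaTable(seed=3, reps=4)
        g = table.get_or_calibrate(2, 0.02, (1, 2), 100, reference="copula")
        table.save(tmp_path / "gamma.tsv")
        loaded = GammaTable.load(tmp_path / "gamma.tsv")
        assert loaded.get_or_calibrate(2, 0.02, (1, 2), 100, reference="copula") == g


# ---------------------------------------------------------------- entropy
def gaussian_renyi_entropy(cov, alpha):
    """Closed-form Rényi entropy of N(0, cov), derived independently:
    H_a = 0.5*log det(2*pi*cov) - (d/2) * log(a)/(1-a)."""
    d = cov.shape[0]
    _, logdet = np.linalg.slogdet(2 * np.pi * np.asarray(cov))
    return 0.5 * logdet - 0.5 * d * np.log(alpha) / (1 - alpha)


class TestRenyiEntropy:
    def test_gaussian_closed_form(self):
        d, alpha, n = 3, 0.99, 4000
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n, d))
        table = GammaTable(seed=0, reps=20)
        gamma = table.get_or_calibrate(d, d * (1 - alpha), (1, 2, 3), n)
        h = renyi_entropy(X, alpha, (1, 2, 3), gamma=gamma)
        assert h == pytest.approx(gaussian_renyi_entropy(np.eye(d), alpha), abs=0.25)

    def test_scaling_shifts_entropy_by_d_log_c(self):
        # L_p scales exactly as c**p, so the shift is exact, not asymptotic
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 4))
        alpha, S, c = 0.9, (1, 2), 2.5
        gamma = calibrate_gamma(4, 4 * (1 - alpha), S, n=300, reps=5,
                                rng=np.random.default_rng(0))
        h1 = renyi_entropy(X, alpha, S, gamma=gamma)
        h2 = renyi_entropy(c * X, alpha, S, gamma=gamma)
        assert h2 - h1 == pytest.approx(4 * np.log(c), rel=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ValueError):
                renyi_entropy(np.zeros((10, 2)), 0.99, (1,), gamma=1.0)


# ---------------------------------------------------------------- multi-information
def bivariate_gaussian_rmi_by_quadrature(rho, alpha):
    """Numerical-integration oracle for the order-alpha divergence between a
    correlated bivariate normal and the product of its (standard) marginals."""
    from scipy import integrate, stats

    det = 1 - rho**2

    def integrand(y, x):
        q = (x * x - 2 * rho * x * y + y * y) / det
        f = np.exp(-0.5 * q) / (2 * np.pi * np.sqrt(det))
        g = stats.norm.pdf(x) * stats.norm.pdf(y)
        return f**alpha * g ** (1 - alpha)

    val, _ = integrate.dblquad(integrand, -8, 8, -8, 8, epsabs=1e-10)
    return np.log(val) / (alpha - 1)


class TestRenyiMultiInformation:
    def test_closed_form_matches_quadrature_oracle(self):
        for rho in (0.3, 0.6, 0.9):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            assert gaussian_copula_rmi(cov, 0.99) == pytest.approx(
                bivariate_gaussian_rmi_by_quadrature(rho, 0.99), abs=1e-6
            )

    def test_closed_form_scale_invariance(self):
        cov = np.array([[4.0, 0.6], [0.6, 0.25]])
        scale = np.diag([3.0, 0.2])
        assert gaussian_copula_rmi(cov, 0.95) == pytest.approx(
            gaussian_copula_rmi(scale @ cov @ scale, 0.95)
        )

    def test_independent_gaussians_near_zero(self):
        X = np.random.default_rng(3).normal(size=(2000, 3))
        assert abs(renyi_multi_information(X)) < 0.05

    def test_dependent_bivariate_gaussian_matches_closed_form(self):
        rho = 0.6
        cov = np.array([[1.0, rho], [rho, 1.0]])
        X = np.random.default_rng(4).multivariate_normal([0, 0], cov, size=4000)
        est = renyi_multi_information(X)
        assert est == pytest.approx(gaussian_copula_rmi(cov, 0.99), abs=0.04)

    def test_rank_invariance_is_exact(self):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=300)
        table = GammaTable(seed=0, reps=5)
        a = renyi_multi_information(X, gamma_table=table)
        b = renyi_multi_information(np.column_stack([np.exp(X[:, 0]), X[:, 1] ** 3]),
                                    gamma_table=table)
        assert a == b

    def test_permuting_a_column_destroys_dependence(self):
        rng = np.random.default_rng(10)
        X = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=1500)
        table = GammaTable(seed=0, reps=10)
        dependent = renyi_multi_information(X, gamma_table=table)
        X[:, 1] = rng.permutation(X[:, 1])
        shuffled = renyi_multi_information(X, gamma_table=table)
        assert dependent > 0.15
        assert abs(shuffled) < 0.07

    def test_too_few_variables_rejected(self):
        with pytest.raises(ValueError):
            renyi_multi_information(np.random.default_rng(0).random((100, 1)))

    def test_min_samples_enforced(self):
        with pytest.raises(ValueError, match="samples"):
            renyi_multi_information(np.random.default_rng(0).random((10, 2)))

    def test_alpha_boundaries_rejected(self):
        X = np.random.default_rng(0).random((50, 2))
        for bad in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(ValueError, match="alpha"):
                renyi_multi_information(X, alpha=bad, min_samples=2)

    def test_estimator_class_params_roundtrip(self):
        est = RenyiMultiInformation(alpha=0.5, neighbor_set=(1, 4))
        assert est.get_params()["alpha"] == 0.5
        est.set_params(alpha=0.7)
        rng = np.random.default_rng(2)
        est.fit(rng.random((100, 2)))
        assert est.n_features_in_ == 2
        assert est.p_ == pytest.approx(2 * 0.3)
        assert np.isfinite(est.mi_)


def test_runtime_growth_is_not_worse_than_quadratic():
    """One evaluation should scale ~O(n^2 d + n d); allow generous slack."""
    import time

    rng = np.random.default_rng(0)
    table = GammaTable(seed=0, reps=2)

    def timed(n):
        X = rng.normal(size=(n, 3))
        t0 = time.perf_counter()
        renyi_multi_information(X, gamma_table=table)
        return time.perf_counter() - t0

    timed(400)  # warm-up (calibration cache, JIT-free but page-warm)
    t1 = min(timed(400) for _ in range(3))
    t2 = min(timed(1600) for _ in range(3))
    assert t2 / t1 < 60  # quadratic growth predicts ~16x
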