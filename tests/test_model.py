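import numpy as np
import pytest
import scipy.linalg as sla
import scipy.stats

from icarlap import (
    ICARParams,
    ModelData,
    edges_to_graph,
    icar_log_density,
    icar_quadratic,
    joint_nll,
    linear_predictor,
    relative_risk,
)
from icarlap.fixtures import cycle_graph, path_graph
from icarlap.model import ModelInputError, log_pdet_Q, icar_normalizing_constant

from conftest import random_graph


class TestLinearPredictor:
    def test_null_everything_gives_zero(self):
        g = path_graph(2)
        d = ModelData([0, 0], [1.0, 1.0], np.empty((2, 0)), g)
        eta = linear_predictor(d, ICARParams(0.0), np.zeros(2))
        np.testing.assert_allclose(eta, [0.0, 0.0])

    def test_direct_substitution(self):
        g = path_graph(2)
        d = ModelData([0, 0], [2.0, 2.0], np.empty((2, 0)), g)
        eta = linear_predictor(d, ICARParams(0.5), np.array([0.1, -0.1]))
        np.testing.assert_allclose(eta, [np.log(2) + 0.6, np.log(2) + 0.4])

    def test_nonpositive_offset_rejected(self):
        g = path_graph(2)
        with pytest.raises(ModelInputError, match="positive"):
            ModelData([0, 0], [1.0, 0.0], np.empty((2, 0)), g)

    def test_shape_mismatch_rejected(self):
        g = path_graph(3)
        d = ModelData([0, 0, 0], [1, 1, 1], np.empty((3, 0)), g)
        with pytest.raises(ModelInputError):
            linear_predictor(d, ICARParams(0.0), np.zeros(2))

    def test_covariates_enter(self):
        g = path_graph(2)
        X = np.array([[1.0], [2.0]])
        d = ModelData([0, 0], [1.0, 1.0], X, g)
        eta = linear_predictor(d, ICARParams(0.0, beta=[0.5]), np.zeros(2))
        np.testing.assert_allclose(eta, [0.5, 1.0])


class TestQuadratic:
    def test_constant_vector_vanishes(self):
        g = cycle_graph(5)
        assert icar_quadratic(np.full(5, 3.7), g) == pytest.approx(0.0, abs=1e-12)

    def test_path_by_hand(self):
        g = path_graph(3)
        assert icar_quadratic(np.array([1.0, 0.0, -1.0]), g) == pytest.approx(2.0)

    def test_matches_dense_matrix_product(self, rng):
        g = random_graph(rng, 8)
        s = rng.standard_normal(8)
        dense = s @ (g.Q.toarray() @ s)
        assert icar_quadratic(s, g) == pytest.approx(dense, rel=1e-12)


class TestICARLogDensity:
    def test_zero_field_unnormalized(self):
        g = cycle_graph(4)
        assert icar_log_density(np.zeros(4), g, 0.3, normalized=False) == 0.0

    def test_tau_doubling_identity(self):
        g = path_graph(4)
        s = np.array([1.0, -0.5, 0.5, -1.0])
        tau = 0.8
        quad = icar_quadratic(s, g)
        before = icar_log_density(s, g, np.log(tau))
        after = icar_log_density(s, g, np.log(2 * tau))
        rank = g.rank_Q
        expected_change = -rank * np.log(2) + (quad / 2) * (1 / tau**2 - 1 / (4 * tau**2))
        assert after - before == pytest.approx(expected_change, rel=1e-10)

    def test_matches_spectrally_reduced_gaussian(self):
        # density on the sum-to-zero subspace == proper Gaussian in the
        # positive eigenbasis coordinates
        g = path_graph(3)
        tau = 1.0
        s = np.array([1.0, 0.0, -1.0])
        lam, V = np.linalg.eigh(g.Q.toarray())
        lam, V = lam[1:], V[:, 1:]
        u = V.T @ s
        expected = scipy.stats.multivariate_normal.logpdf(
            u, mean=np.zeros(2), cov=tau**2 * np.diag(1 / lam)
        )
        assert icar_log_density(s, g, np.log(tau)) == pytest.approx(expected, rel=1e-12)

    def test_normalized_density_integrates_to_one(self):
        # deterministic quadrature over the constrained subspace, n <= 4
        from numpy.polynomial.hermite_e import hermegauss

        g = cycle_graph(4)
        log_tau = np.log(0.7)
        lam, V = np.linalg.eigh(g.Q.toarray())
        lam, V = lam[1:], V[:, 1:]
        x, w = hermegauss(40)
        sds = np.exp(log_tau) / np.sqrt(lam)
        total = 0.0
        for i, xi in enumerate(x):
            for j, xj in enumerate(x):
                for k, xk in enumerate(x):
                    u = np.array([xi * sds[0], xj * sds[1], xk * sds[2]])
                    dens = np.exp(icar_log_density(V @ u, g, log_tau))
                    total += (
                        w[i] * w[j] * w[k]
                        * np.exp((xi**2 + xj**2 + xk**2) / 2)
                        * sds.prod()
                        * dens
                    )
        assert total == pytest.approx(1.0, rel=1e-6)

    def test_nonfinite_field_rejected(self):
        g = path_graph(2)
        with pytest.raises(ModelInputError):
            icar_log_density(np.array([np.nan, 0.0]), g, 0.0)


class TestJointNll:
    def test_null_data_counts(self):
        g = path_graph(3)
        d = ModelData([0, 0, 0], [1.0, 1.0, 1.0], np.empty((3, 0)), g)
        val = joint_nll(d, ICARParams(0.0), np.zeros(3), normalized=False)
        assert val == pytest.approx(3.0)

    def test_intercept_doubles_mean(self):
        g = path_graph(3)
        d = ModelData([0, 0, 0], [1.0, 1.0, 1.0], np.empty((3, 0)), g)
        val = joint_nll(d, ICARParams(np.log(2.0)), np.zeros(3), normalized=False)
        assert val == pytest.approx(6.0)

    def test_matches_scalar_poisson_summation(self, rng):
        # independent oracle: per-region scipy Poisson log-pmf with log(y!)
        # added back, plus the quadratic and the normalizing constant
        g = cycle_graph(4)
        y = rng.poisson(2.0, size=4)
        E = rng.uniform(0.5, 3.0, size=4)
        d = ModelData(y, E, np.empty((4, 0)), g)
        params = ICARParams(0.3, log_tau=np.log(0.8))
        s = rng.standard_normal(4)
        s -= s.mean()
        mu = E * np.exp(params.beta0 + s)
        oracle = -(
            scipy.stats.poisson.logpmf(y, mu).sum()
            + scipy.special.gammaln(y + 1).sum()  # paper drops log(y!)
        )
        oracle += icar_quadratic(s, g) / (2 * params.tau2)
        oracle -= icar_normalizing_constant(g, params.log_tau)
        assert joint_nll(d, params, s) == pytest.approx(oracle, abs=1e-10)

    def test_permutation_invariance(self, rng):
        g = cycle_graph(5)
        y = rng.poisson(2.0, size=5)
        E = rng.uniform(0.5, 2.0, size=5)
        X = rng.standard_normal((5, 1))
        d = ModelData(y, E, X, g)
        params = ICARParams(0.1, beta=[0.2], log_tau=0.1)
        s = rng.standard_normal(5)
        perm = rng.permutation(5)
        labels = [f"v{i}" for i in range(5)]
        edges_p = [(labels[int(np.where(perm == i)[0][0])], labels[int(np.where(perm == j)[0][0])]) for i, j in g.edges]
        g2 = edges_to_graph(edges_p, labels)
        d2 = ModelData(y[perm], E[perm], X[perm], g2)
        assert joint_nll(d2, params, s[perm]) == pytest.approx(
            joint_nll(d, params, s), rel=1e-10
        )


class TestRelativeRisk:
    def test_unit_risk(self):
        g = path_graph(3)
        d = ModelData([0, 1, 2], [1.0, 1.0, 1.0], np.empty((3, 0)), g)
        np.testing.assert_allclose(relative_risk(ICARParams(0.0), np.zeros(3), d), 1.0)

    def test_intercept_scales_risk(self):
        g = path_graph(3)
        d = ModelData([0, 1, 2], [1.0, 1.0, 1.0], np.empty((3, 0)), g)
        np.testing.assert_allclose(
            relative_risk(ICARParams(np.log(2.0)), np.zeros(3), d), 2.0
        )

    def test_fitted_totals_match_observed(self):
        # score equation for the free intercept at the joint mode
        from icarlap import fit_mle

        g = cycle_graph(6)
        rng = np.random.default_rng(7)
        y = rng.poisson(3.0, size=6)
        d = ModelData(y, np.full(6, 1.5), np.empty((6, 0)), g)
        fit = fit_mle(d)
        lam = relative_risk(fit.theta_hat, fit.s_hat, d)
        assert float((d.E * lam).sum()) == pytest.approx(float(y.sum()), rel=1e-5)


class TestPdet:
    def test_pdet_cached_matches_eigenvalues(self):
        g = path_graph(3)
        eigs = np.linalg.eigvalsh(g.Q.toarray())
        np.testing.assert_allclose(eigs, [0.0, 1.0, 3.0], atol=1e-12)
        assert log_pdet_Q(g) == pytest.approx(np.log(3.0))
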