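import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.integrate import quad
from scipy.special import logsumexp

import ethomix as em
from ethomix.model import (ModelSpec, ParamLayout, ParameterSet, REBlock,
                           category_log_probs, corr_chol_to_free,
                           corr_free_to_chol, correlation_from_block,
                           linear_predictors, lkj_cholesky_log_norm,
                           log_posterior_and_grad, log_prior,
                           pointwise_log_lik, transform_noncentered)

finite_eta = hnp.arrays(np.float64, st.integers(1, 6),
                        elements=st.floats(-30, 30))


def _params(beta, sigma=None, corr_L=None, z=None, factor="individual"):
    p = ParameterSet(beta=np.asarray(beta, dtype=float))
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
        L = np.eye(len(sigma)) if corr_L is None else np.asarray(corr_L)
        z = np.zeros((1, len(sigma))) if z is None else np.atleast_2d(z)
        p.re[factor] = REBlock(sigma=sigma, L=L, z=z,
                               v=transform_noncentered(z, sigma, L))
    return p


class TestCategoryLogProbs:
    def test_symmetric_logits_give_uniform(self):
        logp = category_log_probs(np.zeros(2), reference_index=2)
        np.testing.assert_allclose(np.exp(logp), [1 / 3] * 3, atol=1e-15)

    def test_closed_form(self):
        logp = category_log_probs(np.array([math.log(2.0), 0.0]), 2)
        np.testing.assert_allclose(np.exp(logp), [0.5, 0.25, 0.25])

    def test_reference_position_respected(self):
        logp = category_log_probs(np.array([math.log(2.0), 0.0]), 0)
        np.testing.assert_allclose(np.exp(logp), [0.25, 0.5, 0.25])

    @given(eta=finite_eta)
    @settings(max_examples=100, deadline=None)
    def test_simplex_property(self, eta):
        pi = np.exp(category_log_probs(eta, reference_index=len(eta)))
        assert abs(pi.sum() - 1.0) < 1e-12
        assert np.all(pi > 0) and np.all(pi < 1)

    @given(eta=finite_eta, c=st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_softmax_shift_invariance(self, eta, c):
        # contrasts are differences of logits, so a common shift of all K
        # logits (reference included) leaves every probability unchanged
        logits = np.append(eta, 0.0)
        shifted = logits + c
        eta_back = shifted[:-1] - shifted[-1]
        np.testing.assert_allclose(
            category_log_probs(eta_back, len(eta)),
            category_log_probs(eta, len(eta)), atol=1e-12)

    def test_matches_direct_log_softmax(self, rng):
        eta = rng.normal(size=4)
        logits = np.append(eta, 0.0)
        np.testing.assert_allclose(category_log_probs(eta, 4),
                                   logits - logsumexp(logits), atol=1e-12)

    def test_nonfinite_eta_rejected(self):
        with pytest.raises(ValueError):
            category_log_probs(np.array([np.nan, 0.0]), 2)


class TestLinearPredictors:
    def test_intercept_only(self):
        params = _params([[0.3], [-1.1]])
        eta = linear_predictors(params, np.array([[1.0]]))
        np.testing.assert_allclose(eta, [[0.3, -1.1]])

    def test_random_effect_passthrough(self):
        params = _params(np.zeros((2, 1)), sigma=[1.0, 1.0],
                         z=[[0.5, -0.5]])
        eta = linear_predictors(params, np.array([[1.0]]),
                                {"individual": np.array([0])})
        np.testing.assert_allclose(eta, [[0.5, -0.5]])

    def test_k10_has_nine_equations(self):
        params = _params(np.zeros((9, 1)))
        eta = linear_predictors(params, np.ones((5, 1)))
        assert eta.shape == (5, 9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_predictors(_params(np.zeros((2, 3))), np.ones((4, 2)))


class TestPointwiseLogLik:
    def test_fair_coin(self):
        eth = em.Ethogram(("heads", "tails"))
        import pandas as pd
        df = pd.DataFrame({"outcome": ["heads"]})
        data = em.build_design(em.ObservationTable(df, eth), em.Formula())
        ll = pointwise_log_lik(_params([[0.0]]), data)
        np.testing.assert_allclose(ll, [math.log(0.5)])

    def test_brute_force_oracle_all_outcome_vectors(self, rng):
        """Enumerate all 3^4 outcome assignments of a K=3, n=4 problem and
        compare against a direct categorical pmf evaluation."""
        import itertools
        import pandas as pd
        eth = em.Ethogram(("a", "b", "c"))
        beta = rng.normal(size=(2, 2))
        X = np.column_stack([np.ones(4), rng.normal(size=4)])
        # independent oracle: plain softmax per row, no shared code path
        def oracle(y_codes):
            total = []
            for i, yi in enumerate(y_codes):
                logits = [X[i] @ beta[0], X[i] @ beta[1], 0.0]
                probs = [math.exp(l) for l in logits]
                probs = [p / sum(probs) for p in probs]
                total.append(math.log(probs[yi]))
            return np.array(total)

        for y in itertools.product(range(3), repeat=4):
            df = pd.DataFrame({"outcome": [eth.categories[c] for c in y],
                               "x": X[:, 1]})
            data = em.build_design(em.ObservationTable(df, eth),
                                   em.Formula(continuous={"x": 1}))
            ll = pointwise_log_lik(ParameterSet(beta=beta), data)
            np.testing.assert_allclose(ll, oracle(y), atol=1e-12)


class TestNoncenteredTransform:
    def test_zero_innovations(self):
        v = transform_noncentered(np.zeros((3, 2)), np.array([1.0, 2.0]),
                                  np.eye(2))
        np.testing.assert_allclose(v, 0.0)

    def test_identity(self, rng):
        z = rng.normal(size=(5, 3))
        v = transform_noncentered(z, np.ones(3), np.eye(3))
        np.testing.assert_allclose(v, z)

    def test_covariance_recovery(self, rng):
        # sigma=(1,2), rho=0.5 -> cov [[1,1],[1,4]]
        rho = 0.5
        L = np.array([[1.0, 0.0], [rho, math.sqrt(1 - rho ** 2)]])
        z = rng.normal(size=(100_000, 2))
        v = transform_noncentered(z, np.array([1.0, 2.0]), L)
        cov = np.cov(v.T)
        np.testing.assert_allclose(cov, [[1.0, 1.0], [1.0, 4.0]], atol=0.05)

    def test_non_triangular_rejected(self):
        with pytest.raises(ValueError):
            transform_noncentered(np.zeros((1, 2)), np.ones(2),
                                  np.array([[1.0, 0.5], [0.5, 1.0]]))


class TestCorrelation:
    def test_from_covariance(self):
        R = correlation_from_block(None, omega=np.array([[1.0, 0.5],
                                                         [0.5, 1.0]]))
        np.testing.assert_allclose(R[0, 1], 0.5)

    def test_diagonal_covariance_gives_identity(self):
        R = correlation_from_block(None, omega=np.diag([4.0, 9.0]))
        np.testing.assert_allclose(R, np.eye(2))

    def test_rho_formula(self):
        # cov / (sigma_1 sigma_2) = -2.88 / 6 = -0.48
        omega = np.array([[4.0, -2.88], [-2.88, 9.0]])
        R = correlation_from_block(None, omega=omega)
        np.testing.assert_allclose(R[0, 1], -0.48)

    @given(y=hnp.arrays(np.float64, 6, elements=st.floats(-3, 3)))
    @settings(max_examples=50, deadline=None)
    def test_cholesky_rows_unit_norm(self, y):
        L, _ = corr_free_to_chol(y, 4)
        R = L @ L.T
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        assert np.all(np.abs(R) <= 1 + 1e-12)

    @given(y=hnp.arrays(np.float64, 3, elements=st.floats(-2.5, 2.5)))
    @settings(max_examples=50, deadline=None)
    def test_free_coordinate_round_trip(self, y):
        L, _ = corr_free_to_chol(y, 3)
        np.testing.assert_allclose(corr_chol_to_free(L), y, atol=1e-8)


class TestLogPrior:
    def _spec(self, **kw):
        return ModelSpec(K=3, reference_index=2, P=2,
                         re_factors=(em.REFactorSpec("individual", 4),), **kw)

    def test_finite_at_mode(self):
        spec = self._spec()
        params = _params(np.zeros((2, 2)), sigma=[0.5, 0.5],
                         z=np.zeros((4, 2)))
        assert np.isfinite(log_prior(params, spec))

    def test_unimodal_in_beta(self):
        spec = self._spec()
        at_zero = _params(np.zeros((2, 2)), sigma=[0.5, 0.5], z=np.zeros((4, 2)))
        moved = _params([[0.0, 2.0], [0.0, 0.0]], sigma=[0.5, 0.5],
                        z=np.zeros((4, 2)))
        far = _params([[0.0, 4.0], [0.0, 0.0]], sigma=[0.5, 0.5],
                      z=np.zeros((4, 2)))
        assert log_prior(at_zero, spec) > log_prior(moved, spec) > log_prior(far, spec)

    def test_nonpositive_sigma_rejected(self):
        spec = self._spec()
        params = _params(np.zeros((2, 2)), sigma=[0.5, 0.5], z=np.zeros((4, 2)))
        params.re["individual"].sigma = np.array([0.5, -0.1])
        assert log_prior(params, spec) == -np.inf

    def test_lkj_normalizer_matches_quadrature(self):
        # independent oracle for D=2: the density of rho is
        # c * (1 - rho^2)^(eta-1) on (-1, 1); c is the LKJ normalizer
        for eta in (1.0, 2.0, 4.0):
            integral, _ = quad(lambda r: (1 - r ** 2) ** (eta - 1), -1, 1)
            np.testing.assert_allclose(lkj_cholesky_log_norm(2, eta),
                                       -math.log(integral), atol=1e-10)

    def test_lkj_density_at_identity_closed_form(self):
        # D=2, eta=2: p(rho=0) = 1 / (2^3 B(2,2)) = 0.75
        from ethomix.model import _lkj_cholesky_logpdf
        lp, _ = _lkj_cholesky_logpdf(np.eye(2), eta=2.0)
        np.testing.assert_allclose(lp, math.log(0.75), atol=1e-12)


class TestGradients:
    @pytest.mark.parametrize("include_lik", [True, False])
    def test_matches_finite_differences(self, small_sim, include_lik, rng):
        data = small_sim.model_data
        spec = ModelSpec.from_model_data(data)
        layout = ParamLayout(spec)
        theta = 0.4 * rng.standard_normal(layout.dim)
        _, g = log_posterior_and_grad(theta, data, spec, layout,
                                      include_lik=include_lik)
        eps = 1e-6
        for i in rng.choice(layout.dim, size=40, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (log_posterior_and_grad(tp, data, spec, layout,
                                         include_lik=include_lik)[0]
                  - log_posterior_and_grad(tm, data, spec, layout,
                                           include_lik=include_lik)[0]) / (2 * eps)
            assert abs(g[i] - fd) / (1 + abs(fd)) < 1e-5

    def test_pack_unpack_round_trip(self, small_sim, rng):
        data = small_sim.model_data
        spec = ModelSpec.from_model_data(data)
        layout = ParamLayout(spec)
        theta = rng.standard_normal(layout.dim)
        back = layout.pack(layout.unpack(theta))
        np.testing.assert_allclose(back, theta, atol=1e-8)


def test_reference_relabeling_leaves_probabilities_invariant():
    """Refitting with a different reference category changes beta but not the
    fitted category probabilities (checked at the posterior mode)."""
    import pandas as pd
    rng = np.random.default_rng(3)
    cats = ("a", "b", "c")
    y = rng.choice(cats, size=300, p=[0.25, 0.35, 0.4])
    x = rng.normal(size=300)
    pis = {}
    for ref in ("c", "a"):
        eth = em.Ethogram(cats, reference=ref)
        df = pd.DataFrame({"outcome": y, "x": x})
        data = em.build_design(em.ObservationTable(df, eth),
                               em.Formula(continuous={"x": 1}))
        params, _, _ = em.fit_map(data)
        eta = linear_predictors(params, data.X, data.factor_indices)
        pis[ref] = np.exp(category_log_probs(eta, eth.reference_index))
    assert np.max(np.abs(pis["c"] - pis["a"])) < 0.01


def test_spec_json_round_trip(tmp_path, small_sim):
    spec = ModelSpec.from_model_data(small_sim.model_data)
    p = tmp_path / "spec.json"
    spec.to_json(p)
    assert ModelSpec.from_json(p) == spec
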