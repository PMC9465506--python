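"""CJS likelihood, chi recursion, design matrices and information criteria."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cjsdecline import (
    CJSModel,
    CJSModelSpec,
    aicc,
    akaike_weights,
    build_design,
    build_marray,
    chi_vector,
    cjs_loglik,
    count_parameters,
    persistence_over,
)
from cjsdecline.cjs import _marray_loglik_grad

from conftest import direct_simulate_histories, oracle_history_logprob, oracle_suffix_probs


class TestChi:
    def test_dead_population_never_seen(self):
        assert np.allclose(chi_vector([0.0, 0.0], [0.5, 0.5]), 1.0)

    def test_certain_redetection(self):
        assert np.allclose(chi_vector([1.0, 1.0], [1.0, 1.0]), [0.0, 0.0, 1.0])

    def test_hand_value(self):
        chi = chi_vector([0.5], [0.5])
        assert chi[0] == pytest.approx(0.75)
        assert chi[1] == 1.0

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError, match="phi"):
            chi_vector([1.5], [0.5])


class TestLoglik:
    def test_hand_value_redetected_pair(self):
        ll = cjs_loglik(np.array([[1, 1]]), [0.5], [0.5])
        assert ll == pytest.approx(np.log(0.25))

    def test_certain_history_has_zero_loglik(self):
        Y = np.array([[0, 1, 1, 1], [1, 1, 1, 1]])
        assert cjs_loglik(Y, [1, 1, 1], [1, 1, 1]) == pytest.approx(0.0)

    def test_all_zero_history_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cjs_loglik(np.array([[1, 0], [0, 0]]), [0.5], [0.5])

    @pytest.mark.parametrize("T", [3, 4, 5])
    def test_matches_latent_marginalisation_oracle(self, T):
        rng = np.random.default_rng(42 + T)
        phi = rng.uniform(0.2, 0.9, T - 1)
        p = rng.uniform(0.1, 0.9, T - 1)
        Y = direct_simulate_histories(50, T, phi[0], 0.5, rng)
        expected = sum(oracle_history_logprob(h, phi, p) for h in Y)
        assert cjs_loglik(Y, phi, p) == pytest.approx(expected, abs=1e-10)

    def test_marray_equals_direct_likelihood(self):
        rng = np.random.default_rng(9)
        Y = direct_simulate_histories(300, 8, 0.5, 0.4, rng)
        phi = rng.uniform(0.2, 0.9, 7)
        p = rng.uniform(0.1, 0.9, 7)
        m, never, _ = build_marray(Y)
        ll_m, _, _ = _marray_loglik_grad(m, never, phi, p)
        assert ll_m == pytest.approx(cjs_loglik(Y, phi, p), abs=1e-9)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        Y = direct_simulate_histories(200, 6, 0.5, 0.4, rng)
        model = CJSModel(Y, phi="quadratic", p="linear")
        beta = rng.normal(scale=0.5, size=5)
        g = model.score(beta)
        eps = 1e-6
        for i in range(beta.size):
            d = np.zeros_like(beta)
            d[i] = eps
            fd = (model.loglike(beta + d) - model.loglike(beta - d)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestDesign:
    def test_constant_is_intercept_only(self):
        d = build_design(CJSModelSpec("constant", "constant", 12))
        assert d.X_phi.shape == (11, 1) and (d.X_phi == 1).all()

    def test_full_is_identity(self):
        d = build_design(CJSModelSpec("constant", "full", 12))
        assert np.array_equal(d.X_p, np.eye(11))

    def test_quadratic_columns(self):
        d = build_design(CJSModelSpec("quadratic", "constant", 12))
        s = d.time_covariate
        assert s[0] == -1.0 and s[-1] == 1.0
        assert np.allclose(d.X_phi[:, 2], s**2)

    def test_full_rank(self):
        for phi in ("constant", "linear", "quadratic", "full"):
            d = build_design(CJSModelSpec(phi, "constant", 12))
            assert np.linalg.matrix_rank(d.X_phi) == d.X_phi.shape[1]


class TestCountParameters:
    @pytest.mark.parametrize(
        "phi,p,expected",
        [
            ("quadratic", "full", 14),
            ("constant", "full", 12),
            ("linear", "full", 13),
            ("constant", "linear", 3),
            ("constant", "quadratic", 4),
            ("quadratic", "linear", 5),
            ("constant", "constant", 2),
            ("linear", "constant", 3),
            ("full", "full", 21),
        ],
    )
    def test_table_values(self, phi, p, expected):
        assert count_parameters(CJSModelSpec(phi, p, 12)) == expected

    def test_mark_aliases_accepted(self):
        assert count_parameters(CJSModelSpec("Time^2", "t", 12)) == 14
        assert CJSModelSpec(".", "t", 12).name == "Phi(.)p(t)"

    def test_full_full_confounding_matches_hessian_rank(self):
        # at the ML optimum the likelihood is flat along the terminal
        # phi*p ridge, so the numeric information rank equals the analytic K
        rng = np.random.default_rng(11)
        T = 5
        Y = direct_simulate_histories(400, T, 0.6, 0.5, rng)
        model = CJSModel(Y, phi="full", p="full")
        res = model.fit(seed=1)
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(res.params, model.loglike)
        rank = np.linalg.matrix_rank(H, tol=1e-6 * np.abs(H).max())
        assert rank == count_parameters(model.spec) == 2 * (T - 1) - 1


class TestAICc:
    def test_hand_value(self):
        assert aicc(100.0, 3, 10) == pytest.approx(110.0)

    def test_no_parameters_is_m2ll(self):
        assert aicc(123.4, 0, 50) == pytest.approx(123.4)

    def test_large_sample_limit_is_aic(self):
        assert aicc(100.0, 3, 10**9) == pytest.approx(106.0, abs=1e-6)

    def test_undefined_below_k_plus_one(self):
        with pytest.raises(ValueError, match="undefined"):
            aicc(100.0, 9, 10)


class TestAkaikeWeights:
    def test_printed_model_table_values(self):
        delta, w = akaike_weights([1491.25, 1497.94, 1498.39])
        assert round(float(w[0]), 2) == 0.94
        assert delta[0] == 0.0

    def test_printed_delta(self):
        delta, _ = akaike_weights([436.36, 438.24, 438.28])
        assert delta[1] == pytest.approx(1.88)

    def test_single_model(self):
        _, w = akaike_weights([512.3])
        assert w[0] == 1.0

    def test_equal_values_uniform(self):
        _, w = akaike_weights([10.0, 10.0, 10.0, 10.0])
        assert np.allclose(w, 0.25)

    @given(
        vals=st.lists(st.floats(0, 1e4), min_size=2, max_size=8),
        shift=st.floats(-1e3, 1e3),
    )
    @settings(deadline=None, max_examples=50)
    def test_shift_invariance(self, vals, shift):
        _, w1 = akaike_weights(vals)
        _, w2 = akaike_weights([v + shift for v in vals])
        assert np.allclose(w1, w2, atol=1e-12)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)


class TestPersistenceOver:
    def test_constant_power(self):
        assert persistence_over(0.46, 10) == pytest.approx(0.46**10)

    def test_certain_persistence(self):
        assert persistence_over(1.0, 37) == 1.0

    def test_vector_product_oracle(self):
        phi = np.array([0.72, 0.65, 0.55, 0.44, 0.31])
        prod = 1.0
        for v in phi:
            prod *= v
        assert persistence_over(phi, 5) == pytest.approx(prod)
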