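import math

import numpy as np
import pytest

import oracles
from conftest import (
    TYT_AIC,
    TYT_DELTA1,
    TYT_G11,
    TYT_G21,
    TYT_LAM,
    TYT_NLL,
    random_model,
)
from poishmm import (
    ConstraintMap,
    FitOptions,
    InvalidObservationError,
    NaturalParams,
    ObservationSeries,
    default_initial_params,
    delta_method_cov,
    fit_ml,
    information_criteria,
    natural_to_working,
    nll_with_derivatives,
)
from poishmm.fit import FIXED
from poishmm.reparam import WorkingParams, working_to_natural
from poishmm.simulate import simulate_hmm, study_truth


class TestDerivatives:
    """The exact gradient and Hessian against central finite differences."""

    def _nll_of_vector(self, obs, layout):
        def f(vec):
            wp = WorkingParams.from_vector(vec, layout)
            val, _, _ = nll_with_derivatives(obs, wp, order=0)
            return val

        return f

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_gradient_matches_finite_differences(self, rng, m):
        truth = random_model(rng, max(m, 2))
        obs, _ = simulate_hmm(study_truth(2), 60, seed=11)
        wp = natural_to_working(random_model(rng, m))
        _, grad, _ = nll_with_derivatives(obs, wp, order=1)
        fd = oracles.fd_gradient(self._nll_of_vector(obs, wp.layout), wp.to_vector())
        np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-7)

    def test_gradient_with_missing_data(self, rng):
        vals = np.array([2.0, np.nan, 5, 0, 3, 1, np.nan, 4, 2, 0])
        obs = ObservationSeries(vals)
        wp = natural_to_working(random_model(rng, 2))
        _, grad, _ = nll_with_derivatives(obs, wp, order=1)
        fd = oracles.fd_gradient(self._nll_of_vector(obs, wp.layout), wp.to_vector())
        np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-7)

    @pytest.mark.parametrize("m", [2, 3])
    def test_hessian_matches_finite_differences(self, rng, m):
        obs, _ = simulate_hmm(study_truth(2), 50, seed=13)
        wp = natural_to_working(random_model(rng, m))
        _, _, hess = nll_with_derivatives(obs, wp, order=2)
        np.testing.assert_allclose(hess, hess.T, atol=1e-10)
        fd = oracles.fd_hessian(self._nll_of_vector(obs, wp.layout), wp.to_vector())
        np.testing.assert_allclose(hess, fd, rtol=2e-4, atol=1e-5)

    def test_gradient_vanishes_at_optimum(self, tyt_fit):
        assert tyt_fit.gradient_norm < 1e-5

    def test_m1_gradient_closed_form(self):
        # For m = 1, nll(eta) = T e^eta - sum(x) eta + const, so
        # d nll / d eta = T lam - sum(x).
        obs = ObservationSeries(np.array([3.0, 0, 2, 5, 1, 4]))
        for lam in (1.0, 2.5, 4.0):
            wp = WorkingParams(eta=np.array([math.log(lam)]), tau=np.zeros(0))
            _, grad, _ = nll_with_derivatives(obs, wp, order=1)
            assert grad[0] == pytest.approx(obs.T * lam - obs.values.sum(), rel=1e-10)


class TestFitML:
    def test_m1_mle_is_sample_mean(self):
        obs = ObservationSeries(np.array([3.0, 0, 2, 5, 1, 4, 2, 2]))
        res = fit_ml(obs, 1)
        assert res.converged
        assert res.natural_hat.lam[0] == pytest.approx(obs.values.mean(), rel=1e-8)

    def test_two_state_tyt_estimates(self, tyt_fit):
        assert tyt_fit.converged
        nat = tyt_fit.natural_hat
        assert tyt_fit.nll_value == pytest.approx(TYT_NLL, abs=1e-6)
        assert nat.lam[0] == pytest.approx(TYT_LAM[0], abs=1e-5)
        assert nat.lam[1] == pytest.approx(TYT_LAM[1], abs=1e-5)
        assert nat.tpm[0, 0] == pytest.approx(TYT_G11, abs=1e-5)
        assert nat.tpm[1, 0] == pytest.approx(TYT_G21, abs=1e-5)
        assert tyt_fit.delta_hat[0] == pytest.approx(TYT_DELTA1, abs=1e-5)

    def test_deterministic(self, tyt):
        a = fit_ml(tyt, 2)
        b = fit_ml(tyt, 2)
        assert a.nll_value == b.nll_value
        np.testing.assert_array_equal(a.working_hat.to_vector(), b.working_hat.to_vector())

    def test_multistart_stability(self, tyt, tyt_fit, rng):
        # at least 90% of randomized starts must reach the same optimum
        hits = 0
        for _ in range(20):
            lam0 = np.sort(rng.uniform(0.5, 8.0, size=2))
            G0 = rng.uniform(0.2, 1.0, size=(2, 2))
            G0 /= G0.sum(axis=1, keepdims=True)
            init = NaturalParams(m=2, tpm=G0, lam=lam0)
            res = fit_ml(tyt, 2, init=init)
            if res.converged and abs(res.nll_value - tyt_fit.nll_value) < 1e-6:
                hits += 1
        assert hits >= 18

    def test_exact_and_derivative_free_optima_agree(self, tyt, tyt_fit):
        res_fd = fit_ml(tyt, 2, options=FitOptions(optimizer="lbfgs-fd"))
        assert res_fd.nll_value == pytest.approx(tyt_fit.nll_value, abs=1e-6)

    def test_newton_optimizer_agrees(self, tyt, tyt_fit):
        res = fit_ml(tyt, 2, options=FitOptions(optimizer="newton"))
        assert res.converged
        assert res.nll_value == pytest.approx(tyt_fit.nll_value, abs=1e-8)

    def test_parameter_recovery_within_three_se(self):
        truth = study_truth(2)
        obs, _ = simulate_hmm(truth, 2000, seed=29)
        res = fit_ml(obs, 2)
        assert res.converged
        rep = delta_method_cov(res)
        for name, true in [
            ("lambda_1", truth.lam[0]),
            ("lambda_2", truth.lam[1]),
            ("gamma_11", truth.tpm[0, 0]),
            ("gamma_21", truth.tpm[1, 0]),
        ]:
            est, se = rep[name]
            assert abs(est - true) < 3 * se, name

    def test_constant_series_is_handled(self):
        # A constant series makes the states unidentifiable; the fit must
        # either converge (to a degenerate optimum) or report failure, not
        # crash or return a non-finite likelihood.
        obs = ObservationSeries(np.full(30, 2.0))
        res = fit_ml(obs, 2)
        assert np.isfinite(res.nll_value)


class TestConstraints:
    def _fixed_lambda1_map(self, layout):
        labels = list(layout.names)
        labels[layout.eta_position(0)] = FIXED
        return ConstraintMap(tuple(labels))

    def test_fixed_value_is_held_exactly(self, tyt):
        init = NaturalParams(
            m=2, tpm=np.array([[0.8, 0.2], [0.2, 0.8]]), lam=np.array([1.0, 5.0])
        )
        cmap = self._fixed_lambda1_map(natural_to_working(init).layout)
        res = fit_ml(tyt, 2, init=init, constraint_map=cmap)
        assert res.converged
        assert res.natural_hat.lam[0] == 1.0  # exactly, not approximately

    def test_fixed_parameter_has_zero_se(self, tyt):
        init = NaturalParams(
            m=2, tpm=np.array([[0.8, 0.2], [0.2, 0.8]]), lam=np.array([1.0, 5.0])
        )
        cmap = self._fixed_lambda1_map(natural_to_working(init).layout)
        res = fit_ml(tyt, 2, init=init, constraint_map=cmap)
        est, se = delta_method_cov(res)["lambda_1"]
        assert est == 1.0
        assert se == 0.0

    def test_constrained_nll_not_below_unconstrained(self, tyt, tyt_fit):
        # equality constraint tau_12 == tau_21 nests inside the full model
        layout = tyt_fit.layout
        labels = list(layout.names)
        labels[layout.tau_position(0, 1)] = "shared_tau"
        labels[layout.tau_position(1, 0)] = "shared_tau"
        res = fit_ml(tyt, 2, constraint_map=ConstraintMap(tuple(labels)))
        assert res.converged
        assert res.natural_hat.tpm[0, 1] == pytest.approx(res.natural_hat.tpm[1, 0], rel=1e-8)
        assert res.nll_value >= tyt_fit.nll_value - 1e-9

    def test_wrong_length_map_raises(self, tyt):
        with pytest.raises(ValueError):
            fit_ml(tyt, 2, constraint_map=ConstraintMap(("a", "b")))


class TestInformationCriteria:
    def test_published_aic(self, tyt_fit):
        aic, bic = information_criteria(tyt_fit)
        assert aic == pytest.approx(2 * tyt_fit.nll_value + 2 * 4, rel=1e-12)
        assert aic == pytest.approx(TYT_AIC, abs=1e-5)
        assert bic == pytest.approx(2 * tyt_fit.nll_value + 4 * math.log(87), rel=1e-12)

    def test_m2_preferred_over_m3_on_tyt(self, tyt, tyt_fit):
        res3 = fit_ml(tyt, 3)
        aic2, bic2 = information_criteria(tyt_fit)
        aic3, bic3 = information_criteria(res3)
        assert aic2 < aic3
        assert bic2 < bic3


class TestInitialParams:
    def test_defaults_are_valid_and_increasing(self, tyt):
        for m in (1, 2, 3, 4):
            init = default_initial_params(tyt, m)
            assert np.all(np.diff(init.lam) > 0)
            assert np.all(init.lam > 0)
            np.testing.assert_allclose(init.tpm.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diag(init.tpm) == init.tpm[0, 0])  # same persistence
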