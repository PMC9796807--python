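import math

import numpy as np
import pytest

import oracles
from conftest import random_model
from poishmm import (
    ConstraintMap,
    NaturalParams,
    bootstrap_ci,
    chi2_critical,
    delta_method_cov,
    fit_ml,
    natural_to_working,
    profile_ci,
    profile_ci_tpm,
    wald_ci,
)
from poishmm.fit import FIXED
from poishmm.reparam import WorkingParams, working_to_natural
from poishmm.simulate import simulate_hmm, study_truth
from poishmm.uncertainty import align_states, natural_param_names, natural_param_vector


class TestNames:
    def test_report_order(self):
        names = natural_param_names(2)
        assert names == (
            "gamma_11", "gamma_12", "gamma_21", "gamma_22",
            "lambda_1", "lambda_2", "delta_1", "delta_2",
        )

    def test_vector_matches_names(self, table2_params):
        vec = natural_param_vector(table2_params)
        assert vec[0] == table2_params.tpm[0, 0]
        assert vec[4] == table2_params.lam[0]
        assert vec[6] == pytest.approx(table2_params.delta[0])


class TestAlignStates:
    def test_sorts_by_ascending_mean(self):
        params = NaturalParams(
            m=2, tpm=np.array([[0.7, 0.3], [0.2, 0.8]]), lam=np.array([5.0, 1.0])
        )
        out = align_states(params)
        np.testing.assert_array_equal(out.lam, [1.0, 5.0])
        assert out.tpm[0, 0] == 0.8
        assert out.tpm[0, 1] == 0.2
        # the chain itself is unchanged, only labels move
        d_in = np.sort(params.delta)
        d_out = np.sort(out.delta)
        np.testing.assert_allclose(d_in, d_out, atol=1e-12)


class TestChi2Critical:
    def test_value_at_95(self):
        assert chi2_critical(0.95) == pytest.approx(3.841, abs=5e-4)

    def test_monotone_in_level(self):
        assert chi2_critical(0.99) > chi2_critical(0.95) > chi2_critical(0.90)


class TestDeltaMethod:
    def test_against_finite_difference_oracle(self, tyt, tyt_fit):
        from poishmm.fit import nll_with_derivatives

        rep = delta_method_cov(tyt_fit)
        wp_hat = tyt_fit.working_hat
        layout = wp_hat.layout
        vec_hat = wp_hat.to_vector()

        def nll_of(vec):
            val, _, _ = nll_with_derivatives(
                tyt, WorkingParams.from_vector(vec, layout), order=0
            )
            return val

        H_fd = oracles.fd_hessian(nll_of, vec_hat, h=1e-4)

        def natural_of(vec):
            nat = working_to_natural(WorkingParams.from_vector(vec, layout))
            return natural_param_vector(nat)

        k = layout.size
        J_fd = np.empty((len(rep.names), k))
        for i in range(k):
            e = np.zeros(k); e[i] = 1e-6
            J_fd[:, i] = (natural_of(vec_hat + e) - natural_of(vec_hat - e)) / 2e-6
        cov_fd = J_fd @ np.linalg.inv(H_fd) @ J_fd.T
        np.testing.assert_allclose(rep.cov, cov_fd, rtol=1e-3, atol=1e-8)

    def test_covariance_is_symmetric_with_nonnegative_diagonal(self, tyt_fit):
        rep = delta_method_cov(tyt_fit)
        np.testing.assert_allclose(rep.cov, rep.cov.T, atol=1e-12)
        assert np.all(np.diag(rep.cov) >= 0)
        assert np.all(rep.se >= 0)

    def test_row_sum_constraint_propagates(self, tyt_fit):
        # gamma_11 + gamma_12 = 1 identically, so their variances are equal
        # and their covariance is the negative of the variance
        rep = delta_method_cov(tyt_fit)
        i, j = rep.names.index("gamma_11"), rep.names.index("gamma_12")
        assert rep.cov[i, i] == pytest.approx(rep.cov[j, j], rel=1e-8)
        assert rep.cov[i, j] == pytest.approx(-rep.cov[i, i], rel=1e-8)

    def test_fully_fixed_model_has_zero_covariance(self, tyt):
        init = NaturalParams(
            m=2, tpm=np.array([[0.9, 0.1], [0.1, 0.9]]), lam=np.array([1.5, 5.5])
        )
        layout = natural_to_working(init).layout
        cmap = ConstraintMap(tuple(FIXED for _ in range(layout.size)))
        res = fit_ml(tyt, 2, init=init, constraint_map=cmap)
        rep = delta_method_cov(res)
        np.testing.assert_array_equal(rep.cov, 0.0)
        np.testing.assert_array_equal(rep.se, 0.0)


class TestWald:
    def test_centered_on_estimate(self, tyt_fit):
        rep = delta_method_cov(tyt_fit)
        ci = wald_ci(rep, 0.95)
        mid = (ci.lower + ci.upper) / 2
        np.testing.assert_allclose(mid, ci.estimates, atol=1e-10)

    def test_nesting_in_level(self, tyt_fit):
        rep = delta_method_cov(tyt_fit)
        ci95 = wald_ci(rep, 0.95)
        ci99 = wald_ci(rep, 0.99)
        assert np.all(ci99.lower <= ci95.lower + 1e-12)
        assert np.all(ci99.upper >= ci95.upper - 1e-12)

    def test_level_one_limit_covers_everything(self, tyt_fit):
        rep = delta_method_cov(tyt_fit)
        ci = wald_ci(rep, 1.0)
        ci95 = wald_ci(rep, 0.95)
        # z(level -> 1) is clamped large-but-finite (~7.1 vs 1.96 at 95%)
        assert np.all(np.isfinite(ci.lower)) and np.all(np.isfinite(ci.upper))
        assert np.all(ci.upper - ci.lower > 3 * (ci95.upper - ci95.lower))


class TestProfile:
    def test_bound_satisfies_likelihood_ratio_equation(self, tyt, tyt_fit):
        # independently refit with eta_2 pinned at the reported bound and
        # check 2 * (nll_p - nll_hat) equals the chi-square critical value
        pos = tyt_fit.layout.eta_position(1)
        (lo, hi), _, _ = profile_ci(tyt, tyt_fit, pos, 0.95)
        crit = chi2_critical(0.95)
        layout = tyt_fit.layout
        for bound in (lo, hi):
            vec = tyt_fit.working_hat.to_vector().copy()
            vec[pos] = bound
            labels = list(layout.names)
            labels[pos] = FIXED
            init = working_to_natural(WorkingParams.from_vector(vec, layout))
            refit = fit_ml(tyt, 2, init=init, constraint_map=ConstraintMap(tuple(labels)))
            ratio = 2.0 * (refit.nll_value - tyt_fit.nll_value)
            assert ratio == pytest.approx(crit, abs=1e-3)

    def test_natural_interval_is_monotone_transform(self, tyt, tyt_fit):
        pos = tyt_fit.layout.eta_position(0)
        (lo, hi), (nlo, nhi), _ = profile_ci(tyt, tyt_fit, pos, 0.95)
        assert nlo == pytest.approx(math.exp(lo), rel=1e-10)
        assert nhi == pytest.approx(math.exp(hi), rel=1e-10)

    def test_interval_contains_estimate(self, tyt, tyt_fit):
        for i in range(2):
            _, (nlo, nhi), _ = profile_ci(tyt, tyt_fit, tyt_fit.layout.eta_position(i), 0.95)
            assert nlo < tyt_fit.natural_hat.lam[i] < nhi

    def test_tpm_profile_two_state_flags(self, tyt, tyt_fit):
        res = profile_ci_tpm(tyt, tyt_fit, 1, 0, 0.95)
        lo, hi = res["natural"]
        assert 0.0 <= lo < tyt_fit.natural_hat.tpm[1, 0] < hi <= 1.0
        assert res["use_with_care"] is False

    def test_trace_minimum_at_mle(self, tyt, tyt_fit):
        pos = tyt_fit.layout.eta_position(1)
        _, _, trace = profile_ci(tyt, tyt_fit, pos, 0.95)
        assert np.all(trace.profile_nll >= tyt_fit.nll_value - 1e-8)

    def test_approaches_wald_for_large_samples(self):
        # profile and Wald intervals agree asymptotically; at T = 20000 the
        # interval widths for lambda_1 should differ by well under 2%
        obs, _ = simulate_hmm(study_truth(2), 20_000, seed=3)
        res = fit_ml(obs, 2)
        assert res.converged
        ci_w = wald_ci(delta_method_cov(res), 0.95)
        wlo, whi = ci_w["lambda_1"]
        _, (plo, phi), _ = profile_ci(obs, res, res.layout.eta_position(0), 0.95)
        assert (phi - plo) == pytest.approx(whi - wlo, rel=0.02)
        assert plo == pytest.approx(wlo, abs=0.02 * (whi - wlo))

    def test_fixed_target_is_rejected(self, tyt):
        init = NaturalParams(
            m=2, tpm=np.array([[0.9, 0.1], [0.1, 0.9]]), lam=np.array([1.5, 5.5])
        )
        layout = natural_to_working(init).layout
        labels = list(layout.names)
        pos = layout.eta_position(0)
        labels[pos] = FIXED
        res = fit_ml(tyt, 2, init=init, constraint_map=ConstraintMap(tuple(labels)))
        with pytest.raises(ValueError):
            profile_ci(tyt, res, pos, 0.95)


class TestBootstrap:
    def test_deterministic_given_seed(self, tyt, tyt_fit):
        a = bootstrap_ci(tyt, tyt_fit, B=16, seed=77)
        b = bootstrap_ci(tyt, tyt_fit, B=16, seed=77)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)
        assert a.meta["attempts"] == b.meta["attempts"]

    def test_seed_changes_result(self, tyt, tyt_fit):
        a = bootstrap_ci(tyt, tyt_fit, B=16, seed=77)
        b = bootstrap_ci(tyt, tyt_fit, B=16, seed=78)
        assert not np.array_equal(a.lower, b.lower)

    def test_intervals_contain_estimates(self, tyt, tyt_fit):
        ci = bootstrap_ci(tyt, tyt_fit, B=60, seed=5)
        for name in ("lambda_1", "lambda_2", "gamma_11", "delta_1"):
            lo, hi = ci[name]
            i = ci.names.index(name)
            assert lo <= ci.estimates[i] <= hi, name

    def test_replacement_bookkeeping(self, tyt, tyt_fit):
        ci = bootstrap_ci(tyt, tyt_fit, B=40, seed=9)
        meta = ci.meta
        assert meta["attempts"] >= 40
        assert meta["attempts"] == 40 + meta["replaced"]["state_visit"] + meta["replaced"]["fit_failure"]

    def test_width_shrinks_with_series_length(self):
        truth = study_truth(2)
        widths = []
        for T in (150, 4000):
            obs, _ = simulate_hmm(truth, T, seed=21)
            res = fit_ml(obs, 2)
            ci = bootstrap_ci(obs, res, B=40, seed=4)
            lo, hi = ci["lambda_2"]
            widths.append(hi - lo)
        assert widths[1] < 0.5 * widths[0]
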