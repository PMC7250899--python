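"""Predicted-error simulation and parameter-influence decomposition."""

import numpy as np
import pytest

from pathint.influence import (predict_errors, reduced_error,
                               relative_influence, influence_table)
from pathint.params import IntegratorParams, ReportParams


IDEAL = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.0)
NOISELESS = ReportParams(0.0, 0.0)


def test_ideal_parameters_predict_zero_error(small_dataset):
    _, _, arrays = small_dataset
    assert predict_errors(IDEAL, NOISELESS, "full", arrays=arrays,
                          n_reps=20, seed=0) == pytest.approx(0.0, abs=1e-20)


def test_angular_noise_error_grows_with_distance(paths):
    """With only angular reporting noise the error arc grows with the
    homing distance (~ d * sigma_phi to first order)."""
    from pathint.influence import _arrays_from_paths
    arrays = _arrays_from_paths(paths[0])
    rep = ReportParams(0.0, 0.01)
    per = predict_errors(IDEAL, rep, "full", arrays=arrays, n_reps=4000,
                         seed=1, per_stop=True)
    d = np.linalg.norm(np.cumsum(arrays.dx[0], axis=0), axis=1)
    # first-order prediction: E[err^2] ~ 2 d^2 (1 - exp(-sigma^2/2)) ~ d^2 sigma^2
    np.testing.assert_allclose(per, d**2 * 0.01, rtol=0.15)


def test_predicted_mse_matches_closed_form_straight_path():
    """Straight path, no leak/bias: the predicted square error has a
    closed form (accumulating variance + log-normal distance noise +
    angular arc), matched at high repetition count."""
    from pathint.ekf import TrialArrays
    L = 10.0
    arrays = TrialArrays(np.array([[[L / 4, 0.0]] * 4]),
                         np.full((1, 4), 5.0), np.full((1, 4), np.nan),
                         np.full((1, 4), np.nan), np.ones((1, 4), dtype=bool))
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.05)
    sd2, sp2 = 0.01, 0.01
    rep = ReportParams(sd2, sp2)
    per = predict_errors(p, rep, "full", arrays=arrays, n_reps=100_000,
                         seed=3, per_stop=True)
    # per stop s: x ~ N(mu_s e1, v_s I) with v_s = sigma0_sq * s * L/4.
    # E err^2 = E|stop - d_hat u(phi_hat)|^2
    #         = mu^2 + E[d_hat^2] - 2 mu E[d_hat cos(phi_hat)].
    # E[d_hat^2] = E[|x|^2] e^{2 sd2} with E[|x|^2] = mu^2 + 2v;
    # E[d_hat cos phi_hat] = E[|x| cos phi] e^{sd2/2} e^{-sp2/2}
    # and |x| cos phi = x_1, so E[|x| cos phi] = mu exactly.
    for s in range(4):
        mu = (s + 1) * L / 4
        v = p.sigma0_sq * (s + 1) * L / 4
        e_dhat2 = (mu**2 + 2 * v) * np.exp(2 * sd2)
        e_cross = mu * mu * np.exp(sd2 / 2) * np.exp(-sp2 / 2)
        expected = mu**2 + e_dhat2 - 2 * e_cross
        assert per[s] == pytest.approx(expected, rel=0.05)


def test_reduced_error_trivials(small_dataset):
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.3)
    # idealizing a parameter already at ideal leaves the error unchanged
    # (common random numbers make this exact)
    full = predict_errors(p, NOISELESS, "full", arrays=arrays, n_reps=50, seed=2)
    red = reduced_error(p, NOISELESS, "beta", "full", arrays=arrays,
                        n_reps=50, seed=2)
    assert red == pytest.approx(full, abs=1e-12)
    # idealizing the only nonzero parameter removes all error
    red0 = reduced_error(p, NOISELESS, "sigma0_sq", "full", arrays=arrays,
                         n_reps=50, seed=2)
    assert red0 == pytest.approx(0.0, abs=1e-20)


def test_relative_influence_formula():
    assert relative_influence(2.0, 0.0) == pytest.approx(100.0)
    assert relative_influence(2.0, 2.0) == pytest.approx(0.0)
    assert relative_influence(2.0, 2.4) == pytest.approx(-20.0)
    with pytest.raises(ValueError):
        relative_influence(0.0, 1.0)


def test_single_noise_source_influence_near_100(small_dataset):
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.25)
    full = predict_errors(p, NOISELESS, "full", arrays=arrays,
                          n_reps=2000, seed=5)
    red = reduced_error(p, NOISELESS, "sigma0_sq", "full", arrays=arrays,
                        n_reps=2000, seed=5)
    assert relative_influence(full, red) == pytest.approx(100.0, abs=1e-9)


def test_compensating_leak_and_gain_gives_negative_influence(small_dataset):
    """A leak pulling estimates inward can offset a gain pushing them
    outward; idealizing the leak alone then increases the error."""
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.05, alpha=1.4, bias=(0.0, 0.0), sigma0_sq=1e-4)
    full = predict_errors(p, NOISELESS, "full", arrays=arrays, n_reps=400,
                          seed=7)
    red = reduced_error(p, NOISELESS, "beta", "full", arrays=arrays,
                        n_reps=400, seed=7)
    assert relative_influence(full, red) < 0


def test_influence_table_order_invariant(small_dataset, clean_agent):
    """Contributions are independent reductions: the table is the same
    whatever order the parameters are evaluated in."""
    from pathint.model import PathIntegrationModel, PathIntegrationResults
    _, _, arrays = small_dataset
    res = PathIntegrationResults(
        model=PathIntegrationModel(arrays, "full"),
        integrator=clean_agent.integrator, reporter=clean_agent.reporter,
        loglik=0.0, converged=True, n_restarts_used=1, seed=0, xopt=None)
    t1 = influence_table(res, n_reps=100, seed=0,
                         params=("beta", "alpha", "sigma0_sq"))
    t2 = influence_table(res, n_reps=100, seed=0,
                         params=("sigma0_sq", "beta", "alpha"))
    m1 = t1.set_index("parameter")["contribution"]
    m2 = t2.set_index("parameter")["contribution"]
    for k in m1.index:
        assert m1[k] == pytest.approx(m2[k], abs=1e-12)


def test_mc_error_shrinks_with_reps(small_dataset):
    """Monte-Carlo scatter of the predicted MSE scales ~ 1/sqrt(reps)."""
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.3)
    def scatter(n_reps, n_draws=12):
        vals = [predict_errors(p, NOISELESS, "full", arrays=arrays,
                               n_reps=n_reps, seed=100 + i)
                for i in range(n_draws)]
        return np.std(vals)
    s_small, s_big = scatter(50), scatter(50 * 16)
    ratio = s_small / s_big
    assert 2.0 < ratio < 8.0   # ~4 expected at 16x reps
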