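"""EKF correctness: Jacobians, Kalman limits, missing data, and the
particle-filter oracle."""

import numpy as np
import pytest

from pathint.ekf import (Belief, TrialArrays, ekf_step, ekf_step_missing,
                         observe_logpolar, observe_polar, trial_logliks)
from pathint.params import IntegratorParams, ReportParams

from helpers import numerical_jacobian, particle_filter_loglik

LOG2PI = np.log(2 * np.pi)


def test_logpolar_observation_values():
    h, H = observe_logpolar(np.array([1.0, 0.0]))
    np.testing.assert_allclose(h, [0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(H, np.eye(2), atol=1e-12)
    h, _ = observe_logpolar(np.array([0.0, np.e]))
    np.testing.assert_allclose(h, [1.0, np.pi / 2], atol=1e-12)


def test_polar_observation_values():
    h, H = observe_polar(np.array([3.0, 4.0]))
    np.testing.assert_allclose(h, [5.0, np.arctan2(4, 3)], atol=1e-12)
    # angle rows of polar and log-polar Jacobians coincide
    _, Hlp = observe_logpolar(np.array([3.0, 4.0]))
    np.testing.assert_allclose(H[1], Hlp[1], atol=1e-12)


@pytest.mark.parametrize("observe", [observe_logpolar, observe_polar])
def test_jacobians_match_finite_differences(observe):
    rng = np.random.default_rng(42)
    for _ in range(25):
        x = rng.normal(scale=3.0, size=2)
        if np.linalg.norm(x) < 0.1:
            continue
        h, H = observe(x)
        J = numerical_jacobian(lambda v: observe(v)[0], x)
        np.testing.assert_allclose(H, J, atol=1e-6)


def test_origin_singularity_raises():
    with pytest.raises(FloatingPointError):
        observe_logpolar(np.array([1e-9, 0.0]))


def test_uninformative_observation_keeps_predictive():
    p = IntegratorParams(beta=0.05, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.1)
    huge = ReportParams(sigma_d_sq=1e12, sigma_phi_sq=1e12)
    b0 = Belief(np.zeros(2), np.zeros((2, 2)))
    seg = {"dx": np.array([4.0, 1.0])}
    pred = ekf_step_missing(b0, seg, p)
    upd, _ = ekf_step(b0, seg, (4.1, 0.3), p, huge)
    np.testing.assert_allclose(upd.mean, pred.mean, atol=1e-6)
    np.testing.assert_allclose(upd.cov, pred.cov, atol=1e-6)


def test_linear_gaussian_case_matches_exact_kalman():
    """With the polar observation at a point on the +x axis and tiny
    state uncertainty the EKF linearization is locally exact; compare
    against an independently coded Kalman filter on the linearized
    model to 1e-10."""
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=1e-4)
    rep = ReportParams(sigma_d_sq=0.3, sigma_phi_sq=0.2)
    seg = {"dx": np.array([10.0, 0.0])}
    obs = (10.05, 0.01)
    belief, ll = ekf_step(Belief(np.zeros(2), np.zeros((2, 2))), seg, obs,
                          p, rep, "full-RN+CRN")
    # hand-rolled Kalman: state x ~ N(m, P); observation z = H x + noise
    # with the polar map linearized at the predictive mean (10, 0):
    # H = [[1, 0], [0, 1/r]]
    m = np.array([10.0, 0.0])
    P = (1e-4 * 10.0) * np.eye(2)   # accumulating variance over the 10 m leg
    H = np.array([[1.0, 0.0], [0.0, 1.0 / 10.0]])
    z = np.array([obs[0], obs[1]])
    hx = np.array([10.0, 0.0])
    S = H @ P @ H.T + np.diag([0.3, 0.2])
    y = z - hx
    ll_ref = (-LOG2PI - 0.5 * np.log(np.linalg.det(S))
              - 0.5 * y @ np.linalg.inv(S) @ y)
    K = P @ H.T @ np.linalg.inv(S)
    m_ref = m + K @ y
    P_ref = (np.eye(2) - K @ H) @ P
    assert ll == pytest.approx(ll_ref, abs=1e-10)
    np.testing.assert_allclose(belief.mean, m_ref, atol=1e-10)
    np.testing.assert_allclose(belief.cov, P_ref, atol=1e-10)


def _single_trial_arrays(dx_list, d_hat, phi_hat, obs, dt=None):
    dx = np.array(dx_list, dtype=float)[None]
    n_seg = dx.shape[1]
    dt = np.full((1, n_seg), 10.0) if dt is None else np.asarray(dt)[None]
    return TrialArrays(dx, dt, np.array(d_hat, dtype=float)[None],
                       np.array(phi_hat, dtype=float)[None],
                       np.array(obs, dtype=bool)[None])


def test_missing_stops_single_term_and_composition():
    """A non-stopping trial's log-likelihood has exactly one term, and
    equals that of a single merged segment when beta = 0."""
    p = IntegratorParams(beta=0.0, alpha=1.1, bias=(0.02, 0.0), sigma0_sq=0.2)
    rep = ReportParams(0.05, 0.04)
    dxs = [[3.0, 0.0], [1.0, 2.0], [-2.0, 1.5], [0.5, 2.0]]
    arr = _single_trial_arrays(dxs, [4.0, 4.0, 4.0, 3.9], [0.1, 0.1, 0.1, 1.2],
                               [False, False, False, True])
    per = trial_logliks(arr, p, rep, "full", per_stop=True)
    assert np.count_nonzero(per) == 1
    # with beta = 0 the composed prediction collapses to closed form:
    # mean = alpha * total displacement + b * total length, variance =
    # sigma0_sq * total length (the missing-stop chain adds nothing else)
    total = np.sum(dxs, axis=0)
    L_sum = np.sum([np.linalg.norm(d) for d in dxs])
    mean4 = p.alpha * np.array(total) + np.array(p.bias) * L_sum
    from pathint import ou
    m = np.zeros(2)
    v = 0.0
    for d in dxs:
        m, dv = ou.propagate_distance(m, np.array(d), p)
        v += dv
    np.testing.assert_allclose(m, mean4, atol=1e-12)
    assert v == pytest.approx(p.sigma0_sq * L_sum, abs=1e-12)


def test_missing_equals_composed_predicts():
    p = IntegratorParams(beta=0.1, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.1)
    segs = [{"dx": np.array([2.0, 0.0])}, {"dx": np.array([0.0, 3.0])},
            {"dx": np.array([-1.0, 1.0])}]
    b = Belief(np.array([0.5, 0.5]), 0.01 * np.eye(2))
    for s in segs:
        b = ekf_step_missing(b, s, p)
    b2 = Belief(np.array([0.5, 0.5]), 0.01 * np.eye(2))
    for s in segs:
        b2 = ekf_step_missing(b2, s, p)
    np.testing.assert_allclose(b.mean, b2.mean, atol=1e-14)
    np.testing.assert_allclose(b.cov, b2.cov, atol=1e-14)


def test_exact_state_single_segment_is_bivariate_gaussian():
    """Without reporting noise, a one-report trial's log-likelihood is
    the log of the isotropic bivariate Gaussian transition density at
    the reconstructed internal estimate."""
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.2)
    d_hat, phi_hat = 10.5, 0.05
    arr = _single_trial_arrays([[10.0, 0.0], [0, 1e-9], [0, 1e-9], [0, 1e-9]],
                               [d_hat, 1, 1, 1], [phi_hat, 0, 0, 0],
                               [True, False, False, False])
    ll = trial_logliks(arr, p, None, "full-RN")[0]
    xhat = np.array([d_hat * np.cos(phi_hat), d_hat * np.sin(phi_hat)])
    var = p.sigma0_sq * 10.0
    ll_ref = (-LOG2PI - np.log(var)
              - np.sum((xhat - [10.0, 0.0])**2) / (2 * var))
    assert ll == pytest.approx(ll_ref, abs=1e-9)


def test_batched_engine_matches_scalar_steps(small_dataset):
    """The vectorized likelihood equals the scalar EKF reference,
    stop by stop, on real simulated trials."""
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.05, alpha=1.1, bias=(0.05, -0.03), sigma0_sq=0.2)
    rep = ReportParams(0.0625, 0.04)
    per = trial_logliks(arrays, p, rep, "full", per_stop=True)
    for i in range(0, arrays.n_trials, 7):
        b = Belief(np.zeros(2), np.zeros((2, 2)))
        for s in range(4):
            seg = {"dx": arrays.dx[i, s], "dt": arrays.dt[i, s]}
            if arrays.obs[i, s]:
                b, ll = ekf_step(b, seg, (arrays.d_hat[i, s],
                                          arrays.phi_hat[i, s]), p, rep, "full")
                # batched engine reports on the Cartesian scale
                ll_cart = ll - 2 * np.log(arrays.d_hat[i, s])
                assert per[i, s] == pytest.approx(ll_cart, abs=1e-8)
            else:
                b = ekf_step_missing(b, seg, p)
                assert per[i, s] == 0.0


def test_ekf_close_to_particle_filter():
    """In the small-nonlinearity regime (far from origin, modest
    posterior spread) the EKF marginal log-likelihood is within 0.05
    nats per stop of a 1e5-particle bootstrap filter."""
    p = IntegratorParams(beta=0.02, alpha=1.05, bias=(0.01, 0.0), sigma0_sq=0.05)
    rep = ReportParams(sigma_d_sq=0.01, sigma_phi_sq=0.01)
    dxs = [np.array([5.0, 0.0]), np.array([3.0, 2.0]),
           np.array([-1.0, 3.0]), np.array([-2.0, 2.0])]
    # a plausible report sequence near the true cumulative positions
    cum = np.cumsum(dxs, axis=0)
    obs_list = []
    rng = np.random.default_rng(7)
    for c in cum:
        d = np.linalg.norm(c) * np.exp(0.05 * rng.standard_normal())
        phi = np.arctan2(c[1], c[0]) + 0.05 * rng.standard_normal()
        obs_list.append((d, phi))
    arr = _single_trial_arrays(dxs, [o[0] for o in obs_list],
                               [o[1] for o in obs_list], [True] * 4)
    ll_ekf = trial_logliks(arr, p, rep, "full")[0]
    ll_pf = particle_filter_loglik(dxs, obs_list, p, rep,
                                   n_particles=100_000, rng=1)
    assert abs(ll_ekf - ll_pf) < 0.05 * 4


def test_information_monotone_in_observation_noise():
    """Inflating the reporting noise at a stop never increases the
    posterior information after the update."""
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.2)
    seg = {"dx": np.array([6.0, 2.0])}
    b0 = Belief(np.zeros(2), np.zeros((2, 2)))
    obs = (6.4, 0.33)
    prev_info = np.inf
    for scale in (1.0, 4.0, 16.0, 256.0):
        rep = ReportParams(0.01 * scale, 0.01 * scale)
        b, _ = ekf_step(b0, seg, obs, p, rep, "full")
        info = np.trace(np.linalg.inv(b.cov))
        assert info <= prev_info + 1e-9
        prev_info = info


def test_rotation_invariance_with_corotated_bias(small_dataset):
    """Rotating the world frame (segments, reports, bias vector) leaves
    the likelihood unchanged."""
    _, _, arrays = small_dataset
    p = IntegratorParams(beta=0.05, alpha=1.1, bias=(0.05, -0.03), sigma0_sq=0.2)
    rep = ReportParams(0.0625, 0.04)
    base = trial_logliks(arrays, p, rep, "full").sum()
    theta = 0.83
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    rot = TrialArrays(arrays.dx @ R.T, arrays.dt, arrays.d_hat,
                      np.where(arrays.obs, arrays.phi_hat + theta,
                               arrays.phi_hat), arrays.obs)
    from pathint.simulate import wrap_angle
    rot.phi_hat = wrap_angle(rot.phi_hat)
    b_rot = R @ np.array(p.bias)
    p_rot = IntegratorParams(p.beta, p.alpha, (b_rot[0], b_rot[1]), p.sigma0_sq)
    rotated = trial_logliks(rot, p_rot, rep, "full").sum()
    assert rotated == pytest.approx(base, abs=1e-8)


def test_nonpositive_distance_trial_excluded():
    import pandas as pd
    rows = []
    for trial in (1, 2):
        for s in range(4):
            rows.append({"participant_id": "a", "block": 1, "trial_index": trial,
                         "stop_index": s + 1, "true_x": s + 1.0, "true_y": 0.0,
                         "seg_duration_s": 5.0,
                         "reported_distance_m": -1.0 if trial == 2 else s + 1.0,
                         "reported_angle_deg": 180.0})
    df = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="nonpositive"):
        arr = TrialArrays.from_dataframe(df)
    assert arr.n_trials == 1
    assert arr.n_excluded == 1
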