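"""Generative model: internal estimates, reports, verbal bias, cohorts."""

import numpy as np
import pandas as pd
import pytest

from pathint import ou
from pathint.params import IntegratorParams, ReportParams
from pathint.simulate import (GenerativeAgent,
                              apply_verbal_bias, bias_band, simulate_cohort,
                              simulate_internal_estimates, simulate_participant,
                              simulate_reports, wrap_angle)


def _ideal_agent(**kw):
    return GenerativeAgent(integrator=IntegratorParams(), reporter=ReportParams(),
                           **kw)


def test_noiseless_ideal_integrator_tracks_truth(paths):
    xhat, dur = simulate_internal_estimates(paths[0], _ideal_agent(),
                                            mode="distance", seed=0)
    np.testing.assert_allclose(xhat, paths[0].stop_positions, atol=1e-12)
    assert np.all(dur > 0)


def test_pure_gain_scales_displacement(paths):
    ag = GenerativeAgent(integrator=IntegratorParams(alpha=1.2),
                         reporter=ReportParams())
    xhat, _ = simulate_internal_estimates(paths[0], ag, mode="distance", seed=0)
    # each chord displacement is scaled by alpha, so the estimate is 1.2x
    # the cumulative chord sum
    chords = np.diff(np.vstack([np.zeros(2), paths[0].stop_positions]), axis=0)
    np.testing.assert_allclose(xhat, 1.2 * np.cumsum(chords, axis=0), atol=1e-12)


def test_internal_estimate_moments_match_kernel(paths):
    """Empirical mean/variance over many draws match the closed-form
    transition moments of the first segment."""
    p = IntegratorParams(beta=0.1, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.04)
    ag = GenerativeAgent(integrator=p, reporter=ReportParams())
    n = 20_000
    rng = np.random.default_rng(5)
    first = np.array([simulate_internal_estimates(paths[0], ag, "distance",
                                                  rng)[0][0]
                      for _ in range(n)])
    dx = paths[0].stop_positions[0]
    mean, var = ou.propagate_distance(np.zeros(2), dx, p)
    se = np.sqrt(var / n)
    np.testing.assert_array_less(np.abs(first.mean(axis=0) - mean), 4 * se)
    v_emp = first.var(axis=0)
    np.testing.assert_array_less(np.abs(v_emp - var),
                                 4 * var * np.sqrt(2 / n))


def test_reports_zero_noise_identity():
    d, phi = simulate_reports(np.array([[3.0, 4.0]]), (0.0, 0.0),
                              ReportParams(), mode="weber", seed=0)
    assert d[0] == pytest.approx(5.0)
    assert phi[0] == pytest.approx(np.arctan2(4, 3))


def test_weber_noise_is_lognormal_and_proportional():
    rep = ReportParams(sigma_d_sq=0.09, sigma_phi_sq=0.0)
    rng = np.random.default_rng(3)
    for d_true in (2.0, 6.0, 10.0):
        d, _ = simulate_reports(np.tile([d_true, 0.0], (50_000, 1)),
                                (0.0, 0.0), rep, mode="weber", seed=rng)
        assert np.std(np.log(d)) == pytest.approx(0.3, rel=0.03)
    # |d_hat - d| grows ~ linearly with d
    errs = []
    for d_true in (2.0, 6.0, 10.0):
        d, _ = simulate_reports(np.tile([d_true, 0.0], (50_000, 1)),
                                (0.0, 0.0), rep, mode="weber", seed=rng)
        errs.append(np.mean(np.abs(d - d_true)))
    ratios = np.array(errs) / np.array([2.0, 6.0, 10.0])
    assert np.allclose(ratios, ratios[0], rtol=0.05)


def test_weber_degenerate_at_start_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        simulate_reports(np.array([[0.0, 0.0]]), (0.0, 0.0),
                         ReportParams(0.01, 0.01), mode="weber", seed=0)


def test_angles_wrapped():
    rep = ReportParams(sigma_d_sq=0.0, sigma_phi_sq=4.0)
    _, phi = simulate_reports(np.tile([5.0, 0.0], (10_000, 1)), (0.0, 0.0),
                              rep, mode="weber", seed=1)
    assert np.all(phi > -np.pi) and np.all(phi <= np.pi)


def test_verbal_bias_bands_and_roundtrip():
    ag = _ideal_agent(verbal_bias_factors=(2.0, 1.5, 1.25))
    assert bias_band(3.9) == 0 and bias_band(4.0) == 1 and bias_band(8.0) == 2
    out = apply_verbal_bias(np.array([2.0, 6.0, 10.0]), ag)
    np.testing.assert_allclose(out, [1.0, 4.0, 8.0])
    # unit factors are the identity
    same = apply_verbal_bias(np.array([2.0, 6.0, 10.0]), _ideal_agent())
    np.testing.assert_allclose(same, [2.0, 6.0, 10.0])


def test_standardization_recovers_factors_without_noise(paths, design):
    from pathint.errors import correction_factor_table
    ag = _ideal_agent(verbal_bias_factors=(1.3, 1.1, 0.9))
    _, std = simulate_participant(ag, paths, design, rng=0)
    fac = correction_factor_table(std)
    np.testing.assert_allclose(fac["f_short"], 1.3, rtol=1e-12)
    np.testing.assert_allclose(fac["f_middle"], 1.1, rtol=1e-12)
    np.testing.assert_allclose(fac["f_long"], 0.9, rtol=1e-12)


def test_standardization_recovery_unbiased_with_noise():
    """Across many noisy standardization triplets the recovered factor is
    centred on the generating factor (geometric mean, matching the
    log-normal reporting noise)."""
    from pathint.simulate import simulate_standardization
    ag = GenerativeAgent(integrator=IntegratorParams(),
                         reporter=ReportParams(sigma_d_sq=0.04),
                         verbal_bias_factors=(1.4, 1.4, 1.4))
    rng = np.random.default_rng(9)
    recovered = []
    for _ in range(200):
        std = simulate_standardization(ag, rng=rng)
        recovered.extend((std["true_length_m"] / std["response_m"]).tolist())
    gmean = np.exp(np.mean(np.log(recovered)))
    assert gmean == pytest.approx(1.4, rel=0.02)


def test_cohort_counts_and_determinism(paths, design):
    t1, s1, truth1 = simulate_cohort(3, 2, design=design, paths=paths, seed=42)
    t2, s2, truth2 = simulate_cohort(3, 2, design=design, paths=paths, seed=42)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(s1, s2)
    assert truth1.keys() == truth2.keys()
    assert t1["participant_id"].nunique() == 5
    # per participant: 48 trials, 30 with and 18 without stops
    per = t1.drop_duplicates(["participant_id", "block", "trial_index"])
    counts = per.groupby("participant_id")["with_stops"].agg(["sum", "count"])
    assert (counts["count"] == 48).all()
    assert (counts["sum"] == 30).all()
    # standardization: 6 triplets of 3 per participant
    assert (s1.groupby("participant_id").size() == 18).all()


def test_cohort_zero_noise_reports_exact(paths, design):
    from pathint.simulate import GroupSpec
    ideal = GroupSpec(_ideal_agent(), rate_spread=0.0, alpha_sd=0.0, bias_sd=0.0)
    t, _, _ = simulate_cohort(1, 0, {"young": ideal, "old": ideal},
                              design=design, paths=paths, seed=0)
    obs = t.dropna(subset=["reported_distance_m"])
    true_d = np.hypot(obs["true_x"], obs["true_y"])
    np.testing.assert_allclose(obs["reported_distance_m"], true_d, atol=1e-9)


def test_time_mode_pauses_add_variance(paths):
    """In time scaling, pausing at stops lets noise accrue: final-stop
    spread is larger with pauses than without."""
    p = IntegratorParams(beta=0.0, alpha=1.0, bias=(0.0, 0.0), sigma0_sq=0.05)
    ag = GenerativeAgent(integrator=p, reporter=ReportParams(),
                         pause_mean=20.0, pause_sd=0.0)
    rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
    n = 3000
    with_p = np.array([simulate_internal_estimates(
        paths[0], ag, "time", rng1, pauses=np.array([0., 20., 20., 20.]))[0][3]
        for _ in range(n)])
    without = np.array([simulate_internal_estimates(
        paths[0], ag, "time", rng2)[0][3] for _ in range(n)])
    extra = 3 * 20.0 * p.sigma0_sq   # variance added by the pauses per axis
    gap = with_p.var(axis=0) - without.var(axis=0)
    np.testing.assert_allclose(gap, extra, rtol=0.2)


def test_wrap_angle_range():
    a = wrap_angle(np.array([np.pi, -np.pi, 3 * np.pi, -2.5 * np.pi]))
    assert np.all(a > -np.pi) and np.all(a <= np.pi)
    np.testing.assert_allclose(wrap_angle(np.pi), np.pi)
    np.testing.assert_allclose(wrap_angle(-np.pi), np.pi)
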