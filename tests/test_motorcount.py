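"""Displacement-fluctuation statistics: phi curves, asymptotes, quantization."""

import numpy as np
import pytest

import dyntrack as dt
from dyntrack.motorcount import default_tau_grid, phi_theory
from conftest import transport_config


def _simulated_phi_asymptote(step_model, n_motors, seed, duration_s=60.0):
    traj = dt.simulate_cargo_trajectory(
        step_model, transport_config(n_motors=n_motors, seed=seed,
                                     duration_s=duration_s)
    )
    stats = dt.displacement_stats(traj.x_nm, dt_s=0.01)
    curve = dt.phi_curve(stats, noise_sd_nm=2.0)
    phi_inf, converged = dt.phi_asymptote(curve)
    assert converged
    return phi_inf


# ---------------------------------------------------------------------------
# Displacement statistics
# ---------------------------------------------------------------------------

def test_stationary_noise_statistics():
    """Pure localization noise (sigma = 3 nm): mu ~ 0 and s^2 ~ 2 sigma^2."""
    rng = np.random.default_rng(0)
    mus, s2s = [], []
    for _ in range(8):
        pos = rng.normal(0, 3.0, 4000)
        st = dt.displacement_stats(pos, tau_grid=[0.05], dt_s=0.01)[0]
        mus.append(st.mu_nm)
        s2s.append(st.s2_nm2)
    mus, s2s = np.array(mus), np.array(s2s)
    assert abs(mus.mean()) < 3 * mus.std(ddof=1) / np.sqrt(8)
    assert abs(s2s.mean() - 18.0) < 3 * s2s.std(ddof=1) / np.sqrt(8)


def test_single_motor_moments_match_compound_poisson(step_model):
    mus, s2s = [], []
    for seed in range(6):
        traj = dt.simulate_cargo_trajectory(step_model, transport_config(seed=30 + seed))
        st = dt.displacement_stats(traj.x_nm, tau_grid=[0.1], dt_s=0.01)[0]
        mus.append(st.mu_nm)
        s2s.append(st.s2_nm2)
    mus, s2s = np.array(mus), np.array(s2s)
    assert abs(mus.mean() - 120.0) < 3 * mus.std(ddof=1) / np.sqrt(6)
    assert abs(s2s.mean() - 2408.0) < 3 * s2s.std(ddof=1) / np.sqrt(6)


def test_default_tau_grid_includes_display_delays():
    grid = default_tau_grid()
    for tau in (0.01, 0.04, 0.1):
        assert np.any(np.isclose(grid, tau))
    assert grid[0] == 0.01 and np.isclose(grid[-1], 0.2)


def test_off_grid_tau_snapped_with_warning():
    pos = np.arange(1000.0) + np.random.default_rng(1).normal(0, 1, 1000)
    with pytest.warns(UserWarning, match="snapped"):
        st = dt.displacement_stats(pos, tau_grid=[0.0151], dt_s=0.01)
    assert st[0].tau_s == pytest.approx(0.02)


def test_histogram_and_moment_estimates_agree():
    """Within 2% on a Gaussian fixture (cross-check of the fitting mode)."""
    rng = np.random.default_rng(5)
    pos = np.cumsum(rng.normal(30.0, 20.0, 30000))
    m = dt.displacement_stats(pos, tau_grid=[0.05], dt_s=0.01, method="moments")[0]
    h = dt.displacement_stats(pos, tau_grid=[0.05], dt_s=0.01, method="histogram")[0]
    assert abs(h.mu_nm - m.mu_nm) / abs(m.mu_nm) < 0.02
    assert abs(h.s2_nm2 - m.s2_nm2) / m.s2_nm2 < 0.02


# ---------------------------------------------------------------------------
# phi curves and asymptotes
# ---------------------------------------------------------------------------

def test_zero_mean_gives_zero_phi():
    stats = [dt.DisplacementStats(tau_s=t, mu_nm=0.0, s2_nm2=10.0, n_pairs=100)
             for t in (0.1, 0.15, 0.2)]
    curve = dt.phi_curve(stats)
    assert np.all(curve.phi_inv_nm == 0.0)


def test_phi_relaxation_matches_closed_form(step_model):
    """Measured phi(tau) follows 2*lam*tau*d / (lam*tau*(d^2+v) + 2 sigma^2)."""
    curves = []
    for seed in range(4):
        traj = dt.simulate_cargo_trajectory(step_model, transport_config(seed=50 + seed))
        stats = dt.displacement_stats(traj.x_nm, dt_s=0.01)
        curves.append(dt.phi_curve(stats).phi_inv_nm)
    measured = np.mean(curves, axis=0)
    expected = phi_theory(default_tau_grid(), 8.0, 96.0, 150.0, 1, noise_sd_nm=2.0)
    np.testing.assert_allclose(measured, expected, rtol=0.08)


def test_noise_floor_entries_dropped():
    stats = [dt.DisplacementStats(tau_s=0.01, mu_nm=1.0, s2_nm2=5.0, n_pairs=100),
             dt.DisplacementStats(tau_s=0.02, mu_nm=2.0, s2_nm2=50.0, n_pairs=100)]
    with pytest.warns(UserWarning, match="noise floor"):
        curve = dt.phi_curve(stats, noise_sd_nm=2.0)
    assert len(curve.phi_inv_nm) == 1


def test_flat_curve_converges_to_plateau():
    taus = np.arange(0.01, 0.21, 0.01)
    stats = [dt.DisplacementStats(tau_s=t, mu_nm=t * 100, s2_nm2=t * 1000, n_pairs=100)
             for t in taus]
    curve = dt.phi_curve(stats)
    phi_inf, converged = dt.phi_asymptote(curve)
    assert converged
    assert phi_inf == pytest.approx(0.2, abs=1e-12)


def test_drifting_curve_flagged_nonconverged():
    taus = np.arange(0.01, 0.21, 0.01)
    phi_with_drift = 0.2 + 0.5 * taus  # 20%+ drift across the tail
    stats = [dt.DisplacementStats(tau_s=t, mu_nm=p * 5.0, s2_nm2=10.0, n_pairs=100)
             for t, p in zip(taus, phi_with_drift)]
    curve = dt.phi_curve(stats)
    phi_inf, converged = dt.phi_asymptote(curve)
    assert not converged and phi_inf is None


def test_too_few_tail_points_nonconverged():
    stats = [dt.DisplacementStats(tau_s=t, mu_nm=1.0, s2_nm2=10.0, n_pairs=100)
             for t in (0.05, 0.13)]
    _, converged = dt.phi_asymptote(dt.phi_curve(stats))
    assert not converged


def test_phi_asymptote_invariant_under_tail_rescaling(step_model):
    """The asymptote does not depend on which tail window is averaged
    (checked on replicate-averaged curves to beat single-trace noise)."""
    grid_a = np.arange(0.12, 0.21, 0.01)
    grid_b = 2.0 * grid_a
    phis = {0.12: [], 0.24: []}
    for seed in range(4):
        traj = dt.simulate_cargo_trajectory(
            step_model, transport_config(seed=60 + seed, duration_s=120.0))
        for grid, tau_min in [(grid_a, 0.12), (grid_b, 0.24)]:
            stats = dt.displacement_stats(traj.x_nm, tau_grid=grid, dt_s=0.01)
            curve = dt.phi_curve(stats, noise_sd_nm=2.0)
            phi_inf, conv = dt.phi_asymptote(curve, tau_min_s=tau_min)
            assert conv
            phis[tau_min].append(phi_inf)
    a, b = np.mean(phis[0.12]), np.mean(phis[0.24])
    assert abs(a - b) / a < 0.05


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def test_identical_values_form_single_cluster():
    centers, n, phi1 = dt.cluster_quantized(np.full(20, 0.1))
    assert len(centers) == 1
    assert centers[0] == pytest.approx(0.1)
    assert np.all(n == 1)


def test_kmeans_recovers_quantized_mixture():
    rng = np.random.default_rng(9)
    values = np.concatenate([rng.normal(c, 0.02, 40) for c in (0.1, 0.2, 0.3)])
    centers, n, phi1 = dt.cluster_quantized(values, seed=0)
    assert len(centers) == 3
    np.testing.assert_allclose(centers, [0.1, 0.2, 0.3], atol=0.01)
    assert abs(phi1 - 0.1) < 0.01
    assert set(np.unique(n)) == {1, 2, 3}


def test_quantization_law_for_one_to_five_motors(step_model):
    """E[phi_inf] = n * 2d/(d^2+v) = n * 0.1 /nm within 5% for n = 1..5."""
    for n_motors in range(1, 6):
        phis = [_simulated_phi_asymptote(step_model, n_motors, seed=70 + 10 * n_motors + r)
                for r in range(8)]
        assert abs(np.mean(phis) - 0.1 * n_motors) / (0.1 * n_motors) < 0.05


def test_velocity_not_quantized_while_phi_is(step_model):
    """Mean segment velocities for n = 1..3 differ by < 25% while the phi
    asymptotes differ by integer factors."""
    vels, phis = [], []
    for n_motors in (1, 2, 3):
        v_rep, phi_rep = [], []
        for r in range(4):
            traj = dt.simulate_cargo_trajectory(
                step_model, transport_config(n_motors=n_motors, seed=90 + 10 * n_motors + r))
            v_rep.append((traj.x_nm[-1] - traj.x_nm[0]) / traj.t_s[-1])
            phi_rep.append(_simulated_phi_asymptote(
                step_model, n_motors, seed=90 + 10 * n_motors + r))
        vels.append(np.mean(v_rep))
        phis.append(np.mean(phi_rep))
    vels, phis = np.array(vels), np.array(phis)
    assert np.ptp(vels) / vels.mean() < 0.25
    np.testing.assert_allclose(phis / phis[0], [1.0, 2.0, 3.0], rtol=0.1)


def test_motor_count_summary_trivial_and_recovery():
    result = dt.motor_count_summary(np.full(10, 0.1))
    assert result.mean_n == 1.0 and result.se_n == 0.0

    rng = np.random.default_rng(11)
    design = np.repeat([1, 2, 3], [30, 50, 20])
    values = rng.normal(0.1 * design, 0.015)
    result = dt.motor_count_summary(values, seed=1)
    se_design = design.std(ddof=1) / np.sqrt(len(design))
    assert abs(result.mean_n - design.mean()) < 2 * se_design
    assert set(result.histogram()) <= {1, 2, 3, 4, 5}


def test_mixed_cohort_histogram_support(step_model):
    values = np.concatenate([
        [_simulated_phi_asymptote(step_model, n, seed=100 + 20 * n + r) for r in range(8)]
        for n in (1, 2, 3)
    ])
    result = dt.motor_count_summary(values, seed=2)
    assert set(result.histogram()) <= set(range(1, 6))
    np.testing.assert_allclose(result.centers_inv_nm, [0.1, 0.2, 0.3], atol=0.015)
    assert abs(result.phi1_inv_nm - 0.1) < 0.01
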