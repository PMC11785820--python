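"""Step finding, dwell-time MLE, randomness parameter, Arrhenius analysis."""

import numpy as np
import pytest
from scipy import optimize, stats

import dyntrack as dt
from dyntrack.stepkin import R_KCAL_PER_MOL_K


# ---------------------------------------------------------------------------
# Step finding
# ---------------------------------------------------------------------------

def test_noiseless_staircase_recovered_exactly():
    stair = np.repeat([0.0, 8.0, 16.0, 24.0, 32.0, 40.0], 20)
    fit = dt.find_steps(stair)
    assert fit.n_steps == 5
    np.testing.assert_allclose(fit.step_sizes_nm, 8.0)
    np.testing.assert_array_equal(fit.boundaries, [20, 40, 60, 80, 100])
    assert fit.residual_sd_nm < 1e-9


def test_flat_trace_yields_zero_steps():
    assert dt.find_steps(np.zeros(100)).n_steps == 0
    rng = np.random.default_rng(0)
    assert dt.find_steps(rng.normal(0, 2, 500)).n_steps == 0


def test_step_finder_is_idempotent():
    rng = np.random.default_rng(1)
    trace = np.repeat([0.0, 8, 24, 32, 48], 30) + rng.normal(0, 1.5, 150)
    fit = dt.find_steps(trace)
    widths = np.diff(np.concatenate([[0], fit.boundaries, [fit.n_frames]]))
    staircase = np.repeat(fit.levels_nm, widths)
    refit = dt.find_steps(staircase)
    np.testing.assert_array_equal(fit.boundaries, refit.boundaries)
    np.testing.assert_allclose(fit.levels_nm, refit.levels_nm, atol=1e-9)


def test_noisy_staircase_recovery(pure8_model):
    """22 C-like fixture (mean dwell 144 ms, 2.5-ms frames, 2-nm noise):
    >= 95% of true steps found within 1 frame, size RMSE < 2 nm."""
    frame = 0.0025
    trace = dt.simulate_step_trace(pure8_model, dwell_rate_s=13.9, n_steps=120,
                                   noise_sd_nm=2.0, frame_interval_s=frame, seed=3)
    fit = dt.find_steps(trace)
    found_t = fit.boundaries * frame
    true_t = trace.meta["true_step_times_s"]
    errors = []
    matched = 0
    for tt, size in zip(true_t, trace.meta["true_step_sizes_nm"]):
        i = np.argmin(np.abs(found_t - tt))
        if abs(found_t[i] - tt) <= frame:
            matched += 1
            errors.append(fit.step_sizes_nm[i] - size)
    assert matched / len(true_t) >= 0.95
    assert np.sqrt(np.mean(np.square(errors))) < 2.0


def test_step_size_histogram_mode_near_8nm(pure8_model):
    trace = dt.simulate_step_trace(pure8_model, dwell_rate_s=13.9, n_steps=150,
                                   noise_sd_nm=2.0, frame_interval_s=0.0025, seed=5)
    fit = dt.find_steps(trace)
    counts, edges = np.histogram(fit.step_sizes_nm, bins=np.arange(2, 30, 2))
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    assert abs(mode - 8.0) <= 2.0


def test_sub_minimum_steps_merged():
    stair = np.repeat([0.0, 2.0, 10.0], 30)  # 2-nm step below the 4-nm floor
    fit = dt.find_steps(stair, min_step_nm=4.0)
    assert fit.n_steps == 1
    assert fit.step_sizes_nm[0] == pytest.approx(9.0, abs=1.0)


def test_short_traces_rejected():
    with pytest.raises(ValueError, match=">= 20 frames"):
        dt.find_steps(np.zeros(10))


# ---------------------------------------------------------------------------
# Dwell extraction
# ---------------------------------------------------------------------------

def test_dwells_from_boundaries():
    fit = dt.StepFit(boundaries=np.array([10, 20, 35]),
                     levels_nm=np.array([0.0, 8.0, 16.0, 24.0]),
                     residual_sd_nm=1.0, quality=5.0, n_frames=60)
    sample = dt.dwell_times(fit, 0.001)
    np.testing.assert_allclose(sample.dwells_s, [0.010, 0.015])
    assert sample.censor_s == pytest.approx(0.002)


def test_dwell_censoring_excludes_subresolution_intervals():
    fit = dt.StepFit(boundaries=np.array([10, 11, 30]),
                     levels_nm=np.array([0.0, 8.0, 16.0, 24.0]),
                     residual_sd_nm=1.0, quality=5.0, n_frames=60)
    sample = dt.dwell_times(fit, 0.001)
    np.testing.assert_allclose(sample.dwells_s, [0.019])


def test_recovered_dwell_distribution_close_to_truth(pure8_model):
    """Kolmogorov-Smirnov distance < 0.05 between recovered and true dwells."""
    frame = 0.0025
    trace = dt.simulate_step_trace(pure8_model, dwell_rate_s=13.9, n_steps=300,
                                   noise_sd_nm=2.0, frame_interval_s=frame, seed=4)
    fit = dt.find_steps(trace)
    recovered = np.diff(fit.boundaries) * frame
    true = trace.meta["true_dwells_s"][1:]
    assert stats.ks_2samp(recovered, true).statistic < 0.05


def test_censoring_bias_below_three_percent():
    """Excluding dwells under 2 frames biases k by < 3% in magnitude when
    the frame interval is <= 5% of the mean dwell.  (Dropping short dwells
    lengthens the surviving mean, so the small bias is downward.)"""
    k = 13.9
    frame = 0.05 * (2.0 / k) / 2  # exactly at the stated operating point
    d = dt.simulate_dwells("erlang2", {"k": k}, 200_000, seed=6).dwells_s
    kept = d[d >= 2 * frame]
    k_hat = 2.0 / kept.mean()
    assert abs(k_hat - k) / k < 0.03
    assert k_hat <= k  # censoring can only lengthen the surviving mean


# ---------------------------------------------------------------------------
# Dwell MLE
# ---------------------------------------------------------------------------

def test_erlang2_closed_form_on_constant_dwells():
    d = np.full(100, 0.25)
    fit = dt.fit_dwell_mle(d, "erlang2")
    assert fit.rate_s == pytest.approx(8.0)
    assert fit.se_rate_s == pytest.approx(8.0 / np.sqrt(200))
    assert fit.aic == pytest.approx(2 - 2 * fit.loglik)


def test_erlang2_mle_equals_numerical_optimizer():
    d = dt.simulate_dwells("erlang2", {"k": 50.0}, 2000, seed=7).dwells_s
    closed = dt.fit_dwell_mle(d, "erlang2").rate_s

    def nll(logk):
        k = np.exp(logk)
        return -(np.sum(2 * np.log(k) + np.log(d) - k * d))

    res = optimize.minimize_scalar(nll, bounds=(np.log(1.0), np.log(500.0)),
                                   method="bounded", options={"xatol": 1e-12})
    assert closed == pytest.approx(np.exp(res.x), rel=1e-6)


def test_rate_recovered_at_37C(pure8_model):
    d = dt.simulate_dwells("erlang2", {"k": 97.1}, 100_000, seed=8)
    fit = dt.fit_dwell_mle(d, "erlang2")
    assert abs(fit.rate_s - 97.1) < 3 * fit.se_rate_s
    assert fit.se_rate_s == pytest.approx(97.1 / np.sqrt(2e5), rel=0.05)


def test_mle_spread_matches_fisher_information():
    """SD of k across replicates of the 22 C sample size (n = 283) matches
    the Fisher prediction k/sqrt(2n) = 0.584, printed as 0.6."""
    rng = np.random.default_rng(9)
    k_hats = 2.0 / rng.gamma(2.0, 1.0 / 13.9, size=(1000, 283)).mean(axis=1)
    sd = k_hats.std(ddof=1)
    fisher = 13.9 / np.sqrt(2 * 283)
    assert abs(sd - fisher) < 3 * fisher / np.sqrt(2 * 999)
    assert round(float(sd), 1) == 0.6


def test_estimator_error_scales_as_inverse_sqrt_n():
    rng = np.random.default_rng(10)
    ns = np.array([50, 200, 800, 3200])
    sds = [
        (2.0 / rng.gamma(2.0, 1.0 / 20.0, size=(300, n)).mean(axis=1)).std(ddof=1)
        for n in ns
    ]
    slope = np.polyfit(np.log(ns), np.log(sds), 1)[0]
    assert abs(slope + 0.5) < 0.05


def test_gamma_mle_shape_near_two_on_erlang2_data():
    d = dt.simulate_dwells("erlang2", {"k": 97.1}, 5000, seed=11)
    fit = dt.fit_dwell_mle(d, "gamma")
    assert 1.8 < fit.shape < 2.2
    assert fit.se_rate_s > 0


def test_nonpositive_dwells_rejected():
    with pytest.raises(ValueError, match="> 0"):
        dt.fit_dwell_mle(np.array([0.1, -0.2] * 20), "erlang2")


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def test_erlang2_preferred_on_erlang2_data():
    """At the 37 C design size (n = 920) the two-equal-rate model beats the
    single exponential by a wide AIC margin; the gamma shape sits near 2 and
    the unconstrained two-rate fit returns k1 ~= k2."""
    d = dt.simulate_dwells("erlang2", {"k": 97.1}, 920, seed=12)
    ranked = dt.compare_dwell_models(d)
    by_id = {r.model_id: r for r in ranked}
    assert by_id["single_exp"].aic - by_id["erlang2"].aic > 10
    assert 1.8 < by_id["gamma"].shape < 2.2
    two = by_id["two_rate"]
    assert 0.8 < two.rate_s / two.rate2_s <= 1.0


def test_single_exponential_preferred_on_exponential_data():
    d = dt.simulate_dwells("single_exp", {"k": 40.0}, 2000, seed=13)
    ranked = dt.compare_dwell_models(d)
    by_id = {r.model_id: r for r in ranked}
    assert by_id["single_exp"].aic < by_id["erlang2"].aic


# ---------------------------------------------------------------------------
# Randomness parameter
# ---------------------------------------------------------------------------

def test_randomness_erlang2_gives_nmin_two():
    d = dt.simulate_dwells("erlang2", {"k": 97.1}, 100_000, seed=14)
    r = dt.randomness(d, n_boot=200, seed=0)
    assert abs(r.n_min - 2.0) < 0.02
    assert r.ci_low < r.r < r.ci_high


def test_randomness_four_sequential_rates_gives_four():
    rng = np.random.default_rng(15)
    d = rng.exponential(1.0 / 97.1, size=(4, 100_000)).sum(axis=0)
    r = dt.randomness(d, n_boot=100, seed=0)
    assert abs(r.n_min - 4.0) < 0.08


def test_randomness_requires_valid_input():
    with pytest.raises(ValueError, match=">= 100"):
        dt.randomness(np.full(10, 0.5))


# ---------------------------------------------------------------------------
# Arrhenius
# ---------------------------------------------------------------------------

def _rates_from_ea(ea, a, temps_c):
    t = np.asarray(temps_c) + 273.15
    return a * np.exp(-ea / (R_KCAL_PER_MOL_K * t))


def test_arrhenius_exact_recovery():
    temps = [22.0, 30.0, 37.0]
    ks = _rates_from_ea(20.0, 1e16, temps)
    res = dt.arrhenius_fit(list(zip(temps, ks)))
    assert res.ea_kcal_mol == pytest.approx(20.0, rel=1e-6)
    assert res.prefactor_s == pytest.approx(1e16, rel=1e-4)


def test_arrhenius_on_measured_rate_triple():
    """The three fitted stepping rates (13.9, 56.1, 97.1 s^-1 at 22/30/37 C)
    give Ea ~ 23.8 kcal/mol unweighted, inside the reported 25.1 +/- 23."""
    res = dt.arrhenius_fit([(22.0, 13.9, 0.6), (30.0, 56.1, 1.8), (37.0, 97.1, 2.3)])
    assert 22.0 < res.ea_kcal_mol < 26.0
    assert 25.1 - 23.0 < res.ea_kcal_mol < 25.1 + 23.0
    weighted = dt.arrhenius_fit(
        [(22.0, 13.9, 0.6), (30.0, 56.1, 1.8), (37.0, 97.1, 2.3)], weighted=True)
    assert 20.0 < weighted.ea_kcal_mol < 26.0


def test_equal_rates_give_zero_activation_energy():
    res = dt.arrhenius_fit([(22.0, 50.0), (30.0, 50.0), (37.0, 50.0)])
    assert abs(res.ea_kcal_mol) < 1e-9


def test_arrhenius_input_validation():
    with pytest.raises(ValueError, match="duplicate"):
        dt.arrhenius_fit([(22.0, 10.0), (22.0, 20.0)])
    with pytest.raises(ValueError, match=">= 2"):
        dt.arrhenius_fit([(22.0, 10.0)])


def test_truncated_mle_removes_censoring_bias():
    """Conditioning the likelihood on dwells above the censor threshold
    undoes the downward bias of the plain estimator."""
    k = 20.0
    censor = 0.2 * (2.0 / k)  # deliberately harsh censoring
    d = dt.simulate_dwells("erlang2", {"k": k}, 100_000, seed=20).dwells_s
    kept = dt.DwellSample(dwells_s=d[d >= censor], censor_s=censor)
    plain = dt.fit_dwell_mle(kept, "erlang2").rate_s
    corrected = dt.fit_dwell_mle(kept, "erlang2", truncated=True).rate_s
    assert plain < k  # plain MLE is biased down on censored data
    assert abs(corrected - k) < abs(plain - k) / 3
    assert abs(corrected - k) < 3 * k / np.sqrt(2 * kept.n)
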