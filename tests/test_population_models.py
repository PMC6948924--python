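"""Poisson population codes, decoding, calibration, and architectures."""

import numpy as np
import pandas as pd
import pytest

from tilt3d.population_models import (
    LambdaCalibration,
    PopulationSpec,
    architecture_experiment,
    combine_one_pop,
    combine_three_pop,
    combine_two_pop,
    decode_posterior,
    expected_combined_precision,
    expected_decoded_precision,
    fit_condition_gains,
    fit_lambda,
    interpolate_cip_table,
    normalization_bias,
    simulate_population,
    synthetic_cip_table,
    tuning_response,
)

SPEC = PopulationSpec()


class TestTuning:
    def test_preferred_tilt_spacing(self):
        assert SPEC.n_neurons == 72
        assert np.allclose(np.diff(SPEC.preferred_tilts), 5.0)

    def test_peak_and_antipreferred_rates(self):
        r = tuning_response(180.0, 7.0, 1.4)
        mu = SPEC.preferred_tilts
        assert r[mu == 180.0][0] == pytest.approx(7.0)
        assert r[mu == 0.0][0] == pytest.approx(7.0 * np.exp(-2 * 1.4))

    def test_spot_check_against_direct_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t, g, k = rng.uniform(0, 360), rng.uniform(0.1, 40), rng.uniform(0.2, 4)
            r = tuning_response(t, g, k)
            i = rng.integers(0, 72)
            mu_i = np.radians(SPEC.preferred_tilts[i])
            assert r[i] == pytest.approx(g * np.exp(k * (np.cos(np.radians(t) - mu_i) - 1)))


class TestPoissonSimulation:
    def test_zero_gain_all_zero(self):
        assert not simulate_population(180, 0.0, 1.5, seed=1).any()

    def test_mean_and_fano_match_poisson(self):
        R = simulate_population(180, 9.0, 1.2, seed=2, n_trials=8000)
        rates = tuning_response(180, 9.0, 1.2)
        se = np.sqrt(rates / 8000)
        assert np.all(np.abs(R.mean(0) - rates) < 4 * se + 1e-9)
        busy = rates > 0.5
        fano = R.var(0)[busy] / R.mean(0)[busy]
        assert np.median(fano) == pytest.approx(1.0, abs=0.1)


class TestCombinationRules:
    def test_linear_sum(self):
        r = np.ones((2, 72))
        assert np.allclose(combine_three_pop(r, r, r), 3.0)

    def test_binocular_equals_monocular_identity(self):
        rng = np.random.default_rng(3)
        r = rng.poisson(6, (5, 72)).astype(float)
        combined = combine_two_pop(np.zeros_like(r), r, r)
        assert np.allclose(combined, r)

    def test_winner_take_all_with_silent_eye(self):
        rng = np.random.default_rng(4)
        r = rng.poisson(6, (5, 72)).astype(float)
        assert np.allclose(combine_two_pop(np.zeros_like(r), r, np.zeros_like(r)), r)

    def test_zero_over_zero_is_zero(self):
        z = np.zeros((1, 72))
        assert not combine_two_pop(z, z, z).any()
        assert not combine_one_pop(z, z, z).any()

    def test_one_pop_fixed_points(self):
        rng = np.random.default_rng(5)
        r = rng.poisson(6, (5, 72)).astype(float)
        assert np.allclose(combine_one_pop(r, r, r), r)
        z = np.zeros_like(r)
        assert np.allclose(combine_one_pop(r, z, z), r)

    def test_imbalance_interpolates_average_to_winner(self):
        """Sweep right-eye strength: the normalized term moves monotonically
        from the balanced average toward winner-take-all."""
        left = np.full((1, 72), 10.0)
        fracs = np.linspace(0.0, 1.0, 11)
        vals = []
        for frac in fracs:
            right = left * frac
            term = combine_two_pop(np.zeros_like(left), left, right)[0, 0]
            vals.append(term)
            # analytic normalized quadratic sum at every imbalance level
            assert term == pytest.approx(10.0 * (1 + frac**2) / (1 + frac), rel=1e-12)
        # balanced -> 10 (average = monocular); silent eye -> 10 (winner);
        # intermediate imbalance dips below both endpoints
        assert vals[0] == pytest.approx(10.0) and vals[-1] == pytest.approx(10.0)
        assert min(vals) < 10.0

    def test_pointwise_response_ordering(self):
        rng = np.random.default_rng(6)
        r_s = rng.poisson(5, (20, 72)).astype(float)
        r_p = rng.poisson(7, (20, 72)).astype(float)
        one = combine_one_pop(r_s, r_p, r_p)
        two = combine_two_pop(r_s, r_p, r_p)
        three = combine_three_pop(r_s, r_p, r_p)
        assert np.all(one <= two + 1e-9)
        assert np.all(two <= three + 1e-9)


class TestDecoding:
    def test_zero_response_flat_flagged(self):
        d = decode_posterior(np.zeros(72), 1.5, lam=0.01)
        assert d["flat"].iloc[0] and d["precision"].iloc[0] == 0.0

    def test_decoded_mean_unbiased_at_presented_tilt(self):
        R = simulate_population(180, 25, 1.5, seed=7, n_trials=400)
        d = decode_posterior(R, 1.5, lam=0.01)
        err = ((d["mean_deg"] - 180.0 + 180) % 360) - 180
        assert abs(err.mean()) < 3 * err.std() / np.sqrt(len(err))

    def test_precision_proportional_to_gain(self):
        gains = np.arange(1, 11, dtype=float)
        prec = np.array([expected_decoded_precision(g, 1.5, lam=0.01) for g in gains])
        slope = np.sum(prec * gains) / np.sum(gains**2)
        resid = prec - slope * gains
        assert 1 - resid.var() / prec.var() > 0.99
        assert abs(resid).max() / prec.max() < 1e-6  # exactly through origin

    def test_precision_tilt_invariant_for_homogeneous_population(self):
        vals = [
            expected_decoded_precision(10, 1.5, lam=0.01, tilt=t) for t in (60.0, 180.0, 300.0)
        ]
        assert np.ptp(vals) / vals[0] < 1e-6

    def test_summary_variants_ordering(self):
        """Moments and LSQ summaries carry their documented offsets."""
        r = tuning_response(180, 15, 1.5)
        lap = decode_posterior(r, 1.5, lam=0.02, summary="laplace")["precision"].iloc[0]
        mom = decode_posterior(r, 1.5, lam=0.02, summary="moments")["precision"].iloc[0]
        lsq = decode_posterior(r, 1.5, lam=0.02, summary="lsq")["precision"].iloc[0]
        assert lap - 0.8 < mom < lap
        assert lap - 0.5 < lsq < lap

    def test_resolution_guard(self):
        with pytest.raises(ValueError):
            decode_posterior(np.zeros(72), 1.0, resolution=2.0)


class TestLambdaCalibration:
    KS = np.linspace(0.6, 2.4, 16)

    def test_exponential_family_recovered_from_printed_form(self):
        """Targets generated from the exponential calibration (DC=1.3e-3,
        G=3.70, alpha=2.37) with mild noise select the exponential family
        and recover its parameters."""
        true = 1.3e-3 + 3.70 * np.exp(-2.37 * self.KS)
        noisy = true * np.random.default_rng(8).lognormal(0, 0.03, len(self.KS))
        cal = fit_lambda(self.KS, noisy, np.ones_like(self.KS))
        assert cal.family == "exponential"
        dc, g, alpha = cal.params
        assert g == pytest.approx(3.70, rel=0.15)
        assert alpha == pytest.approx(2.37, rel=0.15)

    def test_constant_targets_select_linear_with_flat_slope(self):
        lam = np.full_like(self.KS, 0.05)
        cal = fit_lambda(self.KS, lam, np.ones_like(self.KS))
        assert cal.family == "linear"
        assert abs(cal.params[1]) < 1e-6

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            fit_lambda(self.KS[:3], self.KS[:3], np.ones(3))

    def test_roundtrip_serialization(self):
        cal = fit_lambda(self.KS, 0.1 * np.exp(-self.KS), np.ones_like(self.KS))
        d = cal.to_dict()
        assert d["family"] in {"linear", "exponential", "double-exponential", "two-phase-exponential"}
        assert len(d["aic"]) == 4


def _toy_calibration():
    ks = np.linspace(0.6, 2.4, 8)
    lam = 1.3e-3 + 0.4 * np.exp(-2.0 * ks)
    return fit_lambda(ks, lam, np.ones_like(ks))


class TestGainCalibration:
    def test_zero_target_zero_gain(self):
        cal = _toy_calibration()
        gains = fit_condition_gains(np.array([0.0, 4.0]), np.array([1.0, 1.0]), cal)
        assert gains[0] == 0.0 and gains[1] > 0

    def test_doubling_target_doubles_gain(self):
        cal = _toy_calibration()
        g = fit_condition_gains(np.array([3.0, 6.0]), np.array([1.5, 1.5]), cal)
        assert g[1] / g[0] == pytest.approx(2.0, rel=0.01)

    def test_roundtrip_precision_within_two_percent(self):
        cal = _toy_calibration()
        targets = np.array([2.0, 5.0, 12.0])
        ks = np.array([0.8, 1.5, 2.2])
        gains = fit_condition_gains(targets, ks, cal)
        for t, g, k in zip(targets, gains, ks):
            achieved = expected_decoded_precision(g, k, lam=float(cal(k)))
            assert achieved == pytest.approx(t, rel=0.02)


class TestNormalizationBias:
    def test_zero_rate_no_bias(self):
        assert normalization_bias(0.0) == 0.0

    def test_saturates_at_half(self):
        assert normalization_bias(0.3) < 0.35
        assert normalization_bias(8.0) == pytest.approx(0.5, abs=0.02)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(9)
        m = 1.7
        x = rng.poisson(m, 400_000)
        y = rng.poisson(m, 400_000)
        s = x + y
        q = np.where(s > 0, (x**2 + y**2) / np.where(s > 0, s, 1), 0.0)
        assert normalization_bias(m) == pytest.approx(q.mean() - m, abs=0.01)


class TestArchitectureExperiment:
    def test_ordering_ratio_and_gain_limit(self):
        cal = _toy_calibration()
        conds = pd.DataFrame(
            {
                "kappa_sd": [0.8, 1.2, 1.6, 2.0],
                "target_s": [2.5, 4.0, 6.0, 8.0],
                "target_p": [2.5, 3.0, 3.5, 4.0],
            }
        )
        res = architecture_experiment(conds, cal, n_trials=80, seed=10)
        assert (res["prec_three"] >= res["prec_two"]).all()
        assert (res["prec_two"] >= res["prec_one"]).all()
        ratio = res["prec_three"] / res["prec_two"]
        assert ((ratio > 1.0) & (ratio < 2.0)).all()

    def test_vanishing_stereo_gain_ratio_approaches_two(self):
        """With g_S ~ 0 the three-pop/two-pop gain ratio (g_S+2g_P)/(g_S+g_P)
        approaches 2."""
        cal = _toy_calibration()
        conds = pd.DataFrame({"kappa_sd": [1.2], "target_s": [0.02], "target_p": [6.0]})
        res = architecture_experiment(conds, cal, n_trials=200, seed=11)
        ratio = res["prec_three"].iloc[0] / res["prec_two"].iloc[0]
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_two_pop_matches_analytic_expectation(self):
        cal = _toy_calibration()
        conds = pd.DataFrame({"kappa_sd": [1.4], "target_s": [5.0], "target_p": [4.0]})
        res = architecture_experiment(conds, cal, n_trials=300, seed=12)
        pred = expected_combined_precision(
            res["gain_s"].iloc[0], res["gain_p"].iloc[0], 1.4, res["lambda"].iloc[0], "two"
        )
        assert res["prec_two"].iloc[0] == pytest.approx(pred, rel=0.02)


class TestSyntheticCipTable:
    def test_shape_and_ranges(self):
        t = synthetic_cip_table(seed=1)
        assert len(t) == 16
        assert t["amplitude"].between(5, 60).all()
        assert t["kappa_sd"].between(0.3, 3.5).all()

    def test_interpolation_hits_measured_points(self):
        t = synthetic_cip_table(seed=2)
        full = interpolate_cip_table(t, (37.0, 47.0, 57.0))
        merged = full.merge(t, on=["slant", "distance_cm"], suffixes=("", "_src"), how="inner")
        assert np.allclose(merged["amplitude"], merged["amplitude_src"])
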