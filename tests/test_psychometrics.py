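"""Tilt-error distributions, von Mises fits, chance and oblique-effect tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import vonmises

from tilt3d.psychometrics import (
    DELTA_BINS,
    KAPPA_CAP,
    ErrorDistribution,
    VonMisesFit,
    cardinal_oblique_summary,
    fit_von_mises,
    fit_von_mises_lsq,
    gaussian_refit,
    kappa_identifiability_bound,
    rayleigh_chance_test,
    tilt_errors,
    two_sample_circular_median_test,
    vm_bin_mass,
    wrap_degrees,
)


def table(presented, reported):
    return pd.DataFrame({"tilt": presented, "reported_tilt": reported})


@pytest.mark.parametrize(
    "presented,reported,expected_bin",
    [(270, 270, 0.0), (315, 0, 45.0), (315, 135, 180.0), (0, 225, -135.0)],
)
def test_tilt_error_wrapping(presented, reported, expected_bin):
    ed = tilt_errors(table([presented], [reported]))[0]
    assert ed.probs[np.where(DELTA_BINS == expected_bin)[0][0]] == 1.0


def test_tilt_errors_grouping_and_empty_input():
    df = table([0, 0, 90, 90], [0, 45, 90, 90])
    df["slant"] = [15, 15, 60, 60]
    eds = tilt_errors(df, ["slant"])
    assert len(eds) == 2
    assert eds[0].keys == {"slant": 15}
    with pytest.raises(ValueError):
        tilt_errors(df.iloc[:0])


@given(shift=st.integers(1, 5))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_wrap_invariance_of_reports(shift):
    """Adding full turns to reported tilts changes nothing."""
    rng = np.random.default_rng(0)
    presented = rng.choice(np.arange(0, 360, 45), 200)
    reported = rng.choice(np.arange(0, 360, 45), 200)
    base = tilt_errors(table(presented, reported))[0]
    shifted = tilt_errors(table(presented, reported + 360.0 * shift))[0]
    assert np.allclose(base.probs, shifted.probs)


class TestVonMisesFit:
    def test_uniform_gives_zero_kappa_flagged_mu(self):
        f = fit_von_mises(ErrorDistribution(np.full(8, 0.125), n=400))
        assert f.kappa == pytest.approx(0.0, abs=1e-3)
        assert f.mu == 0.0 and not f.mu_identified

    def test_single_bin_pegs_cap(self):
        f = fit_von_mises(ErrorDistribution(np.eye(8)[5], n=100))
        assert f.kappa == KAPPA_CAP and f.capped
        assert f.mu == pytest.approx(DELTA_BINS[5], abs=0.5)

    def test_recovery_from_binned_draws(self):
        """10^4 draws from kappa=4, mu=10 recover within the oracle band."""
        rng = np.random.default_rng(11)
        draws = np.degrees(vonmises(4, loc=np.radians(10)).rvs(10_000, random_state=rng))
        reported = np.round(draws / 45.0) * 45.0
        f = fit_von_mises(tilt_errors(table(np.zeros(10_000), reported))[0])
        assert 3.5 <= f.kappa <= 4.5
        assert abs(f.mu - 10.0) <= 5.0

    @given(delta=st.sampled_from([-135, -90, -45, 45, 90, 180]))
    @settings(max_examples=6, deadline=None, derandomize=True)
    def test_rotation_equivariance(self, delta):
        """Rotating all errors shifts mu and leaves kappa unchanged."""
        rng = np.random.default_rng(2)
        draws = np.degrees(vonmises(3, loc=np.radians(5)).rvs(4000, random_state=rng))
        reported = np.round(draws / 45.0) * 45.0
        f0 = fit_von_mises(tilt_errors(table(np.zeros(4000), reported))[0])
        f1 = fit_von_mises(tilt_errors(table(np.zeros(4000), reported + delta))[0])
        assert f1.kappa == pytest.approx(f0.kappa, rel=1e-3)
        assert abs(wrap_degrees(f1.mu - f0.mu - delta)) < 0.5

    def test_kappa_monotone_in_generating_concentration(self):
        rng = np.random.default_rng(3)
        medians = []
        for kappa in (1.0, 2.5, 6.0):
            fits = []
            for _ in range(5):
                draws = np.degrees(vonmises(kappa).rvs(800, random_state=rng))
                reported = np.round(draws / 45.0) * 45.0
                fits.append(fit_von_mises(tilt_errors(table(np.zeros(800), reported))[0]).kappa)
            medians.append(np.median(fits))
        assert medians[0] < medians[1] < medians[2]

    def test_lsq_variant_agrees_on_clean_data(self):
        ed = ErrorDistribution(vm_bin_mass(15.0, 3.0), n=10_000)
        mle, lsq = fit_von_mises(ed), fit_von_mises_lsq(ed)
        assert lsq.kappa == pytest.approx(mle.kappa, rel=0.05)
        assert lsq.mu == pytest.approx(mle.mu, abs=1.0)


class TestIdentifiabilityBound:
    def test_full_circle_interval_any_kappa(self):
        assert kappa_identifiability_bound(360.0, 0.90) == 0.0

    def test_sampling_interval_bound_is_cap(self):
        assert kappa_identifiability_bound(45.0, 0.90) == pytest.approx(18.0, abs=0.5)

    def test_wider_interval_against_quadrature_oracle(self):
        """Independent trapezoid-integration oracle for the 90-deg interval."""
        kstar = kappa_identifiability_bound(90.0, 0.90)
        theta = np.linspace(-np.pi, np.pi, 40_001)

        def coverage(kappa):
            dens = np.exp(kappa * np.cos(theta))
            dens /= np.trapezoid(dens, theta)
            inside = np.abs(theta) <= np.pi / 4
            return np.trapezoid(dens[inside], theta[inside])

        assert coverage(kstar) == pytest.approx(0.90, abs=1e-3)
        assert coverage(kstar * 0.9) < 0.90

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kappa_identifiability_bound(0.0, 0.9)
        with pytest.raises(ValueError):
            kappa_identifiability_bound(45.0, 1.5)


class TestChanceAndObliqueTests:
    def test_rayleigh_uniform_not_rejected(self):
        ed = ErrorDistribution(np.full(8, 0.125), n=100_000)
        assert rayleigh_chance_test(ed) > 0.05

    def test_rayleigh_concentrated_rejected(self):
        ed = ErrorDistribution(vm_bin_mass(0.0, 4.0), n=1000)
        assert rayleigh_chance_test(ed) < 1e-6

    def test_rayleigh_single_value_tiny_p(self):
        ed = ErrorDistribution(np.eye(8)[3], n=200)
        assert rayleigh_chance_test(ed) < 1e-12

    def test_bonferroni_scales_p(self):
        ed = ErrorDistribution(vm_bin_mass(0.0, 0.8), n=40)
        p1 = rayleigh_chance_test(ed, n_comparisons=1)
        p24 = rayleigh_chance_test(ed, n_comparisons=24)
        assert p24 == pytest.approx(min(1.0, 24 * p1))

    @staticmethod
    def _fits(rng, kappa, n_fits, bias_scale=5.0):
        out = []
        for _ in range(n_fits):
            draws = np.degrees(vonmises(kappa, loc=np.radians(rng.normal(0, bias_scale))).rvs(
                400, random_state=rng))
            reported = np.round(draws / 45.0) * 45.0
            out.append(fit_von_mises(tilt_errors(
                pd.DataFrame({"tilt": np.zeros(400), "reported_tilt": reported}))[0]))
        return out

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        fits = self._fits(rng, 3.0, 24)
        per_tilt = {t: fits for t in (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)}
        res = cardinal_oblique_summary(per_tilt)
        assert res["p_kappa"] > 0.5
        assert res["median_kappa_cardinal"] == res["median_kappa_oblique"]

    def test_synthetic_oblique_effect_detected(self):
        """Cardinal kappa doubled at 24 conditions/tilt -> significant."""
        rng = np.random.default_rng(6)
        per_tilt = {}
        for t in (0.0, 90.0, 180.0, 270.0):
            per_tilt[t] = self._fits(rng, 6.0, 24)
        for t in (45.0, 135.0, 225.0, 315.0):
            per_tilt[t] = self._fits(rng, 3.0, 24)
        res = cardinal_oblique_summary(per_tilt)
        assert res["median_kappa_cardinal"] > res["median_kappa_oblique"]
        assert res["p_kappa"] < 0.05

    def test_missing_tilt_is_an_error(self):
        with pytest.raises(ValueError):
            cardinal_oblique_summary({0.0: []})

    def test_two_sample_circular_median_shifted_groups(self):
        rng = np.random.default_rng(7)
        a = np.degrees(vonmises(3).rvs(150, random_state=rng))
        b = np.degrees(vonmises(3, loc=np.radians(60)).rvs(150, random_state=rng))
        assert two_sample_circular_median_test(a, b) < 1e-4
        assert two_sample_circular_median_test(a, a) > 0.5


class TestGaussianRefit:
    def test_large_kappa_limit_sigma(self):
        ed = ErrorDistribution(vm_bin_mass(0.0, 9.0), n=1000)
        g = gaussian_refit(ed)
        assert np.radians(g.sigma) == pytest.approx(1.0 / 3.0, rel=0.1)
        assert not g.flagged

    def test_uniform_flagged(self):
        g = gaussian_refit(ErrorDistribution(np.full(8, 0.125), n=100))
        assert g.flagged

    def test_precision_tracks_kappa_across_conditions(self):
        """Gaussian 1/sigma^2 and von Mises kappa agree across 50 conditions."""
        rng = np.random.default_rng(8)
        kappas, precisions = [], []
        for _ in range(50):
            kappa = rng.uniform(1.5, 10.0)
            draws = np.degrees(vonmises(kappa).rvs(600, random_state=rng))
            reported = np.round(draws / 45.0) * 45.0
            ed = tilt_errors(pd.DataFrame({"tilt": np.zeros(600), "reported_tilt": reported}))[0]
            kappas.append(fit_von_mises(ed).kappa)
            precisions.append(gaussian_refit(ed).precision)
        r = np.corrcoef(kappas, precisions)[0, 1]
        assert r > 0.95
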