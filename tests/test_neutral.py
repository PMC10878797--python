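"""Truncated compound-Poisson distribution, likelihood and attack-rate MLE."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from neutralherb import (
    DataError,
    EventParams,
    NeutralDamageModel,
    NeutralModel,
    PlantScaleConfig,
    aicc,
    damage_distribution,
    fit_neutral,
    fit_presence_absence,
    loglik,
    plant_scale_event_params,
    simulate_damage,
)

PLANT_EVENT = EventParams(0.0005, 0.1)


class TestDistribution:
    @pytest.mark.parametrize("lam", [0.01, 0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("event", [EventParams(), PLANT_EVENT])
    def test_conservation_and_analytic_zero_atom(self, lam, event):
        d = damage_distribution(NeutralModel(lam, event))
        assert d.p0 == pytest.approx(math.exp(-lam), abs=1e-12)
        assert d.total_mass == pytest.approx(1.0, abs=1e-6)
        assert d.p1 >= 0 and np.all(d.density >= 0)

    def test_simulator_matches_density(self, rng):
        d = damage_distribution(NeutralModel(5.0))
        s = simulate_damage(NeutralModel(5.0), 100_000, rng)
        assert d.ks_statistic(s) < 0.01

    def test_mean_increasing_cv_decreasing_in_lam(self):
        lams = [0.1, 1.0, 10.0, 100.0]
        dists = [damage_distribution(NeutralModel(l)) for l in lams]
        means = [d.mean() for d in dists]
        cvs = [d.cv() for d in dists]
        assert np.all(np.diff(means) > 0)
        assert np.all(np.diff(cvs) < 0)

    def test_saturation_at_large_lam(self):
        d = damage_distribution(NeutralModel(500.0))
        assert d.p1 >= 0.99


class TestSimulator:
    def test_zero_rate_gives_all_zeros(self):
        assert np.all(simulate_damage(NeutralModel(0.0), 100, 1) == 0.0)

    def test_poisson_zero_class(self, rng):
        n = 50_000
        s = simulate_damage(NeutralModel(2.0), n, rng)
        p = math.exp(-2.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(np.mean(s == 0.0) - p) < 3 * se

    def test_compound_poisson_mean_identity(self, rng, small_bounds):
        # truncation negligible at these bounds: E[damage] = lam E[phi]
        from neutralherb import event_moment

        lam, n = 2.0, 200_000
        s = simulate_damage(NeutralModel(lam, small_bounds), n, rng)
        m1, m2 = event_moment(1, small_bounds), event_moment(2, small_bounds)
        se = math.sqrt(lam * m2 / n)
        assert abs(s.mean() - lam * m1) < 3 * se


class TestLoglik:
    def test_all_zero_data_atom_likelihood(self):
        data = np.zeros(17)
        assert loglik(data, NeutralModel(1.0)) == pytest.approx(-17.0)

    def test_finite_on_self_simulated_data(self, rng):
        m = NeutralModel(2.0)
        assert np.isfinite(loglik(simulate_damage(m, 200, rng), m))

    def test_censoring_converges_to_density_mode(self, rng):
        m = NeutralModel(3.0)
        x = simulate_damage(m, 2_000, rng)
        x = x[(x > 0.02) & (x < 0.98)]
        prec = 1e-4
        li = loglik(x, m, precision=prec, mode="interval")
        ld = loglik(x, m, precision=prec, mode="density")
        assert li - (ld + x.size * math.log(prec)) == pytest.approx(0.0, abs=0.01 * x.size)

    def test_out_of_range_data_rejected(self):
        with pytest.raises(DataError):
            loglik([0.5, 1.2], NeutralModel(1.0))

    def test_zero_probability_band_warns_not_raises(self):
        # value far below the event lower bound has zero probability
        with pytest.warns(RuntimeWarning):
            ll = loglik([0.0005], NeutralModel(1.0, EventParams(0.05, 1.0)), precision=1e-4)
        assert ll == -math.inf


class TestFit:
    def test_parameter_recovery_single(self, rng):
        x = simulate_damage(NeutralModel(2.0), 1_000, rng)
        fit = fit_neutral(x)
        assert fit.lam_hat == pytest.approx(2.0, rel=0.2)
        assert fit.aicc == pytest.approx(-2 * fit.loglik + 2 + 4 / (fit.n - 2))

    def test_all_zero_data_degenerate(self):
        fit = fit_neutral(np.zeros(30))
        assert fit.lam_hat <= 1e-3
        assert fit.degenerate and fit.at_bound == "lower"

    def test_interval_and_density_modes_agree(self, rng):
        m = NeutralModel(2.0)
        x = simulate_damage(m, 1_500, rng)
        x = x[(x > 0) & (x < 1)]
        fi = fit_neutral(x, mode="interval")
        fd = fit_neutral(x, mode="density")
        assert fi.lam_hat == pytest.approx(fd.lam_hat, rel=0.05)

    def test_aicc_diverges_at_tiny_n(self):
        assert aicc(-1.0, 1, 2) == math.inf


class TestPresenceAbsence:
    def test_no_damage(self):
        fit = fit_presence_absence(0, 30)
        assert fit.lam_hat == 0.0 and fit.degenerate

    def test_half_damaged_closed_form(self):
        assert fit_presence_absence(15, 30).lam_hat == pytest.approx(math.log(2))

    def test_all_damaged_flagged_infinite(self):
        fit = fit_presence_absence(30, 30)
        assert math.isinf(fit.lam_hat) and fit.at_bound == "upper"

    def test_recovery_from_thresholded_simulation(self, rng):
        lam, n = 1.0, 5_000
        s = simulate_damage(NeutralModel(lam), n, rng)
        fit = fit_presence_absence(int(np.sum(s > 0)), n)
        p = 1 - math.exp(-lam)
        se_lam = math.sqrt(p / ((1 - p) * n))  # delta method
        assert abs(fit.lam_hat - lam) < 3 * se_lam


class TestPlantScale:
    def test_identity_at_one_leaf(self, event_default):
        assert plant_scale_event_params(event_default, 1) == event_default

    def test_bounds_divided_by_leaf_count(self, event_default):
        ev = plant_scale_event_params(event_default, PlantScaleConfig(10))
        assert ev.phi_m == pytest.approx(0.0005)
        assert ev.phi_M == pytest.approx(0.1)
        assert ev.alpha == event_default.alpha


class TestEstimator:
    def test_fit_sets_attributes(self, rng):
        x = simulate_damage(NeutralModel(2.0), 300, rng)
        est = NeutralDamageModel().fit(x)
        assert est.lam_ > 0 and est.n_ == 300
        assert np.isfinite(est.loglik_) and np.isfinite(est.aicc_)
        assert est.distribution_.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_sklearn_conventions(self, rng):
        assert clone(NeutralDamageModel(phi_m=0.01)).get_params()["phi_m"] == 0.01
        est = NeutralDamageModel()
        x = simulate_damage(NeutralModel(1.0), 100, rng)
        est.fit(x)
        assert np.isfinite(est.score(x))
        assert est.score_samples(x).shape == (100,)

    def test_sample_reproducible(self, rng):
        est = NeutralDamageModel().fit(simulate_damage(NeutralModel(2.0), 200, rng))
        a = est.sample(50, random_state=7)
        b = est.sample(50, random_state=7)
        np.testing.assert_array_equal(a, b)
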