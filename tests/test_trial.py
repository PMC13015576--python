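"""Synthetic trial emulation: simulation, censored fitting, bootstrap and
left-truncated refits."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from chemoswitch import (WeibullParams, bootstrap_shape_scale_corr,
                         fit_parametric, read_ipd, refit_conditional,
                         simulate_ipd, simulate_salto_like, write_ipd)

OS = WeibullParams(shape=1.473, scale=79.4)
TTP = WeibullParams(shape=1.560, scale=53.9)


class TestSimulateIPD:
    def test_reproducible_from_seed(self):
        a = simulate_ipd(200, OS, TTP, seed=1)
        b = simulate_ipd(200, OS, TTP, seed=1)
        assert a.equals(b)

    def test_progression_never_after_death(self):
        ipd = simulate_salto_like(n=500, seed=2)
        assert (ipd["ttp_weeks"] <= ipd["os_weeks"] + 1e-12).all()
        assert set(ipd["os_event"]) <= {0, 1}
        assert (ipd["os_weeks"] > 0).all()

    def test_immediate_cutoff_censors_everyone(self):
        ipd = simulate_ipd(50, OS, TTP, censor_time=0.1, seed=3)
        assert (ipd["os_event"] == 0).all()
        assert (ipd["ttp_event"] == 0).all()

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_ipd(5, OS, TTP)

    def test_km_median_recovers_generating_median(self):
        """Uncensored simulation at n = 1000: the Kaplan-Meier median falls
        within sampling error of the analytic Weibull median (61.9 weeks)."""
        ipd = simulate_ipd(1000, OS, TTP, seed=4)
        km = KaplanMeierFitter().fit(ipd["os_weeks"], ipd["os_event"])
        assert km.median_survival_time_ == pytest.approx(61.9, abs=5.0)

    def test_round_trip_through_csv(self, tmp_path):
        ipd = simulate_salto_like(n=60, seed=5)
        path = tmp_path / "ipd.csv"
        write_ipd(ipd, path)
        again = read_ipd(path)
        assert np.allclose(again["os_weeks"], ipd["os_weeks"])
        assert (again["os_event"] == ipd["os_event"]).all()


class TestFitParametric:
    def test_uncensored_exponential_mle_is_sample_mean(self):
        import pandas as pd
        rng = np.random.default_rng(6)
        times = rng.exponential(50.0, 400)
        ipd = pd.DataFrame({"id": np.arange(400), "os_weeks": times,
                            "os_event": 1, "ttp_weeks": times, "ttp_event": 0})
        fit = fit_parametric(ipd, "os", "exponential")
        assert fit.scale == pytest.approx(times.mean(), rel=1e-3)
        assert fit.shape == 1.0
        assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)

    def test_recovers_exponential_shape_from_memoryless_data(self):
        expo = WeibullParams(shape=1.0, scale=79.4)
        ipd = simulate_ipd(2000, expo, TTP, censor_time=156.0, seed=7)
        fit = fit_parametric(ipd, "os", "weibull")
        assert abs(fit.shape - 1.0) < 3 * fit.shape_se

    def test_recovers_weibull_parameters(self):
        ipd = simulate_ipd(2000, OS, TTP, censor_time=156.0, seed=8)
        fit = fit_parametric(ipd, "os", "weibull")
        assert abs(fit.shape - OS.shape) < 3 * fit.shape_se
        assert abs(fit.scale - OS.scale) < 3 * fit.scale_se
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)

    def test_weibull_beats_exponential_on_weibull_data(self):
        ipd = simulate_ipd(2000, OS, TTP, censor_time=156.0, seed=9)
        assert (fit_parametric(ipd, "os", "weibull").aic
                < fit_parametric(ipd, "os", "exponential").aic)

    def test_aic_selects_weibull_in_most_trial_scale_replicates(self):
        """At the generating shape 1.473 and n = 160, the Weibull wins the
        AIC comparison in over 90% of replicates."""
        wins = 0
        n_rep = 40
        for rep in range(n_rep):
            ipd = simulate_salto_like(n=160, seed=100 + rep)
            wins += (fit_parametric(ipd, "os", "weibull").aic
                     < fit_parametric(ipd, "os", "exponential").aic)
        assert wins / n_rep > 0.9

    def test_wald_interval_coverage(self):
        """95% Wald intervals for shape and scale cover the generating
        values at roughly their nominal rate across replicate trials."""
        n_rep = 120
        cover_shape = cover_scale = 0
        for rep in range(n_rep):
            ipd = simulate_ipd(200, OS, TTP, censor_time=156.0,
                               accrual_weeks=104.0, seed=1000 + rep)
            fit = fit_parametric(ipd, "os", "weibull")
            cover_shape += abs(fit.shape - OS.shape) < 1.96 * fit.shape_se
            cover_scale += abs(fit.scale - OS.scale) < 1.96 * fit.scale_se
        assert 0.89 <= cover_shape / n_rep <= 1.0
        assert 0.89 <= cover_scale / n_rep <= 1.0

    def test_no_events_rejected(self):
        ipd = simulate_ipd(50, OS, TTP, censor_time=0.1, seed=10)
        with pytest.raises(ValueError, match="events"):
            fit_parametric(ipd, "os", "weibull")


class TestBootstrapCorrelation:
    def test_bounded_and_reproducible(self):
        ipd = simulate_salto_like(n=120, seed=11)
        c1 = bootstrap_shape_scale_corr(ipd, "os", B=120, seed=12)
        c2 = bootstrap_shape_scale_corr(ipd, "os", B=120, seed=12)
        assert -1.0 <= c1 <= 1.0
        assert c1 == c2

    def test_minimum_replicates_enforced(self):
        ipd = simulate_salto_like(n=120, seed=13)
        with pytest.raises(ValueError):
            bootstrap_shape_scale_corr(ipd, "os", B=50)


class TestRefitConditional:
    def test_zero_landmark_equals_plain_fit(self):
        ipd = simulate_salto_like(n=200, seed=14)
        plain = fit_parametric(ipd, "os", "weibull")
        cond = refit_conditional(ipd, "os", landmark=0.0)
        assert cond.shape == pytest.approx(plain.shape, rel=1e-6)
        assert cond.scale == pytest.approx(plain.scale, rel=1e-6)

    def test_memoryless_data_unchanged_by_landmark(self):
        expo = WeibullParams(shape=1.0, scale=79.4)
        ipd = simulate_ipd(4000, expo, TTP, seed=15)
        plain = fit_parametric(ipd, "os", "exponential")
        cond = refit_conditional(ipd, "os", landmark=9.0, family="exponential")
        assert cond.scale == pytest.approx(plain.scale, rel=0.05)

    def test_truncated_likelihood_recovers_generating_parameters(self):
        ipd = simulate_ipd(5000, OS, TTP, censor_time=156.0, seed=16)
        fit = refit_conditional(ipd, "os", landmark=9.0)
        assert abs(fit.shape - OS.shape) < 3 * fit.shape_se
        assert abs(fit.scale - OS.scale) < 3 * fit.scale_se

    def test_empty_risk_set_rejected(self):
        ipd = simulate_ipd(50, OS, TTP, seed=17)
        with pytest.raises(ValueError):
            refit_conditional(ipd, "os", landmark=1e6)
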