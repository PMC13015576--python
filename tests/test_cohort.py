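"""Cohort engine: trace integrity, discounting and outcome accrual."""

import dataclasses

import numpy as np
import pytest

from chemoswitch import (ModelSettings, UtilitySet, WeibullParams, accrue,
                         deterministic_outcomes, discount_factor, run_cohort,
                         run_strategy, sample_parameters, survival_at,
                         weekly_cost)

OS = WeibullParams(shape=1.473, scale=79.4)
TTP = WeibullParams(shape=1.560, scale=53.9)


def _strategy(bundle, name):
    return bundle.scenario.strategy(name)


def assert_trace_valid(trace):
    occ = trace.occupancy
    assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(np.diff(occ[:, 4]) >= -1e-12)  # death monotone
    assert np.all(occ >= -1e-12)
    # transient progression state: occupancy is exactly that week's inflow
    assert np.allclose(occ[:, 1], trace.new_progressions, atol=1e-12)


class TestTraceInvariants:
    def test_invariants_hold_across_100_random_parameter_draws(self, bundle_capox):
        rng = np.random.default_rng(7)
        strategies = bundle_capox.scenario.strategies
        for i in range(100):
            draw = sample_parameters(bundle_capox.psa, rng)
            strat = strategies[i % len(strategies)]
            trace = run_cohort(strat, bundle_capox.settings,
                               draw.os_params, draw.ttp_params)
            assert_trace_valid(trace)

    def test_no_exits_without_risk(self, bundle_capox):
        settings = bundle_capox.settings
        zeros = np.zeros(settings.horizon_weeks)
        trace = run_cohort(_strategy(bundle_capox, "sox_irinotecan"), settings,
                           OS, TTP, p_death=zeros, p_prog=zeros)
        assert trace.occupancy[-1, 0] == 1.0

    def test_certain_death_is_absorbing(self, bundle_capox):
        settings = bundle_capox.settings
        ones = np.ones(settings.horizon_weeks)
        trace = run_cohort(_strategy(bundle_capox, "sox_irinotecan"), settings,
                           OS, TTP, p_death=ones, p_prog=np.zeros_like(ones))
        assert np.all(trace.occupancy[1:, 4] == 1.0)

    def test_engine_os_curve_matches_weibull(self, bundle_capox):
        """With relative risk 1 the cohort's survival curve reproduces the
        fitted Weibull to 1e-6 at every week."""
        strat = _strategy(bundle_capox, "reduced_capox_irinotecan")  # rr_os = 1
        trace = run_cohort(strat, bundle_capox.settings, OS, TTP)
        weeks = np.arange(len(trace.occupancy), dtype=float)
        assert np.allclose(1.0 - trace.occupancy[:, 4], survival_at(weeks, OS),
                           atol=1e-6)

    def test_horizon_leaves_negligible_survivors(self, bundle_capox):
        for strat in bundle_capox.scenario.strategies:
            trace = run_cohort(strat, bundle_capox.settings, OS, TTP)
            assert 1.0 - trace.occupancy[-1, 4] < 1e-3


class TestDiscounting:
    def test_week_zero_and_zero_rate(self):
        assert discount_factor(0, 0.03) == 1.0
        assert discount_factor(137, 0.0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(52.18, 0.03, 52.18) == pytest.approx(1 / 1.03)

    def test_zero_discounting_increases_costs_and_qalys(self, bundle_capox):
        strat = _strategy(bundle_capox, "sox_irinotecan")
        base = run_strategy(strat, bundle_capox.settings, bundle_capox.utilities, OS, TTP)
        undisc_settings = dataclasses.replace(bundle_capox.settings,
                                              discount_costs=0.0, discount_qalys=0.0)
        undisc = run_strategy(strat, undisc_settings, bundle_capox.utilities, OS, TTP)
        assert undisc.total_cost > base.total_cost
        assert undisc.qalys > base.qalys


class TestAccrual:
    def test_discontinuation_has_no_first_line_cost(self, bundle_capox):
        out = run_strategy(_strategy(bundle_capox, "stop_irinotecan"),
                           bundle_capox.settings, bundle_capox.utilities, OS, TTP)
        assert out.cost_first_line == 0.0
        assert out.mean_cycles_first_line == 0.0

    def test_zero_utility_configuration_yields_zero_qalys(self, bundle_capox):
        utilities = UtilitySet(u_first_line=0.0, d_second_line=0.0, d_prog_no_treat=0.0)
        out = run_strategy(_strategy(bundle_capox, "stop_irinotecan"),
                           bundle_capox.settings, utilities, OS, TTP)
        assert out.qalys == 0.0

    def test_total_cost_is_sum_of_components(self, bundle_capox):
        for strat in bundle_capox.scenario.strategies:
            out = run_strategy(strat, bundle_capox.settings, bundle_capox.utilities,
                               OS, TTP)
            assert out.total_cost == pytest.approx(
                out.cost_first_line + out.cost_second_line + out.cost_ae, abs=0.01)

    def test_adverse_event_cost_of_capecitabine_continuation(self, bundle_capox):
        out = run_strategy(_strategy(bundle_capox, "reduced_capox_irinotecan"),
                           bundle_capox.settings, bundle_capox.utilities, OS, TTP)
        assert out.cost_ae == pytest.approx(107.5)

    def test_sox_progression_fraction_near_printed_value(self, bundle_capox):
        out = run_strategy(_strategy(bundle_capox, "sox_irinotecan"),
                           bundle_capox.settings, bundle_capox.utilities, OS, TTP)
        assert out.pct_progressed == pytest.approx(65.0, abs=2.0)

    def test_cost_consistent_with_cycle_counts(self, bundle_capox):
        """Discounted first-line cost stays within 10% of the undiscounted
        person-cycles x per-cycle cost product on the same trace."""
        for strat in bundle_capox.scenario.strategies:
            if strat.first_line is None:
                continue
            out = run_strategy(strat, bundle_capox.settings, bundle_capox.utilities,
                               OS, TTP)
            undisc = (out.mean_cycles_first_line * strat.first_line.cycle_length
                      * weekly_cost(strat.first_line))
            assert out.cost_first_line == pytest.approx(undisc, rel=0.10)

    def test_discontinuation_yields_lowest_qalys(self, bundle_capox):
        outs = {o.strategy: o.qalys for o in deterministic_outcomes(bundle_capox)}
        stop = outs.pop("stop_irinotecan")
        assert all(stop < q for q in outs.values())

    def test_invalid_state_utility_rejected(self, bundle_capox):
        strat = _strategy(bundle_capox, "sox_irinotecan")
        trace = run_cohort(strat, bundle_capox.settings, OS, TTP)
        bad = dataclasses.replace(bundle_capox.utilities, u_first_line=0.05,
                                  d_second_line=0.0, d_prog_no_treat=0.0)
        bad = dataclasses.replace(bad, d_second_line=0.0)
        # constructing a UtilitySet with u - d < 0 is itself rejected
        with pytest.raises(ValueError):
            UtilitySet(u_first_line=0.05, d_second_line=0.15, d_prog_no_treat=0.10)
        # a valid set still accrues
        accrue(trace, strat, bundle_capox.settings, bad)
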