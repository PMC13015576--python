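"""Weekly Markov cohort engine.

A closed cohort moves through five mutually exclusive states in 1-week
cycles: first-line treatment, progression (a single transient week),
second-line treatment, progression without treatment, and death (absorbing).
Death is evaluated before progression within a week, so the cohort's overall
survival curve reproduces the fitted Weibull exactly when the relative risk
is 1.  On survival of the transient progression week the cohort splits into
second-line treatment versus no further treatment (80:20 by default).

Costs (medication + administration per week of state occupancy, plus a
one-off expected adverse-event cost at week 0) are discounted at 3% per
year; quality-adjusted life years at 1.5% per year.  No half-cycle
correction is applied — with weekly cycles it is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import (ModelSettings, StrategySpec, UtilitySet,
                     expected_ae_cost, weekly_cost)
from .survival import WeibullParams, weekly_transition_probs

__all__ = [
    "STATES",
    "CohortTrace",
    "StrategyOutcome",
    "discount_factor",
    "run_cohort",
    "accrue",
    "run_strategy",
    "outcomes_frame",
]

STATES = ("first_line", "progression", "second_line", "prog_no_treat", "death")
WEEKS_PER_MONTH = 30.44 / 7.0


@dataclass(frozen=True)
class CohortTrace:
    """Week-indexed state occupancy (fractions of the cohort).

    ``occupancy[t]`` is the distribution over states at the start of week t;
    ``new_progressions[t]`` is the fraction of the cohort that entered the
    transient progression state at week t.
    """

    occupancy: np.ndarray  # (horizon+1, 5)
    new_progressions: np.ndarray  # (horizon+1,)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancy, columns=[f"s_{s}" for s in STATES])
        frame.insert(0, "week", np.arange(len(frame)))
        frame["new_progressions"] = self.new_progressions
        return frame


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted costs, QALYs and trace summaries for one strategy.

    Medians are reported in months (weeks x 7/30.44).  ``median_ttp`` is the
    median progression week among patients who progress; the marginal
    cumulative-incidence median over the whole cohort is reported alongside
    because neither definition is canonical when fewer than all patients
    progress.
    """

    strategy: str
    total_cost: float
    cost_first_line: float
    cost_second_line: float
    cost_ae: float
    qalys: float
    median_os: float
    median_ttp: float
    median_ttp_marginal: float
    mean_cycles_first_line: float
    mean_cycles_second_line: float
    pct_progressed: float


def discount_factor(week, annual_rate: float, weeks_per_year: float = 52.18):
    """Discount multiplier (1 + r)^(-week / weeks_per_year); 1 at week 0."""
    if annual_rate < 0:
        raise ValueError("discount rate must be >= 0")
    w = np.asarray(week, dtype=float)
    out = (1.0 + annual_rate) ** (-w / weeks_per_year)
    return float(out) if np.isscalar(week) else out


def run_cohort(strategy: StrategySpec, settings: ModelSettings,
               os_params: WeibullParams, ttp_params: WeibullParams,
               p_death: Optional[np.ndarray] = None,
               p_prog: Optional[np.ndarray] = None) -> CohortTrace:
    """Propagate the closed cohort through the five states week by week.

    Within each week, from first-line: death first, then progression among
    survivors, else remain.  From the transient progression state: death
    first, survivors split into second-line treatment versus no treatment.
    From either post-progression state: death, else remain.  The same
    time-from-baseline mortality process (adjusted by the strategy's
    relative risk) applies in every alive state.

    Precomputed weekly probability vectors may be passed to avoid
    recomputation inside probabilistic loops.
    """
    horizon = settings.horizon_weeks
    if p_death is None:
        p_death = weekly_transition_probs(os_params, horizon, strategy.rr_os)
    if p_prog is None:
        p_prog = weekly_transition_probs(ttp_params, horizon, strategy.rr_ttp)
    if np.any(p_death < 0) or np.any(p_death > 1) or np.any(p_prog < 0) or np.any(p_prog > 1):
        raise ValueError("weekly transition probabilities outside [0, 1]")

    p2 = settings.p_second_line
    occ = np.zeros((horizon + 1, 5))
    newprog = np.zeros(horizon + 1)
    occ[0, 0] = 1.0
    fl, pr, sl, pnt, dead = 1.0, 0.0, 0.0, 0.0, 0.0
    pdv = p_death.tolist()
    ppv = p_prog.tolist()
    for t in range(horizon):
        d = pdv[t]
        q = ppv[t]
        alive_fl = fl * (1.0 - d)
        pr_surv = pr * (1.0 - d)
        dead = dead + (fl + pr + sl + pnt) * d
        prog_in = alive_fl * q
        fl = alive_fl - prog_in
        sl = sl * (1.0 - d) + pr_surv * p2
        pnt = pnt * (1.0 - d) + pr_surv * (1.0 - p2)
        pr = prog_in
        newprog[t + 1] = prog_in
        occ[t + 1, 0] = fl
        occ[t + 1, 1] = pr
        occ[t + 1, 2] = sl
        occ[t + 1, 3] = pnt
        occ[t + 1, 4] = dead
    return CohortTrace(occupancy=occ, new_progressions=newprog)


def _median_month_from_cum(cum: np.ndarray, threshold: float) -> float:
    hit = np.nonzero(cum >= threshold)[0]
    return float(hit[0]) / WEEKS_PER_MONTH if hit.size else float("nan")


def accrue(trace: CohortTrace, strategy: StrategySpec, settings: ModelSettings,
           utilities: UtilitySet) -> StrategyOutcome:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Costs: state occupancy x weekly regimen cost, discounted; the expected
    adverse-event cost is added once at week 0 (discount factor 1).  QALYs:
    occupancy-weighted state utilities per week of life, discounted; the
    probability-weighted adverse-event disutility is subtracted from the
    first-line utility during the event weeks, floored at 0.  The transient
    progression week carries the progressed-untreated utility.
    """
    horizon = settings.horizon_weeks
    occ = trace.occupancy[:horizon]
    weeks = np.arange(horizon)
    disc_c = discount_factor(weeks, settings.discount_costs, settings.weeks_per_year)
    disc_q = discount_factor(weeks, settings.discount_qalys, settings.weeks_per_year)

    wc_first = weekly_cost(strategy.first_line)
    wc_second = weekly_cost(strategy.second_line)
    cost_first = float(np.sum(occ[:, 0] * wc_first * disc_c))
    cost_second = float(np.sum(occ[:, 2] * wc_second * disc_c))
    cost_ae = expected_ae_cost(strategy.ae)

    u = utilities.u_first_line
    u_first = np.full(horizon, u)
    dur = min(strategy.ae.duration_weeks, horizon)
    u_first[:dur] = max(0.0, u - strategy.ae.disutility * strategy.ae.total_probability)
    u_prog = u - utilities.d_prog_no_treat
    u_second = u - utilities.d_second_line
    for label, val in (("second_line", u_second), ("prog_no_treat", u_prog)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"utility for state {label} is {val}, outside [0, 1]")
    util_weeks = (occ[:, 0] * u_first + occ[:, 1] * u_prog
                  + occ[:, 2] * u_second + occ[:, 3] * u_prog
                  + occ[:, 4] * utilities.u_death)
    qalys = float(np.sum(util_weeks * disc_q) / settings.weeks_per_year)

    median_os = _median_month_from_cum(trace.occupancy[:, 4], 0.5)
    cum_prog = np.cumsum(trace.new_progressions)
    total_prog = float(cum_prog[-1])
    median_ttp = _median_month_from_cum(cum_prog, total_prog / 2.0) if total_prog > 0 else float("nan")
    median_ttp_marginal = _median_month_from_cum(cum_prog, 0.5)

    cycles_first = (float(np.sum(occ[:, 0])) / strategy.first_line.cycle_length
                    if strategy.first_line is not None else 0.0)
    cycles_second = float(np.sum(occ[:, 2])) / strategy.second_line.cycle_length

    return StrategyOutcome(
        strategy=strategy.name,
        total_cost=cost_first + cost_second + cost_ae,
        cost_first_line=cost_first,
        cost_second_line=cost_second,
        cost_ae=cost_ae,
        qalys=qalys,
        median_os=median_os,
        median_ttp=median_ttp,
        median_ttp_marginal=median_ttp_marginal,
        mean_cycles_first_line=cycles_first,
        mean_cycles_second_line=cycles_second,
        pct_progressed=total_prog * 100.0,
    )


def run_strategy(strategy: StrategySpec, settings: ModelSettings,
                 utilities: UtilitySet, os_params: WeibullParams,
                 ttp_params: WeibullParams) -> StrategyOutcome:
    """Run one strategy at the given parameters and accrue its outcome."""
    trace = run_cohort(strategy, settings, os_params, ttp_params)
    return accrue(trace, strategy, settings, utilities)


def outcomes_frame(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """One row per strategy, columns in the results-table ordering."""
    cols = ["strategy", "total_cost", "cost_first_line", "cost_second_line",
            "cost_ae", "qalys", "median_os", "median_ttp", "median_ttp_marginal",
            "mean_cycles_first_line", "mean_cycles_second_line", "pct_progressed"]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in outcomes])[cols]
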