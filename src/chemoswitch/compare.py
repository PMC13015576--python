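"""Cost-effectiveness comparison of strategies.

Incremental cost-effectiveness ratios (ICERs) are computed on PSA-mean costs
and QALYs, not as means of per-run ratios.  The efficiency frontier removes
strictly dominated strategies (costlier, no more effective) and
extended-dominated ones (a pricier alternative achieves a lower ICER against
the same comparator), leaving stepwise ICERs that increase strictly along
the frontier.  Two strategies whose mean outcomes differ by less than
0.005 QALY and 100 EUR are treated as equivalent: both are retained and
reported, reflecting that such differences are negligible against the
model's uncertainty.

The net-benefit framework converts each strategy's outcome into
WTP x QALYs - cost for a willingness-to-pay (WTP) grid from 0 to
100 000 EUR/QALY; the acceptability curve (CEAC) is the fraction of PSA
runs in which each strategy attains the highest net benefit.  Ties are
broken toward the cheaper strategy (conservative payer perspective).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .params import ScenarioBundle
from .psa import DEFAULT_SEED, PSAResults, run_psa

__all__ = [
    "EQUIV_DQALY",
    "EQUIV_DCOST",
    "FrontierResult",
    "CEACResult",
    "icer",
    "frontier",
    "net_benefit",
    "ceac",
    "turning_point",
    "run_sensitivity",
    "SENSITIVITY_VARIANTS",
]

EQUIV_DQALY = 0.005
EQUIV_DCOST = 100.0

SENSITIVITY_VARIANTS = {
    "rr_1.2": 1.2, "rr12": 1.2,
    "rr_1.8": 1.8, "rr18": 1.8,
    "conditional_9wk": None, "cond9w": None,
}


def _cost_qalys(x) -> tuple[float, float]:
    if hasattr(x, "total_cost"):
        return float(x.total_cost), float(x.qalys)
    cost, qalys = x
    return float(cost), float(qalys)


def icer(costlier, cheaper) -> Union[float, str]:
    """ICER of the costlier versus the cheaper strategy, or a dominance flag.

    Arguments may be outcome objects (``total_cost``/``qalys`` attributes)
    or ``(cost, qalys)`` pairs.  Returns ``"equivalent"`` when both
    differences fall inside the equivalence band, ``"dominated"`` when the
    costlier strategy yields no additional QALYs, ``"dominant"`` when it is
    at most as costly yet more effective, and the cost-per-QALY ratio
    otherwise.
    """
    c1, q1 = _cost_qalys(costlier)
    c0, q0 = _cost_qalys(cheaper)
    dc, dq = c1 - c0, q1 - q0
    if abs(dq) < EQUIV_DQALY and abs(dc) < EQUIV_DCOST:
        return "equivalent"
    if dq > 0:
        return "dominant" if dc <= 0 else dc / dq
    return "dominated" if dc > 0 else dc / dq if dq < 0 else "equivalent"


@dataclass(frozen=True)
class FrontierResult:
    """Efficiency-frontier classification with stepwise and vs-reference ICERs."""

    table: pd.DataFrame  # strategy, mean_cost, mean_qalys, status, icer_vs_previous, icer_vs_reference

    def status(self, strategy: str) -> str:
        return str(self.table.set_index("strategy").loc[strategy, "status"])

    def stepwise_icer(self, strategy: str) -> float:
        val = self.table.set_index("strategy").loc[strategy, "icer_vs_previous"]
        return float(val)

    @property
    def frontier_strategies(self) -> list[str]:
        on = self.table["status"].isin(["reference", "on_frontier"])
        return list(self.table.loc[on, "strategy"])


def frontier(means: pd.DataFrame, reference: Optional[str] = None) -> FrontierResult:
    """Classify strategies and compute ICERs along the efficiency frontier.

    Parameters
    ----------
    means : DataFrame
        Columns ``strategy``, ``mean_cost``, ``mean_qalys`` (PSA means).
    reference : str, optional
        Strategy for the vs-reference ICER column; defaults to the cheapest.
    """
    df = means[["strategy", "mean_cost", "mean_qalys"]].copy()
    if len(df) < 2:
        raise ValueError("need at least two strategies")
    df = df.sort_values(["mean_cost", "mean_qalys"],
                        ascending=[True, False], kind="stable").reset_index(drop=True)
    cost = df["mean_cost"].to_numpy()
    qaly = df["mean_qalys"].to_numpy()
    n = len(df)
    status = np.array(["on_frontier"] * n, dtype=object)

    # strict (simple) dominance: some other strategy costs no more and yields
    # at least as many QALYs, with one inequality strict
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (cost[j] <= cost[i] and qaly[j] >= qaly[i]
                    and (cost[j] < cost[i] or qaly[j] > qaly[i])):
                status[i] = "dominated"
                break

    # extended dominance: drop frontier candidates whose stepwise ICER
    # exceeds that of the next candidate, until ICERs increase strictly
    cand = [i for i in range(n) if status[i] == "on_frontier"]
    while len(cand) > 2:
        icers = [(cost[b] - cost[a]) / (qaly[b] - qaly[a])
                 for a, b in zip(cand[:-1], cand[1:])]
        bad = next((k for k in range(len(icers) - 1) if icers[k] >= icers[k + 1]), None)
        if bad is None:
            break
        status[cand[bad + 1]] = "extended_dominated"
        cand.pop(bad + 1)

    status[cand[0]] = "reference"

    # equivalence pass: a removed strategy indistinguishable from a frontier
    # member is reported as equivalent rather than dominated
    for i in range(n):
        if status[i] in ("dominated", "extended_dominated"):
            for j in cand:
                if (abs(qaly[i] - qaly[j]) < EQUIV_DQALY
                        and abs(cost[i] - cost[j]) < EQUIV_DCOST):
                    status[i] = "equivalent"
                    break

    icer_prev = np.full(n, np.nan)
    for a, b in zip(cand[:-1], cand[1:]):
        icer_prev[b] = (cost[b] - cost[a]) / (qaly[b] - qaly[a])

    ref_name = reference if reference is not None else df.loc[cand[0], "strategy"]
    ref_row = df.index[df["strategy"] == ref_name]
    if ref_row.empty:
        raise ValueError(f"reference strategy '{ref_name}' not present")
    r = ref_row[0]
    icer_ref = np.full(n, np.nan)
    for i in range(n):
        if i != r and qaly[i] != qaly[r]:
            icer_ref[i] = (cost[i] - cost[r]) / (qaly[i] - qaly[r])

    df["status"] = status
    df["icer_vs_previous"] = icer_prev
    df["icer_vs_reference"] = icer_ref
    return FrontierResult(table=df)


def net_benefit(outcome, wtp: float) -> float:
    """Net monetary benefit WTP x QALYs - cost (EUR)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    cost, qalys = _cost_qalys(outcome)
    return wtp * qalys - cost


@dataclass(frozen=True)
class CEACResult:
    """Acceptability curves: P(highest net benefit) per strategy over WTP."""

    table: pd.DataFrame  # wtp + one probability column per strategy

    @property
    def strategies(self) -> list[str]:
        return [c for c in self.table.columns if c != "wtp"]

    def most_probable(self, wtp: float) -> str:
        row = self.table.loc[(self.table["wtp"] - wtp).abs().idxmin()]
        return str(row[self.strategies].astype(float).idxmax())


def ceac(psa: PSAResults, wtp_grid: Optional[np.ndarray] = None) -> CEACResult:
    """Cost-effectiveness acceptability curves over a WTP grid.

    Per run and WTP the winning strategy maximizes net benefit, ties going
    to the cheaper strategy; probabilities are fractions of runs won.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100001, 1000, dtype=float)
    costs = psa.matrix("total_cost")  # (runs, strategies)
    qalys = psa.matrix("qalys")
    n_runs, n_strat = costs.shape
    probs = np.zeros((len(wtp_grid), n_strat))
    for k, wtp in enumerate(wtp_grid):
        nmb = wtp * qalys - costs
        is_max = nmb == nmb.max(axis=1, keepdims=True)
        cost_masked = np.where(is_max, costs, np.inf)
        winners = np.argmin(cost_masked, axis=1)
        probs[k] = np.bincount(winners, minlength=n_strat) / n_runs
    table = pd.DataFrame(probs, columns=list(psa.strategies))
    table.insert(0, "wtp", wtp_grid)
    return CEACResult(table=table)


def turning_point(result: CEACResult) -> float:
    """Smallest WTP at which the most probable strategy is no longer the
    one favoured at WTP 0 (the cheapest); NaN if no crossing occurs."""
    base = result.most_probable(0.0)
    for wtp in result.table["wtp"]:
        if result.most_probable(float(wtp)) != base:
            return float(wtp)
    return float("nan")


def run_sensitivity(bundle: ScenarioBundle, variant: str, n_runs: int = 1000,
                    seed: int = DEFAULT_SEED) -> dict:
    """Re-run the full PSA under one of the pre-specified sensitivity analyses.

    ``rr_1.2``/``rr_1.8`` replace the discontinuation relative risk;
    ``conditional_9wk`` replaces the OS Weibull uncertainty by a
    left-truncated refit on emulated trial patients who survived 9 weeks
    (hand-foot syndrome typically emerges only after about three full
    treatment cycles).

    Returns a dict with keys ``psa``, ``means``, ``frontier``, ``ceac``.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(
            f"unknown sensitivity variant '{variant}'; choose from "
            f"{sorted(set(SENSITIVITY_VARIANTS))}")
    rr = SENSITIVITY_VARIANTS[variant]
    if rr is not None:
        results = run_psa(bundle, n_runs=n_runs, seed=seed, rr_discontinuation=rr)
    else:
        from .psa import BivariateNormalSpec
        from .trial import refit_conditional, simulate_salto_like

        ipd = simulate_salto_like(os_params=bundle.os_params, ttp_params=bundle.ttp_params,
                                  seed=seed + 1)
        fit = refit_conditional(ipd, "os", landmark=9.0)
        os_dist = BivariateNormalSpec(
            mean_shape=fit.shape, mean_scale=fit.scale,
            sd_shape=fit.shape_se, sd_scale=fit.scale_se,
            corr=fit.corr_shape_scale)
        dists = replace(bundle.psa, os_dist=os_dist)
        results = run_psa(bundle, n_runs=n_runs, seed=seed, dists=dists)
    means = results.means()
    front = frontier(means, reference=bundle.scenario.reference_strategy)
    curves = ceac(results)
    return {"psa": results, "means": means, "frontier": front, "ceac": curves}
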