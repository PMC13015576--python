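"""Probabilistic sensitivity analysis (PSA).

Parameter uncertainty is propagated by repeatedly (default 1000 times)
drawing a full parameter set from the uncertainty distributions and running
the cohort engine for every strategy of the scenario under that common draw.
Sharing one draw across strategies within a run keeps incremental costs and
effects coherent (paired comparisons), which is what the acceptability
curves rely on.

Distributions:

* costs — gamma with shape sqrt(mean) and rate 1/sqrt(mean), so the mean is
  exactly the point estimate and the variance mean^1.5; one draw per named
  cost component, shared by every regimen containing that component;
* S-1 overall-survival relative risk — lognormal;
* first-line utility — normal, truncated to [0, 1];
* Weibull (shape, scale) pairs for OS and TTP — correlated bivariate
  normals, redrawn on the (practically impossible) event of a non-positive
  draw.

The adverse-event probabilities and costs, disutilities, the discontinuation
relative risk and the second-line uptake probability are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import StrategyOutcome, accrue, outcomes_frame, run_cohort
from .params import ScenarioBundle, ScenarioSpec, StrategySpec
from .survival import WeibullParams, weekly_transition_probs

__all__ = [
    "BivariateNormalSpec",
    "PSADistributions",
    "ParameterDraw",
    "PSAResults",
    "sample_parameters",
    "run_psa",
    "deterministic_outcomes",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20260317


@dataclass(frozen=True)
class BivariateNormalSpec:
    """Correlated normal uncertainty on a Weibull (shape, scale) pair."""

    mean_shape: float
    mean_scale: float
    sd_shape: float
    sd_scale: float
    corr: float

    def __post_init__(self) -> None:
        if not (self.sd_shape > 0 and self.sd_scale > 0):
            raise ValueError("standard deviations must be > 0")
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError(f"correlation must be in [-1, 1], got {self.corr}")

    @property
    def mean(self) -> WeibullParams:
        return WeibullParams(shape=self.mean_shape, scale=self.mean_scale)

    def cov(self) -> np.ndarray:
        off = self.corr * self.sd_shape * self.sd_scale
        return np.array([[self.sd_shape ** 2, off], [off, self.sd_scale ** 2]])


@dataclass(frozen=True)
class PSADistributions:
    """Uncertainty-distribution specification for one scenario.

    ``cost_means`` maps component names to mean per-cycle costs (EUR).
    ``sigma_scale`` scales every spread: 1 is the specified uncertainty,
    0 collapses all draws onto the point estimates (useful for checking
    that PSA means converge to the deterministic run).
    """

    cost_means: dict[str, float]
    rr_s1_mu: float = -0.0726
    rr_s1_sigma: float = 0.058
    utility_mean: float = 0.83
    utility_sd: float = 0.01
    os_dist: BivariateNormalSpec = field(default_factory=lambda: BivariateNormalSpec(
        1.473, 79.4, 0.096, 4.874, 0.555))
    ttp_dist: BivariateNormalSpec = field(default_factory=lambda: BivariateNormalSpec(
        1.560, 53.9, 0.107, 3.243, -0.255))
    rr_discontinuation: float = 1.50
    sigma_scale: float = 1.0

    @classmethod
    def from_config(cls, cfg: dict, scenario: ScenarioSpec,
                    os_params: WeibullParams, ttp_params: WeibullParams) -> "PSADistributions":
        """Build the specification from a config section, collecting the
        named cost components of every regimen in the scenario."""
        cost_means: dict[str, float] = {}
        for strat in scenario.strategies:
            for reg in (strat.first_line, strat.second_line):
                if reg is None:
                    continue
                for comps in (reg.drug_components, reg.admin_components):
                    for name, cost in comps.items():
                        if name in cost_means and cost_means[name] != cost:
                            raise ValueError(
                                f"cost component '{name}' has conflicting means "
                                f"{cost_means[name]} and {cost}")
                        cost_means[name] = cost
        rr = cfg.get("rr_s1") or {}
        ut = cfg.get("utility") or {}
        os_cfg = cfg.get("os") or {}
        ttp_cfg = cfg.get("ttp") or {}
        return cls(
            cost_means=cost_means,
            rr_s1_mu=float(rr.get("mu", -0.0726)),
            rr_s1_sigma=float(rr.get("sigma", 0.058)),
            utility_mean=float(ut.get("mean", 0.83)),
            utility_sd=float(ut.get("sd", 0.01)),
            os_dist=BivariateNormalSpec(
                os_params.shape, os_params.scale,
                float(os_cfg.get("sd_shape", 0.096)),
                float(os_cfg.get("sd_scale", 4.874)),
                float(os_cfg.get("corr", 0.555))),
            ttp_dist=BivariateNormalSpec(
                ttp_params.shape, ttp_params.scale,
                float(ttp_cfg.get("sd_shape", 0.107)),
                float(ttp_cfg.get("sd_scale", 3.243)),
                float(ttp_cfg.get("corr", -0.255))),
            rr_discontinuation=float(cfg.get("rr_discontinuation", 1.50)),
        )

    def to_dict(self) -> dict:
        return {
            "rr_s1": {"mu": self.rr_s1_mu, "sigma": self.rr_s1_sigma},
            "utility": {"mean": self.utility_mean, "sd": self.utility_sd},
            "os": {"sd_shape": self.os_dist.sd_shape, "sd_scale": self.os_dist.sd_scale,
                   "corr": self.os_dist.corr},
            "ttp": {"sd_shape": self.ttp_dist.sd_shape, "sd_scale": self.ttp_dist.sd_scale,
                    "corr": self.ttp_dist.corr},
            "rr_discontinuation": self.rr_discontinuation,
        }


@dataclass(frozen=True)
class ParameterDraw:
    """One full parameter set sampled for a PSA run."""

    costs: dict[str, float]
    rr_s1: float
    u_first_line: float
    os_params: WeibullParams
    ttp_params: WeibullParams


def _draw_gamma_cost(mean: float, ss: float, rng: np.random.Generator) -> float:
    if mean == 0.0 or ss == 0.0:
        return mean
    # shape sqrt(c), rate 1/sqrt(c); sigma_scale rescales the variance only
    shape = np.sqrt(mean) / ss ** 2
    scale = np.sqrt(mean) * ss ** 2
    return float(rng.gamma(shape, scale))


def _draw_positive_bvn(spec: BivariateNormalSpec, ss: float,
                       rng: np.random.Generator) -> WeibullParams:
    if ss == 0.0:
        return spec.mean
    mean = np.array([spec.mean_shape, spec.mean_scale])
    cov = spec.cov() * ss ** 2
    for _ in range(1000):
        shape, scale = rng.multivariate_normal(mean, cov)
        if shape > 0 and scale > 0:
            return WeibullParams(shape=float(shape), scale=float(scale))
    raise RuntimeError("could not draw positive Weibull parameters")


def sample_parameters(dists: PSADistributions, rng: np.random.Generator) -> ParameterDraw:
    """Draw one full parameter set from the uncertainty distributions."""
    ss = dists.sigma_scale
    costs = {name: _draw_gamma_cost(mean, ss, rng)
             for name, mean in sorted(dists.cost_means.items())}
    rr_s1 = float(np.exp(rng.normal(dists.rr_s1_mu, dists.rr_s1_sigma * ss))) \
        if ss > 0 else float(np.exp(dists.rr_s1_mu))
    if ss > 0 and dists.utility_sd > 0:
        u = float(rng.normal(dists.utility_mean, dists.utility_sd * ss))
        while not 0.0 <= u <= 1.0:
            u = float(rng.normal(dists.utility_mean, dists.utility_sd * ss))
    else:
        u = dists.utility_mean
    return ParameterDraw(
        costs=costs,
        rr_s1=rr_s1,
        u_first_line=u,
        os_params=_draw_positive_bvn(dists.os_dist, ss, rng),
        ttp_params=_draw_positive_bvn(dists.ttp_dist, ss, rng),
    )


def _apply_draw(strategy: StrategySpec, draw: ParameterDraw,
                rr_discontinuation: float) -> StrategySpec:
    """Rebuild a strategy with the drawn costs and relative risks."""
    first = strategy.first_line.with_costs(draw.costs) if strategy.first_line else None
    second = strategy.second_line.with_costs(draw.costs)
    rr_os, rr_ttp = strategy.rr_os, strategy.rr_ttp
    if strategy.first_line_class == "s1":
        rr_os = draw.rr_s1
    elif strategy.first_line_class == "none":
        rr_os = rr_ttp = rr_discontinuation
    return replace(strategy, first_line=first, second_line=second,
                   rr_os=rr_os, rr_ttp=rr_ttp)


@dataclass
class PSAResults:
    """Per-draw outcomes for all strategies of a scenario."""

    scenario: str
    n_runs: int
    seed: int
    strategies: tuple[str, ...]
    outcomes: dict[str, list[StrategyOutcome]]
    draws: list[ParameterDraw]

    def matrix(self, attr: str) -> np.ndarray:
        """(n_runs, n_strategies) array of one outcome attribute."""
        return np.column_stack([
            [getattr(o, attr) for o in self.outcomes[s]] for s in self.strategies
        ])

    def means(self) -> pd.DataFrame:
        """Per-strategy means over runs (the headline results table)."""
        frames = []
        for s in self.strategies:
            frame = outcomes_frame(self.outcomes[s])
            num = frame.drop(columns="strategy")
            row = num.mean(skipna=True)
            row["strategy"] = s
            frames.append(row)
        out = pd.DataFrame(frames).set_index("strategy").reset_index()
        out = out.rename(columns={"total_cost": "mean_cost", "qalys": "mean_qalys"})
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long format (run, strategy, outcome columns) for export."""
        parts = []
        for s in self.strategies:
            frame = outcomes_frame(self.outcomes[s])
            frame.insert(0, "run", np.arange(self.n_runs))
            parts.append(frame)
        return pd.concat(parts, ignore_index=True).sort_values(
            ["run", "strategy"], kind="stable").reset_index(drop=True)


def run_psa(bundle: ScenarioBundle, n_runs: int = 1000, seed: int = DEFAULT_SEED,
            dists: Optional[PSADistributions] = None,
            rr_discontinuation: Optional[float] = None) -> PSAResults:
    """Run the probabilistic sensitivity analysis.

    One parameter draw per run is shared by all strategies.  Each run has
    its own random stream derived from the master seed, so results are
    reproducible and independent of execution order.  ``rr_discontinuation``
    overrides the fixed relative risk applied to discontinuation strategies
    (used by the sensitivity analyses).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    dists = dists if dists is not None else bundle.psa
    if rr_discontinuation is not None:
        dists = replace(dists, rr_discontinuation=rr_discontinuation)
    scenario, settings, utilities = bundle.scenario, bundle.settings, bundle.utilities
    names = tuple(s.name for s in scenario.strategies)
    outcomes: dict[str, list[StrategyOutcome]] = {name: [] for name in names}
    draws: list[ParameterDraw] = []
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_runs)]
    for run_idx, rng in enumerate(streams):
        draw = sample_parameters(dists, rng)
        draws.append(draw)
        for strat in scenario.strategies:
            strat_run = _apply_draw(strat, draw, dists.rr_discontinuation)
            try:
                trace = run_cohort(strat_run, settings, draw.os_params, draw.ttp_params)
                outcome = accrue(trace, strat_run, settings,
                                 utilities.with_first_line(draw.u_first_line))
            except ValueError as exc:
                raise RuntimeError(f"PSA run {run_idx}, strategy '{strat.name}': {exc}") from exc
            outcomes[strat.name].append(outcome)
    return PSAResults(scenario=scenario.name, n_runs=n_runs, seed=seed,
                      strategies=names, outcomes=outcomes, draws=draws)


def deterministic_outcomes(bundle: ScenarioBundle,
                           rr_discontinuation: Optional[float] = None) -> list[StrategyOutcome]:
    """Single run of every strategy at the point estimates."""
    out = []
    for strat in bundle.scenario.strategies:
        if rr_discontinuation is not None and strat.first_line_class == "none":
            strat = replace(strat, rr_os=rr_discontinuation, rr_ttp=rr_discontinuation)
        trace = run_cohort(strat, bundle.settings, bundle.os_params, bundle.ttp_params)
        out.append(accrue(trace, strat, bundle.settings, bundle.utilities))
    return out
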