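"""Model parameters: regimen costs, adverse-event profiles, utilities and
scenario configuration.

Every calibration quantity of the model lives here: per-cycle medication and
administration costs for each regimen, the probabilities and costs of the
adverse events that drive the treatment switch (recurrent hand-foot syndrome
and cardiovascular toxicity), quality-of-life weights, discount rates and the
global settings of the weekly cohort model.  Scenario configurations are
loaded from YAML; three built-in scenarios ship with the package
(``"capox"``, ``"folfox"``, ``"cap_mono"``), one per first-line treatment on
which the toxicity occurred.

Costs are stored per treatment cycle and converted to per-week amounts
(oral and short-infusion regimens run on 3-week cycles, i.v.-5FU-based
regimens on 2-week cycles).  No inflation indexing is performed; inputs are
already price-indexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Optional

import yaml

__all__ = [
    "ConfigError",
    "RegimenCost",
    "AdverseEventProfile",
    "UtilitySet",
    "StrategySpec",
    "ScenarioSpec",
    "ModelSettings",
    "ScenarioBundle",
    "weekly_cost",
    "expected_ae_cost",
    "load_scenario",
    "serialize_scenario",
    "BUILTIN_SCENARIOS",
]

BUILTIN_SCENARIOS = ("capox", "folfox", "cap_mono")

#: first-line classes; they determine which relative risks apply and whether
#: the S-1 treatment-effect draw replaces rr_os in probabilistic runs.
FIRST_LINE_CLASSES = ("none", "fluoropyrimidine", "s1")


class ConfigError(ValueError):
    """Raised when a scenario configuration fails validation."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass(frozen=True)
class RegimenCost:
    """Per-cycle cost of one chemotherapy regimen.

    Component costs are kept by name (e.g. ``oxaliplatin``, ``admin_short``)
    so that probabilistic draws of a shared component (oxaliplatin appears in
    CAPOX, FOLFOX and SOX alike) stay coherent across strategies.
    """

    name: str
    drug_components: Mapping[str, float]
    admin_components: Mapping[str, float]
    cycle_length: int

    def __post_init__(self) -> None:
        _require(self.cycle_length in (2, 3), f"regimen '{self.name}'.cycle_weeks",
                 f"cycle length must be 2 or 3 weeks, got {self.cycle_length}")
        for label, comps in (("drug", self.drug_components),
                             ("admin", self.admin_components)):
            for cname, cost in comps.items():
                _require(cost >= 0 and cost == cost,
                         f"regimen '{self.name}'.{label}.{cname}",
                         f"cost must be finite and >= 0, got {cost}")
        object.__setattr__(self, "drug_components", dict(self.drug_components))
        object.__setattr__(self, "admin_components", dict(self.admin_components))

    @property
    def drug_cost_per_cycle(self) -> float:
        return float(sum(self.drug_components.values()))

    @property
    def admin_cost_per_cycle(self) -> float:
        return float(sum(self.admin_components.values()))

    def with_costs(self, costs: Mapping[str, float]) -> "RegimenCost":
        """Return a copy with any component present in *costs* replaced."""
        return replace(
            self,
            drug_components={k: costs.get(k, v) for k, v in self.drug_components.items()},
            admin_components={k: costs.get(k, v) for k, v in self.admin_components.items()},
        )


def weekly_cost(regimen: Optional[RegimenCost]) -> float:
    """Cost per model week (EUR) of a regimen; ``None`` (no treatment) is free.

    The per-cycle medication plus administration cost is spread evenly over
    the cycle's weeks.
    """
    if regimen is None:
        return 0.0
    return (regimen.drug_cost_per_cycle + regimen.admin_cost_per_cycle) / regimen.cycle_length


@dataclass(frozen=True)
class AdverseEventProfile:
    """Adverse-event probabilities, costs and quality-of-life impact.

    Recurrent hand-foot syndrome (HFS) and cardiovascular toxicity (CVT)
    carry costs; diarrhoea and anorexia enter only through disutility if
    their probabilities are set (they default to 0).  Events are assumed to
    occur immediately at the start of first-line treatment and to last
    ``duration_weeks`` weeks.
    """

    p_hfs: float = 0.0
    p_cvt: float = 0.0
    p_diarrhoea: float = 0.0
    p_anorexia: float = 0.0
    cost_hfs: float = 50.0
    cost_cvt: float = 200.0
    disutility: float = 0.15
    duration_weeks: int = 2

    def __post_init__(self) -> None:
        for key in ("p_hfs", "p_cvt", "p_diarrhoea", "p_anorexia"):
            p = getattr(self, key)
            _require(0.0 <= p <= 1.0, f"ae.{key}", f"probability must be in [0, 1], got {p}")
        _require(self.cost_hfs >= 0, "ae.cost_hfs", "cost must be >= 0")
        _require(self.cost_cvt >= 0, "ae.cost_cvt", "cost must be >= 0")
        _require(0.0 <= self.disutility <= 1.0, "ae.disutility",
                 f"disutility must be in [0, 1], got {self.disutility}")
        _require(self.duration_weeks >= 1, "ae.duration_weeks", "duration must be >= 1 week")

    @property
    def total_probability(self) -> float:
        return self.p_hfs + self.p_cvt + self.p_diarrhoea + self.p_anorexia


def expected_ae_cost(ae: AdverseEventProfile) -> float:
    """Expected adverse-event cost per patient (EUR).

    Only HFS and CVT carry costs, applied to the whole cohort as
    probability-weighted expectations (both probabilities act on everyone
    simultaneously, not on disjoint subpopulations).
    """
    return ae.p_hfs * ae.cost_hfs + ae.p_cvt * ae.cost_cvt


@dataclass(frozen=True)
class UtilitySet:
    """Quality-of-life weights per health state.

    The first-line utility anchors all states; later states are decrements
    from it.  Death carries utility 0.
    """

    u_first_line: float = 0.83
    d_second_line: float = 0.15
    d_prog_no_treat: float = 0.10
    u_death: float = 0.0

    def __post_init__(self) -> None:
        _require(self.u_death == 0.0, "utilities.u_death", "death utility must be 0")
        for key in ("d_second_line", "d_prog_no_treat"):
            u = self.u_first_line - getattr(self, key)
            _require(0.0 <= u <= 1.0, f"utilities.{key}",
                     f"state utility {u} outside [0, 1]")
        _require(0.0 <= self.u_first_line <= 1.0, "utilities.first_line",
                 "utility must be in [0, 1]")

    def with_first_line(self, u: float) -> "UtilitySet":
        return replace(self, u_first_line=float(u))


@dataclass(frozen=True)
class StrategySpec:
    """One treatment strategy: a first-line/second-line regimen pair.

    ``first_line is None`` encodes discontinuation until progression.
    ``first_line_class`` records what the first-line treatment is ("none",
    "fluoropyrimidine" or "s1"); probabilistic analyses replace ``rr_os`` of
    "s1" strategies by the sampled S-1 treatment effect and both relative
    risks of "none" strategies by the discontinuation relative risk under
    study.
    """

    name: str
    first_line: Optional[RegimenCost]
    second_line: RegimenCost
    rr_os: float
    rr_ttp: float
    ae: AdverseEventProfile = field(default_factory=AdverseEventProfile)
    first_line_class: str = "fluoropyrimidine"

    def __post_init__(self) -> None:
        _require(self.rr_os > 0, f"strategy '{self.name}'.rr_os", "relative risk must be > 0")
        _require(self.rr_ttp > 0, f"strategy '{self.name}'.rr_ttp", "relative risk must be > 0")
        _require(self.first_line_class in FIRST_LINE_CLASSES,
                 f"strategy '{self.name}'.first_line_class",
                 f"must be one of {FIRST_LINE_CLASSES}")
        if self.first_line_class == "none":
            _require(self.first_line is None, f"strategy '{self.name}'.first_line",
                     "discontinuation strategies have no first-line regimen")


@dataclass(frozen=True)
class ScenarioSpec:
    """An ordered set of strategies compared against a reference."""

    name: str
    strategies: tuple[StrategySpec, ...]
    reference_strategy: str

    def __post_init__(self) -> None:
        names = [s.name for s in self.strategies]
        _require(len(names) >= 2, f"scenario '{self.name}'.strategies",
                 "need at least two strategies to compare")
        _require(len(set(names)) == len(names), f"scenario '{self.name}'.strategies",
                 "strategy names must be unique")
        _require(self.reference_strategy in names, f"scenario '{self.name}'.reference",
                 f"reference strategy '{self.reference_strategy}' not among {names}")
        object.__setattr__(self, "strategies", tuple(self.strategies))

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ModelSettings:
    """Global settings of the weekly cohort model.

    The 780-week (~15-year) horizon leaves a negligible fraction of the
    cohort alive at the end under the default survival parameters, so the
    lifetime accounting is effectively complete.
    """

    horizon_weeks: int = 780
    weeks_per_year: float = 52.18
    discount_costs: float = 0.03
    discount_qalys: float = 0.015
    p_second_line: float = 0.80
    cohort_size: int = 1000

    def __post_init__(self) -> None:
        _require(self.horizon_weeks >= 1, "settings.horizon_weeks", "horizon must be >= 1")
        _require(0.0 <= self.p_second_line <= 1.0, "settings.p_second_line",
                 "must be a probability")
        _require(self.weeks_per_year > 0, "settings.weeks_per_year", "must be > 0")
        _require(self.discount_costs >= 0, "settings.discount_costs", "must be >= 0")
        _require(self.discount_qalys >= 0, "settings.discount_qalys", "must be >= 0")


@dataclass(frozen=True)
class ScenarioBundle:
    """Everything a run needs: scenario, settings, utilities, survival, PSA.

    ``survival`` maps ``"os"``/``"ttp"`` to Weibull parameter pairs and
    ``psa`` holds the uncertainty-distribution specification (see
    :mod:`chemoswitch.psa`).  Typed lazily as plain objects to avoid a
    circular import with the survival module.
    """

    scenario: ScenarioSpec
    settings: ModelSettings
    utilities: UtilitySet
    os_params: "object"
    ttp_params: "object"
    psa: "object"
    raw: dict = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# configuration loading

def _parse_regimen(node: Optional[dict], key: str) -> Optional[RegimenCost]:
    if node is None:
        return None
    _require(isinstance(node, dict), key, "must be a mapping or null")
    for req in ("name", "cycle_weeks"):
        _require(req in node, f"{key}.{req}", "missing required key")
    drug = node.get("drug_components")
    admin = node.get("admin_components")
    if drug is None:
        _require("drug_cost" in node, f"{key}.drug_cost",
                 "missing (provide drug_cost or drug_components)")
        drug = {f"{node['name']}_drug": node["drug_cost"]}
    if admin is None:
        admin = {f"{node['name']}_admin": node["admin_cost"]} if "admin_cost" in node else {}
    return RegimenCost(
        name=str(node["name"]),
        drug_components={str(k): float(v) for k, v in drug.items()},
        admin_components={str(k): float(v) for k, v in admin.items()},
        cycle_length=int(node["cycle_weeks"]),
    )


def _parse_ae(node: Optional[dict], key: str) -> AdverseEventProfile:
    node = node or {}
    _require(isinstance(node, dict), key, "must be a mapping")
    known = {"p_hfs", "p_cvt", "p_diarrhoea", "p_anorexia",
             "cost_hfs", "cost_cvt", "disutility", "duration_weeks"}
    for k in node:
        _require(k in known, f"{key}.{k}", "unknown adverse-event key")
    return AdverseEventProfile(**{k: v for k, v in node.items()})


def _parse_strategy(node: dict, key: str) -> StrategySpec:
    for req in ("name", "second_line", "rr_os", "rr_ttp"):
        _require(req in node, f"{key}.{req}", "missing required key")
    first = _parse_regimen(node.get("first_line"), f"{key}.first_line")
    second = _parse_regimen(node["second_line"], f"{key}.second_line")
    _require(second is not None, f"{key}.second_line", "must not be null")
    klass = node.get("first_line_class",
                     "none" if first is None else "fluoropyrimidine")
    return StrategySpec(
        name=str(node["name"]),
        first_line=first,
        second_line=second,
        rr_os=float(node["rr_os"]),
        rr_ttp=float(node["rr_ttp"]),
        ae=_parse_ae(node.get("ae"), f"{key}.ae"),
        first_line_class=str(klass),
    )


def _read_config_text(config_source) -> str:
    if isinstance(config_source, str) and config_source in BUILTIN_SCENARIOS:
        ref = resources.files("chemoswitch") / "configs" / f"{config_source}.yaml"
        return ref.read_text(encoding="utf-8")
    if hasattr(config_source, "read"):
        return config_source.read()
    with open(config_source, "r", encoding="utf-8") as fh:
        return fh.read()


def load_scenario(config_source) -> ScenarioBundle:
    """Load and validate a scenario configuration.

    Parameters
    ----------
    config_source
        A built-in scenario name (``"capox"``, ``"folfox"``, ``"cap_mono"``),
        a path to a YAML file, or an open text stream.

    Returns
    -------
    ScenarioBundle
        Validated scenario, settings, utilities, Weibull survival parameters
        and PSA distribution specification, with defaults filled in.
    """
    from .psa import PSADistributions  # deferred: psa imports params
    from .survival import WeibullParams

    raw = yaml.safe_load(_read_config_text(config_source))
    _require(isinstance(raw, dict), "<root>", "config must be a mapping")
    _require("scenario" in raw, "scenario", "missing required section")
    sc = raw["scenario"]
    for req in ("name", "strategies", "reference"):
        _require(req in sc, f"scenario.{req}", "missing required key")
    strategies = tuple(
        _parse_strategy(s, f"scenario.strategies[{i}]")
        for i, s in enumerate(sc["strategies"])
    )
    scenario = ScenarioSpec(name=str(sc["name"]), strategies=strategies,
                            reference_strategy=str(sc["reference"]))

    settings = ModelSettings(**(raw.get("settings") or {}))

    ut = raw.get("utilities") or {}
    utilities = UtilitySet(
        u_first_line=float(ut.get("first_line", 0.83)),
        d_second_line=float(ut.get("decrement_second_line", 0.15)),
        d_prog_no_treat=float(ut.get("decrement_progressed_untreated", 0.10)),
    )

    surv = raw.get("survival") or {}
    _require("os" in surv and "ttp" in surv, "survival",
             "missing 'os'/'ttp' Weibull parameters")
    os_params = WeibullParams(**{k: float(v) for k, v in surv["os"].items()})
    ttp_params = WeibullParams(**{k: float(v) for k, v in surv["ttp"].items()})

    psa = PSADistributions.from_config(raw.get("psa") or {}, scenario, os_params, ttp_params)

    return ScenarioBundle(scenario=scenario, settings=settings, utilities=utilities,
                          os_params=os_params, ttp_params=ttp_params, psa=psa, raw=raw)


def _regimen_to_dict(r: Optional[RegimenCost]) -> Optional[dict]:
    if r is None:
        return None
    return {
        "name": r.name,
        "cycle_weeks": r.cycle_length,
        "drug_components": dict(r.drug_components),
        "admin_components": dict(r.admin_components),
    }


def serialize_scenario(bundle: ScenarioBundle) -> str:
    """Serialize a loaded bundle back to canonical YAML."""
    sc = bundle.scenario
    doc = {
        "scenario": {
            "name": sc.name,
            "reference": sc.reference_strategy,
            "strategies": [
                {
                    "name": s.name,
                    "first_line_class": s.first_line_class,
                    "first_line": _regimen_to_dict(s.first_line),
                    "second_line": _regimen_to_dict(s.second_line),
                    "rr_os": s.rr_os,
                    "rr_ttp": s.rr_ttp,
                    "ae": {
                        "p_hfs": s.ae.p_hfs, "p_cvt": s.ae.p_cvt,
                        "p_diarrhoea": s.ae.p_diarrhoea, "p_anorexia": s.ae.p_anorexia,
                        "cost_hfs": s.ae.cost_hfs, "cost_cvt": s.ae.cost_cvt,
                        "disutility": s.ae.disutility,
                        "duration_weeks": s.ae.duration_weeks,
                    },
                }
                for s in sc.strategies
            ],
        },
        "settings": {
            "horizon_weeks": bundle.settings.horizon_weeks,
            "weeks_per_year": bundle.settings.weeks_per_year,
            "discount_costs": bundle.settings.discount_costs,
            "discount_qalys": bundle.settings.discount_qalys,
            "p_second_line": bundle.settings.p_second_line,
            "cohort_size": bundle.settings.cohort_size,
        },
        "utilities": {
            "first_line": bundle.utilities.u_first_line,
            "decrement_second_line": bundle.utilities.d_second_line,
            "decrement_progressed_untreated": bundle.utilities.d_prog_no_treat,
        },
        "survival": {
            "os": {"shape": bundle.os_params.shape, "scale": bundle.os_params.scale},
            "ttp": {"shape": bundle.ttp_params.shape, "scale": bundle.ttp_params.scale},
        },
        "psa": bundle.psa.to_dict(),
    }
    return yaml.safe_dump(doc, sort_keys=True)
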