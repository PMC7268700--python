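"""Policy-intervention scenarios as pure configuration transforms.

Each scenario rescales baseline parameters once, at load time: the first-visit
promotion degree (patient side), doctor incomes/workloads and their growth
rates (supplier side), and subsidy growth rates per institution type
(government side).  The combined scenario stacks the three single-agent
interventions at their marginal-value intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

from .config import INSTITUTION_TYPES, SimulationConfig

__all__ = ["ScenarioConfig", "SCENARIOS", "get_scenario", "apply_scenario"]

_HOSPITAL_TYPES = ("tertiary_comprehensive", "specialized", "district_hospital")


@dataclass(frozen=True)
class ScenarioConfig:
    """One intervention scenario: multipliers applied to a baseline config."""

    name: str
    promotion_multiplier: Optional[float] = None
    rationalize: bool = False
    income_multiplier: Optional[float] = None
    income_growth_multiplier: Optional[float] = None
    hours_multiplier: Optional[float] = None
    hours_cap: Optional[float] = None  # set all weekly hours to this value
    hours_growth_multiplier: Optional[float] = None
    subsidy_growth_multipliers: Optional[Mapping[str, float]] = None


def _gov(mult_hospital: float, mult_community: float) -> Dict[str, float]:
    m = {t: mult_hospital for t in _HOSPITAL_TYPES}
    m["community_center"] = mult_community
    return m


SCENARIOS: Dict[str, ScenarioConfig] = {
    "baseline": ScenarioConfig(name="baseline"),
    # Patient side: community first-visit promotion degree and rationalization.
    "patient_test1": ScenarioConfig(name="patient_test1", promotion_multiplier=0.5),
    "patient_test2": ScenarioConfig(name="patient_test2", promotion_multiplier=1.5, rationalize=True),
    "patient_test3": ScenarioConfig(name="patient_test3", promotion_multiplier=2.0, rationalize=True),
    # Doctor side: income level/growth and weekly workload level/growth.
    "doctor_test1": ScenarioConfig(
        name="doctor_test1",
        income_multiplier=0.5,
        income_growth_multiplier=0.5,
        hours_cap=60.0,
        hours_growth_multiplier=1.5,
    ),
    "doctor_test2": ScenarioConfig(
        name="doctor_test2",
        income_multiplier=2.0,
        income_growth_multiplier=1.5,
        hours_multiplier=0.75,
        hours_growth_multiplier=0.5,
    ),
    "doctor_test3": ScenarioConfig(
        name="doctor_test3",
        income_multiplier=3.0,
        income_growth_multiplier=2.0,
        hours_multiplier=0.5,
        hours_growth_multiplier=0.2,
    ),
    # Government side: subsidy growth per institution type.
    "government_test1": ScenarioConfig(
        name="government_test1", subsidy_growth_multipliers=_gov(0.5, 0.5)
    ),
    "government_test2": ScenarioConfig(
        name="government_test2", subsidy_growth_multipliers=_gov(2.0, 1.75)
    ),
    "government_test3": ScenarioConfig(
        name="government_test3", subsidy_growth_multipliers=_gov(3.0, 2.0)
    ),
    # Combined: the three marginal-value interventions simultaneously.
    "combined": ScenarioConfig(
        name="combined",
        promotion_multiplier=1.5,
        rationalize=True,
        income_multiplier=2.0,
        income_growth_multiplier=1.5,
        hours_multiplier=0.75,
        hours_growth_multiplier=0.5,
        subsidy_growth_multipliers=_gov(2.0, 1.75),
    ),
}


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name]
    except KeyError as exc:
        raise KeyError(
            f"unknown scenario {name!r}; known scenarios: {', '.join(sorted(SCENARIOS))}"
        ) from exc


def apply_scenario(config: SimulationConfig, scenario: ScenarioConfig) -> SimulationConfig:
    """Return a new configuration with the scenario applied; input unmodified."""
    cfg = config.model_copy(deep=True)
    if scenario.promotion_multiplier is not None:
        cfg.policy.promotion_degree *= scenario.promotion_multiplier
    if scenario.rationalize:
        cfg.policy.preference_rationalization = True

    dp = cfg.doctor_params
    if scenario.income_multiplier is not None:
        dp.income_by_title = {t: v * scenario.income_multiplier for t, v in dp.income_by_title.items()}
    if scenario.income_growth_multiplier is not None:
        dp.income_growth *= scenario.income_growth_multiplier
    if scenario.hours_cap is not None:
        dp.weekly_hours_by_title = {t: scenario.hours_cap for t in dp.weekly_hours_by_title}
    if scenario.hours_multiplier is not None:
        dp.weekly_hours_by_title = {
            t: min(60.0, v * scenario.hours_multiplier) for t, v in dp.weekly_hours_by_title.items()
        }
    if scenario.hours_growth_multiplier is not None:
        dp.hours_change *= scenario.hours_growth_multiplier

    if scenario.subsidy_growth_multipliers is not None:
        cfg.policy.subsidy_growth = {
            t: cfg.policy.subsidy_growth[t] * scenario.subsidy_growth_multipliers.get(t, 1.0)
            for t in INSTITUTION_TYPES
        }
    return cfg
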