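"""Doctor behaviour: income expectations, over-prescription, public welfare.

A doctor's expected income is a linear function of weekly workload,
``expected = -12685.5 + 678.13 * weekly_hours``.  Comparing expected against
actual income selects one of two over-prescription regimes (10% vs 50% of
doctors over-prescribe); the realized probability is damped by the
institution's public-welfare responsibility index, which rises with government
subsidies and saturates at a configurable subsidy ratio (175% of baseline for
community health centres).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List

import numpy as np

from .config import DoctorParams, GovernmentPolicy, OverPrescriptionRule, SimulationConfig

__all__ = [
    "DoctorAgent",
    "expected_income",
    "over_prescription_probability",
    "decide_over_prescription",
    "advance_doctor_year",
    "responsibility_index",
    "population_over_prescription_rate",
    "build_doctors",
]

MAX_WEEKLY_HOURS = 60.0


@dataclass(slots=True)
class DoctorAgent:
    id: int
    title: str
    institution_id: int
    actual_income: float  # CNY per year
    weekly_hours: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weekly_hours <= MAX_WEEKLY_HOURS:
            raise ValueError(
                f"doctor {self.id}: weekly_hours={self.weekly_hours} outside (0, {MAX_WEEKLY_HOURS}]"
            )


def expected_income(weekly_hours: float, params: DoctorParams) -> float:
    """Workload-implied income expectation (CNY), linear in weekly hours."""
    if weekly_hours <= 0:
        raise ValueError(f"weekly_hours={weekly_hours} must be > 0")
    return params.expectation_intercept + params.expectation_slope * weekly_hours


def over_prescription_probability(
    doctor: DoctorAgent,
    rule: OverPrescriptionRule,
    responsibility_index: float,
    params: DoctorParams,
) -> float:
    """Probability that this doctor over-prescribes in the current cycle.

    The income-expectation comparison picks the base regime probability
    (optionally with the comparison direction swapped — see docs/methods.md),
    then the institution's responsibility index damps it multiplicatively:
    full public-welfare commitment (index 1) eliminates over-prescription.
    """
    if not 0.0 <= responsibility_index <= 1.0:
        raise ValueError(f"responsibility_index={responsibility_index} outside [0, 1]")
    expectation_holds = expected_income(doctor.weekly_hours, params) >= doctor.actual_income
    if expectation_holds != rule.condition_swapped:  # XOR
        base = rule.p_expectation_met
    else:
        base = rule.p_expectation_unmet
    return base * (1.0 - responsibility_index)


def decide_over_prescription(prob: float, rng: np.random.Generator) -> bool:
    """Bernoulli over-prescription decision."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob={prob} outside [0, 1]")
    return bool(rng.random() < prob)


def advance_doctor_year(doctor: DoctorAgent, params: DoctorParams) -> DoctorAgent:
    """One year of income growth and workload change; hours capped at 60."""
    hours = doctor.weekly_hours * (1.0 + params.hours_change)
    hours = min(MAX_WEEKLY_HOURS, hours)
    return replace(
        doctor,
        actual_income=doctor.actual_income * (1.0 + params.income_growth),
        weekly_hours=hours,
    )


def responsibility_index(
    subsidy_proportion: float,
    baseline_subsidy: float,
    policy: GovernmentPolicy,
    institution_type: str = "community_center",
) -> float:
    """Public-welfare responsibility index, piecewise linear in the subsidy ratio.

    ``index = clamp((subsidy/baseline - r0) / (rmax - r0), 0, 1)`` where
    ``rmax`` is the per-type saturation ratio (1.75 for community centres:
    subsidies at 175% of baseline yield a perfect commitment) and ``r0`` is the
    ratio at which the index starts rising.
    """
    if subsidy_proportion < 0 or baseline_subsidy < 0:
        raise ValueError("subsidy proportions must be non-negative")
    if baseline_subsidy == 0:
        raise ValueError("baseline_subsidy must be positive")
    r0 = policy.responsibility_start
    rmax = policy.responsibility_saturation[institution_type]
    ratio = subsidy_proportion / baseline_subsidy
    return float(min(1.0, max(0.0, (ratio - r0) / (rmax - r0))))


def population_over_prescription_rate(
    doctors: List[DoctorAgent],
    rule: OverPrescriptionRule,
    params: DoctorParams,
    responsibility: float,
    n_decisions: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo estimate of the population over-prescription rate.

    Cycles through the doctor pool for ``n_decisions`` independent
    doctor-cycle decisions at a common responsibility index and returns the
    fraction that over-prescribe.
    """
    if n_decisions <= 0:
        raise ValueError("n_decisions must be positive")
    hits = 0
    for k in range(n_decisions):
        doctor = doctors[k % len(doctors)]
        prob = over_prescription_probability(doctor, rule, responsibility, params)
        hits += decide_over_prescription(prob, rng)
    return hits / n_decisions


def build_doctors(config: SimulationConfig, rng: np.random.Generator) -> List[DoctorAgent]:
    """Instantiate a representative doctor pool per institution.

    Titles are drawn from the configured title mix; incomes get a small
    multiplicative jitter around the title table so the income-expectation
    boundary is not knife-edge degenerate across a title class.
    """
    params = config.doctor_params
    titles = list(params.title_mix.keys())
    probs = np.asarray(list(params.title_mix.values()))
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    doctors: List[DoctorAgent] = []
    next_id = 0
    for inst in config.institutions:
        draws = np.searchsorted(cum, rng.random(params.doctors_per_institution), side="right")
        jitters = rng.uniform(1.0 - params.income_jitter, 1.0 + params.income_jitter,
                              params.doctors_per_institution)
        for k in range(params.doctors_per_institution):
            title = titles[int(draws[k])]
            doctors.append(
                DoctorAgent(
                    id=next_id,
                    title=title,
                    institution_id=inst.id,
                    actual_income=params.income_by_title[title] * float(jitters[k]),
                    weekly_hours=params.weekly_hours_by_title[title],
                )
            )
            next_id += 1
    return doctors
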