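"""Multi-year simulation orchestration, validation and scenario comparison.

:func:`run` executes the full model: per year, institutions' subsidy
proportions grow and set their public-welfare responsibility index; per
two-week cycle, a patient cohort is generated, each patient chooses an
institution type and is matched to the nearest facility, a doctor decides
whether to over-prescribe, and the episode's expenses are priced; each year
aggregates to one :class:`~hospexp.expenses.AnnualSummary`.

Randomness is a hierarchical seed tree keyed on (module, year, cycle), so a
given (config, scenario, seed) triple is fully reproducible and two scenarios
run at the same seed share their random numbers stream-for-stream (common
random numbers), which makes direction-of-effect comparisons sharp at small
sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .careseeking import (
    apply_first_visit_promotion,
    base_preference,
    choose_institution_type,
)
from .config import INSTITUTION_TYPES, SimulationConfig
from .expenses import AnnualSummary, aggregate_year, draw_care_events, episode_expense
from .providers import (
    advance_doctor_year,
    build_doctors,
    decide_over_prescription,
    over_prescription_probability,
    responsibility_index,
)
from .population import generate_patients
from .scenarios import ScenarioConfig, apply_scenario, get_scenario

__all__ = [
    "run",
    "growth_rate",
    "validate",
    "compare",
    "summary_metrics",
    "ValidationReport",
    "ValidationRow",
]

#: Tolerance band (percent) of the simulated-vs-actual validation protocol.
VALIDATION_TOLERANCE_PCT = 10.0


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


def run(
    config: SimulationConfig,
    scenario: Union[ScenarioConfig, str, None] = None,
    seed: Optional[int] = None,
    return_records: bool = False,
):
    """Run the simulator for ``config.years`` years under a scenario.

    Returns a list with one :class:`AnnualSummary` per year (years are
    1-indexed in the summaries).  With ``return_records=True`` also returns
    the per-episode expense records, keyed by year.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    cfg = apply_scenario(config, scenario) if scenario is not None else config
    if seed is None:
        seed = cfg.seed

    doctors = build_doctors(cfg, _rng(seed, 0))
    doctors_by_inst: Dict[int, List[int]] = {}
    for idx, doc in enumerate(doctors):
        doctors_by_inst.setdefault(doc.institution_id, []).append(idx)

    # Pre-index the roster per type, sorted by id so argmin ties favour low ids.
    inst_by_type: Dict[str, Tuple[list, np.ndarray, np.ndarray]] = {}
    for itype in INSTITUTION_TYPES:
        insts = sorted(cfg.institutions_of_type(itype), key=lambda i: i.id)
        lats = np.array([i.location[0] for i in insts])
        lons = np.array([i.location[1] for i in insts])
        inst_by_type[itype] = (insts, lats, lons)

    baseline_subsidy = dict(cfg.policy.subsidy_proportion)
    subsidy = dict(baseline_subsidy)
    rule = cfg.overrx_rule
    params = cfg.doctor_params

    summaries: List[AnnualSummary] = []
    records_by_year: Dict[int, list] = {}
    for year in range(cfg.years):
        resp = {
            t: responsibility_index(subsidy[t], baseline_subsidy[t], cfg.policy, t)
            for t in INSTITUTION_TYPES
        }
        records: list = []
        decisions: List[bool] = []
        for cycle in range(cfg.cycles_per_year):
            rng_pop = _rng(seed, 1, year, cycle)
            rng_choice = _rng(seed, 2, year, cycle)
            rng_events = _rng(seed, 3, year, cycle)
            rng_decide = _rng(seed, 4, year, cycle)
            for patient in generate_patients(cfg, year * cfg.cycles_per_year + cycle, rng_pop):
                weights = base_preference(patient, cfg)
                weights = apply_first_visit_promotion(
                    weights, cfg.policy.promotion_degree, patient.severity
                )
                itype = choose_institution_type(weights, rng_choice)
                insts, lats, lons = inst_by_type[itype]
                if len(insts) == 1:
                    inst = insts[0]
                else:
                    dists = _haversine_vec(patient.location, lats, lons)
                    inst = insts[int(np.argmin(dists))]

                pool = doctors_by_inst[inst.id]
                doctor = doctors[pool[int(rng_decide.integers(len(pool)))]]
                prob = over_prescription_probability(doctor, rule, resp[itype], params)
                decision = decide_over_prescription(prob, rng_decide)
                # degree drawn unconditionally to keep stream consumption
                # constant per episode (common random numbers across scenarios)
                degree_draw = float(rng_events.uniform(*rule.degree_range))
                degree = degree_draw if decision else 0.0

                events = draw_care_events(cfg.disease(patient.disease_id), rng_events)
                records.append(
                    episode_expense(patient, inst, decision, degree, events, cfg, year)
                )
                decisions.append(decision)

        summaries.append(aggregate_year(records, decisions, cfg, year + 1, subsidy))
        if return_records:
            records_by_year[year + 1] = records

        doctors = [advance_doctor_year(d, params) for d in doctors]
        subsidy = {
            t: min(1.0, subsidy[t] * (1.0 + cfg.policy.subsidy_growth[t]))
            for t in INSTITUTION_TYPES
        }

    if return_records:
        return summaries, records_by_year
    return summaries


def _haversine_vec(point: Tuple[float, float], lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    lat0, lon0 = np.radians(point[0]), np.radians(point[1])
    lat = np.radians(lats)
    lon = np.radians(lons)
    h = np.sin((lat - lat0) / 2) ** 2 + np.cos(lat0) * np.cos(lat) * np.sin((lon - lon0) / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.minimum(1.0, np.sqrt(h)))


# ---------------------------------------------------------------------------
# Analytics: growth rates, validation, scenario comparison
# ---------------------------------------------------------------------------


def growth_rate(current: float, previous: float) -> float:
    """Annual growth rate in percent, reported to 0.1."""
    if previous <= 0:
        raise ValueError(f"previous={previous} must be > 0")
    return round(100.0 * (current - previous) / previous, 1)


@dataclass(frozen=True)
class ValidationRow:
    metric: str
    simulated: float
    actual: float
    difference_pct: float

    @property
    def within_tolerance(self) -> bool:
        return abs(self.difference_pct) <= VALIDATION_TOLERANCE_PCT


@dataclass(frozen=True)
class ValidationReport:
    rows: Tuple[ValidationRow, ...]

    @property
    def passed(self) -> bool:
        return all(r.within_tolerance for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [r.metric for r in self.rows],
                "simulated": [r.simulated for r in self.rows],
                "actual": [r.actual for r in self.rows],
                "difference_pct": [r.difference_pct for r in self.rows],
                "within_tolerance": [r.within_tolerance for r in self.rows],
            }
        )


#: Scalar metrics of an AnnualSummary exposed to validation and comparison,
#: with percent scaling for ratio/share metrics.
_SCALAR_METRICS = (
    ("outpatient_total", 1.0),
    ("outpatient_medicine", 1.0),
    ("outpatient_exam", 1.0),
    ("inpatient_total", 1.0),
    ("inpatient_medicine", 1.0),
    ("inpatient_exam", 1.0),
    ("outpatient_medicine_ratio", 100.0),
    ("outpatient_exam_ratio", 100.0),
    ("inpatient_medicine_ratio", 100.0),
    ("inpatient_exam_ratio", 100.0),
    ("overprescription_rate", 100.0),
)


def summary_metrics(summary: AnnualSummary) -> Dict[str, float]:
    """Flatten an AnnualSummary to a metric -> value mapping (ratios in percent)."""
    metrics = {name: getattr(summary, name) * scale for name, scale in _SCALAR_METRICS}
    for itype in INSTITUTION_TYPES:
        metrics[f"subsidy_proportion_{itype}"] = 100.0 * summary.subsidy_proportion[itype]
        metrics[f"patient_share_{itype}"] = 100.0 * summary.patient_share[itype]
    return metrics


def validate(
    simulated: Union[AnnualSummary, Mapping[str, float]],
    actual: Mapping[str, float],
) -> ValidationReport:
    """Compare simulated against observed values, metric by metric.

    Percent difference is ``100 * (simulated - actual) / actual`` to 0.1; the
    model is credible when every metric falls within the +/-10% band.
    """
    sim = summary_metrics(simulated) if isinstance(simulated, AnnualSummary) else dict(simulated)
    missing = set(actual) - set(sim)
    if missing:
        raise KeyError(f"simulated values lack metrics {sorted(missing)}")
    rows = tuple(
        ValidationRow(
            metric=m,
            simulated=float(sim[m]),
            actual=float(a),
            difference_pct=round(100.0 * (float(sim[m]) - float(a)) / float(a), 1),
        )
        for m, a in actual.items()
    )
    return ValidationReport(rows=rows)


def compare(
    baseline: Sequence[AnnualSummary], scenario: Sequence[AnnualSummary]
) -> pd.DataFrame:
    """Per-metric, per-year deltas of a scenario run against a baseline run."""
    if len(baseline) != len(scenario):
        raise ValueError(
            f"run lengths differ: baseline {len(baseline)} vs scenario {len(scenario)} years"
        )
    rows = []
    for b, s in zip(baseline, scenario):
        mb, ms = summary_metrics(b), summary_metrics(s)
        for metric in mb:
            delta = ms[metric] - mb[metric]
            rows.append(
                {
                    "metric": metric,
                    "year": b.year,
                    "baseline": mb[metric],
                    "scenario": ms[metric],
                    "delta": delta,
                    "pct_change": 100.0 * delta / mb[metric] if mb[metric] != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
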