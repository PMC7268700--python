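"""Episode expense generation and annual aggregation.

For each patient episode the engine draws care events (outpatient visit,
hospitalization, conditional surgery, physical examination), prices the
applicable schedule components at the episode's year with compounded annual
growth, adds the over-prescribed extra on medicine and examination components
when the doctor over-prescribes, scales that extra by the patient's adherence
(the insurance reimbursement proportion), and aggregates episodes into a
yearbook-shaped annual summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .config import (
    INPATIENT_COMPONENTS,
    INSTITUTION_TYPES,
    OUTPATIENT_COMPONENTS,
    DiseaseProfile,
    Institution,
    InsuranceScheme,
    SimulationConfig,
)
from .errors import ConfigurationError
from .population import PatientAgent

__all__ = [
    "CareEvents",
    "ExpenseRecord",
    "AnnualSummary",
    "draw_care_events",
    "grown_expense",
    "adherence_factor",
    "episode_expense",
    "aggregate_year",
]

_MEDICINE_COMPONENTS = ("outpatient_medicine", "inpatient_medicine")
_EXAM_COMPONENTS = ("outpatient_exam", "inpatient_exam")


@dataclass(slots=True)
class CareEvents:
    """Care events drawn for one episode."""

    outpatient: bool
    hospitalized: bool
    surgery: bool
    physical_exam: bool


@dataclass(slots=True)
class ExpenseRecord:
    """Final expenses for one episode, base and over-prescribed extra separate."""

    patient_id: int
    institution_id: int
    institution_type: str
    year: int
    base_components: Dict[str, float]
    extra_components: Dict[str, float]
    adherence: float
    over_prescribed: bool
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.base_components.values()) + sum(self.extra_components.values())

    def component_sum(self, components: Sequence[str]) -> float:
        return sum(
            self.base_components.get(c, 0.0) + self.extra_components.get(c, 0.0)
            for c in components
        )

    @property
    def has_outpatient(self) -> bool:
        return any(c in self.base_components for c in OUTPATIENT_COMPONENTS)

    @property
    def has_inpatient(self) -> bool:
        return any(c in self.base_components for c in INPATIENT_COMPONENTS)


@dataclass(slots=True)
class AnnualSummary:
    """Per-capita expenses, ratios, patient shares and over-prescription for one year.

    Per-capita outpatient figures average over episodes with an outpatient
    visit; inpatient figures over hospitalized episodes (the yearbook's
    per-visit / per-admission convention).  Ratios are fractions in [0, 1].
    """

    year: int
    outpatient_total: float
    outpatient_medicine: float
    outpatient_exam: float
    inpatient_total: float
    inpatient_medicine: float
    inpatient_exam: float
    outpatient_medicine_ratio: float
    outpatient_exam_ratio: float
    inpatient_medicine_ratio: float
    inpatient_exam_ratio: float
    subsidy_proportion: Dict[str, float]
    patient_share: Dict[str, float]
    overprescription_rate: float
    n_outpatient: int
    n_inpatient: int
    n_episodes: int


def draw_care_events(disease: DiseaseProfile, rng: np.random.Generator) -> CareEvents:
    """Draw this episode's care events from the disease's event probabilities.

    Surgery happens only given hospitalization.  A generated patient seeks
    care, so if neither an outpatient visit nor a hospitalization is drawn the
    episode falls back to an outpatient visit.

    Exactly four uniforms are consumed per call regardless of the outcomes, so
    event draws stay aligned across scenario runs sharing a seed (common
    random numbers).
    """
    u_out, u_hosp, u_surg, u_exam = rng.random(4)
    outpatient = bool(u_out < disease.p_outpatient)
    hospitalized = bool(u_hosp < disease.p_hospitalization)
    surgery = bool(hospitalized and u_surg < disease.p_surgery)
    physical_exam = bool(u_exam < disease.p_physical_exam)
    if not (outpatient or hospitalized):
        outpatient = True
    return CareEvents(outpatient, hospitalized, surgery, physical_exam)


def grown_expense(base: float, growth: float, year: int) -> float:
    """Base amount compounded by the annual growth rate for ``year`` years."""
    if growth <= -1.0:
        raise ValueError(f"growth={growth} must be > -1")
    if year < 0:
        raise ValueError(f"year={year} must be >= 0")
    return base * (1.0 + growth) ** year


def adherence_factor(scheme: InsuranceScheme, level: str) -> float:
    """Prescription adherence = the insurance reimbursement proportion (1 - copay)."""
    try:
        copay = scheme.copay_by_level[level]
    except KeyError as exc:
        raise ConfigurationError(f"scheme {scheme.name}: no copay for level {level!r}") from exc
    return 1.0 - copay


def _applicable_components(events: CareEvents) -> List[str]:
    comps: List[str] = []
    if events.outpatient:
        comps += ["outpatient_base", "outpatient_medicine"]
        if events.physical_exam:
            comps.append("outpatient_exam")
    if events.hospitalized:
        comps += ["inpatient_base", "inpatient_medicine", "treatment", "material"]
        if events.physical_exam:
            comps.append("inpatient_exam")
        if events.surgery:
            comps.append("surgery")
    return comps


def episode_expense(
    patient: PatientAgent,
    institution: Institution,
    decision: bool,
    degree: float,
    events: CareEvents,
    config: SimulationConfig,
    year: int,
) -> ExpenseRecord:
    """Price one episode.

    Base components are the disease's schedule for the institution's type,
    compounded to ``year``.  If the doctor over-prescribed, the extra is
    ``degree``  times the episode's base medicine + examination components,
    scaled by the patient's adherence and allocated pro-rata across those
    components; all other components are unaffected.
    """
    disease = config.disease(patient.disease_id)
    try:
        schedule = disease.base_expenses[institution.type]
    except KeyError as exc:
        raise ConfigurationError(
            f"disease {disease.id}: no expense schedule for institution type {institution.type!r}"
        ) from exc

    base: Dict[str, float] = {}
    for comp in _applicable_components(events):
        base[comp] = grown_expense(schedule.components[comp], schedule.annual_growth[comp], year)

    extra: Dict[str, float] = {}
    adherence = adherence_factor(patient.insurance, institution.level)
    if decision:
        inflatable = [c for c in (*_MEDICINE_COMPONENTS, *_EXAM_COMPONENTS) if c in base]
        pool = sum(base[c] for c in inflatable)
        accepted = degree * pool * adherence
        if pool > 0:
            for c in inflatable:
                extra[c] = accepted * base[c] / pool
    return ExpenseRecord(
        patient_id=patient.id,
        institution_id=institution.id,
        institution_type=institution.type,
        year=year,
        base_components=base,
        extra_components=extra,
        adherence=adherence,
        over_prescribed=decision,
    )


def _mean(values: List[float]) -> float:
    return float(np.mean(values)) if values else 0.0


def _ratio(part: float, whole: float) -> float:
    return part / whole if whole > 0 else 0.0


def aggregate_year(
    records: Sequence[ExpenseRecord],
    decisions: Sequence[bool],
    config: SimulationConfig,
    year: int,
    subsidy_proportions: Optional[Mapping[str, float]] = None,
) -> AnnualSummary:
    """Aggregate one year of episode records into an annual summary.

    Outpatient per-capita figures average over episodes with an outpatient
    visit, inpatient figures over hospitalized episodes; patient shares count
    episodes per institution type; the over-prescription rate is the fraction
    of positive doctor decisions.
    """
    if not records:
        raise ValueError("aggregate_year requires at least one expense record")
    if subsidy_proportions is None:
        subsidy_proportions = config.policy.subsidy_proportion

    out_totals, out_med, out_exam = [], [], []
    in_totals, in_med, in_exam = [], [], []
    type_counts = {t: 0 for t in INSTITUTION_TYPES}
    for r in records:
        type_counts[r.institution_type] += 1
        if r.has_outpatient:
            out_totals.append(r.component_sum(OUTPATIENT_COMPONENTS))
            out_med.append(r.component_sum(["outpatient_medicine"]))
            out_exam.append(r.component_sum(["outpatient_exam"]))
        if r.has_inpatient:
            in_totals.append(r.component_sum(INPATIENT_COMPONENTS))
            in_med.append(r.component_sum(["inpatient_medicine"]))
            in_exam.append(r.component_sum(["inpatient_exam"]))

    out_total = _mean(out_totals)
    in_total = _mean(in_totals)
    n = len(records)
    return AnnualSummary(
        year=year,
        outpatient_total=out_total,
        outpatient_medicine=_mean(out_med),
        outpatient_exam=_mean(out_exam),
        inpatient_total=in_total,
        inpatient_medicine=_mean(in_med),
        inpatient_exam=_mean(in_exam),
        outpatient_medicine_ratio=_ratio(_mean(out_med), out_total),
        outpatient_exam_ratio=_ratio(_mean(out_exam), out_total),
        inpatient_medicine_ratio=_ratio(_mean(in_med), in_total),
        inpatient_exam_ratio=_ratio(_mean(in_exam), in_total),
        subsidy_proportion={t: float(subsidy_proportions[t]) for t in INSTITUTION_TYPES},
        patient_share={t: type_counts[t] / n for t in INSTITUTION_TYPES},
        overprescription_rate=float(np.mean(decisions)) if len(decisions) else 0.0,
        n_outpatient=len(out_totals),
        n_inpatient=len(in_totals),
        n_episodes=n,
    )
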