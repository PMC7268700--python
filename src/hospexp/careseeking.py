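"""Care-seeking: institution-type preference and nearest-facility assignment.

A patient's first-stage preference over the four institution types comes from
a deterministic lookup on (disease severity, age band, income band).
Government promotion of the community first-visit system then scales the
community weight multiplicatively for minor/common cases; severe cases are
never steered to primary care.  The concrete facility is the nearest one of
the chosen type by great-circle distance, ties broken by lowest id.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, cos, radians, sin, sqrt
from typing import Dict, Sequence

import numpy as np

from .config import INSTITUTION_TYPES, Institution, SimulationConfig
from .errors import AssignmentError
from .population import PatientAgent

__all__ = [
    "PreferenceWeights",
    "base_preference",
    "apply_first_visit_promotion",
    "choose_institution_type",
    "haversine_km",
    "nearest_institution",
]

EARTH_RADIUS_KM = 6371.0

#: Fixed sampling order: the community interval sits last on the unit line, so
#: under common random numbers raising the community weight can only grow the
#: community interval and shrink the leading tertiary-comprehensive interval.
TYPE_ORDER = INSTITUTION_TYPES


@dataclass(slots=True)
class PreferenceWeights:
    """Non-negative preference mass per institution type."""

    weights: Dict[str, float]

    def __post_init__(self) -> None:
        for itype, w in self.weights.items():
            if w < 0:
                raise ValueError(f"preference weight[{itype}]={w} is negative")

    def total(self) -> float:
        return sum(self.weights.get(t, 0.0) for t in TYPE_ORDER)

    def normalized(self) -> Dict[str, float]:
        total = self.total()
        if total <= 0:
            raise ValueError("all preference weights are zero")
        return {t: self.weights.get(t, 0.0) / total for t in TYPE_ORDER}


def base_preference(patient: PatientAgent, config: SimulationConfig) -> PreferenceWeights:
    """Deterministic first-stage preference weights for one patient.

    Severe cases get zero community weight; the specialized-hospital weight is
    only active for diseases flagged specialized-eligible.  When preference
    rationalization is in force (a patient-side intervention), minor cases
    additionally get zero tertiary-comprehensive weight.
    """
    entry = config.preferences.lookup(
        patient.severity,
        patient.demographics["age_band"],
        patient.demographics["income_band"],
    )
    weights = {t: entry.get(t, 0.0) for t in TYPE_ORDER}
    if not patient.specialized_eligible:
        weights["specialized"] = 0.0
    if patient.severity == "severe":
        weights["community_center"] = 0.0
    if config.policy.preference_rationalization and patient.severity == "minor":
        weights["tertiary_comprehensive"] = 0.0
    return PreferenceWeights(weights=weights)


def apply_first_visit_promotion(
    weights: PreferenceWeights, promotion_degree: float, severity: str
) -> PreferenceWeights:
    """Scale the community weight by the first-visit promotion degree.

    Only minor/common cases respond to the promotion; degree 1.0 is the
    identity (up to renormalization, which happens at sampling time).
    """
    if promotion_degree < 0:
        raise ValueError(f"promotion_degree={promotion_degree} must be >= 0")
    new = dict(weights.weights)
    if severity in ("minor", "common"):
        new["community_center"] = new.get("community_center", 0.0) * promotion_degree
    return PreferenceWeights(weights=new)


def choose_institution_type(weights: PreferenceWeights, rng: np.random.Generator) -> str:
    """Categorical draw of an institution type proportional to the weights."""
    norm = weights.normalized()  # raises on all-zero weights
    u = rng.random()
    acc = 0.0
    for itype in TYPE_ORDER:
        acc += norm[itype]
        if u < acc:
            return itype
    return TYPE_ORDER[-1]


def haversine_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance in km between (lat, lon) points on a 6371-km sphere."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates ({lat}, {lon}) out of range")
    phi1, phi2 = radians(lat1), radians(lat2)
    dphi = radians(lat2 - lat1)
    dlam = radians(lon2 - lon1)
    h = sin(dphi / 2.0) ** 2 + cos(phi1) * cos(phi2) * sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * asin(min(1.0, sqrt(h)))


def nearest_institution(
    patient: PatientAgent, institutions: Sequence[Institution], chosen_type: str
) -> Institution:
    """The closest institution of the chosen type; ties broken by lowest id."""
    best: Institution | None = None
    best_d = float("inf")
    for inst in institutions:
        if inst.type != chosen_type:
            continue
        d = haversine_km(patient.location, inst.location)
        if d < best_d or (d == best_d and best is not None and inst.id < best.id):
            best, best_d = inst, d
    if best is None:
        raise AssignmentError(f"no institution of type {chosen_type!r} in the roster")
    return best
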