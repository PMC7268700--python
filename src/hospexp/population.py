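"""Patient-agent generation.

Each two-week cycle, the model draws a fresh cohort of patients: a binomial
count per disease from its two-week prevalence, then independent categorical
draws for demographics, an insurance scheme by population share, and a home
district by population share with a uniform location inside the district's
bounding box.  The population is static — shares and distributions never
change across cycles — so episodes in different cycles are independent
replicates of the same generative process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import DEMOGRAPHIC_FIELDS, InsuranceScheme, SimulationConfig

__all__ = ["PatientAgent", "draw_patient_count", "generate_patients"]


@dataclass(slots=True)
class PatientAgent:
    """A patient episode: one person seeking care for one disease in one cycle."""

    id: int
    disease_id: int
    severity: str
    specialized_eligible: bool
    demographics: Dict[str, str]
    insurance: InsuranceScheme
    district_id: int
    location: Tuple[float, float]  # (latitude deg, longitude deg)
    cycle_created: int


def draw_patient_count(population_size: int, prevalence: float, rng: np.random.Generator) -> int:
    """Binomial draw of this cycle's case count for one disease."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence={prevalence} outside [0, 1]")
    return int(rng.binomial(population_size, prevalence))


def _categorical(labels: Sequence[str], probs: Sequence[float], n: int, rng: np.random.Generator) -> List[str]:
    cum = np.cumsum(probs)
    cum[-1] = 1.0  # guard against float drift in the final bin
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return [labels[i] for i in idx]


def generate_patients(
    config: SimulationConfig, cycle: int, rng: np.random.Generator
) -> List[PatientAgent]:
    """Generate the patient cohort for one two-week cycle.

    Draw order is fixed (disease by ascending id, then per-disease attribute
    blocks), so a given (config, generator state) pair always yields the same
    cohort.
    """
    if cycle < 0:
        raise ValueError(f"cycle={cycle} must be >= 0")

    demo_labels = {f: list(config.demographics[f].keys()) for f in DEMOGRAPHIC_FIELDS}
    demo_probs = {f: list(config.demographics[f].values()) for f in DEMOGRAPHIC_FIELDS}
    district_shares = [d.population_share for d in config.districts]
    scheme_shares = [s.population_share for s in config.insurance]

    patients: List[PatientAgent] = []
    next_id = 0
    for disease in config.diseases:
        n = draw_patient_count(config.population_size, disease.two_week_prevalence, rng)
        if n == 0:
            continue
        demos = {f: _categorical(demo_labels[f], demo_probs[f], n, rng) for f in DEMOGRAPHIC_FIELDS}
        scheme_idx = np.searchsorted(np.cumsum(scheme_shares), rng.random(n), side="right")
        district_idx = np.searchsorted(np.cumsum(district_shares), rng.random(n), side="right")
        district_idx = np.minimum(district_idx, len(config.districts) - 1)
        u_lat = rng.random(n)
        u_lon = rng.random(n)
        for k in range(n):
            d = config.districts[int(district_idx[k])]
            patients.append(
                PatientAgent(
                    id=next_id,
                    disease_id=disease.id,
                    severity=disease.severity_class,
                    specialized_eligible=disease.specialized_eligible,
                    demographics={f: demos[f][k] for f in DEMOGRAPHIC_FIELDS},
                    insurance=config.insurance[min(int(scheme_idx[k]), len(config.insurance) - 1)],
                    district_id=d.id,
                    location=(
                        d.lat_min + u_lat[k] * (d.lat_max - d.lat_min),
                        d.lon_min + u_lon[k] * (d.lon_max - d.lon_min),
                    ),
                    cycle_created=cycle,
                )
            )
            next_id += 1
    return patients
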