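"""Configuration schema, synthetic parameter generation, and summary I/O.

The whole simulator is driven by one structured configuration (a YAML file or
a :class:`SimulationConfig` object) that plays the role of the model's flat
input-parameter table: 30 disease profiles with two-week prevalences and
expense schedules, a district map with population shares, an institution
roster over the four public-institution types, insurance schemes with
level-dependent copayments, government subsidy/promotion policy, and doctor
income/workload parameters.

The true calibrated input values for the Shanghai system are not publicly
available, so :func:`generate_fixture` produces a complete *synthetic* stand-in
configuration from a seed.  The fixture preserves the structural facts that
the model's behaviour depends on (expense ordering tertiary > district >
community, copay 30% at primary vs 50% at tertiary level, 16 districts,
30 diseases, both doctor-income regimes populated) while all specific numbers
are plausible-band draws, documented as synthetic in ``docs/methods.md``.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Dict, List, Literal, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError, NormalizationError

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a runtime cycle
    from .expenses import AnnualSummary

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

InstitutionType = Literal[
    "tertiary_comprehensive", "specialized", "district_hospital", "community_center"
]
InstitutionLevel = Literal["primary", "secondary", "tertiary"]
Severity = Literal["minor", "common", "severe"]

INSTITUTION_TYPES: Tuple[str, ...] = (
    "tertiary_comprehensive",
    "specialized",
    "district_hospital",
    "community_center",
)

#: Institutional tier implied by each institution type (Chinese three-level system).
LEVEL_OF_TYPE: Dict[str, str] = {
    "tertiary_comprehensive": "tertiary",
    "specialized": "tertiary",
    "district_hospital": "secondary",
    "community_center": "primary",
}

EXPENSE_COMPONENTS: Tuple[str, ...] = (
    "outpatient_base",
    "outpatient_medicine",
    "outpatient_exam",
    "inpatient_base",
    "inpatient_medicine",
    "inpatient_exam",
    "treatment",
    "surgery",
    "material",
)

OUTPATIENT_COMPONENTS: Tuple[str, ...] = (
    "outpatient_base",
    "outpatient_medicine",
    "outpatient_exam",
)
INPATIENT_COMPONENTS: Tuple[str, ...] = (
    "inpatient_base",
    "inpatient_medicine",
    "inpatient_exam",
    "treatment",
    "surgery",
    "material",
)

SEVERITIES: Tuple[str, ...] = ("minor", "common", "severe")
DEMOGRAPHIC_FIELDS: Tuple[str, ...] = (
    "gender",
    "age_band",
    "occupation",
    "marital_status",
    "education",
    "income_band",
)
AGE_BANDS: Tuple[str, ...] = ("0-14", "15-34", "35-59", "60+")
INCOME_BANDS: Tuple[str, ...] = ("low", "middle", "high")

_SHARE_TOL = 1e-9


def _check_unit_interval(owner: str, **fields: float) -> None:
    for name, value in fields.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{owner}: {name}={value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ExpenseSchedule(BaseModel):
    """Base expense components (CNY, year 0) and their annual growth rates."""

    model_config = ConfigDict(extra="forbid")

    components: Dict[str, float]
    annual_growth: Dict[str, float]

    @model_validator(mode="after")
    def _validate(self) -> "ExpenseSchedule":
        for mapping, label in ((self.components, "components"), (self.annual_growth, "annual_growth")):
            missing = set(EXPENSE_COMPONENTS) - set(mapping)
            extra = set(mapping) - set(EXPENSE_COMPONENTS)
            if missing or extra:
                raise ValueError(
                    f"expense schedule {label}: missing={sorted(missing)} unknown={sorted(extra)}"
                )
        for name, amount in self.components.items():
            if amount < 0:
                raise ValueError(f"expense schedule component {name}={amount} is negative")
        for name, rate in self.annual_growth.items():
            if rate <= -1:
                raise ValueError(f"expense schedule growth {name}={rate} must be > -1")
        return self


class DiseaseProfile(BaseModel):
    """One of the 30 disease classes the patient generator draws from."""

    model_config = ConfigDict(extra="forbid")

    id: int = Field(ge=1, le=30)
    name: str
    two_week_prevalence: float
    severity_class: Severity
    p_outpatient: float
    p_hospitalization: float
    p_surgery: float  # conditional on hospitalization
    p_physical_exam: float
    specialized_eligible: bool = False
    base_expenses: Dict[InstitutionType, ExpenseSchedule]

    @model_validator(mode="after")
    def _validate(self) -> "DiseaseProfile":
        _check_unit_interval(
            f"disease {self.id} ({self.name})",
            two_week_prevalence=self.two_week_prevalence,
            p_outpatient=self.p_outpatient,
            p_hospitalization=self.p_hospitalization,
            p_surgery=self.p_surgery,
            p_physical_exam=self.p_physical_exam,
        )
        missing = set(INSTITUTION_TYPES) - set(self.base_expenses)
        if missing:
            raise ValueError(
                f"disease {self.id} ({self.name}): no expense schedule for {sorted(missing)}"
            )
        return self


class District(BaseModel):
    """Administrative district: population share and an axis-aligned lat/lon box."""

    model_config = ConfigDict(extra="forbid")

    id: int
    name: str
    population_share: float = Field(ge=0.0, le=1.0)
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    @model_validator(mode="after")
    def _validate(self) -> "District":
        if not (self.lat_min < self.lat_max and self.lon_min < self.lon_max):
            raise ValueError(f"district {self.id} ({self.name}): degenerate bounding box")
        return self

    def contains(self, lat: float, lon: float) -> bool:
        return self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max


class Institution(BaseModel):
    """A public medical institution (hospital or community health centre)."""

    model_config = ConfigDict(extra="forbid")

    id: int
    name: str
    type: InstitutionType
    level: InstitutionLevel
    location: Tuple[float, float]  # (latitude deg, longitude deg)
    subsidy_proportion: float = Field(ge=0.0, le=1.0)
    responsibility_index: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "Institution":
        expected = LEVEL_OF_TYPE[self.type]
        if self.level != expected:
            raise ValueError(
                f"institution {self.id} ({self.name}): type {self.type} implies level "
                f"{expected}, got {self.level}"
            )
        return self


class InsuranceScheme(BaseModel):
    """An insurance scheme with level-dependent out-of-pocket proportions."""

    model_config = ConfigDict(extra="forbid")

    name: Literal["urban_worker", "urban_rural_resident", "uninsured"]
    population_share: float = Field(ge=0.0, le=1.0)
    copay_by_level: Dict[InstitutionLevel, float]

    @model_validator(mode="after")
    def _validate(self) -> "InsuranceScheme":
        missing = {"primary", "secondary", "tertiary"} - set(self.copay_by_level)
        if missing:
            raise ValueError(f"insurance scheme {self.name}: missing copay for {sorted(missing)}")
        for level, copay in self.copay_by_level.items():
            if not 0.0 <= copay <= 1.0:
                raise ValueError(f"insurance scheme {self.name}: copay[{level}]={copay} outside [0, 1]")
        return self


class GovernmentPolicy(BaseModel):
    """Government levers: subsidies per institution type and first-visit promotion.

    ``responsibility_saturation`` is, per institution type, the subsidy ratio
    (current / baseline) at which the public-welfare responsibility index
    saturates at 1.  For community health centres the default saturation is
    1.75: subsidies at 175% of baseline mean responsibilities are undertaken
    perfectly.  ``responsibility_start`` is the ratio at which the index starts
    rising from 0 (default 0, i.e. proportional up to saturation).
    """

    model_config = ConfigDict(extra="forbid")

    subsidy_proportion: Dict[InstitutionType, float]
    subsidy_growth: Dict[InstitutionType, float]
    promotion_degree: float = Field(default=1.0, ge=0.0)
    responsibility_saturation: Dict[InstitutionType, float] = Field(
        default_factory=lambda: {
            "tertiary_comprehensive": 3.0,
            "specialized": 3.0,
            "district_hospital": 3.0,
            "community_center": 1.75,
        }
    )
    responsibility_start: float = Field(default=0.0, ge=0.0)
    preference_rationalization: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "GovernmentPolicy":
        for mapping, label in (
            (self.subsidy_proportion, "subsidy_proportion"),
            (self.subsidy_growth, "subsidy_growth"),
            (self.responsibility_saturation, "responsibility_saturation"),
        ):
            missing = set(INSTITUTION_TYPES) - set(mapping)
            if missing:
                raise ValueError(f"policy {label}: missing institution types {sorted(missing)}")
        for itype, prop in self.subsidy_proportion.items():
            if not 0.0 <= prop <= 1.0:
                raise ValueError(f"policy subsidy_proportion[{itype}]={prop} outside [0, 1]")
        for itype, rmax in self.responsibility_saturation.items():
            if rmax <= self.responsibility_start:
                raise ValueError(
                    f"policy responsibility_saturation[{itype}]={rmax} must exceed "
                    f"responsibility_start={self.responsibility_start}"
                )
        return self


class DoctorParams(BaseModel):
    """Doctor income/workload parameters and the expected-income regression.

    The expected-income line ``intercept + slope * weekly_hours`` converts a
    doctor's workload into the income they feel their effort warrants; its
    output is compared against ``actual_income`` on the same (annual CNY)
    scale, and only the sign of the comparison enters the over-prescription
    decision.
    """

    model_config = ConfigDict(extra="forbid")

    income_by_title: Dict[str, float]
    income_growth: float = Field(gt=-1.0)
    weekly_hours_by_title: Dict[str, float]
    hours_change: float = Field(gt=-1.0)
    expectation_intercept: float = -12685.5
    expectation_slope: float = 678.13
    title_mix: Dict[str, float]
    doctors_per_institution: int = Field(default=4, ge=1)
    income_jitter: float = Field(default=0.1, ge=0.0, lt=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "DoctorParams":
        if set(self.income_by_title) != set(self.weekly_hours_by_title) or set(
            self.income_by_title
        ) != set(self.title_mix):
            raise ValueError("doctor_params: title sets of income/hours/mix must coincide")
        for title, income in self.income_by_title.items():
            if income <= 0:
                raise ValueError(f"doctor_params income_by_title[{title}]={income} must be > 0")
        for title, hours in self.weekly_hours_by_title.items():
            if not 0 < hours <= 60:
                raise ValueError(
                    f"doctor_params weekly_hours_by_title[{title}]={hours} outside (0, 60]"
                )
        total = sum(self.title_mix.values())
        if abs(total - 1.0) > _SHARE_TOL:
            raise NormalizationError(
                f"doctor_params title_mix sums to {total!r}; shares must sum to 1"
            )
        return self


class OverPrescriptionRule(BaseModel):
    """Two-regime over-prescription rule with public-welfare damping.

    Base probability is 10% when the income expectation comparison holds and
    50% otherwise; ``condition_swapped`` flips which side of the
    expected-vs-actual comparison maps to which probability (see
    docs/methods.md for why both orientations are provided).  The realized
    probability is damped by ``(1 - responsibility_index)``.
    """

    model_config = ConfigDict(extra="forbid")

    p_expectation_met: float = 0.10
    p_expectation_unmet: float = 0.50
    degree_range: Tuple[float, float] = (0.1, 0.5)
    condition_swapped: bool = False

    @model_validator(mode="after")
    def _validate(self) -> "OverPrescriptionRule":
        if not 0.0 <= self.p_expectation_met <= self.p_expectation_unmet <= 1.0:
            raise ValueError(
                "over-prescription rule requires 0 <= p_expectation_met <= "
                f"p_expectation_unmet <= 1, got ({self.p_expectation_met}, {self.p_expectation_unmet})"
            )
        lo, hi = self.degree_range
        if not (0.0 < lo <= hi):
            raise ValueError(f"over-prescription degree_range {self.degree_range} must lie in (0, inf)")
        return self


class PreferenceTable(BaseModel):
    """Care-seeking preference weights keyed on (severity, age band, income band).

    Weights are non-negative per institution type and are normalized at
    sampling time; severe rows must give community centres zero weight (severe
    cases are never steered to primary care).
    """

    model_config = ConfigDict(extra="forbid")

    table: Dict[str, Dict[str, Dict[str, Dict[str, float]]]]

    @model_validator(mode="after")
    def _validate(self) -> "PreferenceTable":
        for severity, by_age in self.table.items():
            if severity not in SEVERITIES:
                raise ValueError(f"preference table: unknown severity {severity!r}")
            for age, by_income in by_age.items():
                for income, weights in by_income.items():
                    key = f"preferences[{severity}][{age}][{income}]"
                    unknown = set(weights) - set(INSTITUTION_TYPES)
                    if unknown:
                        raise ValueError(f"{key}: unknown institution types {sorted(unknown)}")
                    for itype, w in weights.items():
                        if w < 0:
                            raise ValueError(f"{key}: weight[{itype}]={w} is negative")
                    if severity == "severe" and weights.get("community_center", 0.0) != 0.0:
                        raise ValueError(f"{key}: severe cases must have zero community weight")
        return self

    def lookup(self, severity: str, age_band: str, income_band: str) -> Dict[str, float]:
        try:
            return self.table[severity][age_band][income_band]
        except KeyError as exc:
            raise ConfigurationError(
                f"no preference entry for (severity={severity!r}, age_band={age_band!r}, "
                f"income_band={income_band!r})"
            ) from exc


class SimulationConfig(BaseModel):
    """The complete input-parameter set for one simulation."""

    model_config = ConfigDict(extra="forbid")

    diseases: List[DiseaseProfile]
    districts: List[District]
    institutions: List[Institution]
    insurance: List[InsuranceScheme]
    policy: GovernmentPolicy
    doctor_params: DoctorParams
    overrx_rule: OverPrescriptionRule
    preferences: PreferenceTable
    demographics: Dict[str, Dict[str, float]]
    population_size: int = Field(gt=0)
    years: int = Field(default=3, ge=1)
    cycles_per_year: int = Field(default=26, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        if len(self.diseases) != 30:
            raise ValueError(f"a full configuration defines exactly 30 diseases, got {len(self.diseases)}")
        ids = sorted(d.id for d in self.diseases)
        if ids != list(range(1, 31)):
            raise ValueError("disease ids must be exactly 1..30 without repeats")

        share = sum(d.population_share for d in self.districts)
        if abs(share - 1.0) > _SHARE_TOL:
            raise NormalizationError(
                f"district population shares sum to {share!r}; they must sum to 1"
            )
        ins_share = sum(s.population_share for s in self.insurance)
        if abs(ins_share - 1.0) > _SHARE_TOL:
            raise NormalizationError(
                f"insurance scheme shares sum to {ins_share!r}; they must sum to 1"
            )

        present = {i.type for i in self.institutions}
        missing = set(INSTITUTION_TYPES) - present
        if missing:
            raise ValueError(f"institution roster lacks types {sorted(missing)}")
        inst_ids = [i.id for i in self.institutions]
        if len(inst_ids) != len(set(inst_ids)):
            raise ValueError("institution ids must be unique")

        missing_demo = set(DEMOGRAPHIC_FIELDS) - set(self.demographics)
        if missing_demo:
            raise ValueError(f"demographics: missing distributions for {sorted(missing_demo)}")
        for field, dist in self.demographics.items():
            total = sum(dist.values())
            if abs(total - 1.0) > _SHARE_TOL:
                raise NormalizationError(
                    f"demographics[{field}] sums to {total!r}; shares must sum to 1"
                )
            for cat, p in dist.items():
                if p < 0:
                    raise ValueError(f"demographics[{field}][{cat}]={p} is negative")
        return self

    # convenience lookups ---------------------------------------------------

    def disease(self, disease_id: int) -> DiseaseProfile:
        for d in self.diseases:
            if d.id == disease_id:
                return d
        raise KeyError(disease_id)

    def institutions_of_type(self, itype: str) -> List[Institution]:
        return [i for i in self.institutions if i.type == itype]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_config(path) -> SimulationConfig:
    """Read and fully validate a configuration file.

    Raises :class:`ConfigurationError` (or its subclass
    :class:`NormalizationError` for share-sum violations) with a message naming
    the offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as exc:
        messages = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        if "must sum to 1" in messages:
            raise NormalizationError(messages) from exc
        raise ConfigurationError(messages) from exc


def save_config(config: SimulationConfig, path) -> None:
    """Write a configuration to YAML (round-trips through :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

_DISEASE_CATALOG: Tuple[Tuple[str, str, bool], ...] = (
    # (name, severity, specialized_eligible)
    ("acute upper respiratory infection", "minor", False),
    ("acute gastroenteritis", "minor", False),
    ("influenza", "minor", False),
    ("acute pharyngitis", "minor", False),
    ("dermatitis", "minor", True),
    ("conjunctivitis", "minor", True),
    ("low back pain", "minor", False),
    ("migraine", "minor", False),
    ("allergic rhinitis", "minor", False),
    ("dental caries", "minor", True),
    ("hypertension", "common", False),
    ("type 2 diabetes", "common", False),
    ("chronic gastritis", "common", False),
    ("asthma", "common", True),
    ("chronic bronchitis", "common", False),
    ("arthritis", "common", False),
    ("peptic ulcer", "common", False),
    ("urinary tract infection", "common", False),
    ("gallstones", "common", False),
    ("anemia", "common", False),
    ("hyperlipidemia", "common", False),
    ("cervical spondylosis", "common", True),
    ("coronary heart disease", "severe", True),
    ("stroke", "severe", False),
    ("lung cancer", "severe", True),
    ("gastric cancer", "severe", True),
    ("chronic kidney disease", "severe", False),
    ("cirrhosis", "severe", False),
    ("severe pneumonia", "severe", False),
    ("hip fracture", "severe", True),
)

# Two-week prevalence bands per severity class (per person per two-week cycle).
_PREVALENCE_BANDS = {"minor": (0.005, 0.05), "common": (0.001, 0.02), "severe": (0.0005, 0.005)}

# Community-level base expense bands (CNY); higher tiers are scaled multiples.
_COMMUNITY_EXPENSE_BANDS = {
    "outpatient_base": (15.0, 40.0),
    "outpatient_medicine": (30.0, 90.0),
    "outpatient_exam": (8.0, 30.0),
    "inpatient_base": (800.0, 2500.0),
    "inpatient_medicine": (600.0, 2500.0),
    "inpatient_exam": (150.0, 500.0),
    "treatment": (300.0, 1200.0),
    "surgery": (1500.0, 6000.0),
    "material": (200.0, 900.0),
}

_SEVERITY_EXPENSE_SCALE = {"minor": 0.7, "common": 1.0, "severe": 1.8}

# Approximate lat/lon extent of the modelled municipality, tiled 4x4.
_LAT_RANGE = (30.70, 31.87)
_LON_RANGE = (120.85, 121.97)


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def _make_disease(idx: int, name: str, severity: str, specialized: bool, rng: np.random.Generator) -> DiseaseProfile:
    lo, hi = _PREVALENCE_BANDS[severity]
    prevalence = _round6(rng.uniform(lo, hi))
    if severity == "minor":
        p_out = rng.uniform(0.85, 0.98)
        p_hosp = rng.uniform(0.0, 0.05)
        p_surg = rng.uniform(0.0, 0.1)
    elif severity == "common":
        p_out = rng.uniform(0.7, 0.95)
        p_hosp = rng.uniform(0.05, 0.25)
        p_surg = rng.uniform(0.05, 0.3)
    else:
        p_out = rng.uniform(0.4, 0.8)
        p_hosp = rng.uniform(0.5, 0.9)
        p_surg = rng.uniform(0.3, 0.7)
    p_exam = rng.uniform(0.3, 0.9)

    scale = _SEVERITY_EXPENSE_SCALE[severity]
    schedules: Dict[str, ExpenseSchedule] = {}
    community = {
        comp: _round6(rng.uniform(lo_, hi_) * scale)
        for comp, (lo_, hi_) in _COMMUNITY_EXPENSE_BANDS.items()
    }
    # Tier multipliers enforce the fee-schedule ordering
    # tertiary_comprehensive >= specialized > district > community, componentwise.
    district = {c: _round6(v * rng.uniform(1.5, 2.0)) for c, v in community.items()}
    specialized_s = {c: _round6(district[c] * rng.uniform(1.3, 1.6)) for c in community}
    tertiary = {c: _round6(specialized_s[c] * rng.uniform(1.05, 1.3)) for c in community}
    growth = {c: _round6(rng.uniform(0.03, 0.08)) for c in community}
    for itype, comps in (
        ("tertiary_comprehensive", tertiary),
        ("specialized", specialized_s),
        ("district_hospital", district),
        ("community_center", community),
    ):
        schedules[itype] = ExpenseSchedule(components=comps, annual_growth=dict(growth))

    return DiseaseProfile(
        id=idx,
        name=name,
        two_week_prevalence=prevalence,
        severity_class=severity,
        p_outpatient=_round6(p_out),
        p_hospitalization=_round6(p_hosp),
        p_surgery=_round6(p_surg),
        p_physical_exam=_round6(p_exam),
        specialized_eligible=specialized,
        base_expenses=schedules,
    )


def _make_districts(rng: np.random.Generator) -> List[District]:
    lat_edges = np.linspace(*_LAT_RANGE, 5)
    lon_edges = np.linspace(*_LON_RANGE, 5)
    raw = rng.gamma(2.0, 1.0, size=16)
    shares = raw / raw.sum()
    shares = [_round6(s) for s in shares[:-1]]
    shares.append(float(1.0 - sum(shares)))  # exact unit sum after rounding
    districts = []
    k = 0
    for i in range(4):
        for j in range(4):
            districts.append(
                District(
                    id=k + 1,
                    name=f"district_{k + 1:02d}",
                    population_share=shares[k],
                    lat_min=float(lat_edges[i]),
                    lat_max=float(lat_edges[i + 1]),
                    lon_min=float(lon_edges[j]),
                    lon_max=float(lon_edges[j + 1]),
                )
            )
            k += 1
    return districts


def _make_institutions(
    districts: Sequence[District], policy: GovernmentPolicy, rng: np.random.Generator
) -> List[Institution]:
    institutions: List[Institution] = []
    next_id = 1

    def _add(name: str, itype: str, lat: float, lon: float) -> None:
        nonlocal next_id
        institutions.append(
            Institution(
                id=next_id,
                name=name,
                type=itype,
                level=LEVEL_OF_TYPE[itype],
                location=(_round6(lat), _round6(lon)),
                subsidy_proportion=policy.subsidy_proportion[itype],
            )
        )
        next_id += 1

    # one community health centre at each district centre
    for d in districts:
        _add(
            f"community_center_{d.id:02d}",
            "community_center",
            (d.lat_min + d.lat_max) / 2,
            (d.lon_min + d.lon_max) / 2,
        )
    # district hospitals in 10 of the 16 districts, jittered off-centre
    for d in districts[:10]:
        _add(
            f"district_hospital_{d.id:02d}",
            "district_hospital",
            rng.uniform(d.lat_min, d.lat_max),
            rng.uniform(d.lon_min, d.lon_max),
        )
    # tertiary comprehensive and specialized hospitals clustered centrally
    lat_c = sum(_LAT_RANGE) / 2
    lon_c = sum(_LON_RANGE) / 2
    for k in range(8):
        _add(
            f"tertiary_comprehensive_{k + 1:02d}",
            "tertiary_comprehensive",
            rng.uniform(lat_c - 0.35, lat_c + 0.35),
            rng.uniform(lon_c - 0.35, lon_c + 0.35),
        )
    for k in range(4):
        _add(
            f"specialized_{k + 1:02d}",
            "specialized",
            rng.uniform(lat_c - 0.4, lat_c + 0.4),
            rng.uniform(lon_c - 0.4, lon_c + 0.4),
        )
    return institutions


def _make_preferences() -> PreferenceTable:
    # Baseline weights per severity; deterministic age/income modifiers.
    base = {
        "minor": {
            "tertiary_comprehensive": 0.25,
            "specialized": 0.06,
            "district_hospital": 0.34,
            "community_center": 0.35,
        },
        "common": {
            "tertiary_comprehensive": 0.36,
            "specialized": 0.05,
            "district_hospital": 0.44,
            "community_center": 0.15,
        },
        "severe": {
            "tertiary_comprehensive": 0.50,
            "specialized": 0.06,
            "district_hospital": 0.44,
            "community_center": 0.0,
        },
    }
    age_mod = {"0-14": 0.0, "15-34": -0.02, "35-59": 0.0, "60+": 0.05}  # added to community
    income_mod = {"low": -0.03, "middle": 0.0, "high": 0.06}  # added to tertiary comprehensive
    table: Dict[str, Dict[str, Dict[str, Dict[str, float]]]] = {}
    for severity, weights in base.items():
        table[severity] = {}
        for age in AGE_BANDS:
            table[severity][age] = {}
            for income in INCOME_BANDS:
                w = dict(weights)
                if severity != "severe":
                    w["community_center"] = _round6(max(0.0, w["community_center"] + age_mod[age]))
                w["tertiary_comprehensive"] = _round6(
                    max(0.0, w["tertiary_comprehensive"] + income_mod[income])
                )
                table[severity][age][income] = w
    return PreferenceTable(table=table)


def generate_fixture(
    seed: int,
    population_size: int = 10_000,
    years: int = 3,
    cycles_per_year: int = 26,
) -> SimulationConfig:
    """Generate a complete, schema-valid synthetic configuration from a seed.

    Identical seeds produce field-for-field identical configurations.  All
    quantitative content is a synthetic stand-in for the unavailable calibrated
    parameter table; structural constraints (expense-tier ordering, copay
    schedule, severity gating, 16 districts, 30 diseases) are guaranteed by
    construction.
    """
    if population_size <= 0:
        raise ValueError(f"population_size={population_size} must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))

    diseases = [
        _make_disease(i + 1, name, severity, specialized, rng)
        for i, (name, severity, specialized) in enumerate(_DISEASE_CATALOG)
    ]
    districts = _make_districts(rng)

    policy = GovernmentPolicy(
        subsidy_proportion={
            "tertiary_comprehensive": 0.062,
            "specialized": 0.093,
            "district_hospital": 0.097,
            "community_center": 0.152,
        },
        subsidy_growth={
            "tertiary_comprehensive": 0.005,
            "specialized": 0.005,
            "district_hospital": 0.010,
            "community_center": 0.035,
        },
        promotion_degree=1.0,
    )
    institutions = _make_institutions(districts, policy, rng)

    insurance = [
        InsuranceScheme(
            name="urban_worker",
            population_share=0.50,
            copay_by_level={"primary": 0.30, "secondary": 0.40, "tertiary": 0.50},
        ),
        InsuranceScheme(
            name="urban_rural_resident",
            population_share=0.40,
            copay_by_level={"primary": 0.30, "secondary": 0.45, "tertiary": 0.55},
        ),
        # Uninsured patients bear the full expense at every level.
        InsuranceScheme(
            name="uninsured",
            population_share=0.10,
            copay_by_level={"primary": 1.0, "secondary": 1.0, "tertiary": 1.0},
        ),
    ]

    # Incomes sit on the expected-income regression's scale so that both
    # regimes of the income-expectation comparison are populated (synthetic
    # stand-in values; see docs/methods.md).
    doctor_params = DoctorParams(
        income_by_title={
            "resident": 15_000.0,
            "attending": 19_000.0,
            "associate_chief": 24_000.0,
            "chief": 30_000.0,
        },
        income_growth=0.04,
        weekly_hours_by_title={
            "resident": 52.0,
            "attending": 48.0,
            "associate_chief": 44.0,
            "chief": 40.0,
        },
        hours_change=0.01,
        title_mix={"resident": 0.30, "attending": 0.35, "associate_chief": 0.20, "chief": 0.15},
    )

    demographics = {
        "gender": {"male": 0.49, "female": 0.51},
        "age_band": {"0-14": 0.12, "15-34": 0.30, "35-59": 0.38, "60+": 0.20},
        "occupation": {"employed": 0.55, "student": 0.15, "retired": 0.20, "unemployed": 0.10},
        "marital_status": {"single": 0.25, "married": 0.65, "other": 0.10},
        "education": {"primary": 0.20, "secondary": 0.50, "tertiary": 0.30},
        "income_band": {"low": 0.30, "middle": 0.50, "high": 0.20},
    }

    return SimulationConfig(
        diseases=diseases,
        districts=districts,
        institutions=institutions,
        insurance=insurance,
        policy=policy,
        doctor_params=doctor_params,
        overrx_rule=OverPrescriptionRule(),
        preferences=_make_preferences(),
        demographics=demographics,
        population_size=population_size,
        years=years,
        cycles_per_year=cycles_per_year,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Annual-summary table I/O
# ---------------------------------------------------------------------------

#: Row labels of the annual-summary table, in report order, mapped to
#: (attribute, optional dict key, scale) where scale "pct" renders a fraction
#: as a percentage.
SUMMARY_ROWS: Tuple[Tuple[str, str, str, str], ...] = (
    ("Outpatient total medical expenses (CNY)", "outpatient_total", "", "cny"),
    ("Outpatient medicine expenses (CNY)", "outpatient_medicine", "", "cny"),
    ("Outpatient physical examination expenses (CNY)", "outpatient_exam", "", "cny"),
    ("Ratio of outpatient medicine to total medical expenses (%)", "outpatient_medicine_ratio", "", "pct"),
    ("Ratio of outpatient physical examinations to total medical expenses (%)", "outpatient_exam_ratio", "", "pct"),
    ("Inpatient total medical expenses (CNY)", "inpatient_total", "", "cny"),
    ("Inpatient medicine expenses (CNY)", "inpatient_medicine", "", "cny"),
    ("Inpatient physical examination expenses (CNY)", "inpatient_exam", "", "cny"),
    ("Ratio of inpatient medicine to total medical expenses (%)", "inpatient_medicine_ratio", "", "pct"),
    ("Ratio of inpatient physical examinations to total medical expenses (%)", "inpatient_exam_ratio", "", "pct"),
    ("Subsidy proportion: tertiary comprehensive hospital (%)", "subsidy_proportion", "tertiary_comprehensive", "pct"),
    ("Subsidy proportion: specialized hospital (%)", "subsidy_proportion", "specialized", "pct"),
    ("Subsidy proportion: district hospital (%)", "subsidy_proportion", "district_hospital", "pct"),
    ("Subsidy proportion: community health service center (%)", "subsidy_proportion", "community_center", "pct"),
    ("Patient share: tertiary comprehensive hospital (%)", "patient_share", "tertiary_comprehensive", "pct"),
    ("Patient share: specialized hospital (%)", "patient_share", "specialized", "pct"),
    ("Patient share: district hospital (%)", "patient_share", "district_hospital", "pct"),
    ("Patient share: community health service center (%)", "patient_share", "community_center", "pct"),
    ("Probability of over-prescription (%)", "overprescription_rate", "", "pct"),
)


def summaries_to_frame(summaries: Sequence["AnnualSummary"]) -> pd.DataFrame:
    """Render annual summaries as a metric-by-year table.

    Expenses are reported to 0.1 CNY and ratios/shares to 0.1 percentage point.
    """
    if not summaries:
        raise ValueError("at least one annual summary is required")
    columns = {}
    for s in summaries:
        col = []
        for _, attr, key, scale in SUMMARY_ROWS:
            value = getattr(s, attr)
            if key:
                value = value[key]
            if scale == "pct":
                value = 100.0 * value
            col.append(round(float(value), 1))
        columns[f"year_{s.year}"] = col
    return pd.DataFrame(columns, index=[label for label, *_ in SUMMARY_ROWS])


def write_summary(summaries: Sequence["AnnualSummary"], path) -> None:
    """Write annual summaries as a CSV with one row per metric, one column per year."""
    frame = summaries_to_frame(summaries)
    frame.to_csv(path, index_label="metric")


def read_summary(path) -> pd.DataFrame:
    """Read back a summary table written by :func:`write_summary`."""
    return pd.read_csv(path, index_col="metric")
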