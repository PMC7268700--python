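"""Care-seeking preference, promotion effects and facility assignment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hospexp import (
    AssignmentError,
    Institution,
    PatientAgent,
    PreferenceWeights,
    apply_first_visit_promotion,
    base_preference,
    choose_institution_type,
    generate_patients,
    haversine_km,
    nearest_institution,
    run,
)


def _patient(config, severity="minor", age="35-59", income="middle", specialized=False,
             location=(31.2, 121.4)):
    return PatientAgent(
        id=0,
        disease_id=next(d.id for d in config.diseases if d.severity_class == severity),
        severity=severity,
        specialized_eligible=specialized,
        demographics={
            "gender": "female", "age_band": age, "occupation": "employed",
            "marital_status": "married", "education": "secondary", "income_band": income,
        },
        insurance=config.insurance[0],
        district_id=1,
        location=location,
        cycle_created=0,
    )


class TestBasePreference:
    def test_severe_has_zero_community_weight(self, config):
        w = base_preference(_patient(config, "severe"), config)
        assert w.weights["community_center"] == 0.0

    def test_deterministic(self, config):
        p = _patient(config, "common")
        assert base_preference(p, config) == base_preference(p, config)

    def test_specialized_gated_by_disease(self, config):
        assert base_preference(_patient(config, specialized=False), config).weights["specialized"] == 0.0
        assert base_preference(_patient(config, specialized=True), config).weights["specialized"] > 0.0

    def test_baseline_majority_prefers_district_and_tertiary(self, config):
        """Most first choices go to district + tertiary comprehensive hospitals,
        the qualitative pattern of the observed system."""
        cfg = config.model_copy(deep=True)
        cfg.population_size = 10_000
        rng = np.random.default_rng(11)
        rng_choice = np.random.default_rng(12)
        chosen = []
        for p in generate_patients(cfg, 0, rng):
            w = apply_first_visit_promotion(base_preference(p, cfg), 1.0, p.severity)
            chosen.append(choose_institution_type(w, rng_choice))
        share = sum(1 for c in chosen if c in ("district_hospital", "tertiary_comprehensive"))
        assert share / len(chosen) > 0.5


class TestPromotion:
    def test_identity_at_degree_one(self, config):
        w = base_preference(_patient(config, "minor"), config)
        assert apply_first_visit_promotion(w, 1.0, "minor").normalized() == w.normalized()

    def test_monotone_in_degree(self, config):
        w = base_preference(_patient(config, "minor"), config)
        low = apply_first_visit_promotion(w, 0.5, "minor").normalized()
        assert low["community_center"] < w.normalized()["community_center"]

    def test_severe_unaffected(self, config):
        w = base_preference(_patient(config, "severe"), config)
        assert apply_first_visit_promotion(w, 2.0, "severe").weights == w.weights

    def test_negative_degree_rejected(self, config):
        w = base_preference(_patient(config, "minor"), config)
        with pytest.raises(ValueError):
            apply_first_visit_promotion(w, -0.1, "minor")

    @given(degree=st.floats(0.1, 5.0), comm=st.floats(0.0, 2.0))
    def test_renormalized_weights_sum_to_one(self, degree, comm):
        w = PreferenceWeights(weights={
            "tertiary_comprehensive": 1.0, "specialized": 0.2,
            "district_hospital": 0.8, "community_center": comm,
        })
        norm = apply_first_visit_promotion(w, degree, "common").normalized()
        assert math.isclose(sum(norm.values()), 1.0, abs_tol=1e-12)

    def test_promotion_monotonicity_under_common_random_numbers(self, config):
        """Raising the promotion degree never shrinks the community share of
        minor/common patients nor grows the tertiary-comprehensive share."""
        comm_shares, tert_shares = [], []
        for degree in (0.5, 1.0, 1.5, 2.0):
            cfg = config.model_copy(deep=True)
            cfg.policy.promotion_degree = degree
            cfg.years = 1
            summaries = run(cfg, seed=99)
            comm_shares.append(summaries[0].patient_share["community_center"])
            tert_shares.append(summaries[0].patient_share["tertiary_comprehensive"])
        assert comm_shares == sorted(comm_shares)
        assert tert_shares == sorted(tert_shares, reverse=True)


class TestChooseInstitutionType:
    def test_degenerate_weight(self, rng):
        w = PreferenceWeights(weights={"tertiary_comprehensive": 1.0, "specialized": 0.0,
                                       "district_hospital": 0.0, "community_center": 0.0})
        assert all(choose_institution_type(w, rng) == "tertiary_comprehensive" for _ in range(50))

    def test_zero_weight_type_never_chosen(self, rng):
        w = PreferenceWeights(weights={"tertiary_comprehensive": 2.0, "specialized": 1.0,
                                       "district_hospital": 1.0, "community_center": 0.0})
        assert all(choose_institution_type(w, rng) != "community_center" for _ in range(200))

    def test_multinomial_shares(self, rng):
        w = PreferenceWeights(weights={t: 0.25 for t in (
            "tertiary_comprehensive", "specialized", "district_hospital", "community_center")})
        draws = [choose_institution_type(w, rng) for _ in range(100_000)]
        se = math.sqrt(100_000 * 0.25 * 0.75)
        for itype in w.weights:
            assert abs(draws.count(itype) - 25_000) < 3 * se

    def test_all_zero_weights_rejected(self, rng):
        w = PreferenceWeights(weights={"tertiary_comprehensive": 0.0, "specialized": 0.0,
                                       "district_hospital": 0.0, "community_center": 0.0})
        with pytest.raises(ValueError):
            choose_institution_type(w, rng)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            PreferenceWeights(weights={"tertiary_comprehensive": -1.0})


class TestHaversine:
    def test_zero_iff_identical(self):
        assert haversine_km((31.0, 121.0), (31.0, 121.0)) == 0.0
        assert haversine_km((31.0, 121.0), (31.0, 121.001)) > 0.0

    def test_one_degree_longitude_at_31N(self):
        # independent check: spherical law of cosines
        lat = math.radians(31.0)
        expected = 6371.0 * math.acos(
            math.sin(lat) ** 2 + math.cos(lat) ** 2 * math.cos(math.radians(1.0))
        )
        d = haversine_km((31.0, 121.0), (31.0, 122.0))
        assert d == pytest.approx(expected, abs=1e-9)
        assert d == pytest.approx(95.2, abs=0.3)

    @given(
        lat1=st.floats(-89, 89), lon1=st.floats(-179, 179),
        lat2=st.floats(-89, 89), lon2=st.floats(-179, 179),
    )
    def test_symmetry_and_nonnegativity(self, lat1, lon1, lat2, lon2):
        d1 = haversine_km((lat1, lon1), (lat2, lon2))
        d2 = haversine_km((lat2, lon2), (lat1, lon1))
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 >= 0.0

    def test_out_of_range_coordinates(self):
        with pytest.raises(ValueError):
            haversine_km((91.0, 0.0), (0.0, 0.0))


class TestNearestInstitution:
    def _inst(self, id_, lat, lon, itype="district_hospital"):
        levels = {"district_hospital": "secondary", "community_center": "primary"}
        return Institution(id=id_, name=f"i{id_}", type=itype, level=levels[itype],
                           location=(lat, lon), subsidy_proportion=0.1)

    def test_single_candidate(self, config):
        p = _patient(config)
        roster = [self._inst(1, 30.9, 121.2)]
        assert nearest_institution(p, roster, "district_hospital").id == 1

    def test_colocated_wins(self, config):
        p = _patient(config, location=(31.2, 121.4))
        far = self._inst(1, 30.8, 121.0)
        here = self._inst(2, 31.2, 121.4)
        assert nearest_institution(p, [far, here], "district_hospital").id == 2

    def test_tie_broken_by_lowest_id(self, config):
        p = _patient(config, location=(31.0, 121.0))
        a = self._inst(4, 31.0, 121.1)
        b = self._inst(2, 31.0, 120.9)  # equidistant by symmetry
        assert nearest_institution(p, [a, b], "district_hospital").id == 2

    def test_missing_type_raises(self, config):
        p = _patient(config)
        with pytest.raises(AssignmentError):
            nearest_institution(p, [self._inst(1, 31.0, 121.0)], "community_center")
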