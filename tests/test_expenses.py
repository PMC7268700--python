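"""Episode expense arithmetic and annual aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hospexp import (
    CareEvents,
    adherence_factor,
    aggregate_year,
    draw_care_events,
    episode_expense,
    grown_expense,
    run,
)
from hospexp.config import INPATIENT_COMPONENTS, OUTPATIENT_COMPONENTS
from hospexp.population import generate_patients


def _first(config, predicate):
    return next(d for d in config.diseases if predicate(d))


class TestDrawCareEvents:
    def test_no_hospitalization_means_no_surgery(self, config, rng):
        d = config.diseases[0].model_copy(update={"p_hospitalization": 0.0})
        for _ in range(200):
            ev = draw_care_events(d, rng)
            assert not ev.hospitalized and not ev.surgery

    def test_certain_outpatient_only(self, config, rng):
        d = config.diseases[0].model_copy(
            update={"p_outpatient": 1.0, "p_hospitalization": 0.0})
        for _ in range(100):
            ev = draw_care_events(d, rng)
            assert ev.outpatient and not ev.hospitalized

    def test_care_always_sought(self, config, rng):
        d = config.diseases[0].model_copy(
            update={"p_outpatient": 0.0, "p_hospitalization": 0.0})
        for _ in range(100):
            assert draw_care_events(d, rng).outpatient

    def test_conditional_surgery_share(self, config, rng):
        d = config.diseases[0].model_copy(
            update={"p_hospitalization": 1.0, "p_surgery": 0.3})
        n = 10_000
        surg = sum(draw_care_events(d, rng).surgery for _ in range(n))
        assert abs(surg / n - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)


class TestGrownExpense:
    @pytest.mark.parametrize(
        "base, growth, year, expected",
        [(100.0, 0.05, 0, 100.0), (100.0, 0.05, 2, 110.25), (100.0, -0.02, 1, 98.0)],
    )
    def test_compounding(self, base, growth, year, expected):
        assert grown_expense(base, growth, year) == pytest.approx(expected)

    @given(base=st.floats(0, 1e5), growth=st.floats(-0.5, 0.5), year=st.integers(0, 30))
    def test_matches_closed_form(self, base, growth, year):
        assert grown_expense(base, growth, year) == base * (1.0 + growth) ** year

    def test_invalid_growth(self):
        with pytest.raises(ValueError):
            grown_expense(100.0, -1.0, 1)


class TestAdherence:
    def test_default_scheme_levels(self, config):
        worker = next(s for s in config.insurance if s.name == "urban_worker")
        assert adherence_factor(worker, "primary") == pytest.approx(0.70)
        assert adherence_factor(worker, "tertiary") == pytest.approx(0.50)

    def test_uninsured_has_zero_adherence(self, config):
        uninsured = next(s for s in config.insurance if s.name == "uninsured")
        for level in ("primary", "secondary", "tertiary"):
            assert adherence_factor(uninsured, level) == 0.0


class TestEpisodeExpense:
    def _episode(self, config, decision, degree=0.2, scheme_name="urban_worker",
                 events=None, year=0):
        patient = generate_patients(config, 0, np.random.default_rng(1))[0]
        patient.insurance = next(s for s in config.insurance if s.name == scheme_name)
        inst = config.institutions_of_type("district_hospital")[0]
        if events is None:
            events = CareEvents(outpatient=True, hospitalized=False, surgery=False,
                                physical_exam=True)
        return patient, inst, episode_expense(
            patient, inst, decision, degree, events, config, year)

    def test_no_decision_is_pure_base_schedule(self, config):
        patient, inst, rec = self._episode(config, decision=False)
        disease = config.disease(patient.disease_id)
        schedule = disease.base_expenses[inst.type]
        assert rec.extra_components == {}
        for comp, value in rec.base_components.items():
            assert value == pytest.approx(schedule.components[comp])
        assert rec.total == pytest.approx(sum(rec.base_components.values()))

    def test_uninsured_extra_contributes_nothing(self, config):
        _, _, rec = self._episode(config, decision=True, scheme_name="uninsured")
        assert rec.adherence == 0.0
        assert sum(rec.extra_components.values()) == pytest.approx(0.0)

    def test_hand_arithmetic_on_extra(self, config):
        """degree 0.2 on medicine 100 + exam 50 at adherence 0.7 adds 21.0."""
        cfg = config.model_copy(deep=True)
        patient = generate_patients(cfg, 0, np.random.default_rng(1))[0]
        patient.insurance = next(s for s in cfg.insurance if s.name == "urban_worker")
        disease = cfg.disease(patient.disease_id)
        inst = cfg.institutions_of_type("community_center")[0]  # primary: copay 0.30
        sched = disease.base_expenses[inst.type]
        sched.components["outpatient_medicine"] = 100.0
        sched.components["outpatient_exam"] = 50.0
        events = CareEvents(outpatient=True, hospitalized=False, surgery=False,
                            physical_exam=True)
        rec = episode_expense(patient, inst, True, 0.2, events, cfg, 0)
        assert sum(rec.extra_components.values()) == pytest.approx(0.2 * 150.0 * 0.7)
        assert rec.extra_components["outpatient_medicine"] == pytest.approx(0.2 * 100.0 * 0.7)
        assert rec.extra_components["outpatient_exam"] == pytest.approx(0.2 * 50.0 * 0.7)

    def test_components_follow_events(self, config):
        events = CareEvents(outpatient=False, hospitalized=True, surgery=True,
                            physical_exam=False)
        _, _, rec = self._episode(config, decision=False, events=events)
        assert not rec.has_outpatient
        assert "surgery" in rec.base_components
        assert "inpatient_exam" not in rec.base_components

    def test_growth_applied_to_base(self, config):
        _, inst, rec0 = self._episode(config, decision=False, year=0)
        patient, _, rec2 = self._episode(config, decision=False, year=2)
        sched = config.disease(patient.disease_id).base_expenses[inst.type]
        for comp, v in rec2.base_components.items():
            g = sched.annual_growth[comp]
            assert v == pytest.approx(rec0.base_components[comp] * (1 + g) ** 2)


class TestAggregateYear:
    def test_printed_ratio_example(self, config):
        """A single outpatient record with total 304.2 and medicine 176.5 gives a
        medicine ratio of 58.0%."""
        patient = generate_patients(config, 0, np.random.default_rng(1))[0]
        cfg = config.model_copy(deep=True)
        inst = cfg.institutions_of_type("district_hospital")[0]
        sched = cfg.disease(patient.disease_id).base_expenses[inst.type]
        sched.components.update(
            outpatient_base=304.2 - 176.5 - 35.6,
            outpatient_medicine=176.5,
            outpatient_exam=35.6,
        )
        events = CareEvents(outpatient=True, hospitalized=False, surgery=False,
                            physical_exam=True)
        rec = episode_expense(patient, inst, False, 0.0, events, cfg, 0)
        summary = aggregate_year([rec], [False], cfg, 1)
        assert summary.outpatient_total == pytest.approx(304.2)
        assert round(100 * summary.outpatient_medicine_ratio, 1) == 58.0

    def test_single_type_share_is_one(self, config):
        patient = generate_patients(config, 0, np.random.default_rng(1))[0]
        inst = config.institutions_of_type("community_center")[0]
        events = CareEvents(True, False, False, False)
        recs = [episode_expense(patient, inst, False, 0.0, events, config, 0)
                for _ in range(3)]
        summary = aggregate_year(recs, [False] * 3, config, 1)
        assert summary.patient_share["community_center"] == 1.0

    def test_empty_input_rejected(self, config):
        with pytest.raises(ValueError):
            aggregate_year([], [], config, 1)

    def test_conservation_against_brute_force(self, config):
        """Per-capita aggregates times headcounts equal the brute-force sums."""
        cfg = config.model_copy(deep=True)
        cfg.years = 1
        summaries, records = run(cfg, seed=5, return_records=True)
        s = summaries[0]
        recs = records[1]
        out_sum = sum(r.component_sum(OUTPATIENT_COMPONENTS) for r in recs if r.has_outpatient)
        in_sum = sum(r.component_sum(INPATIENT_COMPONENTS) for r in recs if r.has_inpatient)
        assert s.outpatient_total * s.n_outpatient == pytest.approx(out_sum, rel=1e-9)
        assert s.inpatient_total * s.n_inpatient == pytest.approx(in_sum, rel=1e-9)
        total = sum(r.total for r in recs)
        assert out_sum + in_sum == pytest.approx(total, rel=1e-9)

    def test_ratio_bounds(self, config):
        cfg = config.model_copy(deep=True)
        cfg.years = 2
        for s in run(cfg, seed=6):
            for r in (s.outpatient_medicine_ratio, s.outpatient_exam_ratio,
                      s.inpatient_medicine_ratio, s.inpatient_exam_ratio):
                assert 0.0 <= r <= 1.0
            assert abs(sum(s.patient_share.values()) - 1.0) < 1e-9


class TestStructuralInvariants:
    def test_zero_overprescription_isolates_base_schedule(self, config):
        """With over-prescription off, summaries are unaffected by doctor incomes
        and subsidy levels — all variation comes from the expense schedules."""
        base = config.model_copy(deep=True)
        base.years = 1
        base.overrx_rule.p_expectation_met = 0.0
        base.overrx_rule.p_expectation_unmet = 0.0

        altered = base.model_copy(deep=True)
        altered.doctor_params.income_by_title = {
            t: v * 10 for t, v in altered.doctor_params.income_by_title.items()}
        altered.policy.subsidy_proportion = {
            t: v * 1.5 for t, v in altered.policy.subsidy_proportion.items()}

        s1 = run(base, seed=8)[0]
        s2 = run(altered, seed=8)[0]
        for attr in ("outpatient_total", "outpatient_medicine", "outpatient_exam",
                     "inpatient_total", "inpatient_medicine", "inpatient_exam"):
            assert getattr(s1, attr) == getattr(s2, attr)

    def test_year_over_year_growth_tracks_schedule(self, config):
        """With one shared growth rate and deterministic events, per-capita
        outpatient expenses grow by that rate within Monte-Carlo error."""
        cfg = config.model_copy(deep=True)
        cfg.years = 2
        cfg.overrx_rule.p_expectation_met = 0.0
        cfg.overrx_rule.p_expectation_unmet = 0.0
        g = 0.05
        for d in cfg.diseases:
            d.p_outpatient = 1.0
            d.p_hospitalization = 0.0
            d.p_physical_exam = 1.0
            for sched in d.base_expenses.values():
                sched.annual_growth = {c: g for c in sched.annual_growth}
        s1, s2 = run(cfg, seed=9)
        observed = s2.outpatient_total / s1.outpatient_total - 1.0
        assert observed == pytest.approx(g, abs=0.02)
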