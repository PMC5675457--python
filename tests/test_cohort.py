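"""Synthetic virtual-patient generator: statistics, rules, dynamics."""

import numpy as np
import pytest

from glucoge import (DynamicsState, ScenarioConfig, VirtualPatientParams,
                     carb_counting_error, glucose_dynamics_step,
                     hypotreatment_rule, sample_meals, simulate_cohort,
                     simulate_patient)


class TestSampleMeals:
    def test_zero_cv_gives_exact_means(self, rng):
        cfg = ScenarioConfig(meal_cv=0.0)
        meals = sample_meals(0, cfg, rng)
        assert [m.grams for m in meals] == [50.0, 60.0, 63.5]

    def test_meal_statistics_match_scenario(self):
        rng = np.random.default_rng(17)
        cfg = ScenarioConfig()
        by_slot = [[], [], []]
        for day in range(500):
            for slot, meal in enumerate(sample_meals(day, cfg, rng)):
                by_slot[slot].append(meal.grams)
        for slot, mean in enumerate(cfg.meal_means_g):
            draws = np.array(by_slot[slot])
            se = mean * cfg.meal_cv / np.sqrt(len(draws))
            assert abs(draws.mean() - mean) < 2 * se
            assert draws.std(ddof=1) / draws.mean() == pytest.approx(0.20, abs=0.02)

    def test_floor_and_jitter(self):
        rng = np.random.default_rng(3)
        cfg = ScenarioConfig()
        for day in range(50):
            for slot, meal in enumerate(sample_meals(day, cfg, rng)):
                assert meal.grams >= cfg.meal_floor_g
                nominal = day * 1440 + cfg.meal_times_min[slot]
                assert abs(meal.time - nominal) <= cfg.meal_jitter_min


class TestCarbCounting:
    def test_zero_cv_returns_truth(self, rng):
        cfg = ScenarioConfig(carb_error_cv=0.0)
        assert carb_counting_error(55.0, cfg, rng) == 55.0

    def test_unbiased_with_20_percent_cv(self):
        rng = np.random.default_rng(5)
        cfg = ScenarioConfig()
        draws = np.array([carb_counting_error(50.0, cfg, rng)
                          for _ in range(10000)])
        assert draws.mean() == pytest.approx(50.0, abs=3 * 10.0 / 100)
        assert draws.std(ddof=1) / 50.0 == pytest.approx(0.20, abs=0.01)

    def test_rejects_nonpositive_mass(self, rng):
        with pytest.raises(ValueError):
            carb_counting_error(0.0, ScenarioConfig(), rng)


class TestDynamics:
    def test_steady_basal_holds_bg_constant(self):
        p = VirtualPatientParams(circadian_amplitude=1e-9)
        u = p.steady_basal(0.0)
        state = DynamicsState(bg=p.basal_target_mgdl, x1=u, x2=u,
                              sensor_bg=p.basal_target_mgdl)
        for _ in range(1440):
            state = glucose_dynamics_step(state, 0.0, u, 1.0, 1.0, p)
        assert abs(state.bg - p.basal_target_mgdl) < 1.0

    def test_meal_without_bolus_raises_bg(self):
        from glucoge.cohort import _ra_at
        from glucoge import MealEvent

        p = VirtualPatientParams()
        u = p.steady_basal(0.0)
        state = DynamicsState(bg=120.0, x1=u, x2=u, sensor_bg=120.0)
        meal = [MealEvent(0.0, 50.0)]
        trace = []
        for t in range(60):
            state = glucose_dynamics_step(state, _ra_at(meal, float(t),
                                                        p.absorption), u, 1.0, 1.0, p)
            trace.append(state.bg)
        assert all(b > a for a, b in zip(trace[1:], trace[2:]))
        assert trace[-1] > 130.0

    def test_bolus_without_meal_lowers_bg(self):
        p = VirtualPatientParams()
        u = p.steady_basal(0.0)
        state = DynamicsState(bg=120.0, x1=u, x2=u, sensor_bg=120.0)
        trace = []
        for t in range(120):
            rate = u + (2.0 if t == 0 else 0.0)  # 2-U impulse at t=0
            state = glucose_dynamics_step(state, 0.0, rate, 1.0, 1.0, p)
            trace.append(state.bg)
        assert all(b < a for a, b in zip(trace[2:], trace[3:]))
        assert trace[-1] < 100.0

    def test_nonfinite_state_raises(self):
        from glucoge import SimulationError

        p = VirtualPatientParams()
        with pytest.raises(SimulationError):
            glucose_dynamics_step(DynamicsState(bg=float("nan")), 0.0, 0.0,
                                  1.0, 1.0, p)


class TestHypotreatmentRule:
    CFG = ScenarioConfig()

    def test_low_smbg_triggers_20g_event(self):
        ev = hypotreatment_rule(55.0, None, 100.0, self.CFG)
        assert ev is not None and ev.grams == 20.0 and ev.time == 100.0

    def test_refractory_period_suppresses(self):
        assert hypotreatment_rule(55.0, 90.0, 100.0, self.CFG) is None
        assert hypotreatment_rule(55.0, 80.0, 100.0, self.CFG) is not None

    def test_above_trigger_no_event(self):
        assert hypotreatment_rule(61.0, None, 100.0, self.CFG) is None
        assert hypotreatment_rule(None, None, 100.0, self.CFG) is None


class TestSimulatePatient:
    def test_seed_determinism(self, scenario):
        p = VirtualPatientParams()
        a = simulate_patient(p, scenario, seed=5)
        b = simulate_patient(p, scenario, seed=5)
        np.testing.assert_array_equal(a.cgm.values, b.cgm.values)
        assert a.cho_events == b.cho_events
        assert a.insulin.boluses == b.insulin.boluses

    def test_fourteen_days_of_cgm(self, patient14):
        assert len(patient14.cgm) == 14 * 288
        assert patient14.cgm.dt == 5.0
        assert np.all(patient14.cgm.values > 0)

    def test_rescue_events_have_fixed_mass_and_spacing(self):
        # an over-aggressive carb ratio elicits hypoglycemia and rescues
        p = VirtualPatientParams()
        from dataclasses import replace
        from glucoge import BolusTherapyParams

        aggressive = replace(p, therapy=BolusTherapyParams(cr=7.0, cf=40.0,
                                                           g_target=110.0))
        ds = simulate_patient(aggressive, ScenarioConfig(), seed=9)
        assert len(ds.hypotreatments) > 0
        assert all(ev.grams == 20.0 for ev in ds.hypotreatments)
        times = [ev.time for ev in ds.hypotreatments]
        assert all(b - a >= 20.0 for a, b in zip(times, times[1:]))

    def test_boluses_only_at_meal_times(self, patient14):
        meal_minutes = {int(np.floor(ev.time)) for ev in patient14.cho_events}
        for t, dose in patient14.insulin.boluses:
            assert int(np.floor(t)) in meal_minutes
            assert dose > 0

    def test_basal_strictly_positive(self, patient14):
        assert np.all(patient14.insulin.basal.values > 0)


class TestSimulateCohort:
    def test_master_seed_determinism(self):
        cfg = ScenarioConfig(days=2)
        a, ma = simulate_cohort(3, cfg, master_seed=4)
        b, mb = simulate_cohort(3, cfg, master_seed=4)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.cgm.values, db.cgm.values)
        assert ma.equals(mb)

    def test_child_reproducible_from_manifest(self):
        cfg = ScenarioConfig(days=2)
        datasets, _ = simulate_cohort(2, cfg, master_seed=6)
        ds = datasets[1]
        redo = simulate_patient(ds.params, cfg, ds.seed)
        np.testing.assert_array_equal(redo.cgm.values, ds.cgm.values)

    def test_interpatient_exceeds_intrapatient_variability(self):
        datasets, _ = simulate_cohort(8, ScenarioConfig(days=6), master_seed=2)
        patient_means, within = [], []
        for ds in datasets:
            daily = ds.true_bg.values.reshape(6, -1).mean(axis=1)
            patient_means.append(daily.mean())
            within.append(daily.var(ddof=1))
        assert np.var(patient_means, ddof=1) > np.mean(within)
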