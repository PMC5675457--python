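"""Synthetic type-1-diabetes virtual-patient cohort generator.

Produces 14-day per-patient records — CGM glucose, carbohydrate events,
basal/bolus insulin, SMBG readings — with the behavioral statistics of a
simulated outpatient scenario: three daily meals (means 50/60/63.5 g, 20%
CV, Gaussian), carbohydrate counting error (zero-mean Gaussian, 20% CV),
standard-therapy boluses, time-varying basal following circadian insulin
sensitivity (20% amplitude), 20-g rescue carbohydrates every 20 min while
SMBG reads below 60 mg/dl, and a lagged, noisy CGM sensor sampled every
5 min.

The glucose dynamics behind the records are a deliberately minimal
surrogate — a single glucose pool with endogenous drift, insulin-dependent
clearance through a remote insulin-action compartment, and meal input via
the two-compartment absorption kernel:

    dBG/dt  = -S_G * (BG - G_endo) - k_I * c(t) * X2 + k_meal * Ra(t)
    dX1/dt  = p2 * (u(t) - X1)
    dX2/dt  = p2 * (X1 - X2)
    c(t)    = 1 + A * sin(2*pi*(t - phi) / 1440)

The two-stage insulin-action chain gives the sigmoidal onset of rapid
insulin analogs (peak effect near 1/p2 = 50 min), and its total effect per
unit is k_I regardless of timing.

This surrogate makes no fidelity claim against any reference simulator; it
exists so every downstream stage (signal preprocessing, evolution, metrics,
pipeline) is testable end to end on data with realistic structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .physiology import (MealEvent, AbsorptionParams, BolusTherapyParams,
                         InsulinDelivery, bolus_dose)
from .signals import UniformSignal

__all__ = [
    "ScenarioConfig",
    "VirtualPatientParams",
    "DynamicsState",
    "PatientDataset",
    "SimulationError",
    "sample_meals",
    "carb_counting_error",
    "glucose_dynamics_step",
    "hypotreatment_rule",
    "simulate_patient",
    "simulate_cohort",
]

MINUTES_PER_DAY = 1440


class SimulationError(RuntimeError):
    """Dynamics produced a non-finite state."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Behavioral scenario: meals, therapy behavior, sensing."""

    days: int = 14
    meal_times_min: tuple[float, ...] = (7 * 60.0, 13 * 60.0, 19 * 60.0)
    meal_means_g: tuple[float, ...] = (50.0, 60.0, 63.5)
    meal_cv: float = 0.20
    meal_floor_g: float = 10.0
    meal_jitter_min: float = 30.0
    carb_error_cv: float = 0.20
    hypo_grams: float = 20.0
    hypo_interval_min: float = 20.0
    hypo_trigger_mgdl: float = 60.0
    hypo_monitor_mgdl: float = 80.0
    smbg_cv: float = 0.05
    cgm_period_min: float = 5.0
    cgm_noise_sd: float = 3.0
    cgm_noise_rho: float = 0.7
    cgm_lag_min: float = 10.0
    cgm_floor_mgdl: float = 39.0

    def __post_init__(self) -> None:
        if len(self.meal_times_min) != len(self.meal_means_g):
            raise ValueError("one mean per meal slot required")
        if any(m <= 0 for m in self.meal_means_g):
            raise ValueError("meal means must be positive")
        if not (0 <= self.meal_cv < 1):
            raise ValueError("meal CV must lie in [0, 1)")
        if self.hypo_trigger_mgdl >= 85.0:
            raise ValueError("rescue trigger must be hypoglycemic")


@dataclass(frozen=True)
class VirtualPatientParams:
    """One virtual patient: surrogate dynamics constants plus therapy settings.

    ``body_scale`` divides both the per-gram and per-unit glucose effects
    (a larger body dilutes both); ``insulin_sens`` scales only the insulin
    effect. ``k_insulin`` is mg/dl lowered per U, ``k_meal`` mg/dl raised
    per g absorbed, ``s_g`` the fractional glucose drift rate per minute
    toward ``g_endo``, and ``p2`` the remote-insulin-action rate.
    """

    body_scale: float = 1.0
    insulin_sens: float = 1.0
    s_g: float = 0.01
    g_endo: float = 180.0
    k_insulin: float = 40.0
    k_meal: float = 5.0
    p2: float = 0.0125  # action peak at 1/p2 = 80 min, after the meal peak
    circadian_amplitude: float = 0.20
    circadian_phase_min: float = 180.0
    therapy: BolusTherapyParams = field(
        default_factory=lambda: BolusTherapyParams(cr=10.0, cf=40.0, g_target=110.0))
    basal_target_mgdl: float = 120.0
    basal_bias: float = 1.0  # patient's mis-setting of the computed basal rate
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)

    def __post_init__(self) -> None:
        if min(self.body_scale, self.insulin_sens, self.s_g, self.p2,
               self.k_insulin, self.k_meal) <= 0:
            raise ValueError("dynamics constants must be positive")
        if not (0 <= self.circadian_amplitude <= 0.5):
            raise ValueError("circadian amplitude must lie in [0, 0.5]")

    @property
    def k_insulin_eff(self) -> float:
        return self.k_insulin * self.insulin_sens / self.body_scale

    @property
    def k_meal_eff(self) -> float:
        return self.k_meal / self.body_scale

    def sensitivity(self, t_min: float) -> float:
        """Circadian insulin-sensitivity multiplier c(t)."""
        return 1.0 + self.circadian_amplitude * math.sin(
            2.0 * math.pi * (t_min - self.circadian_phase_min) / MINUTES_PER_DAY)

    def steady_basal(self, t_min: float) -> float:
        """Basal rate (U/min) the patient programs for time t: the rate that
        would hold BG at ``basal_target_mgdl``, times the setting bias."""
        drift = self.s_g * (self.g_endo - self.basal_target_mgdl)
        return self.basal_bias * drift / (self.k_insulin_eff * self.sensitivity(t_min))

    @classmethod
    def sample(cls, rng: np.random.Generator) -> "VirtualPatientParams":
        """Draw one patient from the declared interpatient distributions."""
        body = float(rng.lognormal(0.0, 0.15))
        sens = float(rng.lognormal(0.0, 0.20))
        # Glycemic set points differ between patients: the basal profile is
        # programmed for an individual target, with a persistent setting
        # bias, which spreads cohort mean glucose the way real cohorts do.
        basal_target = float(rng.uniform(110.0, 150.0))
        base = cls(
            body_scale=body,
            insulin_sens=sens,
            s_g=0.01 * float(rng.lognormal(0.0, 0.10)),
            g_endo=180.0 * (1.0 + float(rng.normal(0.0, 0.05))),
            p2=0.0125 * float(rng.lognormal(0.0, 0.15)),
            circadian_phase_min=float(rng.uniform(0, MINUTES_PER_DAY)),
            basal_target_mgdl=basal_target,
            basal_bias=float(rng.lognormal(0.0, 0.08)),
        )
        # Therapy settings the patient actually uses: the physiologic values
        # with a modest setting error, as real therapy parameters carry.
        cf_true = base.k_insulin_eff
        cr_true = cf_true / base.k_meal_eff
        therapy = BolusTherapyParams(
            cr=max(2.0, cr_true * (1.0 + float(rng.normal(0.0, 0.10)))),
            cf=max(5.0, cf_true * (1.0 + float(rng.normal(0.0, 0.10)))),
            g_target=max(100.0, basal_target - 10.0),
        )
        return replace(base, therapy=therapy)


@dataclass
class DynamicsState:
    """Surrogate state: plasma BG, the two insulin-action stages, and the
    sensor-compartment BG."""

    bg: float = 120.0
    x1: float = 0.0
    x2: float = 0.0
    sensor_bg: float = 120.0


def glucose_dynamics_step(state: DynamicsState, ra_value: float,
                          insulin_rate: float, circadian_factor: float,
                          dt: float, params: VirtualPatientParams,
                          sensor_lag_min: float = 10.0) -> DynamicsState:
    """One explicit Euler step of the surrogate model.

    ``ra_value`` is the meal appearance rate in g/min, ``insulin_rate`` the
    delivery u(t) in U/min. BG is clamped to the physiologic band
    [20, 600] mg/dl; the sensor compartment follows plasma with a
    first-order lag.
    """
    x1 = state.x1 + params.p2 * (insulin_rate - state.x1) * dt
    x2 = state.x2 + params.p2 * (state.x1 - state.x2) * dt
    dbg = (-params.s_g * (state.bg - params.g_endo)
           - params.k_insulin_eff * circadian_factor * state.x2
           + params.k_meal_eff * ra_value)
    bg_raw = state.bg + dbg * dt
    if not (np.isfinite(bg_raw) and np.isfinite(x2)):
        raise SimulationError(f"non-finite state: bg={bg_raw}, x2={x2}")
    bg = min(600.0, max(20.0, bg_raw))
    sensor = state.sensor_bg + (bg - state.sensor_bg) * dt / sensor_lag_min
    return DynamicsState(bg=bg, x1=x1, x2=x2, sensor_bg=sensor)


def sample_meals(day_index: int, config: ScenarioConfig,
                 rng: np.random.Generator) -> list[MealEvent]:
    """Gaussian meal masses (sd = CV * mean, floored) at jittered slot times."""
    meals = []
    for slot_time, mean in zip(config.meal_times_min, config.meal_means_g):
        grams = max(config.meal_floor_g,
                    float(rng.normal(mean, config.meal_cv * mean)))
        jitter = float(rng.uniform(-config.meal_jitter_min, config.meal_jitter_min))
        t = day_index * MINUTES_PER_DAY + slot_time + jitter
        meals.append(MealEvent(time=max(0.0, t), grams=grams))
    return meals


def carb_counting_error(true_grams: float, config: ScenarioConfig,
                        rng: np.random.Generator) -> float:
    """The patient's carbohydrate estimate: truth times (1 + eps), eps ~ N(0, CV)."""
    if true_grams <= 0:
        raise ValueError("true meal mass must be positive")
    return max(0.0, true_grams * (1.0 + float(rng.normal(0.0, config.carb_error_cv))))


def hypotreatment_rule(latest_smbg: float | None, last_treatment_time: float | None,
                       now: float, config: ScenarioConfig) -> MealEvent | None:
    """Emit a rescue-carbohydrate event when SMBG is hypoglycemic.

    A fixed-mass event (20 g by default) is produced iff the latest SMBG
    reading is below the trigger and at least the refractory interval has
    elapsed since the previous rescue.
    """
    if latest_smbg is None or latest_smbg >= config.hypo_trigger_mgdl:
        return None
    if (last_treatment_time is not None
            and now - last_treatment_time < config.hypo_interval_min):
        return None
    return MealEvent(time=now, grams=config.hypo_grams)


@dataclass
class PatientDataset:
    """One virtual patient's 14-day record."""

    cgm: UniformSignal                       # 5-min grid, mg/dl
    cho_events: list[MealEvent]              # meals + rescues, true grams
    hypotreatments: list[MealEvent]          # the rescue subset of cho_events
    insulin: InsulinDelivery                 # basal (1-min) + boluses
    smbg: list[tuple[float, float]]          # (time min, mg/dl)
    true_bg: UniformSignal | None = None     # surrogate internal, validation only
    params: VirtualPatientParams | None = None
    seed: int | None = None

    @property
    def n_days(self) -> int:
        return int(round(len(self.cgm) * self.cgm.dt / MINUTES_PER_DAY))


def _ra_at(events: list[MealEvent], t: float, ap: AbsorptionParams) -> float:
    """Instantaneous appearance rate (g/min) from recent events."""
    cutoff = 12.0 * ap.t_max_g
    total = 0.0
    for ev in events:
        tau = t - ev.time
        if 0.0 <= tau <= cutoff:
            total += (ev.grams * ap.cho_bio * tau
                      * math.exp(-tau / ap.t_max_g) / ap.t_max_g ** 2)
    return total


def simulate_patient(patient: VirtualPatientParams, scenario: ScenarioConfig,
                     seed: int) -> PatientDataset:
    """Closed-behavioral-loop simulation on the 1-min grid.

    Per day: meals are sampled, counted with error, and bolused per the
    patient's therapy settings against a preprandial SMBG reading; basal
    follows the circadian steady-state profile; SMBG is re-checked every
    20 min while true BG is below the monitoring threshold, and rescue
    carbohydrates follow the hypotreatment rule. The CGM trace is the
    lag-filtered plasma signal plus first-order autocorrelated noise,
    sampled every 5 min.
    """
    rng = np.random.default_rng(seed)
    n_min = scenario.days * MINUTES_PER_DAY

    meals: list[MealEvent] = []
    estimates: dict[float, float] = {}
    for day in range(scenario.days):
        for meal in sample_meals(day, scenario, rng):
            meals.append(meal)
            estimates[meal.time] = carb_counting_error(meal.grams, scenario, rng)
    meal_minutes = {int(math.floor(m.time)): m for m in meals}

    basal = np.array([patient.steady_basal(t) for t in range(n_min)])
    boluses: list[tuple[float, float]] = []
    events: list[MealEvent] = list(meals)
    rescues: list[MealEvent] = []
    smbg: list[tuple[float, float]] = []

    u0 = patient.steady_basal(0.0)
    state = DynamicsState(bg=patient.basal_target_mgdl, x1=u0, x2=u0,
                          sensor_bg=patient.basal_target_mgdl)
    true_bg = np.empty(n_min)
    sensor_bg = np.empty(n_min)
    bolus_rate = np.zeros(n_min)

    last_rescue: float | None = None
    last_hypo_check = -scenario.hypo_interval_min

    for k in range(n_min):
        t = float(k)
        # Therapy behavior at this minute.
        if k in meal_minutes:
            reading = state.bg * (1.0 + float(rng.normal(0.0, scenario.smbg_cv)))
            smbg.append((t, reading))
            est = estimates[meal_minutes[k].time]
            dose = bolus_dose(est, patient.therapy, reading)
            if dose > 0:
                boluses.append((t, dose))
                bolus_rate[k] += dose
        if (state.bg < scenario.hypo_monitor_mgdl
                and t - last_hypo_check >= scenario.hypo_interval_min):
            last_hypo_check = t
            reading = state.bg * (1.0 + float(rng.normal(0.0, scenario.smbg_cv)))
            smbg.append((t, reading))
            rescue = hypotreatment_rule(reading, last_rescue, t, scenario)
            if rescue is not None:
                events.append(rescue)
                rescues.append(rescue)
                last_rescue = t

        # Dynamics over [t, t+1).
        ra = _ra_at(events, t, patient.absorption)
        u = basal[k] + bolus_rate[k]
        true_bg[k] = state.bg
        sensor_bg[k] = state.sensor_bg
        try:
            state = glucose_dynamics_step(state, ra, u, patient.sensitivity(t),
                                          1.0, patient,
                                          sensor_lag_min=scenario.cgm_lag_min)
        except SimulationError as exc:
            raise SimulationError(
                f"day {k // MINUTES_PER_DAY} minute {k % MINUTES_PER_DAY}: {exc}"
            ) from exc

    # CGM: 5-min sampling of the lagged signal plus AR(1) noise.
    step = int(scenario.cgm_period_min)
    samples = sensor_bg[::step]
    rho = scenario.cgm_noise_rho
    innovation_sd = scenario.cgm_noise_sd * math.sqrt(max(1e-12, 1.0 - rho ** 2))
    noise = np.empty(samples.size)
    noise[0] = rng.normal(0.0, scenario.cgm_noise_sd)
    shocks = rng.normal(0.0, innovation_sd, size=samples.size)
    for i in range(1, samples.size):
        noise[i] = rho * noise[i - 1] + shocks[i]
    cgm = np.maximum(scenario.cgm_floor_mgdl, samples + noise)

    return PatientDataset(
        cgm=UniformSignal(cgm, t0=0.0, dt=scenario.cgm_period_min),
        cho_events=sorted(events, key=lambda e: e.time),
        hypotreatments=rescues,
        insulin=InsulinDelivery(basal=UniformSignal(basal, t0=0.0, dt=1.0),
                                boluses=boluses),
        smbg=smbg,
        true_bg=UniformSignal(true_bg, t0=0.0, dt=1.0),
        params=patient,
        seed=seed,
    )


def simulate_cohort(n_patients: int, scenario: ScenarioConfig = ScenarioConfig(),
                    master_seed: int = 0
                    ) -> tuple[list[PatientDataset], pd.DataFrame]:
    """Simulate ``n_patients`` with distinct characteristics.

    Patient parameters and per-patient child seeds both derive
    deterministically from ``master_seed``; returns the datasets and a
    manifest (patient id, seed, parameter draws).
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    ss = np.random.SeedSequence(master_seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_patients + 1)[1:]]

    datasets = []
    rows = []
    for pid, seed in enumerate(child_seeds):
        params = VirtualPatientParams.sample(param_rng)
        datasets.append(simulate_patient(params, scenario, seed))
        rows.append({
            "patient_id": pid, "seed": seed,
            "body_scale": params.body_scale, "insulin_sens": params.insulin_sens,
            "s_g": params.s_g, "g_endo": params.g_endo, "p2": params.p2,
            "circadian_phase_min": params.circadian_phase_min,
            "cr": params.therapy.cr, "cf": params.therapy.cf,
        })
    return datasets, pd.DataFrame(rows)
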