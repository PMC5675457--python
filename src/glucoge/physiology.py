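"""Physiological preprocessing: meal absorption, insulin on board, bolus dosing.

Discrete therapy events (meals in grams, insulin doses in units) are turned
into the two continuous signals the predictor consumes:

* ``Ra(t)`` — the rate of appearance of meal glucose in plasma, from a
  two-compartment absorption model with impulse response
  ``CHO_IN * CHO_BIO * tau * exp(-tau/t_max_G) / t_max_G**2``.
  Population parameters: ``t_max_G = 50`` min, ``CHO_BIO = 0.8``.
* ``IOB(t)`` — insulin on board, the insulin delivered but still active,
  from the two-compartment chain
  ``dC1/dt = u - K*C1``, ``dC2/dt = K*(C1 - C2)``, ``IOB = C1 + C2``
  with ``K = 0.039 / min`` (a 2-h duration of insulin action).

Carbohydrate mass is kept in grams throughout, so Ra is on a g/min scale;
``mass_factor`` converts to mg/min (1000) if the conventional unit is wanted.
Downstream, evolved constants absorb any fixed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import UniformSignal

__all__ = [
    "MealEvent",
    "AbsorptionParams",
    "IOBParams",
    "IOBState",
    "InsulinDelivery",
    "BolusTherapyParams",
    "glucose_absorption_signal",
    "iob_signal",
    "bolus_dose",
    "DIA_TO_KDIA",
]

#: Known (duration of insulin action h -> per-minute rate constant) pairs.
#: Only the single published pair is available; other durations require an
#: explicitly supplied rate constant.
DIA_TO_KDIA = {2.0: 0.039}

#: Relative horizon beyond which the absorption kernel is treated as zero;
#: tau * exp(-tau/t_max) / t_max**2 at tau = 12 t_max is ~7e-5 of its peak.
_RA_CUTOFF_TMAX = 12.0


@dataclass(frozen=True)
class MealEvent:
    """A carbohydrate intake: ``time`` minutes since scenario start, ``grams`` of CHO."""

    time: float
    grams: float

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValueError(f"meal mass must be positive, got {self.grams}")
        if self.time < 0:
            raise ValueError(f"meal time must be nonnegative, got {self.time}")


@dataclass(frozen=True)
class AbsorptionParams:
    """Two-compartment glucose absorption parameters.

    ``t_max_g``: time of peak appearance (min). ``cho_bio``: fraction of the
    ingested mass that reaches plasma, in (0, 1].
    """

    t_max_g: float = 50.0
    cho_bio: float = 0.8

    def __post_init__(self) -> None:
        if self.t_max_g <= 0:
            raise ValueError("t_max_g must be positive")
        if not (0 < self.cho_bio <= 1):
            raise ValueError("cho_bio must be in (0, 1]")


@dataclass(frozen=True)
class IOBParams:
    """Insulin-on-board model constants.

    ``k_dia`` is the per-minute rate constant of both compartments;
    ``dia_hours`` is the nominal duration of insulin action it encodes.
    """

    k_dia: float = 0.039
    dia_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.k_dia <= 0:
            raise ValueError("k_dia must be positive")

    @classmethod
    def from_dia(cls, dia_hours: float) -> "IOBParams":
        try:
            return cls(k_dia=DIA_TO_KDIA[dia_hours], dia_hours=dia_hours)
        except KeyError:
            raise ValueError(
                f"no published rate constant for DIA = {dia_hours} h; "
                f"known durations: {sorted(DIA_TO_KDIA)}") from None


@dataclass
class IOBState:
    """Compartment masses of the IOB chain; ``iob`` is their sum."""

    c1: float = 0.0
    c2: float = 0.0

    @property
    def iob(self) -> float:
        return self.c1 + self.c2


@dataclass
class InsulinDelivery:
    """Pump record: continuous basal (U/min on a 1-min grid) plus discrete boluses.

    The combined input is ``u(t) = basal(t) + impulse boluses``; a bolus is
    delivered as its full dose within the single 1-min sample containing its
    timestamp.
    """

    basal: UniformSignal
    boluses: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.basal.dt - 1.0) > 1e-9:
            raise ValueError("basal must be sampled on the 1-min grid")
        if np.any(self.basal.values < 0):
            raise ValueError("basal rates must be nonnegative")
        for t, dose in self.boluses:
            if dose < 0:
                raise ValueError(f"bolus dose at t={t} is negative")

    def rate(self, dt: float = 1.0) -> UniformSignal:
        """Combined delivery rate u(t) in U/min on a ``dt``-min grid.

        Each bolus contributes ``dose/dt`` over one sample so its integral is
        the dose regardless of the grid.
        """
        duration = self.basal.duration
        n = int(round(duration / dt)) + 1
        t = self.basal.t0 + dt * np.arange(n)
        u = np.interp(t, self.basal.times, self.basal.values)
        for tb, dose in self.boluses:
            i = int(np.floor((tb - self.basal.t0) / dt + 1e-9))
            if 0 <= i < n:
                u[i] += dose / dt
        return UniformSignal(u, t0=self.basal.t0, dt=dt)


@dataclass(frozen=True)
class BolusTherapyParams:
    """Patient therapy parameters for the mealtime bolus calculator.

    ``cr``: carbohydrate-to-insulin ratio, g of CHO covered per U.
    ``cf``: correction factor, mg/dl of glucose lowered per U.
    ``g_target``: target glucose, mg/dl.
    """

    cr: float = 10.0
    cf: float = 40.0
    g_target: float = 120.0

    def __post_init__(self) -> None:
        if self.cr <= 0 or self.cf <= 0:
            raise ValueError("cr and cf must be positive")


def glucose_absorption_signal(
    meals: list[MealEvent],
    params: AbsorptionParams = AbsorptionParams(),
    dt: float = 1.0,
    duration: float | None = None,
    mass_factor: float = 1.0,
) -> UniformSignal:
    """Rate of appearance Ra(t) of meal glucose, superposed over meals.

    Each meal contributes
    ``grams * cho_bio * tau * exp(-tau / t_max_g) / t_max_g**2`` for
    ``tau = t - t_meal >= 0`` and zero before ingestion. The kernel is
    truncated at ``tau > 12 * t_max_g`` where it is numerically negligible.

    Units are (g * mass_factor)/min; pass ``mass_factor=1000`` for mg/min.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        last = max((m.time for m in meals), default=0.0)
        duration = last + _RA_CUTOFF_TMAX * params.t_max_g
    if duration <= 0:
        raise ValueError("duration must be positive")
    if meals and duration < max(m.time for m in meals):
        raise ValueError("duration does not cover all meal times")

    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    ra = np.zeros(n)
    cutoff = _RA_CUTOFF_TMAX * params.t_max_g
    for meal in meals:
        tau = t - meal.time
        mask = (tau >= 0) & (tau <= cutoff)
        ra[mask] += (meal.grams * mass_factor * params.cho_bio
                     * tau[mask] * np.exp(-tau[mask] / params.t_max_g)
                     / params.t_max_g ** 2)
    return UniformSignal(ra, t0=0.0, dt=dt)


def iob_signal(
    insulin: InsulinDelivery,
    params: IOBParams = IOBParams(),
    dt: float = 1.0,
    duration: float | None = None,
) -> UniformSignal:
    """Insulin on board from the two-compartment chain, explicit forward Euler.

    ``C1[k+1] = C1[k] + dt*(u[k] - K*C1[k])``,
    ``C2[k+1] = C2[k] + dt*K*(C1[k] - C2[k])``, zero initial state.
    Stable for ``K*dt < 1`` (0.039 at the native 1-min grid).
    """
    u = insulin.rate(dt=dt).values
    if duration is not None:
        n = int(round(duration / dt)) + 1
        if n > u.size:
            u = np.concatenate([u, np.zeros(n - u.size)])
        else:
            u = u[:n]
    return _iob_from_rate(u, params.k_dia, dt, t0=insulin.basal.t0)


def _iob_from_rate(u: np.ndarray, k: float, dt: float, t0: float = 0.0,
                   c1_init: float = 0.0) -> UniformSignal:
    n = u.size
    c1 = np.empty(n)
    c2 = np.empty(n)
    c1[0], c2[0] = c1_init, 0.0
    kdt = k * dt
    for i in range(n - 1):
        c1[i + 1] = c1[i] + dt * u[i] - kdt * c1[i]
        c2[i + 1] = c2[i] + kdt * (c1[i] - c2[i])
    return UniformSignal(c1 + c2, t0=t0, dt=dt)


def iob_impulse_response(dose: float, params: IOBParams, dt: float,
                         duration: float) -> UniformSignal:
    """Discrete IOB response to a single dose at t=0; used to check the
    scheme against the closed form ``dose * exp(-K t) * (1 + K t)``.

    The impulse is the initial condition C1(0) = dose, matching the
    closed form's convention."""
    n = int(round(duration / dt)) + 1
    return _iob_from_rate(np.zeros(n), params.k_dia, dt, c1_init=dose)


def bolus_dose(
    cho_est: float,
    params: BolusTherapyParams,
    g_b: float,
    correction: str = "clinical",
) -> float:
    """Mealtime bolus in U: meal term ``cho_est / cr`` plus a correction.

    ``correction="clinical"`` (default) adds ``(g_b - g_target) / cf`` —
    extra insulin when the preprandial reading ``g_b`` is above target.
    ``correction="as-printed"`` uses the opposite sign,
    ``(g_target - g_b) / cf``, kept available for comparison.
    Negative totals are clamped to zero: a pump cannot withdraw insulin.
    """
    if cho_est < 0:
        raise ValueError("estimated CHO must be nonnegative")
    if correction == "clinical":
        corr = (g_b - params.g_target) / params.cf
    elif correction == "as-printed":
        corr = (params.g_target - g_b) / params.cf
    else:
        raise ValueError(f"unknown correction convention {correction!r}")
    return max(0.0, cho_est / params.cr + corr)
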