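"""Clinically weighted accuracy metrics for glucose forecasts.

The training loss is the glucose-specific mean squared error

    gMSE = mean_t [ Pen(g_t, ghat_t) * (g_t - ghat_t)^2 ]

where ``Pen >= 1`` inflates errors that are clinically dangerous: predicting
too high when the patient is hypoglycemic (a missed low) and predicting too
low when the patient is hyperglycemic (a missed high). Pen is a sum of two
weighted products of smooth transition functions; with the default constants
it is bounded in [1, 3.5] and equals 1 for accurate midrange predictions.

The same penalty weights the g-variants of the standard accuracy metrics
(gRMSE, gMAD, gMARD). Clinical acceptability is summarized with the Clarke
error grid, which classifies each (reference, prediction) pair into zones
A-E using the canonical published boundary inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PenParams",
    "PairedSeries",
    "MetricsReport",
    "CEGCounts",
    "pen",
    "gmse",
    "mse",
    "standard_metrics",
    "ceg_classify",
    "ceg_zones",
    "ceg_summary",
]

CEG_ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class PenParams:
    """Constants of the clinical penalty.

    ``alpha_l``/``alpha_h`` weight the hypo- and hyperglycemic terms;
    ``t_l``/``t_h`` are the glucose thresholds (mg/dl) where each term
    engages, with transition widths ``beta_l``/``beta_h``; ``gamma_l``/
    ``gamma_h`` are the error widths (mg/dl) over which the penalty ramps up.
    """

    alpha_l: float = 1.5
    alpha_h: float = 1.0
    beta_l: float = 30.0
    beta_h: float = 100.0
    gamma_l: float = 10.0
    gamma_h: float = 20.0
    t_l: float = 85.0
    t_h: float = 155.0

    def __post_init__(self) -> None:
        if self.alpha_l < 0 or self.alpha_h < 0:
            raise ValueError("penalty weights must be nonnegative")
        if not self.t_l < self.t_h:
            raise ValueError("need t_l < t_h")
        if min(self.beta_l, self.beta_h, self.gamma_l, self.gamma_h) <= 0:
            raise ValueError("transition widths must be positive")

    @property
    def upper_bound(self) -> float:
        return 1.0 + self.alpha_l + self.alpha_h


@dataclass
class PairedSeries:
    """Aligned reference and predicted glucose series, mg/dl."""

    g: np.ndarray
    g_hat: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.g_hat = np.asarray(self.g_hat, dtype=float)
        if self.g.shape != self.g_hat.shape or self.g.ndim != 1:
            raise ValueError("g and g_hat must be 1-d arrays of equal length")
        if self.g.size < 1:
            raise ValueError("series must be non-empty")
        if np.any(self.g <= 0):
            raise ValueError("reference glucose must be positive")

    @property
    def n(self) -> int:
        return self.g.size

    @property
    def errors(self) -> np.ndarray:
        return self.g - self.g_hat


@dataclass(frozen=True)
class MetricsReport:
    """The six accuracy metrics: plain and penalty-weighted.

    RMSE/gRMSE and MAD/gMAD in mg/dl; MARD/gMARD in percent.
    """

    rmse: float
    g_rmse: float
    mad: float
    g_mad: float
    mard: float
    g_mard: float

    def as_dict(self) -> dict[str, float]:
        return {"RMSE (mg/dl)": self.rmse, "gRMSE (mg/dl)": self.g_rmse,
                "MAD (mg/dl)": self.mad, "gMAD (mg/dl)": self.g_mad,
                "MARD (%)": self.mard, "gMARD (%)": self.g_mard}


@dataclass(frozen=True)
class CEGCounts:
    """Clarke error-grid zone counts and percentages."""

    counts: dict[str, int]
    n: int

    @property
    def percentages(self) -> dict[str, float]:
        return {z: 100.0 * self.counts[z] / self.n for z in CEG_ZONES}

    @property
    def ab_percent(self) -> float:
        """Clinical-acceptability headline: share of pairs in zones A or B."""
        return 100.0 * (self.counts["A"] + self.counts["B"]) / self.n


def _smoothstep(u):
    """C1 ramp: 0 for u<=0, 1 for u>=1, 3u^2 - 2u^3 between."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def pen(g, g_hat, params: PenParams = PenParams()):
    """Clinical penalty factor Pen(g, ghat), vectorized; in [1, 1+aL+aH].

    The hypoglycemic term engages when the reference is low (falling
    transition from 1 at ``t_l`` to 0 at ``t_l + beta_l``) and the forecast
    overshoots (rising over an overprediction of 0..``gamma_l``). The
    hyperglycemic term engages when the reference is high (rising from
    ``t_h`` to ``t_h + beta_h``) and the forecast undershoots (rising over an
    underprediction of 0..``gamma_h``). Both factors vanish at zero error, so
    an exact forecast is never penalized.
    """
    g = np.asarray(g, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if np.any(g <= 0) or np.any(g_hat <= 0):
        raise ValueError("glucose values must be positive")
    err = g_hat - g
    low_g = 1.0 - _smoothstep((g - params.t_l) / params.beta_l)
    over = _smoothstep(err / params.gamma_l)
    high_g = _smoothstep((g - params.t_h) / params.beta_h)
    under = _smoothstep(-err / params.gamma_h)
    return 1.0 + params.alpha_l * low_g * over + params.alpha_h * high_g * under


def mse(series: PairedSeries) -> float:
    return float(np.mean(series.errors ** 2))


def gmse(series: PairedSeries, params: PenParams = PenParams()) -> float:
    """Mean of pointwise-penalized squared errors, mg^2/dl^2."""
    w = pen(series.g, series.g_hat, params)
    return float(np.mean(w * series.errors ** 2))


def standard_metrics(series: PairedSeries,
                     params: PenParams = PenParams()) -> MetricsReport:
    """RMSE, MAD, MARD and their penalty-weighted counterparts."""
    e = np.abs(series.errors)
    w = pen(series.g, series.g_hat, params)
    return MetricsReport(
        rmse=float(np.sqrt(np.mean(e ** 2))),
        g_rmse=float(np.sqrt(np.mean(w * e ** 2))),
        mad=float(np.mean(e)),
        g_mad=float(np.mean(w * e)),
        mard=float(np.mean(e / series.g) * 100.0),
        g_mard=float(np.mean(w * e / series.g) * 100.0),
    )


def ceg_classify(g_ref: float, g_pred: float) -> str:
    """Clarke error-grid zone of one (reference, prediction) pair.

    Values above 400 mg/dl are clamped to the grid edge; non-positive values
    are a domain error. Boundary ties resolve toward the more benign zone
    (a pair exactly 20% off is zone A).
    """
    return str(ceg_zones(np.array([g_ref]), np.array([g_pred]))[0])


def ceg_zones(g_ref: np.ndarray, g_pred: np.ndarray) -> np.ndarray:
    """Vectorized Clarke error-grid classification; returns an array of zone letters."""
    ref = np.asarray(g_ref, dtype=float)
    pred = np.asarray(g_pred, dtype=float)
    if np.any(ref <= 0) or np.any(pred <= 0):
        raise ValueError("glucose values must be positive")
    ref = np.minimum(ref, 400.0)
    pred = np.minimum(pred, 400.0)

    zones = np.full(ref.shape, "B", dtype="<U1")
    a = ((np.abs(pred - ref) <= 0.2 * ref) | ((ref < 70) & (pred < 70)))
    e = (((ref >= 180) & (pred <= 70)) | ((ref <= 70) & (pred >= 180)))
    c = (((ref >= 70) & (pred >= ref + 110))
         | ((ref >= 130) & (ref <= 180) & (pred <= 7.0 / 5.0 * ref - 182)))
    d = (((ref >= 240) & (pred >= 70) & (pred <= 180))
         | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
         | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= 6.0 / 5.0 * ref)))
    zones[d] = "D"
    zones[c] = "C"
    zones[e] = "E"
    zones[a] = "A"
    return zones


def ceg_summary(series: PairedSeries) -> CEGCounts:
    """Zone counts and percentages over a paired series."""
    z = ceg_zones(series.g, series.g_hat)
    counts = {zone: int(np.sum(z == zone)) for zone in CEG_ZONES}
    return CEGCounts(counts=counts, n=series.n)
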