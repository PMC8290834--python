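"""Growth-curve and rate estimation.

Batch growth of a fast-growing Mollicute in semi-defined medium is modeled
as simple exponential growth ``A(t) = A0 * exp(r t)`` with doubling time
``d = ln 2 / r``. Substrate dependence of the endpoint biomass and of the
growth rate follows a rectangular hyperbola ``y = vmax * x / (k + x)``
(Monod form). Specific uptake/secretion rates are computed from linear
regressions of metabolite concentrations within the exponential window as

    qS = dS * r / X(t2)

where ``dS`` (mmol/l) is the concentration change over a 1-h interval,
``r`` (1/h) the fitted growth rate, and ``X(t2)`` (gDW/l) the fitted
biomass at the end of the interval, giving qS in mmol/gDW/h. Biomass is
obtained from colony counts via a fixed per-cell dry mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeSeries",
    "ExpFit",
    "LinearFit",
    "HyperbolaFit",
    "RateEstimate",
    "CELL_DRY_MASS_G",
    "fit_exponential",
    "fit_linear",
    "doubling_time",
    "fit_hyperbola",
    "cfu_to_gdw",
    "specific_rate",
    "rate_windows",
    "select_qsmax",
]

#: Per-cell dry mass in grams: 0.013 gDW/l at 5.95e8 CFU/ml.
CELL_DRY_MASS_G = 0.013 / (5.95e8 * 1000)

#: Default exponential-phase regression window (hours).
EXPONENTIAL_WINDOW = (14.0, 16.0)


@dataclass
class TimeSeries:
    """A measured quantity over time (hours, strictly increasing)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ExpFit:
    """Exponential model A(t) = A0 * exp(r t)."""

    A0: float
    r: float
    rss: float

    def predict(self, t) -> np.ndarray:
        return self.A0 * np.exp(self.r * np.asarray(t, dtype=float))


@dataclass
class LinearFit:
    """Straight line y = slope * t + intercept."""

    slope: float
    intercept: float

    def predict(self, t) -> np.ndarray:
        return self.slope * np.asarray(t, dtype=float) + self.intercept


@dataclass
class HyperbolaFit:
    """Rectangular hyperbola y = vmax * x / (k + x)."""

    vmax: float
    k: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.vmax * x / (self.k + x)


@dataclass
class RateEstimate:
    """Specific rate over a 1-h interval of the exponential phase."""

    qS: float
    interval: tuple[float, float]
    delta_S: float
    x_t2: float


def fit_exponential(ts: TimeSeries) -> ExpFit:
    """Least-squares fit of the log-linearized exponential model.

    Log-linear fitting is exact on noiseless data and has no initializer
    sensitivity, so fits are bit-deterministic. Raises on non-positive
    values (the log is undefined) or fewer than 3 points.
    """
    if ts.times.size < 3:
        raise ValueError("need at least 3 points for an exponential fit")
    if np.any(ts.values <= 0):
        raise ValueError("exponential fit requires strictly positive values")
    r, log_a0 = np.polyfit(ts.times, np.log(ts.values), 1)
    fit = ExpFit(A0=float(np.exp(log_a0)), r=float(r), rss=0.0)
    fit.rss = float(np.sum((fit.predict(ts.times) - ts.values) ** 2))
    return fit


def fit_linear(ts: TimeSeries) -> LinearFit:
    """Ordinary least-squares line, used for concentration regressions."""
    if ts.times.size < 2:
        raise ValueError("need at least 2 points for a linear fit")
    slope, intercept = np.polyfit(ts.times, ts.values, 1)
    return LinearFit(slope=float(slope), intercept=float(intercept))


def doubling_time(r: float) -> float:
    """d = ln 2 / r, in hours. Requires r > 0."""
    if r <= 0:
        raise ValueError(f"doubling time undefined for growth rate {r}")
    return float(np.log(2.0) / r)


def fit_hyperbola(x: Sequence[float], y: Sequence[float]) -> HyperbolaFit:
    """Nonlinear least squares of the rectangular hyperbola.

    Initialization is fixed at ``vmax = max(y), k = median(x)`` so the fit
    is deterministic. Degenerate inputs (all-equal x, all-zero y) raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a hyperbola fit")
    if np.all(x == x[0]):
        raise ValueError("degenerate x values: all equal")
    if np.all(y == 0):
        raise ValueError("degenerate y values: all zero")
    p0 = (float(np.max(y)), float(np.median(x)))
    popt, _ = curve_fit(
        lambda xx, vmax, k: vmax * xx / (k + xx), x, y, p0=p0, maxfev=10000
    )
    vmax, k = (float(v) for v in popt)
    if vmax <= 0 or k <= 0:
        raise ValueError(f"hyperbola fit degenerate: vmax={vmax:.3g}, k={k:.3g}")
    return HyperbolaFit(vmax=vmax, k=k)


def cfu_to_gdw(cfu_per_ml: float, cell_dry_mass: float = CELL_DRY_MASS_G) -> float:
    """Convert CFU/ml to gDW/l via the per-cell dry mass (grams)."""
    if cfu_per_ml < 0:
        raise ValueError("CFU/ml cannot be negative")
    if cell_dry_mass <= 0:
        raise ValueError("cell dry mass must be positive")
    return cfu_per_ml * 1000.0 * cell_dry_mass


def specific_rate(
    biomass_fit: ExpFit,
    conc_fit: LinearFit,
    interval: tuple[float, float],
    exact_integral: bool = False,
) -> RateEstimate:
    """Specific uptake/secretion rate over one interval.

    ``qS = dS * r / X(t2)`` with ``dS`` from the concentration regression
    and ``X(t2)`` the fitted biomass at the interval end. With
    ``exact_integral`` the denominator is the integral form
    ``dX = X(t2) - X(t1)`` instead of ``X(t2) / 1``, which removes the
    end-point approximation. Sign of dS is preserved (negative = the
    concentration fell).
    """
    if biomass_fit.r <= 0:
        raise ValueError("specific rate requires a positive growth rate")
    t1, t2 = interval
    if t2 <= t1:
        raise ValueError("interval must have positive length")
    delta_s = conc_fit.slope * (t2 - t1)
    x_t2 = float(biomass_fit.predict(t2))
    if x_t2 <= 0:
        raise ValueError("biomass at interval end is not positive")
    if exact_integral:
        x_t1 = float(biomass_fit.predict(t1))
        denom = x_t2 - x_t1
        if denom <= 0:
            raise ValueError("biomass change over interval is not positive")
        qs = delta_s * biomass_fit.r / denom
    else:
        qs = delta_s * biomass_fit.r / x_t2
    return RateEstimate(qS=float(qs), interval=(t1, t2), delta_S=float(delta_s), x_t2=x_t2)


def rate_windows(
    start: float = EXPONENTIAL_WINDOW[0],
    end: float = EXPONENTIAL_WINDOW[1],
    width: float = 1.0,
) -> list[tuple[float, float]]:
    """Consecutive intervals of ``width`` hours spanning [start, end]."""
    windows = []
    t = start
    while t + width <= end + 1e-9:
        windows.append((t, t + width))
        t += width
    return windows


def select_qsmax(per_condition_rates: Mapping[float, Sequence[float]]) -> float:
    """Mean interval rate over the two highest initial-substrate conditions.

    The maximum specific rate plateaus with initial substrate, so the two
    richest conditions are averaged.
    """
    if len(per_condition_rates) < 2:
        raise ValueError("need at least two substrate conditions")
    top_two = sorted(per_condition_rates, reverse=True)[:2]
    rates = [r for cond in top_two for r in per_condition_rates[cond]]
    if not rates:
        raise ValueError("no interval rates available in the top conditions")
    return float(np.mean(rates))
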