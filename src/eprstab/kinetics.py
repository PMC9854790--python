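"""Kinetic analysis of adduct-intensity time series.

A heated-oil spin-trapping run yields double-integral intensity vs time.
The sigmoidal rise is summarised by a four-parameter Boltzmann fit,

    I(t) = I1 + (I2 - I1) / (1 + exp((t0 - t)/dt)),

with the induction period defined as the intersection of the tangent at the
inflection point with the initial plateau, IP = t0 - 2*dt.  The area under
the raw curve (AUC, trapezoids over the observed span) is the model-free
stability summary: larger AUC means a less stable oil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .spin_quant import double_integrate
from .spin_sim import Spectrum

__all__ = ["KineticSeries", "BoltzmannFit", "fit_boltzmann", "auc", "series_from_spectra"]

_DT_BOUNDS = (0.1, 500.0)
_CONVERGED_R2 = 0.95


@dataclass(frozen=True)
class KineticSeries:
    """Time (minutes, strictly increasing) vs double-integral intensity."""

    time: np.ndarray
    intensity: np.ndarray
    temperature: float = 90.0  # deg C

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise ValueError("time and intensity must be 1-D and equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class BoltzmannFit:
    I1: float
    I2: float
    t0: float
    dt: float
    converged: bool
    rss: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.I2 < self.I1:
            raise ValueError("I2 must be >= I1")

    @property
    def IP(self) -> float:
        """Induction period: tangent-intercept with the initial plateau."""
        return self.t0 - 2.0 * self.dt

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _boltzmann(np.asarray(t, dtype=float), self.I1, self.I2, self.t0, self.dt)


def _boltzmann(t: np.ndarray, i1: float, i2: float, t0: float, dt: float) -> np.ndarray:
    return i1 + (i2 - i1) / (1.0 + np.exp((t0 - t) / dt))


def fit_boltzmann(series: KineticSeries) -> BoltzmannFit:
    """Bounded least-squares Boltzmann fit with deterministic multi-starts.

    Five starts spread ``t0`` over the observed time range; the lowest-rss
    solution wins.  Degenerate series (no sigmoidal phase, e.g. a straight
    line that drives ``dt`` to its bound, or a rise-then-decay curve that a
    monotone sigmoid cannot follow) yield ``converged=False`` instead of an
    exception.
    """
    t = series.time
    y = series.intensity
    if t.size < 8:
        raise ValueError("at least 8 points are required for a Boltzmann fit")
    y_range = float(y.max() - y.min())
    if y_range <= 0:
        raise ValueError("intensity has zero dynamic range")

    span = float(t[-1] - t[0])
    # I1 is allowed slightly below zero: clipping it at 0 truncates the noise
    # distribution and biases the recovered induction period when the initial
    # plateau is barely observed
    lower = np.array([-y_range, 0.0, t[0] - span, _DT_BOUNDS[0]])
    upper = np.array([np.inf, np.inf, t[-1] + span, _DT_BOUNDS[1]])

    def resid(p: np.ndarray) -> np.ndarray:
        return _boltzmann(t, *p) - y

    best = None
    for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
        p0 = np.array(
            [
                float(y[:3].mean()),
                max(float(y[-3:].mean()), float(y[:3].mean()) + y_range),
                t[0] + frac * span,
                max(span / 10.0, _DT_BOUNDS[0] * 1.5),
            ]
        )
        p0 = np.clip(p0, lower + 1e-12, upper)
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper))
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)

    if best is None:
        raise RuntimeError("all Boltzmann fit starts failed")
    sol, rss = best
    i1, i2, t0, dt = (float(v) for v in sol.x)
    if i2 < i1:
        i1, i2 = i2, i1

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    at_dt_bound = dt >= 0.95 * _DT_BOUNDS[1] or dt <= 1.05 * _DT_BOUNDS[0]
    # no sigmoidal phase if a straight line explains the data as well as the
    # four-parameter sigmoid does
    line_rss = float(np.sum((np.polyval(np.polyfit(t, y, 1), t) - y) ** 2))
    line_like = line_rss <= 1.05 * rss + 1e-12 * tss
    converged = bool(
        sol.success and r2 >= _CONVERGED_R2 and not at_dt_bound and not line_like
    )

    return BoltzmannFit(I1=i1, I2=i2, t0=t0, dt=dt, converged=converged, rss=rss)


def auc(series: KineticSeries) -> float:
    """Trapezoidal area under the raw intensity-time curve (no extrapolation)."""
    if series.time.size < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(series.intensity, series.time))


def series_from_spectra(
    spectra: Sequence[tuple[float, Spectrum]], temperature: float = 90.0
) -> KineticSeries:
    """Double-integrate a timestamped spectrum sequence into a KineticSeries."""
    items = list(spectra)
    if len(items) < 2:
        raise ValueError("at least 2 timestamped spectra are required")
    times = np.array([t for t, _ in items], dtype=float)
    if np.unique(times).size != times.size:
        raise ValueError("duplicate timestamps")
    order = np.argsort(times)
    values = np.array([double_integrate(items[i][1]) for i in order])
    return KineticSeries(times[order], values, temperature=temperature)
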