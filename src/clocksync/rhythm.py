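"""Bioluminescence rhythm analysis: detrend, periodogram, cosinor.

Reporter traces (10-min sampling by default) are detrended by subtracting a
centered 24-h moving average, screened for rhythmicity with a least-squares
(Lomb–Scargle) periodogram over an 18–30 h period range, and summarized by a
single-component cosinor fit

    y(t) = M + A·cos(2π(t − φ)/τ)

with mesor M, amplitude A ≥ 0, acrophase φ ∈ [0, τ) (time of the fitted
peak on the trace's time axis, mod τ) and period τ.  Phase shifts between
conditions are circular differences of acrophases.

The moving-average kernel is trapezoidal (half-weight endpoints) spanning
exactly one window: it annihilates both a cosine at the window period and
any linear trend exactly, and half-window edges are dropped, not padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .errors import ClockSyncError

__all__ = [
    "BioluminescenceTrace",
    "CosinorFit",
    "PeriodogramResult",
    "detrend_moving_average",
    "periodogram",
    "cosinor_fit",
    "phase_shift_between",
    "peak_to_trough",
]

DEFAULT_PERIOD_RANGE = (18.0, 30.0)


@dataclass
class BioluminescenceTrace:
    """Uniformly sampled luminescence record (times in hours)."""

    time_h: np.ndarray
    value: np.ndarray
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, float)
        self.value = np.asarray(self.value, float)
        if self.time_h.shape != self.value.shape:
            raise ClockSyncError("time and value arrays differ in length")
        if len(self.time_h) > 1 and not (np.diff(self.time_h) > 0).all():
            raise ClockSyncError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        d = np.diff(self.time_h)
        if len(d) == 0:
            raise ClockSyncError("trace too short")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ClockSyncError("sampling not uniform (gap detected)")
        return float(d[0])

    def window(self, t0: float, t1: float) -> "BioluminescenceTrace":
        m = (self.time_h >= t0) & (self.time_h <= t1)
        return BioluminescenceTrace(self.time_h[m], self.value[m], self.condition)

    @classmethod
    def from_csv(cls, path: str | Path, condition: str = "") -> "BioluminescenceTrace":
        df = pd.read_csv(path)
        if "time_min" in df.columns:
            t = df["time_min"].to_numpy() / 60.0
        elif "time_h" in df.columns:
            t = df["time_h"].to_numpy()
        else:
            raise ClockSyncError("CSV needs a time_min or time_h column")
        return cls(t, df["luminescence"].to_numpy(), condition)


def detrend_moving_average(trace: BioluminescenceTrace, window_h: float = 24.0
                           ) -> BioluminescenceTrace:
    """Subtract a centered trapezoidal moving average of ``window_h`` hours.

    The record must be uniformly sampled and longer than the window; the
    half-window at each edge is dropped from the output.
    """
    dt = trace.dt
    n = len(trace.value)
    k = int(round(window_h / dt))
    if k < 2:
        raise ClockSyncError("window shorter than two samples")
    if n <= k:
        raise ClockSyncError(
            f"record ({(n - 1) * dt:g} h) not longer than the window ({window_h:g} h)"
        )
    # trapezoidal kernel over k+1 points spanning exactly k*dt
    w = np.ones(k + 1)
    w[0] = w[-1] = 0.5
    w /= k
    trend = np.convolve(trace.value, w, mode="valid")  # length n - k
    half = k // 2
    lo, hi = half, half + len(trend)
    detrended = trace.value[lo:hi] - trend
    return BioluminescenceTrace(
        trace.time_h[lo:hi], detrended, trace.condition,
        {"trend": trend, "window_h": window_h},
    )


@dataclass
class PeriodogramResult:
    periods: np.ndarray
    power: np.ndarray            # normalized least-squares power in [0, 1]
    peak_period: float
    peak_power: float
    fap: float                   # false-alarm probability of the peak
    n_samples: int

    def false_alarm_level(self, fap: float = 0.01) -> float:
        """Power threshold exceeded by chance with probability ``fap``."""
        m = len(self.periods)
        nu = (self.n_samples - 3) / 2
        return 1.0 - (1.0 - (1.0 - fap) ** (1.0 / m)) ** (1.0 / nu)


def periodogram(trace: BioluminescenceTrace,
                period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
                n_grid: int = 512) -> PeriodogramResult:
    """Normalized Lomb–Scargle periodogram over a period grid.

    Power is the fraction of variance explained by the best-fit sinusoid at
    each trial period (0..1).  The false-alarm probability uses the beta
    null distribution of the single-frequency power, Bonferroni-style over
    the grid size — a standard analytic approximation.
    """
    lo, hi = period_range
    if not (0 < lo < hi):
        raise ClockSyncError("empty or invalid period range")
    t, y = trace.time_h, trace.value - trace.value.mean()
    span = t[-1] - t[0]
    if span < 2 * lo:
        raise ClockSyncError("need at least ~2 cycles of data in the period range")
    periods = np.linspace(lo, hi, n_grid)
    freqs = 2 * np.pi / periods
    power = lombscargle(t, y, freqs, normalize=True)
    i = int(np.argmax(power))
    n = len(y)
    nu = (n - 3) / 2
    single = (1.0 - power[i]) ** nu          # P(power > observed) at one frequency
    fap = float(1.0 - (1.0 - single) ** n_grid)
    return PeriodogramResult(periods, power, float(periods[i]), float(power[i]),
                             fap, n)


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase: float     # time of the fitted peak on the trace's time axis, mod period
    period: float
    resid_var: float
    degenerate: bool = False

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (np.asarray(t) - self.acrophase) / self.period
        )


def _cosinor_at(t: np.ndarray, y: np.ndarray, period: float):
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def cosinor_fit(trace: BioluminescenceTrace,
                period: float | None = None,
                period_grid: np.ndarray | None = None) -> CosinorFit:
    """Least-squares cosinor fit at a fixed or grid-searched period.

    With neither ``period`` nor ``period_grid`` given, the period search is
    seeded by the periodogram peak and refined over ±2 h in 0.01-h steps.
    A constant trace returns amplitude 0 with the ``degenerate`` flag.
    """
    t, y = trace.time_h, trace.value
    if np.ptp(y) == 0:
        tau = period if period else 24.0
        return CosinorFit(float(y.mean()), 0.0, 0.0, tau, 0.0, degenerate=True)
    if period is None and period_grid is None:
        pk = periodogram(trace).peak_period
        period_grid = np.arange(max(1.0, pk - 2.0), pk + 2.0 + 1e-9, 0.01)
    if period is not None:
        taus = [float(period)]
    else:
        span = t[-1] - t[0]
        taus = [float(p) for p in period_grid if span >= 1.5 * p] or [float(period_grid[0])]
    best = None
    for tau in taus:
        beta, rss = _cosinor_at(t, y, tau)
        if best is None or rss < best[2]:
            best = (tau, beta, rss)
    tau, (m, b, c), rss = best
    amp = float(np.hypot(b, c))
    phi = float((np.arctan2(c, b) * tau / (2 * np.pi)) % tau)
    dof = max(len(y) - 3, 1)
    return CosinorFit(float(m), amp, phi, tau, rss / dof)


def phase_shift_between(fit_a: CosinorFit, fit_b: CosinorFit,
                        period_tol: float = 1.0) -> float:
    """Circular acrophase difference φ_a − φ_b in (−τ/2, τ/2] (hours).

    Positive means condition *a* peaks later (phase delay of a relative
    to b).  The two fits must agree in period within ``period_tol`` hours.
    """
    if abs(fit_a.period - fit_b.period) > period_tol:
        raise ClockSyncError(
            f"period mismatch: {fit_a.period:.2f} vs {fit_b.period:.2f} h"
        )
    tau = 0.5 * (fit_a.period + fit_b.period)
    d = (fit_a.acrophase - fit_b.acrophase + tau / 2) % tau - tau / 2
    return float(tau / 2 if np.isclose(d, -tau / 2) else d)


def peak_to_trough(trace: BioluminescenceTrace) -> float:
    """Amplitude alternative: max minus min of a (detrended) trace."""
    return float(trace.value.max() - trace.value.min())
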