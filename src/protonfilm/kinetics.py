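"""Post-irradiation darkening kinetics of radiochromic film.

After irradiation the polymer keeps darkening for hours to days. The netOD
time course is modelled as a biexponential approach to saturation,

    netOD(t) = netOD_inf - C1*exp(-t/T1) - C2*exp(-t/T2),

with a fast component (T1, hours scale) and a slow one (T2, tens of hours).
Readout protocols hinge on when darkening has effectively stopped; the
model-independent statistic for that is the differential growth rate,

    DGR(t) = 100 * (d netOD / dt) / netOD(48 h)    [%/h],

reported positive for growth, with the derivative taken numerically on the
(generally non-uniform) scan-time grid. The film is declared plateaued once
the DGR falls below 0.05 %/h.

Biexponential fits are notoriously ill-conditioned, so :class:`DarkeningModel`
uses damped least squares with multi-start over (T1, T2) and canonicalises
T1 <= T2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from ._constants import PLATEAU_THRESHOLD_PCT_PER_H, REFERENCE_TIME_H

__all__ = [
    "biexponential",
    "DarkeningModel",
    "DarkeningResults",
    "GrowthRateSeries",
    "numerical_derivative",
    "differential_growth_rate",
    "series_plateau_time",
]

#: RMSE above which a biexponential fit is flagged as not accepted.
RMSE_ACCEPT = 1e-3

_T1_STARTS = (0.5, 2.0, 8.0)
_T2_STARTS = (12.0, 24.0, 72.0)


def biexponential(t, netod_inf: float, c1: float, t1: float, c2: float, t2: float):
    """netOD(t) = netOD_inf - C1*exp(-t/T1) - C2*exp(-t/T2)."""
    tt = np.asarray(t, dtype=float)
    out = netod_inf - c1 * np.exp(-tt / t1) - c2 * np.exp(-tt / t2)
    return out if out.ndim else float(out)


def _interp_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Value at t: exact sample when present, else linear interpolation."""
    hit = np.isclose(times, t)
    if hit.any():
        return float(values[hit][0])
    if t < times[0] or t > times[-1]:
        raise ValueError(f"time {t} h outside series span [{times[0]}, {times[-1]}] h")
    return float(np.interp(t, times, values))


class DarkeningModel:
    """Biexponential darkening model bound to one channel's netOD time series.

    Parameters
    ----------
    times_h : array
        Scan times in hours post-irradiation, strictly increasing, >= 5
        points including at least one at or beyond 24 h.
    netods : array
        netOD at those times.
    sigmas : array, optional
        netOD uncertainties for inverse-variance weighting.
    """

    def __init__(self, times_h, netods, sigmas=None):
        self.times = np.asarray(times_h, dtype=float)
        self.netods = np.asarray(netods, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.netods.shape:
            raise ValueError("times and netods must be matching 1-D arrays")
        if self.times.size < 5:
            raise ValueError("at least 5 time points required for a biexponential fit")
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if self.times.max() < 24.0:
            raise ValueError("series must include a time point at or beyond 24 h")
        self.sigmas = None
        if sigmas is not None:
            self.sigmas = np.asarray(sigmas, dtype=float)
            if self.sigmas.shape != self.times.shape:
                raise ValueError("sigmas must match times in shape")
            if np.any(self.sigmas <= 0):
                self.sigmas = None

    def _residual(self, params, weighted: bool):
        r = self.netods - biexponential(self.times, *params)
        if weighted and self.sigmas is not None:
            r = r / self.sigmas
        return r

    def fit(self, max_nfev: int = 4000) -> "DarkeningResults":
        """Damped least-squares fit with multi-start over (T1, T2).

        Amplitude starts come from the endpoint deficits: the late plateau
        estimates netOD_inf, the t=0 deficit is split between the two
        components. Parameters are canonicalised to T1 <= T2; fits whose RMSE
        is not below 1e-3 are returned with ``accepted=False``.
        """
        y = self.netods
        inf0 = max(float(y[-1]), 1e-6)
        deficit = max(inf0 - float(y[0]), 0.0)
        weighted = self.sigmas is not None
        best = None
        diagnostics = []
        for t1_0 in _T1_STARTS:
            for t2_0 in _T2_STARTS:
                x0 = [inf0, 0.6 * deficit + 1e-9, t1_0, 0.4 * deficit + 1e-9, t2_0]
                try:
                    sol = least_squares(
                        self._residual,
                        x0=x0,
                        args=(weighted,),
                        bounds=([1e-9, 0.0, 1e-3, 0.0, 1e-3],
                                [np.inf, np.inf, 1e4, np.inf, 1e4]),
                        method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=max_nfev,
                    )
                except Exception as exc:  # keep per-start diagnostics
                    diagnostics.append((t1_0, t2_0, f"error: {exc}"))
                    continue
                sse = float(np.sum(self._residual(sol.x, weighted=False) ** 2))
                diagnostics.append((t1_0, t2_0, f"sse={sse:.3e}"))
                if best is None or sse < best[0]:
                    best = (sse, sol)
        if best is None:
            raise RuntimeError(
                "biexponential fit failed from every start; diagnostics: "
                + "; ".join(f"T1={a} T2={b}: {m}" for a, b, m in diagnostics)
            )
        inf_, c1, t1, c2, t2 = best[1].x
        if t1 > t2:  # canonical ordering
            c1, c2 = c2, c1
            t1, t2 = t2, t1
        rmse = float(np.sqrt(best[0] / y.size))
        return DarkeningResults(
            model=self,
            netod_inf=float(inf_), c1=float(c1), t1_h=float(t1),
            c2=float(c2), t2_h=float(t2),
            rmse=rmse, accepted=rmse < RMSE_ACCEPT,
            start_diagnostics=diagnostics,
        )


@dataclass
class DarkeningResults:
    """Fitted biexponential darkening parameters for one channel."""

    model: DarkeningModel | None
    netod_inf: float
    c1: float
    t1_h: float
    c2: float
    t2_h: float
    rmse: float
    accepted: bool = True
    start_diagnostics: list = field(default_factory=list)

    def predict(self, t):
        """netOD at time t (hours); nondecreasing in t."""
        tt = np.asarray(t, dtype=float)
        if np.any(tt < 0):
            raise ValueError("time must be non-negative")
        return biexponential(t, self.netod_inf, self.c1, self.t1_h, self.c2, self.t2_h)

    def growth_rate(self, t, t_ref: float = REFERENCE_TIME_H):
        """Analytic differential growth rate at t, %/h, positive for growth."""
        tt = np.asarray(t, dtype=float)
        ref = float(self.predict(t_ref))
        if ref <= 0:
            raise ValueError("reference netOD must be positive")
        deriv = (self.c1 / self.t1_h) * np.exp(-tt / self.t1_h) + (
            self.c2 / self.t2_h
        ) * np.exp(-tt / self.t2_h)
        out = 100.0 * deriv / ref
        return out if out.ndim else float(out)

    def plateau_time(
        self, threshold_pct_per_h: float = PLATEAU_THRESHOLD_PCT_PER_H
    ) -> float:
        """First time (hours) at which the growth rate falls below threshold.

        The analytic rate is strictly decreasing, so the crossing is unique;
        it is bracketed geometrically and solved by Brent's method.
        """
        if threshold_pct_per_h <= 0:
            raise ValueError("threshold must be positive")
        if self.c1 == 0 and self.c2 == 0:
            return 0.0
        f = lambda t: self.growth_rate(t) - threshold_pct_per_h
        if f(0.0) <= 0:
            return 0.0
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e7:
                raise ValueError(
                    f"growth rate never falls below {threshold_pct_per_h} %/h "
                    f"(rate at {hi:.0f} h = {self.growth_rate(hi):.3g} %/h)"
                )
        return float(brentq(f, hi / 2.0, hi, xtol=1e-9))

    def fraction_of_final(self, t) -> float:
        """netOD(t) / netOD_inf — the fraction of the saturation value reached."""
        if self.netod_inf <= 0:
            raise ValueError("netod_inf must be positive")
        out = np.asarray(self.predict(t), dtype=float) / self.netod_inf
        return out if out.ndim else float(out)

    def time_correction_factor(self, t_scan: float, t_ref: float = REFERENCE_TIME_H) -> float:
        """Multiplier taking a netOD read at t_scan to its t_ref equivalent."""
        if t_scan < 0:
            raise ValueError("scan time must be non-negative")
        num = float(self.predict(t_ref))
        den = float(self.predict(t_scan))
        if den <= 0:
            raise ValueError("netOD at scan time is non-positive; factor undefined")
        return num / den

    def summary(self) -> str:
        return "\n".join([
            "Biexponential darkening fit: netOD(t) = netOD_inf - C1 e^(-t/T1) - C2 e^(-t/T2)",
            f"  netOD_inf = {self.netod_inf:.4f}",
            f"  C1 = {self.c1:.4f}  T1 = {self.t1_h:.3g} h",
            f"  C2 = {self.c2:.4f}  T2 = {self.t2_h:.3g} h",
            f"  RMSE = {self.rmse:.2e} netOD  ({'accepted' if self.accepted else 'NOT accepted'})",
            f"  plateau (<{PLATEAU_THRESHOLD_PCT_PER_H} %/h) at t = {self.plateau_time():.1f} h",
        ])


@dataclass(frozen=True)
class GrowthRateSeries:
    """Numerical differential growth rate at each sample time, %/h."""

    times_h: np.ndarray
    rates_pct_per_h: np.ndarray
    netod_ref: float  # normalisation netOD at the reference time (48 h)


def numerical_derivative(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Derivative on a non-uniform grid: three-point Lagrange formula at
    interior points, two-point one-sided at the ends. Exact for quadratics
    (interior) and linear data (everywhere)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to differentiate")
    d = np.empty_like(y)
    d[0] = (y[1] - y[0]) / (t[1] - t[0])
    d[-1] = (y[-1] - y[-2]) / (t[-1] - t[-2])
    for i in range(1, t.size - 1):
        h1 = t[i] - t[i - 1]
        h2 = t[i + 1] - t[i]
        d[i] = (
            -h2 / (h1 * (h1 + h2)) * y[i - 1]
            + (h2 - h1) / (h1 * h2) * y[i]
            + h1 / (h2 * (h1 + h2)) * y[i + 1]
        )
    return d


def differential_growth_rate(
    times_h, netods, t_ref: float = REFERENCE_TIME_H
) -> GrowthRateSeries:
    """Model-independent growth rate: numerical d(netOD)/dt normalised to the
    netOD at the reference time (48 h), in %/h, positive for growth.

    The reference netOD is the measured sample at t_ref when present,
    otherwise linear interpolation in time; the series must reach t_ref.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(netods, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and netods must be matching 1-D arrays")
    if not np.all(np.diff(t) > 0) or np.any(t < 0):
        raise ValueError("times must be non-negative and strictly increasing")
    if t.max() < t_ref:
        raise ValueError(f"series must reach the {t_ref} h reference time")
    ref = _interp_at(t, y, t_ref)
    if ref <= 0:
        raise ValueError("reference netOD must be positive")
    rates = 100.0 * numerical_derivative(t, y) / ref
    return GrowthRateSeries(times_h=t, rates_pct_per_h=rates, netod_ref=ref)


def series_plateau_time(
    times_h, netods, threshold_pct_per_h: float = PLATEAU_THRESHOLD_PCT_PER_H,
    t_ref: float = REFERENCE_TIME_H,
) -> float:
    """First sample time from which the numerical growth rate stays below
    threshold. Raises if the rate never settles below it."""
    grs = differential_growth_rate(times_h, netods, t_ref=t_ref)
    below = grs.rates_pct_per_h < threshold_pct_per_h
    # first index i such that all rates from i on are below threshold
    stay = np.flip(np.logical_and.accumulate(np.flip(below)))
    idx = np.argmax(stay)
    if not stay[idx]:
        raise ValueError(
            "growth rate never settles below threshold "
            f"(final rate {grs.rates_pct_per_h[-1]:.3g} %/h)"
        )
    return float(grs.times_h[idx])
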