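"""Rational dose-response calibration of radiochromic film, per colour channel.

The forward dose-response model maps delivered dose D (Gy) to net optical
density:

    netOD(D) = a * D / (1 + b * D**n),        a > 0, b >= 0, n > 0.

At low dose the response is linear with slope ``a``; the ``b*D**n`` term bends
the curve toward saturation. The model has no closed-form inverse, so dose
recovery uses a separately fitted empirical inverse of the same rational
family,

    D(netOD) = a' * netOD / (1 + b' * netOD**n'),      b' <= 0,

fitted densely on the forward curve over the calibrated dose range. The
negative denominator coefficient captures how dose grows faster than
linearly in netOD as the response saturates (for n = 1 the exact inverse is
D = (x/a)/(1 - (b/a)x), i.e. this family with b' = -b/a); an additive
power-law correction D = a'x + b'x^n' cannot track that growth to better
than ~2 % over a 0.25-20 Gy range and is not used. Both fits
are damped least squares with multi-start initialisation: the exponent varies
widely between film lots, and a single start is unreliable.

Calibration is valid only within a film production batch; a
:class:`CalibrationModel` bundles the three channel fits for one batch with
JSON (de)serialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from ._constants import CHANNELS

__all__ = [
    "rational_response",
    "inverse_response",
    "DoseResponseModel",
    "DoseResponseResults",
    "CalibrationModel",
    "goodness",
]

#: RMSE above which a fit on noiseless input is declared failed (netOD units).
RMSE_ACCEPT = 1e-3

#: Number of dense samples used when fitting the empirical inverse.
_INVERSE_GRID_N = 512

_B0_GRID = (0.01, 0.1, 0.5)
_N0_GRID = (0.7, 1.0, 1.5, 2.0)


def rational_response(dose, a: float, b: float, n: float):
    """Forward model netOD = a*D / (1 + b*D**n); exactly 0 at D=0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(invalid="ignore"):
        out = a * d / (1.0 + b * np.power(d, n, where=d > 0, out=np.zeros_like(d)))
    return out if out.ndim else float(out)


def inverse_response(netod, a_inv: float, b_inv: float, n_inv: float):
    """Empirical inverse D = a'*netOD / (1 + b'*netOD**n'); 0 at netOD=0."""
    x = np.asarray(netod, dtype=float)
    with np.errstate(invalid="ignore"):
        out = a_inv * x / (1.0 + b_inv * np.power(x, n_inv, where=x > 0, out=np.zeros_like(x)))
    return out if out.ndim else float(out)


def goodness(y_obs, y_pred) -> tuple[float, float]:
    """(R^2, RMSE) of predictions against observations.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the observation mean;
    RMSE = sqrt(mean squared residual). Requires at least two points.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.size < 2 or y_obs.shape != y_pred.shape:
        raise ValueError("need at least two matched observation/prediction pairs")
    resid = y_obs - y_pred
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return r2, float(np.sqrt(ss_res / y_obs.size))


class DoseResponseModel:
    """Single-channel rational dose-response model bound to calibration data.

    Parameters
    ----------
    doses : array of Gy
        Delivered doses; at least 6 distinct values.
    netods : array
        Measured netOD, same length.
    sigmas : array, optional
        netOD uncertainties; when given, the fit minimises
        sum(((y - f)/sigma)^2) (inverse-variance weighting).
    """

    def __init__(self, doses, netods, sigmas=None):
        self.doses = np.asarray(doses, dtype=float)
        self.netods = np.asarray(netods, dtype=float)
        if self.doses.shape != self.netods.shape or self.doses.ndim != 1:
            raise ValueError("doses and netods must be matching 1-D arrays")
        if np.unique(self.doses).size < 6:
            raise ValueError("at least 6 distinct doses required to identify (a, b, n)")
        if not np.all(np.isfinite(self.netods)):
            raise ValueError("netods must be finite")
        if np.any(self.doses < 0):
            raise ValueError("doses must be non-negative")
        self.sigmas = None
        if sigmas is not None:
            self.sigmas = np.asarray(sigmas, dtype=float)
            if self.sigmas.shape != self.doses.shape:
                raise ValueError("sigmas must match doses in shape")
            if np.any(self.sigmas <= 0):
                # zero-sigma points would blow up the weights; fall back to
                # unweighted, which is exact for noiseless data anyway
                self.sigmas = None

    # -- fitting -----------------------------------------------------------

    def _residual(self, params, weighted: bool):
        a, b, n = params
        r = self.netods - rational_response(self.doses, a, b, n)
        if weighted and self.sigmas is not None:
            r = r / self.sigmas
        return r

    def fit(self, max_nfev: int = 2000, with_inverse: bool = True) -> "DoseResponseResults":
        """Weighted least-squares fit of (a, b, n) with multi-start.

        The linear coefficient starts at the secant slope through the two
        lowest doses; (b, n) start on a small grid. The best final SSE wins,
        ties broken by the smallest exponent.
        """
        order = np.argsort(self.doses)
        d, y = self.doses[order], self.netods[order]
        nz = d > 0
        if nz.sum() >= 2:
            d0, d1 = d[nz][0], d[nz][1]
            y0, y1 = y[nz][0], y[nz][1]
            a0 = (y1 - y0) / (d1 - d0) if d1 > d0 else y0 / d0
            if not np.isfinite(a0) or a0 <= 0:
                a0 = max(y[nz][0] / d[nz][0], 1e-6)
        else:
            a0 = 0.05
        weighted = self.sigmas is not None
        best = None
        for b0 in _B0_GRID:
            for n0 in _N0_GRID:
                try:
                    sol = least_squares(
                        self._residual,
                        x0=[a0, b0, n0],
                        args=(weighted,),
                        bounds=([1e-12, 0.0, 1e-6], [np.inf, np.inf, 10.0]),
                        method="trf",
                        xtol=1e-14,
                        ftol=1e-14,
                        gtol=1e-14,
                        max_nfev=max_nfev,
                    )
                except Exception:
                    continue
                sse = float(np.sum(self._residual(sol.x, weighted=False) ** 2))
                key = (sse, sol.x[2])
                if best is None or key < best[0]:
                    best = (key, sol)
        if best is None:
            raise RuntimeError("dose-response fit failed to converge from any start")
        a, b, n = best[1].x
        r2, rmse = goodness(self.netods, rational_response(self.doses, a, b, n))
        res = DoseResponseResults(
            model=self, a=float(a), b=float(b), n=float(n), r2=r2, rmse=rmse,
            dose_range_gy=(float(self.doses[self.doses > 0].min())
                           if np.any(self.doses > 0) else 0.0,
                           float(self.doses.max())),
        )
        if with_inverse:
            res.fit_inverse()
        return res


@dataclass
class DoseResponseResults:
    """Fitted single-channel calibration: forward, inverse, and diagnostics."""

    model: DoseResponseModel | None
    a: float
    b: float
    n: float
    r2: float
    rmse: float
    dose_range_gy: tuple[float, float]
    a_inv: float | None = None
    b_inv: float | None = None
    n_inv: float | None = None
    roundtrip_max_rel_err: float | None = None
    warnings: list = field(default_factory=list)

    # -- forward -----------------------------------------------------------

    def predict(self, dose):
        """Forward evaluation netOD(D); flags extrapolation beyond the fit range."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValueError("dose must be non-negative")
        if np.any(d > self.dose_range_gy[1]):
            self.warnings.append(f"extrapolating forward model beyond {self.dose_range_gy[1]} Gy")
        return rational_response(dose, self.a, self.b, self.n)

    # -- inverse -----------------------------------------------------------

    def fit_inverse(self, n_grid: int = _INVERSE_GRID_N) -> None:
        """Fit D = a'*netOD/(1 + b'*netOD**n') on a dense forward-model sweep.

        Minimises relative dose residuals so low doses are not sacrificed.
        Starts: a' from the secant through the lowest dose, b' chosen per
        exponent start so the top of the range is matched exactly. Stores the
        worst round-trip relative error |inv(fwd(D)) - D|/D over the sweep as
        a diagnostic; > 2 % is recorded as a warning with the worst dose.
        """
        lo, hi = self.dose_range_gy
        lo = max(lo, 1e-3)
        dense = np.linspace(lo, hi, n_grid)
        x = rational_response(dense, self.a, self.b, self.n)

        def resid(p):
            return (inverse_response(x, *p) - dense) / dense

        best = None
        a0 = dense[0] / x[0]
        for n0 in (0.5, 0.7, 1.0, 1.5, 2.0, 3.0):
            b0 = min((a0 * x[-1] / dense[-1] - 1.0) / x[-1] ** n0, -1e-9)
            sol = least_squares(
                resid,
                x0=[a0, b0, n0],
                bounds=([0.0, -np.inf, 0.05], [np.inf, 0.0, 10.0]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=8000,
            )
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, sol)
        self.a_inv, self.b_inv, self.n_inv = (float(v) for v in best[1].x)
        rel = np.abs(inverse_response(x, self.a_inv, self.b_inv, self.n_inv) - dense) / dense
        self.roundtrip_max_rel_err = float(rel.max())
        if self.roundtrip_max_rel_err > 0.02:
            worst = float(dense[int(np.argmax(rel))])
            self.warnings.append(
                f"inverse round-trip error {100 * self.roundtrip_max_rel_err:.2f}% "
                f"exceeds 2% (worst at {worst:.2f} Gy)"
            )

    def invert(self, netod: float, sigma_netod: float = 0.0) -> tuple[float, float]:
        """Dose (Gy) and first-order dose uncertainty from a netOD measurement.

        sigma_D = |dD/dnetOD| * sigma_netOD along the empirical inverse.
        """
        if self.a_inv is None:
            self.fit_inverse()
        if sigma_netod < 0:
            raise ValueError("sigma_netod must be non-negative")
        if netod < -3 * sigma_netod:
            raise ValueError("netOD below -3 sigma: invalid measurement")
        x = max(netod, 0.0)
        top = rational_response(self.dose_range_gy[1], self.a, self.b, self.n)
        if x > top:
            self.warnings.append(f"netOD {x:.4f} beyond calibrated range (max {top:.4f})")
        xn = x ** self.n_inv if x > 0 else 0.0
        denom = 1.0 + self.b_inv * xn
        if denom <= 0:
            raise ValueError(
                f"netOD {x:.4f} beyond the inverse model's validity (denominator <= 0)"
            )
        dose = inverse_response(x, self.a_inv, self.b_inv, self.n_inv)
        # d/dx [a'x/(1+b'x^n')] = a'(1 + b'(1-n')x^n') / (1+b'x^n')^2
        deriv = self.a_inv * (1.0 + self.b_inv * (1.0 - self.n_inv) * xn) / denom**2
        return float(dose), float(abs(deriv) * sigma_netod)

    def summary(self) -> str:
        lines = [
            "Rational dose-response fit: netOD = a*D/(1 + b*D^n)",
            f"  a = {self.a:.4f}   b = {self.b:.4f}   n = {self.n:.4f}",
            f"  R^2 = {self.r2:.4f}   RMSE = {self.rmse:.2e} netOD",
            f"  dose range: {self.dose_range_gy[0]:.2f}-{self.dose_range_gy[1]:.2f} Gy",
            f"  inverse: D = {self.a_inv:.4f}*netOD/(1 + {self.b_inv:.4f}*netOD^{self.n_inv:.4f})",
            f"  round-trip max rel. error: {100 * (self.roundtrip_max_rel_err or 0):.3f}%",
        ]
        return "\n".join(lines)


@dataclass
class CalibrationModel:
    """Per-batch calibration: one fitted channel model for red, green, blue."""

    film_model: str
    batch: str
    channels: dict[str, DoseResponseResults]
    dose_range_gy: tuple[float, float]

    @classmethod
    def fit(cls, dataset, film_model: str | None = None, batch: str | None = None,
            weighted: bool = False) -> "CalibrationModel":
        """Fit all three channels from a calibration dataset.

        ``dataset`` is anything with a pandas DataFrame attribute/shape
        carrying columns ``dose_gy, channel, netod, sigma`` (a
        ``CalibrationDataset`` from the synthetic generator, or a raw frame).
        """
        df = getattr(dataset, "frame", dataset)
        film_model = film_model or getattr(dataset, "film_model", "unknown")
        batch = batch or getattr(dataset, "batch", "unknown")
        fits: dict[str, DoseResponseResults] = {}
        for ch in CHANNELS:
            sub = df[df["channel"] == ch]
            sig = sub["sigma"].to_numpy() if weighted and "sigma" in sub else None
            m = DoseResponseModel(sub["dose_gy"].to_numpy(), sub["netod"].to_numpy(), sig)
            fits[ch] = m.fit()
        rng = next(iter(fits.values())).dose_range_gy
        return cls(film_model=film_model, batch=batch, channels=fits, dose_range_gy=rng)

    def predict(self, dose) -> dict[str, np.ndarray]:
        return {ch: self.channels[ch].predict(dose) for ch in CHANNELS}

    def summary(self) -> str:
        head = f"Calibration for {self.film_model} batch {self.batch}"
        parts = [head, "=" * len(head)]
        for ch in CHANNELS:
            parts.append(f"[{ch}]")
            parts.append(self.channels[ch].summary())
        return "\n".join(parts)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "film_model": self.film_model,
            "batch": self.batch,
            "dose_range_gy": list(self.dose_range_gy),
            "channels": {
                ch: {
                    "a": r.a, "b": r.b, "n": r.n,
                    "a_inv": r.a_inv, "b_inv": r.b_inv, "n_inv": r.n_inv,
                    "r2": r.r2, "rmse": r.rmse,
                    "roundtrip_max_rel_err": r.roundtrip_max_rel_err,
                }
                for ch, r in self.channels.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        channels = {}
        for ch, p in d["channels"].items():
            channels[ch] = DoseResponseResults(
                model=None, a=p["a"], b=p["b"], n=p["n"], r2=p["r2"], rmse=p["rmse"],
                dose_range_gy=tuple(d["dose_range_gy"]),
                a_inv=p.get("a_inv"), b_inv=p.get("b_inv"), n_inv=p.get("n_inv"),
                roundtrip_max_rel_err=p.get("roundtrip_max_rel_err"),
            )
        return cls(
            film_model=d["film_model"], batch=d["batch"], channels=channels,
            dose_range_gy=tuple(d["dose_range_gy"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
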