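"""Synthetic scanner and beam data with the statistical structure of real
film dosimetry, so every pipeline stage can be exercised end to end.

The generators invert the measurement chain: a calibration truth (rational
dose-response parameters for a known film batch) fixes netOD(D); the scanner
forward model turns that into pre/post transmission frames

    I = I0 * 10**(-netOD(D))

with independent per-pixel, per-channel multiplicative noise; darkening truths
drive biexponential netOD time series; and a parametric Bragg-peak/flat-field
stand-in supplies depth and lateral dose profiles, with film quenching applied
as a depth-ramped multiplicative under-response. Everything is reproducible
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from ._constants import (
    BATCH_PRESETS,
    CALIBRATION_DOSE_GRID_GY,
    CHANNELS,
    DEFAULT_I0_MEAN,
    DEFAULT_NOISE_FRACTIONS,
    KINETICS_TIME_GRID_H,
)
from .calibration import rational_response
from .kinetics import biexponential
from .profiles import DoseProfile
from .scan import ScanFrame, central_roi, netod_triplet

__all__ = [
    "CalibrationTruth",
    "KineticsTruth",
    "BeamTruth",
    "NoiseSpec",
    "CalibrationDataset",
    "TimeSeries",
    "preset_truth",
    "default_kinetics_truth",
    "simulate_scan_pair",
    "simulate_calibration_dataset",
    "simulate_kinetics_series",
    "simulate_depth_profiles",
    "simulate_lateral_profiles",
]


@dataclass(frozen=True)
class CalibrationTruth:
    """Ground-truth rational dose-response parameters for one film batch."""

    film_model: str
    batch: str
    channels: dict  # channel -> (a, b, n)

    def __post_init__(self) -> None:
        for ch, (a, b, n) in self.channels.items():
            if not (a > 0 and b >= 0 and n > 0):
                raise ValueError(f"invalid (a, b, n) for channel {ch}: {(a, b, n)}")

    def netod(self, dose, channel: str):
        a, b, n = self.channels[channel]
        return rational_response(dose, a, b, n)

    def to_dict(self) -> dict:
        return {
            "film_model": self.film_model,
            "batch": self.batch,
            "channels": {ch: list(p) for ch, p in self.channels.items()},
        }


@dataclass(frozen=True)
class KineticsTruth:
    """Ground-truth biexponential darkening parameters per channel.

    Each channel maps to (netod_inf, c1, t1_h, c2, t2_h); the netOD at t=0
    (netod_inf - c1 - c2) must be non-negative.
    """

    channels: dict  # channel -> (netod_inf, c1, t1_h, c2, t2_h)

    def __post_init__(self) -> None:
        for ch, (inf_, c1, t1, c2, t2) in self.channels.items():
            if not (inf_ > 0 and c1 >= 0 and c2 >= 0 and t1 > 0 and t2 > 0):
                raise ValueError(f"invalid kinetics parameters for {ch}")
            if inf_ - c1 - c2 < 0:
                raise ValueError(f"negative netOD at t=0 for channel {ch}")

    def netod(self, t, channel: str):
        return biexponential(t, *self.channels[channel])


@dataclass(frozen=True)
class BeamTruth:
    """Parametric stand-in for a pristine ~150 MeV proton beam and film response.

    The depth-dose is an entrance plateau with a gentle linear rise plus a
    skewed Gaussian peak (separate proximal/distal sigmas); the lateral
    profile is a flat field with error-function penumbrae. Film quenching is
    a multiplicative under-response ramping linearly from zero at
    ``quench_onset_mm`` before the peak to ``quench_max`` at and beyond it —
    a generator knob calibrated to the 13-20 % under-response scale seen at
    clinical doses, not a physics model.
    """

    entrance_plateau: float = 1.0
    peak_depth_mm: float = 157.0
    peak_sigma_mm: float = 4.0
    peak_to_plateau: float = 3.5
    distal_falloff_sigma_mm: float = 2.5
    field_half_width_mm: float = 50.0
    penumbra_sigma_mm: float = 3.0
    quench_max: float = 0.18
    quench_onset_mm: float = 15.0
    plateau_slope_per_mm: float = 0.002

    def __post_init__(self) -> None:
        if self.peak_to_plateau <= 1:
            raise ValueError("peak_to_plateau must exceed 1")
        for name in ("peak_depth_mm", "peak_sigma_mm", "distal_falloff_sigma_mm",
                     "field_half_width_mm", "penumbra_sigma_mm", "quench_onset_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.quench_max < 1:
            raise ValueError("quench_max must lie in [0, 1)")

    # -- parametric curves -------------------------------------------------

    def depth_dose(self, z_mm) -> np.ndarray:
        z = np.asarray(z_mm, dtype=float)
        plateau = self.entrance_plateau * (1.0 + self.plateau_slope_per_mm * z)
        sigma = np.where(z <= self.peak_depth_mm, self.peak_sigma_mm,
                         self.distal_falloff_sigma_mm)
        peak_height = self.entrance_plateau * self.peak_to_plateau - (
            self.entrance_plateau * (1.0 + self.plateau_slope_per_mm * self.peak_depth_mm)
        )
        gauss = peak_height * np.exp(-0.5 * ((z - self.peak_depth_mm) / sigma) ** 2)
        # suppress the plateau term past the distal edge so dose falls to ~0
        distal = 0.5 * (1.0 - erf((z - self.peak_depth_mm - 2.0 * self.distal_falloff_sigma_mm)
                                  / (np.sqrt(2.0) * self.distal_falloff_sigma_mm)))
        return np.maximum(plateau * distal + gauss, 0.0)

    def quench_fraction(self, z_mm) -> np.ndarray:
        z = np.asarray(z_mm, dtype=float)
        ramp = (z - (self.peak_depth_mm - self.quench_onset_mm)) / self.quench_onset_mm
        return self.quench_max * np.clip(ramp, 0.0, 1.0)

    def lateral_dose(self, x_mm) -> np.ndarray:
        x = np.asarray(x_mm, dtype=float)
        w, s = self.field_half_width_mm, self.penumbra_sigma_mm
        return 50.0 * (erf((w - x) / (np.sqrt(2.0) * s)) + erf((w + x) / (np.sqrt(2.0) * s)))


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel multiplicative scanner noise and baseline intensity."""

    fractions: tuple = DEFAULT_NOISE_FRACTIONS
    i0_mean: float = DEFAULT_I0_MEAN
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("need three non-negative noise fractions (red, green, blue)")
        if not 0 < self.i0_mean <= 65535:
            raise ValueError("i0_mean must lie in (0, 65535]")

    @classmethod
    def noiseless(cls, i0_mean: float = DEFAULT_I0_MEAN) -> "NoiseSpec":
        return cls(fractions=(0.0, 0.0, 0.0), i0_mean=i0_mean)


@dataclass
class CalibrationDataset:
    """netOD measurements over a dose grid: long-format DataFrame with columns
    ``dose_gy, replicate, channel, netod, sigma``."""

    frame: pd.DataFrame
    film_model: str = "unknown"
    batch: str = "unknown"

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, film_model="unknown", batch="unknown"):
        return cls(pd.read_csv(path), film_model=film_model, batch=batch)


@dataclass
class TimeSeries:
    """Per-channel netOD time series: times (h) and an (n_times, 3) array."""

    times_h: np.ndarray
    netods: np.ndarray

    def channel(self, name: str) -> np.ndarray:
        return self.netods[:, CHANNELS.index(name)]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "time_h": self.times_h,
            "netod_r": self.netods[:, 0],
            "netod_g": self.netods[:, 1],
            "netod_b": self.netods[:, 2],
        })
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeSeries":
        df = pd.read_csv(path)
        return cls(
            times_h=df["time_h"].to_numpy(),
            netods=df[["netod_r", "netod_g", "netod_b"]].to_numpy(),
        )


def preset_truth(batch_id: str) -> CalibrationTruth:
    """Calibration truth for a supported film batch (B1, B2: EBT4; B4: EBT3)."""
    if batch_id not in BATCH_PRESETS:
        raise KeyError(
            f"unknown batch {batch_id!r}; valid presets: {sorted(BATCH_PRESETS)}"
        )
    p = BATCH_PRESETS[batch_id]
    return CalibrationTruth(
        film_model=p["film_model"],
        batch=batch_id,
        channels={ch: tuple(v[:3]) for ch, v in p["channels"].items()},
    )


def default_kinetics_truth() -> KineticsTruth:
    """Package fixture darkening truth (no published numeric values exist).

    Chosen to reproduce the qualitative behaviour of radiochromic film at
    ~5 Gy: ~80 % of saturation immediately after exposure, ≈95 % within a few
    hours, plateau (<0.05 %/h) within 24-48 h, red > green > blue amplitude.
    """
    return KineticsTruth(channels={
        "red": (0.40, 0.05, 1.0, 0.03, 12.0),
        "green": (0.24, 0.03, 1.0, 0.018, 12.0),
        "blue": (0.09, 0.012, 1.2, 0.007, 14.0),
    })


def _rng(noise: NoiseSpec, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(noise.seed)


def simulate_scan_pair(
    dose_gy: float,
    truth: CalibrationTruth,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] = (32, 32),
    rng: np.random.Generator | None = None,
    dpi: float = 300.0,
) -> tuple[ScanFrame, ScanFrame]:
    """Pre- and post-irradiation scans of one film piece at a given dose.

    The pre frame sits at the unexposed level I0; the post frame is
    attenuated by 10**(-netOD(D)) per channel. Noise is per-pixel
    multiplicative Gaussian, independent between frames and channels. Pixels
    are clipped to [0, 65535]; if more than 1 % of pixels clip, a warning is
    issued and recorded in the frame metadata.
    """
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError("frames must be at least 8x8 pixels")
    noise = noise or NoiseSpec.noiseless()
    gen = _rng(noise, rng)
    h, w = shape
    fracs = np.asarray(noise.fractions)
    netods = np.array([truth.netod(dose_gy, ch) for ch in CHANNELS])
    pre_mean = np.full(3, noise.i0_mean)
    post_mean = noise.i0_mean * 10.0 ** (-netods)
    frames = []
    for means in (pre_mean, post_mean):
        pix = means[None, None, :] * (1.0 + fracs[None, None, :] * gen.standard_normal((h, w, 3)))
        n_clip = int(np.sum((pix < 0) | (pix > 65535)))
        meta = {"dose_gy": dose_gy, "batch": truth.batch}
        if n_clip:
            meta["clipped_pixels"] = n_clip
            if n_clip > 0.01 * pix.size:
                warnings.warn(
                    f"{n_clip} of {pix.size} pixels clipped to [0, 65535]",
                    stacklevel=2,
                )
        frames.append(ScanFrame(np.clip(pix, 0.0, 65535.0), dpi=dpi, metadata=meta))
    return frames[0], frames[1]


def simulate_calibration_dataset(
    truth: CalibrationTruth,
    dose_grid_gy=None,
    replicates: int = 1,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] = (32, 32),
    sigma_form: str = "standard",
    rng: np.random.Generator | None = None,
) -> CalibrationDataset:
    """Full calibration acquisition: scan pairs at every grid dose, netOD via
    the central-ROI pipeline, one row per (dose, replicate, channel).

    The default grid is the standard 18-point ladder 0.25-20 Gy.
    """
    doses = np.asarray(
        CALIBRATION_DOSE_GRID_GY if dose_grid_gy is None else dose_grid_gy, dtype=float
    )
    if doses.size == 0:
        raise ValueError("dose grid must be non-empty")
    if np.any(doses < 0) or (doses.size > 1 and not np.all(np.diff(doses) > 0)):
        raise ValueError("dose grid must be non-negative and strictly increasing")
    noise = noise or NoiseSpec.noiseless()
    gen = _rng(noise, rng)
    rows = []
    for dose in doses:
        for rep in range(replicates):
            pre, post = simulate_scan_pair(dose, truth, noise, shape=shape, rng=gen)
            trip = netod_triplet(pre, post, central_roi(pre), sigma_form=sigma_form)
            for i, ch in enumerate(CHANNELS):
                rows.append({
                    "dose_gy": dose, "replicate": rep, "channel": ch,
                    "netod": trip.netod[i], "sigma": trip.sigma[i],
                })
    return CalibrationDataset(
        frame=pd.DataFrame(rows), film_model=truth.film_model, batch=truth.batch
    )


def simulate_kinetics_series(
    truth: KineticsTruth,
    times_h=None,
    noise_fraction: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Biexponential netOD time course per channel with additive noise.

    Noise is Gaussian with standard deviation ``noise_fraction * netod_inf``
    per channel. The default grid is the standard nine scan times 0-120 h.
    """
    t = np.asarray(KINETICS_TIME_GRID_H if times_h is None else times_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    gen = rng if rng is not None else np.random.default_rng(seed)
    out = np.empty((t.size, 3))
    for i, ch in enumerate(CHANNELS):
        clean = np.asarray(truth.netod(t, ch), dtype=float)
        inf_ = truth.channels[ch][0]
        out[:, i] = clean + noise_fraction * inf_ * gen.standard_normal(t.size)
    return TimeSeries(times_h=t, netods=out)


def simulate_depth_profiles(
    beam: BeamTruth, grid_mm=None
) -> tuple[DoseProfile, DoseProfile, DoseProfile]:
    """Chamber depth-dose, true film dose, and quenched film response.

    Returns (chamber, film_true_dose, film_response): the film receives the
    chamber dose, but its response is suppressed by the quench factor
    1 - q(z) near and beyond the Bragg peak.
    """
    if grid_mm is None:
        grid_mm = np.arange(0.0, beam.peak_depth_mm + 8.0 * beam.distal_falloff_sigma_mm, 1.0)
    z = np.asarray(grid_mm, dtype=float)
    if z.size > 1 and not np.all(np.diff(z) > 0):
        raise ValueError("grid must be strictly increasing")
    dose = beam.depth_dose(z)
    q = beam.quench_fraction(z)
    chamber = DoseProfile(z, dose, geometry="depth", source="chamber")
    film_true = DoseProfile(z, dose.copy(), geometry="depth", source="film-R")
    film_resp = DoseProfile(z, dose * (1.0 - q), geometry="depth", source="film-R")
    return chamber, film_true, film_resp


def simulate_lateral_profiles(
    beam: BeamTruth, grid_mm=None
) -> tuple[DoseProfile, DoseProfile]:
    """Chamber and film lateral profiles of a flat field with erf penumbrae.

    The film matches the chamber (no lateral quenching by default). The grid
    must extend beyond the field half-width so the penumbra is sampled.
    """
    if grid_mm is None:
        half = beam.field_half_width_mm + 8.0 * beam.penumbra_sigma_mm
        grid_mm = np.arange(-half, half + 0.5, 1.0)
    x = np.asarray(grid_mm, dtype=float)
    if x.size > 1 and not np.all(np.diff(x) > 0):
        raise ValueError("grid must be strictly increasing")
    if x.max() <= beam.field_half_width_mm and x.min() >= -beam.field_half_width_mm:
        raise ValueError("grid lies entirely inside the flat top; no penumbra sampled")
    dose = beam.lateral_dose(x)
    chamber = DoseProfile(x, dose, geometry="lateral", source="chamber")
    film = DoseProfile(x, dose.copy(), geometry="lateral", source="film-R")
    return chamber, film
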