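"""Depth and lateral dose-profile comparison between film and ionization chamber.

Radiochromic film under-responds where the proton linear energy transfer is
high — near the Bragg peak and in the distal fall-off — so a film-derived
depth-dose read against a parallel-plate chamber shows a characteristic dose
deficit ("quenching"). This module provides the comparison toolkit: common-grid
resampling, pointwise relative dose difference, central-axis normalization,
penumbra level crossings and the lateral deviation table.

Linear interpolation is used throughout (profiles are sampled at ~1 mm pitch);
splines are deliberately avoided to prevent overshoot at the sharp peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DoseProfile",
    "resample",
    "relative_dose_difference",
    "normalize_central_axis",
    "level_crossings",
    "lateral_deviation_table",
    "peak_under_response",
]

#: Chamber dose below this fraction of the profile maximum is flagged
#: unreliable for relative differences (steep-gradient region).
LOW_DOSE_FRACTION = 0.01


@dataclass
class DoseProfile:
    """Ordered (position, value) samples for film or chamber.

    ``geometry`` is ``'depth'`` (water-equivalent depth along the beam axis)
    or ``'lateral'`` (offset from the central axis); ``source`` labels the
    detector (``'chamber'`` or ``'film-R'``/``'film-G'``/``'film-B'``).
    """

    positions_mm: np.ndarray
    values: np.ndarray
    geometry: str
    source: str
    metadata: dict = field(default_factory=dict)
    check_nonnegative: bool = True

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.ndim != 1 or self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must be 1-D arrays of equal length")
        if self.positions_mm.size >= 2 and not np.all(np.diff(self.positions_mm) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.geometry not in ("depth", "lateral"):
            raise ValueError("geometry must be 'depth' or 'lateral'")
        if not self.source:
            raise ValueError("source label required")
        if self.check_nonnegative and np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    def value_at(self, position_mm: float) -> float:
        """Linearly interpolated value at a position inside the span."""
        p = self.positions_mm
        if position_mm < p[0] or position_mm > p[-1]:
            raise ValueError(f"position {position_mm} mm outside span [{p[0]}, {p[-1]}]")
        return float(np.interp(position_mm, p, self.values))


def resample(profile: DoseProfile, grid_mm: np.ndarray) -> DoseProfile:
    """Linear interpolation onto a new grid; no extrapolation allowed."""
    grid = np.asarray(grid_mm, dtype=float)
    p = profile.positions_mm
    if grid.min() < p[0] or grid.max() > p[-1]:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] mm extends beyond profile span "
            f"[{p[0]}, {p[-1]}] mm"
        )
    return replace(
        profile, positions_mm=grid, values=np.interp(grid, p, profile.values)
    )


def relative_dose_difference(
    film: DoseProfile,
    chamber: DoseProfile,
    low_dose_fraction: float = LOW_DOSE_FRACTION,
) -> np.ma.MaskedArray:
    """Pointwise film-vs-chamber difference, 100*(film/chamber - 1), in %.

    Both profiles must share a grid (use :func:`resample` first). Points where
    the chamber dose is zero or below ``low_dose_fraction`` of its maximum are
    masked: beyond the distal fall-off the gradient makes the ratio meaningless.
    """
    if not np.array_equal(film.positions_mm, chamber.positions_mm):
        raise ValueError("profiles are on different grids; resample first")
    c = chamber.values
    mask = (c <= 0) | (c < low_dose_fraction * c.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = 100.0 * (film.values / np.where(mask, 1.0, c) - 1.0)
    return np.ma.MaskedArray(diff, mask=mask)


def normalize_central_axis(profile: DoseProfile) -> DoseProfile:
    """Scale a lateral profile so the central-axis (position 0) value is 100 %.

    Idempotent; raises if the profile does not span position 0 or the central
    value is non-positive.
    """
    v0 = profile.value_at(0.0)
    if v0 <= 0:
        raise ValueError("central-axis value must be positive to normalize")
    return replace(profile, values=profile.values * (100.0 / v0))


def level_crossings(
    profile: DoseProfile, levels: list[float], side: str = "positive"
) -> dict[float, float]:
    """Outward positions where a normalized profile falls through given levels.

    Searches outward from the field centre (position 0) on the requested side
    of a lateral profile and linearly interpolates the crossing of each level
    (in % of the central-axis value). Levels never crossed map to ``nan``.
    """
    if side == "positive":
        sel = profile.positions_mm >= 0
        pos = profile.positions_mm[sel]
        val = profile.values[sel]
    elif side == "negative":
        sel = profile.positions_mm <= 0
        pos = -profile.positions_mm[sel][::-1]
        val = profile.values[sel][::-1]
    else:
        raise ValueError("side must be 'positive' or 'negative'")
    out: dict[float, float] = {}
    for level in levels:
        x = np.nan
        if val.size and val[0] <= level:
            x = float(pos[0]) if val[0] == level else np.nan
        else:
            for i in range(val.size - 1):
                if val[i] >= level > val[i + 1]:
                    frac = (val[i] - level) / (val[i] - val[i + 1])
                    x = float(pos[i] + frac * (pos[i + 1] - pos[i]))
                    break
        out[level] = x if side == "positive" else -x
    return out


def lateral_deviation_table(
    film: DoseProfile,
    chamber: DoseProfile,
    positions_mm: list[float],
    tol_pct: float = 0.1,
) -> pd.DataFrame:
    """Film-vs-chamber deviations at chosen lateral positions, percentage points.

    Both profiles must already be normalized to 100 % at the central axis
    (checked to ``tol_pct``). Rows are ordered by decreasing chamber level,
    mirroring how penumbra readings are tabulated (≈50 %, ≈20 %, ≈5 %).
    """
    for prof, name in ((film, "film"), (chamber, "chamber")):
        if abs(prof.value_at(0.0) - 100.0) > tol_pct:
            raise ValueError(f"{name} profile not normalized to central axis (100 %)")
    rows = []
    for x in positions_mm:
        c = chamber.value_at(x)
        f = film.value_at(x)
        rows.append(
            {
                "position_mm": x,
                "chamber_pct": c,
                "film_pct": f,
                "deviation_pp": f - c,
                "deviation_rel_pct": 100.0 * (f / c - 1.0) if c > 0 else np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values("chamber_pct", ascending=False)
    return df.reset_index(drop=True)


def peak_under_response(
    film: DoseProfile, chamber: DoseProfile, window_mm: float = 1.0
) -> float:
    """Mean relative dose difference (%) over a window around the chamber maximum.

    Negative values mean the film under-responds (quenching) at the Bragg peak.
    """
    if not np.array_equal(film.positions_mm, chamber.positions_mm):
        raise ValueError("profiles are on different grids; resample first")
    z_peak = chamber.positions_mm[int(np.argmax(chamber.values))]
    sel = np.abs(chamber.positions_mm - z_peak) <= window_mm
    if not sel.any():
        raise ValueError("window contains no grid points")
    diff = relative_dose_difference(film, chamber)
    window_vals = diff[sel]
    if window_vals.mask.all() if np.ma.is_masked(window_vals) else False:
        raise ValueError("all points in window are masked")
    return float(np.ma.mean(window_vals))
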