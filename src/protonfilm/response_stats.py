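"""Film characterization statistics.

Percent-level summaries used to qualify a film batch for clinical work:
energy dependence of the response, day-to-day reproducibility, agreement with
the calibration model under small dose perturbations (sensitivity), dose
resolvability against measurement noise, batch-to-batch variation, and the
per-channel noise-to-signal ratio of a calibration dataset.

Conventions: percent differences between two measured quantities are
symmetric (100*|x - y| / mean(x, y)); the sensitivity deviation divides by
the model prediction instead, since the model is the reference there. All
statistics operate on netOD and are invariant under a common rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._constants import CHANNELS
from .calibration import CalibrationModel

__all__ = [
    "MeasurementGroup",
    "percent_difference",
    "reproducibility",
    "energy_dependence",
    "sensitivity_deviation",
    "resolvable",
    "batch_variation",
    "noise_to_signal",
]

#: Separation multiple used by :func:`resolvable`: two equal-variance
#: measurements are called distinct when their netOD difference exceeds
#: k*sqrt(2)*sigma (k=2 gives ~95 % two-sided separation).
DEFAULT_K = 2.0


@dataclass
class MeasurementGroup:
    """netOD measurements of several films sharing one nominal dose.

    ``netods`` has shape (n_films, 3) in red/green/blue order; ``label``
    identifies the group (an energy, a session day, or a batch).
    """

    label: str
    dose_gy: float
    netods: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.netods = np.atleast_2d(np.asarray(self.netods, dtype=float))
        if self.netods.shape[1] != 3:
            raise ValueError("netods must have 3 columns (red, green, blue)")
        if self.netods.shape[0] < 1:
            raise ValueError("group must contain at least one film")
        if self.sigmas is not None:
            self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
            if self.sigmas.shape != self.netods.shape:
                raise ValueError("sigmas must match netods in shape")

    @property
    def mean(self) -> np.ndarray:
        """Per-channel mean netOD, length 3."""
        return self.netods.mean(axis=0)


def percent_difference(x: float, y: float) -> float:
    """Symmetric percent difference 100*|x - y| / mean(x, y).

    Both inputs must be positive.
    """
    if x <= 0 or y <= 0:
        raise ValueError("percent difference requires positive inputs")
    return 100.0 * abs(x - y) / ((x + y) / 2.0)


def reproducibility(day1: MeasurementGroup, day2: MeasurementGroup) -> np.ndarray:
    """Per-channel symmetric percent difference of two sessions' mean netOD.

    The sessions must share the nominal dose.
    """
    if not np.isclose(day1.dose_gy, day2.dose_gy):
        raise ValueError(
            f"dose mismatch: {day1.dose_gy} Gy vs {day2.dose_gy} Gy"
        )
    m1, m2 = day1.mean, day2.mean
    return np.array([percent_difference(m1[i], m2[i]) for i in range(3)])


def energy_dependence(groups: list[MeasurementGroup]) -> np.ndarray:
    """Max per-channel percent deviation of any group mean from the grand mean.

    The groups (one per beam energy) must share the nominal dose; returns
    100 * max_g |mean_g - grand| / grand per channel, length 3.
    """
    if len(groups) < 2:
        raise ValueError("at least two energy groups required")
    doses = {round(g.dose_gy, 6) for g in groups}
    if len(doses) != 1:
        raise ValueError(f"groups are at different doses: {sorted(doses)}")
    means = np.stack([g.mean for g in groups])  # (n_groups, 3)
    grand = means.mean(axis=0)
    if np.any(grand <= 0):
        raise ValueError("grand mean netOD must be positive in every channel")
    return 100.0 * np.max(np.abs(means - grand), axis=0) / grand


def sensitivity_deviation(
    measured: np.ndarray, model: CalibrationModel, delivered_gy: float
) -> np.ndarray:
    """Per-channel percent deviation of measured netOD from the model prediction.

    100*(measured - predicted)/predicted, signed; ``measured`` is a length-3
    netOD triplet in channel order. The delivered dose must be positive and
    inside the fitted range.
    """
    measured = np.asarray(measured, dtype=float).reshape(3)
    if delivered_gy <= 0:
        raise ValueError("delivered dose must be positive (prediction is zero at 0 Gy)")
    lo, hi = model.dose_range_gy
    if delivered_gy > hi:
        raise ValueError(f"delivered dose {delivered_gy} Gy beyond fitted range (max {hi})")
    pred = np.array([float(model.channels[ch].predict(delivered_gy)) for ch in CHANNELS])
    return 100.0 * (measured - pred) / pred


def resolvable(
    dose_a_gy: float,
    dose_b_gy: float,
    model: CalibrationModel,
    sigma_netod: float | np.ndarray,
    k: float = DEFAULT_K,
) -> np.ndarray:
    """Whether two doses are distinguishable against netOD noise, per channel.

    True where |netOD(A) - netOD(B)| > k*sqrt(2)*sigma: the factor sqrt(2)
    accounts for both measurements carrying noise sigma, and k sets the
    confidence (k=2 ~ 95 %).
    """
    sigma = np.broadcast_to(np.asarray(sigma_netod, dtype=float), (3,))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    na = np.array([float(model.channels[ch].predict(dose_a_gy)) for ch in CHANNELS])
    nb = np.array([float(model.channels[ch].predict(dose_b_gy)) for ch in CHANNELS])
    return np.abs(na - nb) > k * np.sqrt(2.0) * sigma


def batch_variation(group_a: MeasurementGroup, group_b: MeasurementGroup) -> np.ndarray:
    """Per-channel symmetric percent difference of two batches' mean netOD at
    a common dose."""
    if not np.isclose(group_a.dose_gy, group_b.dose_gy):
        raise ValueError(
            f"dose mismatch: {group_a.dose_gy} Gy vs {group_b.dose_gy} Gy"
        )
    ma, mb = group_a.mean, group_b.mean
    return np.array([percent_difference(ma[i], mb[i]) for i in range(3)])


def noise_to_signal(dataset) -> np.ndarray:
    """Mean per-channel noise-to-signal ratio of a calibration dataset, %.

    Averages 100*sigma/netOD over all nonzero-dose entries per channel. A
    well-behaved scanner shows red < green < blue. Entries with non-positive
    netOD are excluded with a warning.
    """
    df = getattr(dataset, "frame", dataset)
    if "sigma" not in df.columns:
        raise ValueError("dataset has no sigma column")
    out = np.empty(3)
    for i, ch in enumerate(CHANNELS):
        sub = df[(df["channel"] == ch) & (df["dose_gy"] > 0)]
        bad = sub["netod"] <= 0
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} non-positive netOD entries excluded from "
                f"noise-to-signal ({ch} channel)",
                stacklevel=2,
            )
            sub = sub[~bad]
        if sub.empty:
            raise ValueError(f"no usable entries for channel {ch}")
        out[i] = float((100.0 * sub["sigma"] / sub["netod"]).mean())
    return out
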