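"""Shared constants: channel order, standard dose/time grids, protocol defaults.

The dose grid is the standard film-calibration ladder for proton work:
0.25 Gy steps up to 1 Gy, 1 Gy steps to 10 Gy, 2 Gy steps to 20 Gy.
"""

from __future__ import annotations

import numpy as np

#: Channel order used everywhere a per-channel array of length 3 appears.
CHANNELS: tuple[str, str, str] = ("red", "green", "blue")

#: Calibration dose ladder, Gy (18 points).
CALIBRATION_DOSE_GRID_GY: tuple[float, ...] = (
    0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0,
    12.0, 14.0, 16.0, 18.0, 20.0,
)

#: Post-irradiation scan times, hours (9 points).
KINETICS_TIME_GRID_H: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 120.0)

#: Differential growth rate below which darkening is declared plateaued, %/h.
PLATEAU_THRESHOLD_PCT_PER_H: float = 0.05

#: Reference readout time for netOD, hours.
REFERENCE_TIME_H: float = 48.0

#: Fractional dose perturbation used in sensitivity (dose-resolution) tests.
SENSITIVITY_PERTURBATION: float = 0.05

#: Default unexposed-film scanner level, 16-bit counts (transmission mode).
DEFAULT_I0_MEAN: float = 42000.0

#: Default per-pixel multiplicative intensity noise fractions (red, green, blue),
#: chosen so the pipeline's mean noise-to-signal ratio per channel shows the
#: characteristic red < green < blue ordering of flatbed film scans.
DEFAULT_NOISE_FRACTIONS: tuple[float, float, float] = (0.010, 0.016, 0.038)

#: Rational dose-response parameters (a, b, n) and fit R-squared per channel
#: for the supported film batches: two EBT4 production lots (B1, B2) and one
#: EBT3 reference lot (B4).
BATCH_PRESETS: dict[str, dict] = {
    "B1": {
        "film_model": "EBT4",
        "channels": {
            "red": (0.0740, 0.0842, 0.9684, 0.9998),
            "green": (0.0418, 0.0258, 1.0355, 0.9994),
            "blue": (0.0142, 0.0004, 2.1124, 0.9998),
        },
    },
    "B2": {
        "film_model": "EBT4",
        "channels": {
            "red": (0.1084, 0.2339, 0.7978, 0.9997),
            "green": (0.0532, 0.0959, 0.7919, 0.9995),
            "blue": (0.0205, 0.0593, 0.8161, 0.9997),
        },
    },
    "B4": {
        "film_model": "EBT3",
        "channels": {
            "red": (0.1844, 0.5289, 0.7403, 0.9989),
            "green": (0.0912, 0.2252, 0.7597, 0.9997),
            "blue": (0.0393, 0.2132, 0.6624, 0.9998),
        },
    },
}

LN10: float = float(np.log(10.0))
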