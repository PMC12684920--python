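"""Forward model of the nlsGPS FRET biosensors.

The emission ratio saturates with GA4 concentration along a Hill-type
titration curve, R(c) = R_min + (R_max − R_min)·c^h/(K_d^h + c^h); the
default Hill coefficient is 1 (rectangular hyperbola).  The map is a
monotone bijection from [0, ∞) onto [R_min, R_max), so gradient-shape
statements survive the nonlinearity, and it is analytically invertible
for unsaturated readings.
"""

from __future__ import annotations

import numpy as np

from .params import SENSOR_CALIBRATIONS, SensorCalibration

__all__ = ["emission_ratio", "invert_ratio", "SENSOR_CALIBRATIONS", "SensorCalibration"]


def emission_ratio(c, cal: SensorCalibration):
    """Emission ratio at GA4 concentration c (nM); strictly increasing."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("GA4 concentration must be >= 0")
    ch = c ** cal.hill
    out = cal.r_min + (cal.r_max - cal.r_min) * ch / (cal.kd ** cal.hill + ch)
    return float(out) if out.ndim == 0 else out


def invert_ratio(r, cal: SensorCalibration):
    """GA4 concentration (nM) for an emission ratio in (R_min, R_max).

    Saturated or sub-baseline readings carry no concentration information
    and raise ValueError.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= cal.r_min) or np.any(r >= cal.r_max):
        raise ValueError("ratio outside the open interval (r_min, r_max)")
    y = (r - cal.r_min) / (cal.r_max - r)
    out = cal.kd * y ** (1.0 / cal.hill)
    return float(out) if out.ndim == 0 else out
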