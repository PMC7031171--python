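"""Trunk-angle proxy from the lever-arm accelerometer.

Under a quasi-static contraction the gravity component along the sensor's
z axis encodes the lever-arm inclination: angle = asin(acc_z / g).  Two
quality-control metrics summarise the mechanics of a test: the onset
angle (mean over the first second of the analysis window) and the drift
rate (OLS slope of angle versus time over the window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Channel

STANDARD_GRAVITY = 9.80665  # m/s^2, for traces not already in g units


@dataclass
class KinematicsConfig:
    """Analysis window and sensor-range handling.

    Samples marginally outside |z| <= 1 (sensor noise, 8-bit quantisation
    at +/-1.5 g) are clamped when within ``clamp_tol``; if more than
    ``max_over_range_fraction`` of samples exceed 1 + clamp_tol the trace
    is rejected as out of sensor range.
    """

    trim_start: float = 3.0
    analysis_end: float = 30.0
    onset_window_s: float = 1.0
    clamp_tol: float = 0.02
    max_over_range_fraction: float = 0.01
    axis: str = "z"
    in_g_units: bool = True


@dataclass
class TrunkAngleSeries:
    """Inclination angle trace plus the two quality-control metrics."""

    times: np.ndarray
    angle_deg: np.ndarray
    onset_angle: float  # degrees
    drift_rate: float  # deg/s


def angle_from_accel(
    z: Channel, config: KinematicsConfig | None = None
) -> TrunkAngleSeries:
    """Trunk-angle series and QC metrics from the z-axis accelerometer trace.

    The trace must be in g units (set ``config.in_g_units = False`` for
    m/s^2 input).  Noise-free input g*sin(theta(t)) is reproduced exactly
    for |theta| < 90 degrees.
    """
    config = config or KinematicsConfig()
    acc = z.samples if config.in_g_units else z.samples / STANDARD_GRAVITY
    over = np.abs(acc) > 1.0 + config.clamp_tol
    if over.mean() > config.max_over_range_fraction:
        raise ValueError(
            f"{over.mean() * 100:.1f}% of accelerometer samples exceed the "
            "+/-1 g gravity range beyond tolerance: sensor range error"
        )
    clamped = np.clip(acc, -1.0, 1.0)
    angle = np.degrees(np.arcsin(clamped))
    times = z.times

    end = min(config.analysis_end, float(times[-1]) + 0.5 / z.fs)
    win = (times >= config.trim_start) & (times < end)
    if win.sum() < 2:
        raise ValueError("analysis window contains fewer than 2 accelerometer samples")
    t_w = times[win]
    a_w = angle[win]
    onset_sel = t_w < t_w[0] + config.onset_window_s
    onset_angle = float(a_w[onset_sel].mean())
    drift = float(np.polyfit(t_w - t_w[0], a_w, 1)[0])
    return TrunkAngleSeries(
        times=times, angle_deg=angle, onset_angle=onset_angle, drift_rate=drift
    )
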