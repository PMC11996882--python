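"""Gravity-based sagittal inclinometry.

During slow trunk flexion, the accelerometer output is dominated by the
gravity vector expressed in the sensor's local frame.  The sagittal
inclination of the sensor is then the angle between its longitudinal
axis and the vertical, recovered as ``atan2(a_anteroposterior,
a_longitudinal)``.  Positive angles mean the segment is rotated forward
of vertical; negative angles mean backward.  The lumbar angle is the
difference between trunk (T12) and pelvic (S1) inclination; negative
lumbar angles quantify lumbar lordosis, positive ones lumbar kyphosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from trunkmotion.signal_io import AccelTrace, moving_average

logger = logging.getLogger(__name__)

ROLES = ("trunk", "pelvic", "lumbar")

# Plausible standing trunk inclination; outside this a flipped sensor is likely.
STANDING_PLAUSIBLE_DEG = (-30.0, 10.0)


@dataclass(frozen=True)
class AngleSeries:
    """Signed sagittal inclination in degrees (positive = forward-rotated)."""

    role: str
    sampling_rate: float
    theta: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("angles must be finite")
        if np.any(np.abs(self.theta) > 180.0):
            raise ValueError("|theta| must be <= 180 degrees")

    def __len__(self) -> int:
        return self.theta.size


def sagittal_inclination(
    trace: AccelTrace,
    role: str,
    smooth_window_ms: float = 500.0,
    flip_anteroposterior: bool = False,
    check_standing: bool = False,
) -> AngleSeries:
    """Sagittal inclination angle of a sensor from its gravity projection.

    Parameters
    ----------
    trace
        Preprocessed (filtered, smoothed, gravity-gated) trace.
    role
        ``"pelvic"`` for the S1 sensor, ``"trunk"`` for T12.
    smooth_window_ms
        Width of the centered moving average applied to the *angle*
        signal after extraction (0 disables).  The measurement chain
        smooths both the raw accelerations and the derived angles.
    flip_anteroposterior
        Set when the sensor was mounted inverted, so that forward
        rotation still maps to positive angles.
    check_standing
        If set, warn when the first sample's angle falls outside the
        plausible standing range — a hint of a flipped sensor.
    """
    ax = -trace.ax if flip_anteroposterior else trace.ax
    az = trace.az
    sagittal_norm = np.sqrt(ax**2 + az**2)
    if np.median(sagittal_norm) < 0.2:
        raise ValueError(
            "gravity projection onto the sagittal plane below 0.2 g; "
            "sensor placement/axis convention invalid for inclinometry"
        )
    theta = np.degrees(np.arctan2(ax, az))
    if smooth_window_ms > 0:
        theta = moving_average(theta, smooth_window_ms, trace.sampling_rate)
    if check_standing and not (
        STANDING_PLAUSIBLE_DEG[0] <= theta[0] <= STANDING_PLAUSIBLE_DEG[1]
    ):
        logger.warning(
            "standing %s angle %.1f° outside plausible range %s; check sensor mounting",
            role,
            theta[0],
            STANDING_PLAUSIBLE_DEG,
        )
    return AngleSeries(role=role, sampling_rate=trace.sampling_rate, theta=theta)


def lumbar_angle_series(trunk: AngleSeries, pelvic: AngleSeries) -> AngleSeries:
    """Lumbar angle = trunk − pelvic, pointwise.

    Negative values indicate the magnitude of lumbar lordosis; the sign
    flip to positive during deep flexion marks the lordosis→kyphosis
    transition.
    """
    if len(trunk) != len(pelvic):
        raise ValueError(
            f"trunk ({len(trunk)}) and pelvic ({len(pelvic)}) series lengths differ"
        )
    if trunk.sampling_rate != pelvic.sampling_rate:
        raise ValueError("trunk and pelvic sampling rates differ")
    return AngleSeries(
        role="lumbar",
        sampling_rate=trunk.sampling_rate,
        theta=trunk.theta - pelvic.theta,
    )
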