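"""Sensor-trace I/O and preprocessing.

Traces are delimited text files (comma or tab separated, header row) with
columns ``t, ax, ay, az`` (or only the three axes, with time synthesized
from a declared sampling rate).  Acceleration is in units of g; ``az`` is
the sensor's longitudinal axis (vertical when upright), ``ax`` the
anteroposterior axis, ``ay`` the mediolateral axis.

Preprocessing follows the inclinometry measurement chain: zero-phase
low-pass Butterworth filtering, centered moving-average smoothing, and a
gravity-norm gate that rejects trials in which the acceleration norm
strays from 1 g by more than a tolerance (default 0.10 g) — i.e. trials
with appreciable non-gravitational acceleration, which would corrupt the
quasi-static inclination estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

VALID_SENSORS = ("S1", "T12", "T2")


@dataclass(frozen=True)
class AccelTrace:
    """Timestamped tri-axial acceleration (units of g) for one sensor."""

    sensor_id: str
    sampling_rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise ValueError("AccelTrace needs at least 2 samples")
        if not (self.ax.size == self.ay.size == self.az.size == n):
            raise ValueError("t/ax/ay/az must have equal lengths")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        # uniform spacing within 1 ppm of the median step
        step = np.median(dt)
        if np.any(np.abs(dt - step) > 1e-6 * step + 1e-12):
            raise ValueError("timestamps must be uniformly spaced (within 1 ppm)")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def norms(self) -> np.ndarray:
        """Euclidean norm of (ax, ay, az) per sample, in g."""
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)

    def replace_axes(self, ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> "AccelTrace":
        return AccelTrace(self.sensor_id, self.sampling_rate, self.t, ax, ay, az)


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass zero-phase Butterworth filter specification."""

    cutoff: float
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class GateResult:
    """Outcome of the gravity-norm trial gate."""

    accepted: bool
    min_norm: float
    max_norm: float
    tolerance: float


def read_accel_table(path, sensor_id: str, sampling_rate: float = 500.0) -> AccelTrace:
    """Read a delimited-text trace file into an :class:`AccelTrace`.

    The file must contain a header row with columns ``t, ax, ay, az`` or
    ``ax, ay, az``.  When a ``t`` column is present the sampling rate is
    inferred from it and cross-checked against the declared value (a
    mismatch warns but does not fail, since synthetic data may use other
    rates); otherwise timestamps are synthesized from ``sampling_rate``.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise ValueError(f"could not parse trace file {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in ("ax", "ay", "az") if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks required column(s): {', '.join(missing)}")
    cols = ["t", "ax", "ay", "az"] if "t" in df.columns else ["ax", "ay", "az"]
    for c in cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"non-numeric value in column '{c}' at row {row} of {path}")
        df[c] = numeric
    if "t" in df.columns:
        t = df["t"].to_numpy(float)
        inferred = 1.0 / np.median(np.diff(t))
        if abs(inferred - sampling_rate) > 0.01 * sampling_rate:
            logger.warning(
                "declared sampling rate %.6g Hz differs from file-inferred %.6g Hz; using file",
                sampling_rate,
                inferred,
            )
        sampling_rate = inferred
    else:
        t = np.arange(len(df)) / sampling_rate
    return AccelTrace(
        sensor_id=sensor_id,
        sampling_rate=float(sampling_rate),
        t=t,
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
    )


def write_accel_table(trace: AccelTrace, path, sep: str = ",") -> None:
    """Write a trace as delimited text with a ``t, ax, ay, az`` header."""
    df = pd.DataFrame({"t": trace.t, "ax": trace.ax, "ay": trace.ay, "az": trace.az})
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def lowpass_zero_phase(x: np.ndarray, spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward–backward).

    The effective magnitude response is the squared single-pass
    Butterworth response; phase lag is zero.  Reflective padding of
    3 × (filter order) samples suppresses edge transients.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if not spec.cutoff < nyq:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist ({nyq} Hz)")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=sampling_rate, output="sos")
    padlen = 3 * (2 * spec.order + 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal of length {x.size} too short for zero-phase filtering; need > {padlen} samples"
        )
    if not spec.zero_phase:
        return sps.sosfilt(sos, x)
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def window_samples(window_ms: float, sampling_rate: float) -> int:
    """Convert a window in milliseconds to the nearest odd sample count >= 1."""
    w = int(round(window_ms * 1e-3 * sampling_rate))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def moving_average(x: np.ndarray, window_ms: float, sampling_rate: float) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available samples.

    The window is converted to an odd number of samples (round to nearest
    odd).  Truncation at the boundaries means no data are fabricated at
    trial edges: each output is the mean over samples actually present in
    the centered window.
    """
    x = np.asarray(x, dtype=float)
    w = window_samples(window_ms, sampling_rate)
    if w > x.size:
        raise ValueError(f"window of {w} samples exceeds signal length {x.size}")
    if w == 1:
        return x.copy()
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, x.size - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def preprocess_trace(
    trace: AccelTrace,
    spec: FilterSpec | None = None,
    smooth_window_ms: float = 500.0,
) -> AccelTrace:
    """Apply the standard preprocessing chain to all three axes.

    Default chain for flexion trials: 5 Hz 2nd-order zero-phase
    Butterworth, then a 500 ms centered moving average.
    """
    if spec is None:
        spec = FilterSpec(cutoff=5.0, order=2)
    axes = []
    for a in (trace.ax, trace.ay, trace.az):
        a = lowpass_zero_phase(a, spec, trace.sampling_rate)
        if smooth_window_ms > 0:
            a = moving_average(a, smooth_window_ms, trace.sampling_rate)
        axes.append(a)
    return trace.replace_axes(*axes)


def gravity_norm_gate(trace: AccelTrace, tolerance: float = 0.10) -> GateResult:
    """Accept a (preprocessed) trial iff every sample norm is within 1 ± tolerance g.

    A norm outside the band indicates non-gravitational acceleration
    large enough to invalidate gravity-based inclinometry.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    norms = trace.norms()
    lo, hi = float(norms.min()), float(norms.max())
    accepted = (lo >= 1.0 - tolerance) and (hi <= 1.0 + tolerance)
    if not accepted:
        logger.info(
            "trial rejected by gravity gate: norm range [%.4f, %.4f] g outside 1 ± %.2f g",
            lo,
            hi,
            tolerance,
        )
    return GateResult(accepted=accepted, min_norm=lo, max_norm=hi, tolerance=tolerance)
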