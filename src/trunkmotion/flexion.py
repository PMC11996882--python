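"""Trunk-flexion cycle segmentation and lumbo-pelvic metrics.

A flexion trial contains three slow trunk forward-bending repetitions.
Each cycle runs from quiet standing to maximal flexion: the end of a
cycle is the local maximum of the trunk angle, and the start is found by
scanning backward from that peak to the last sample whose 100 ms secant
slope is still below a threshold (default 0.1° per increment) — i.e. the
quiet-standing/movement boundary.  Cycles are time-normalized to 1,000
points, averaged into a mean trial, and the posture/coordination metrics
are computed from that mean trial:

* ranges of motion (trunk, pelvic, lumbar): maximum minus standing angle;
* lordosis duration: movement start to the first positive lumbar angle;
* pelvic excursions during the lordotic and kyphotic phases;
* lumbo-pelvic ratios (LPR): lumbar change over pelvic change, for the
  full movement and per phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from trunkmotion.inclinometry import AngleSeries

N_NORMALIZED = 1000


@dataclass(frozen=True)
class FlexionCycle:
    """One (or a mean) flexion cycle, time-normalized to a fixed grid."""

    trunk: np.ndarray
    pelvic: np.ndarray
    lumbar: np.ndarray
    duration: float
    start_index: int = 0
    end_index: int = 0

    def __post_init__(self) -> None:
        for name in ("trunk", "pelvic", "lumbar"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.trunk.size
        if not (self.pelvic.size == self.lumbar.size == n):
            raise ValueError("trunk/pelvic/lumbar arrays must have equal lengths")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class FlexionMetrics:
    """Per-trial lumbo-pelvic posture and coordination metrics (degrees / seconds)."""

    time_mov: float
    trunk_RoM: float
    pelvic_RoM: float
    lumbar_RoM: float
    trunk_stand: float
    trunk_end: float
    pelvic_stand: float
    pelvic_end: float
    lumbar_stand: float
    lumbar_end: float
    pelvic_lordosis_end: float
    pelvic_RoM_lordosis: float
    pelvic_RoM_kyphosis: float
    LOR_dur: float
    LOR_dur_norm: float
    LPR_full: float
    LPR_lordosis: float
    LPR_kyphosis: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def secant_slopes(theta: np.ndarray, sampling_rate: float, increment_ms: float = 100.0) -> np.ndarray:
    """Forward secant slopes over a fixed time increment (degrees per increment).

    ``s[i] = theta[i + inc] - theta[i]``; the last ``inc`` entries repeat the
    final computable slope so the array matches the input length.
    """
    theta = np.asarray(theta, dtype=float)
    inc = max(int(round(increment_ms * 1e-3 * sampling_rate)), 1)
    if theta.size <= inc:
        raise ValueError("signal shorter than one secant increment")
    s = np.empty_like(theta)
    s[:-inc] = theta[inc:] - theta[:-inc]
    s[-inc:] = s[-inc - 1]
    return s


def detect_cycles(
    trunk: AngleSeries,
    slope_increment_ms: float = 100.0,
    slope_threshold: float = 0.1,
    expected_cycles: int = 3,
    min_separation_s: float = 2.0,
) -> list[tuple[int, int]]:
    """Locate the flexion cycles in a trunk-angle series.

    Cycle ends are local maxima of the trunk angle separated by at least
    ``min_separation_s`` and exceeding 50% of the global angle range
    (ties on a flat maximum break to the earliest sample).  Each cycle's
    start is the last sample before its peak at which the 100 ms secant
    slope is below ``slope_threshold`` degrees per increment.
    """
    theta = trunk.theta
    fs = trunk.sampling_rate
    rng = theta.max() - theta.min()
    if rng < 1.0:
        raise ValueError("trunk angle range below 1°: no flexion cycles to segment")
    height = theta.min() + 0.5 * rng
    min_sep = max(int(round(min_separation_s * fs)), 1)

    # local maxima on the (possibly plateaued) signal: earliest sample of flat tops
    from scipy.signal import find_peaks

    peaks, props = find_peaks(theta, height=height, distance=min_sep, plateau_size=1)
    if "left_edges" in props:
        peaks = props["left_edges"]
    # a maximum held to the end of the recording has no falling edge and is
    # missed by peak finding; the earliest sample of that terminal plateau
    # still ends a cycle
    gmax = int(np.argmax(theta))
    if peaks.size == 0 or (gmax - peaks.max() > min_sep and theta[gmax] >= height):
        peaks = np.sort(np.append(peaks, gmax))
    if peaks.size < expected_cycles:
        raise ValueError(
            f"expected {expected_cycles} flexion peaks, found {peaks.size}"
        )
    # keep the expected_cycles tallest peaks, in temporal order
    if peaks.size > expected_cycles:
        order = np.argsort(theta[peaks])[::-1][:expected_cycles]
        peaks = np.sort(peaks[order])

    slopes = secant_slopes(theta, fs, slope_increment_ms)
    cycles: list[tuple[int, int]] = []
    prev_end = -1
    for pk in peaks:
        # scan backward from the peak: first skip the near-peak deceleration
        # zone (slope already sub-threshold), then walk down the main rise
        # until the slope falls below threshold again — that sample is the
        # quiet-standing/movement boundary.
        i = int(pk) - 1
        while i > prev_end and slopes[i] < slope_threshold:
            i -= 1
        if i <= prev_end:
            raise ValueError(
                f"no suprathreshold rise before peak at sample {pk}; "
                "cannot locate movement onset"
            )
        while i > prev_end and slopes[i] >= slope_threshold:
            i -= 1
        if slopes[i] >= slope_threshold:
            raise ValueError(
                f"no sub-threshold secant slope before the rise toward sample {pk}"
            )
        cycles.append((i, int(pk)))
        prev_end = int(pk)
    return cycles


def normalize_cycle(
    trunk_seg: np.ndarray,
    pelvic_seg: np.ndarray,
    lumbar_seg: np.ndarray,
    duration: float,
    n_points: int = N_NORMALIZED,
    start_index: int = 0,
    end_index: int = 0,
) -> FlexionCycle:
    """Resample one cycle's angle segments onto ``n_points`` by linear interpolation."""
    trunk_seg = np.asarray(trunk_seg, dtype=float)
    if trunk_seg.size < 2:
        raise ValueError("cycle segment must contain at least 2 samples")
    src = np.linspace(0.0, 1.0, trunk_seg.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return FlexionCycle(
        trunk=np.interp(dst, src, trunk_seg),
        pelvic=np.interp(dst, src, np.asarray(pelvic_seg, dtype=float)),
        lumbar=np.interp(dst, src, np.asarray(lumbar_seg, dtype=float)),
        duration=duration,
        start_index=start_index,
        end_index=end_index,
    )


def mean_trial(cycles: list[FlexionCycle]) -> FlexionCycle:
    """Pointwise mean of normalized cycles; duration is the mean duration."""
    if not cycles:
        raise ValueError("need at least one cycle")
    n = cycles[0].trunk.size
    if any(c.trunk.size != n for c in cycles):
        raise ValueError("all cycles must share the normalized length")
    return FlexionCycle(
        trunk=np.mean([c.trunk for c in cycles], axis=0),
        pelvic=np.mean([c.pelvic for c in cycles], axis=0),
        lumbar=np.mean([c.lumbar for c in cycles], axis=0),
        duration=float(np.mean([c.duration for c in cycles])),
    )


def lordosis_transition(lumbar: np.ndarray) -> int:
    """Index of the first strictly positive lumbar value; ``len(lumbar)`` if none.

    The returned index marks the lordosis→kyphosis transition on the
    normalized time axis; a return of ``len(lumbar)`` means the movement
    stayed lordotic throughout.
    """
    lumbar = np.asarray(lumbar, dtype=float)
    pos = np.flatnonzero(lumbar > 0)
    return int(pos[0]) if pos.size else int(lumbar.size)


def _phase_lpr(d_lumbar: float, d_pelvic: float) -> float:
    if abs(d_pelvic) < 1e-6:
        return math.nan
    return d_lumbar / d_pelvic


def flexion_metrics(trial: FlexionCycle) -> FlexionMetrics:
    """All lumbo-pelvic metrics of a normalized (mean) flexion cycle.

    Standing values are index 0, end-of-movement values the last index;
    RoM is the maximum over the cycle minus the standing value.  Phase
    boundaries come from the lordosis transition.  LPRs with a pelvic
    change below 1e-6° are returned as NaN rather than extreme ratios.
    """
    n = trial.trunk.size
    last = n - 1
    k = lordosis_transition(trial.lumbar)
    k_star = min(k, last)

    trunk_stand, trunk_end = float(trial.trunk[0]), float(trial.trunk[last])
    pelvic_stand, pelvic_end = float(trial.pelvic[0]), float(trial.pelvic[last])
    lumbar_stand, lumbar_end = float(trial.lumbar[0]), float(trial.lumbar[last])
    pelvic_at_k = float(trial.pelvic[k_star])
    lumbar_at_k = float(trial.lumbar[k_star])

    lor_frac = k / n
    no_kyphosis = k >= n  # fully lordotic movement

    return FlexionMetrics(
        time_mov=trial.duration,
        trunk_RoM=float(trial.trunk.max() - trunk_stand),
        pelvic_RoM=float(trial.pelvic.max() - pelvic_stand),
        lumbar_RoM=float(trial.lumbar.max() - lumbar_stand),
        trunk_stand=trunk_stand,
        trunk_end=trunk_end,
        pelvic_stand=pelvic_stand,
        pelvic_end=pelvic_end,
        lumbar_stand=lumbar_stand,
        lumbar_end=lumbar_end,
        pelvic_lordosis_end=pelvic_at_k,
        pelvic_RoM_lordosis=pelvic_at_k - pelvic_stand,
        pelvic_RoM_kyphosis=math.nan if no_kyphosis else pelvic_end - pelvic_at_k,
        LOR_dur=trial.duration * lor_frac,
        LOR_dur_norm=100.0 * lor_frac,
        LPR_full=_phase_lpr(lumbar_end - lumbar_stand, pelvic_end - pelvic_stand),
        LPR_lordosis=_phase_lpr(lumbar_at_k - lumbar_stand, pelvic_at_k - pelvic_stand),
        LPR_kyphosis=(
            math.nan
            if no_kyphosis
            else _phase_lpr(lumbar_end - lumbar_at_k, pelvic_end - pelvic_at_k)
        ),
    )


def process_flexion_trial(
    trunk: AngleSeries,
    pelvic: AngleSeries,
    lumbar: AngleSeries,
    expected_cycles: int = 3,
    slope_threshold: float = 0.1,
    slope_increment_ms: float = 100.0,
    n_points: int = N_NORMALIZED,
) -> tuple[FlexionMetrics, FlexionCycle, list[FlexionCycle]]:
    """Full trial pipeline: segment, normalize, average, compute metrics.

    Returns ``(metrics, mean_cycle, per_cycle_list)``.
    """
    bounds = detect_cycles(
        trunk,
        slope_increment_ms=slope_increment_ms,
        slope_threshold=slope_threshold,
        expected_cycles=expected_cycles,
    )
    fs = trunk.sampling_rate
    cycles = [
        normalize_cycle(
            trunk.theta[s : e + 1],
            pelvic.theta[s : e + 1],
            lumbar.theta[s : e + 1],
            duration=(e - s) / fs,
            n_points=n_points,
            start_index=s,
            end_index=e,
        )
        for s, e in bounds
    ]
    trial = mean_trial(cycles)
    return flexion_metrics(trial), trial, cycles
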