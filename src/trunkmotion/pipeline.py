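"""End-to-end drivers tying the processing stages together.

These are the entry points the analysis scripts use: raw sensor traces
in, metrics out, with the preprocessing chain applied exactly as in the
measurement protocol (5 Hz / 20 Hz zero-phase Butterworth, 500 ms
moving averages, gravity gate).
"""

from __future__ import annotations

import numpy as np

from trunkmotion.flexion import FlexionCycle, FlexionMetrics, process_flexion_trial
from trunkmotion.inclinometry import lumbar_angle_series, sagittal_inclination
from trunkmotion.signal_io import AccelTrace, FilterSpec, gravity_norm_gate, lowpass_zero_phase, preprocess_trace
from trunkmotion.stability import analyze_pointing_trial


def flexion_pipeline(
    s1: AccelTrace,
    t12: AccelTrace,
    gate_tolerance: float = 0.10,
    smooth_window_ms: float = 500.0,
    expected_cycles: int = 3,
) -> tuple[FlexionMetrics, FlexionCycle, list[FlexionCycle]]:
    """Full flexion-trial analysis from raw S1/T12 traces.

    Filters and smooths both traces, enforces the gravity-norm gate,
    extracts pelvic/trunk/lumbar angle series, segments the flexion
    cycles and returns ``(metrics, mean_cycle, per_cycle_list)``.

    Raises
    ------
    ValueError
        If either trace fails the 1 ± tolerance g gravity gate.
    """
    spec = FilterSpec(cutoff=5.0, order=2)
    s1p = preprocess_trace(s1, spec, smooth_window_ms)
    t12p = preprocess_trace(t12, spec, smooth_window_ms)
    for name, tr in (("S1", s1p), ("T12", t12p)):
        gate = gravity_norm_gate(tr, gate_tolerance)
        if not gate.accepted:
            raise ValueError(
                f"{name} trace rejected by gravity gate "
                f"(norms in [{gate.min_norm:.3f}, {gate.max_norm:.3f}] g)"
            )
    pelvic = sagittal_inclination(s1p, "pelvic", smooth_window_ms)
    trunk = sagittal_inclination(t12p, "trunk", smooth_window_ms)
    lumbar = lumbar_angle_series(trunk, pelvic)
    return process_flexion_trial(trunk, pelvic, lumbar, expected_cycles=expected_cycles)


def stability_pipeline(
    t2: AccelTrace,
    tau: int | None = None,
    m: int | None = None,
    **kwargs,
) -> dict:
    """Full pointing-task analysis from a raw T2 trace (20 Hz pre-filter)."""
    spec = FilterSpec(cutoff=20.0, order=2)
    axes = [lowpass_zero_phase(a, spec, t2.sampling_rate) for a in (t2.ax, t2.ay, t2.az)]
    filtered = t2.replace_axes(*axes)
    return analyze_pointing_trial(filtered, tau=tau, m=m, **kwargs)
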