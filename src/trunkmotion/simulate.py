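"""Synthetic data with known ground truth for every pipeline stage.

Four generators, all pure functions of their parameters and a seed:

* :func:`simulate_flexion_trial` — a forward model of the slow
  trunk-flexion measurement: prescribed pelvic and lumbar angle
  trajectories (minimum-jerk timing), sensor traces obtained by rotating
  the gravity unit vector into each sensor frame, optional white sensor
  noise.  Kinematic (non-gravitational) acceleration is omitted by
  default — the same quasi-static assumption the measurement itself
  relies on at slow, controlled speed.
* :func:`simulate_pointing_task` — a quasi-periodic ~0.17 Hz, 32-cycle
  acceleration signal with controllable cycle-to-cycle amplitude and
  period jitter, optional chaotic amplitude modulation (Lorenz-driven),
  and additive noise.
* :func:`simulate_lorenz` / :func:`benettin_lyapunov` — a chaotic
  benchmark series and the independent tangent-space (Benettin/QR)
  estimate of its largest Lyapunov exponent (≈0.906 per time unit at the
  standard parameters), used to validate the Kantz estimator.
* :func:`simulate_cohort` — participant tables with known sex / pain /
  chronicity effects injected into outcome metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trunkmotion.signal_io import AccelTrace
from trunkmotion.flexion import FlexionMetrics
from trunkmotion.cohort import ParticipantRecord

#: cohort pain-group proportions emulating a large mixed LBP sample
DEFAULT_GROUP_PROBS = (0.17, 0.61, 0.22)  # ASY, LMP, MHP


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 10u³ − 15u⁴ + 6u⁵ on normalized time."""
    u = np.clip(u, 0.0, 1.0)
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


@dataclass(frozen=True)
class FlexionSimParams:
    """Prescribed kinematics of a simulated trunk-flexion trial.

    Defaults reproduce a typical asymptomatic adult trial: standing
    pelvic tilt ~+8°, standing lumbar lordosis −25°, pelvic excursion
    70°, lumbar excursion 45° (ending in ~20° kyphosis), 8 s per
    flexion at a slow pace, three repetitions.
    """

    standing_pelvic_angle: float = 8.0
    pelvic_rom: float = 70.0
    standing_lumbar_angle: float = -25.0
    lumbar_rom: float = 45.0
    movement_time: float = 8.0
    lordosis_transition_fraction: float = 0.45
    n_cycles: int = 3
    rest_between: float = 3.0
    # a dwell at max flexion shifts the detected (max-angle) cycle end to the
    # dwell's center after smoothing; default to an immediate return so the
    # prescribed movement_time is the construct the detection rule measures
    hold_top: float = 0.0
    noise_sd: float = 0.0
    sampling_rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.movement_time <= 0:
            raise ValueError("movement_time must be positive")
        if self.pelvic_rom < 0:
            raise ValueError("pelvic_rom must be non-negative")
        if not 0.0 < self.lordosis_transition_fraction < 1.0:
            raise ValueError("lordosis_transition_fraction must be in (0, 1)")
        if self.lumbar_rom <= -self.standing_lumbar_angle:
            raise ValueError(
                "lumbar_rom must exceed |standing_lumbar_angle| so the lumbar "
                "angle crosses zero during the movement"
            )


def _minimum_jerk_inverse(y: float) -> float:
    """Normalized time u with minimum_jerk(u) = y (bisection; y in (0, 1))."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if minimum_jerk(np.array([mid]))[0] < y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _lumbar_time_warp_exponent(params: FlexionSimParams) -> float:
    """Power-warp exponent β so the lumbar zero crossing lands at the transition.

    The lumbar profile is ``l0 + lumbar_rom * s(u^β)`` — a monotone time
    warp of the minimum-jerk shape that keeps zero velocity at both ends.
    β solves ``s(f^β) = −l0 / lumbar_rom``.
    """
    target = -params.standing_lumbar_angle / params.lumbar_rom  # in (0, 1)
    u_target = _minimum_jerk_inverse(target)
    return math.log(u_target) / math.log(params.lordosis_transition_fraction)


def flexion_angle_profiles(
    params: FlexionSimParams, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prescribed (pelvic, lumbar, trunk) angles at normalized movement times u."""
    beta = _lumbar_time_warp_exponent(params)
    u = np.clip(u, 0.0, 1.0)
    pelvic = params.standing_pelvic_angle + params.pelvic_rom * minimum_jerk(u)
    lumbar = params.standing_lumbar_angle + params.lumbar_rom * minimum_jerk(u**beta)
    return pelvic, lumbar, pelvic + lumbar


def _analytic_start_fraction(
    params: FlexionSimParams,
    slope_threshold: float = 0.1,
    increment_s: float = 0.1,
    smooth_window_s: float = 0.5,
) -> float:
    """Movement-start fraction under the secant-slope rule, for the prescribed trunk curve.

    The cycle-start construct is *defined* by the measurement protocol:
    the angle signal is smoothed with two 500 ms centered moving
    averages, and the start is the last sample before the rise whose
    100 ms secant slope is below threshold (default 0.1° per increment).
    The ground truth applies exactly that rule to the prescribed
    trajectory (padded with quiet standing before the onset and the
    mirror-image return after the peak).  The fraction can be negative —
    smoothing smears a steep onset backward into quiet standing.
    """
    T = params.movement_time
    dt = 2e-3
    pad = 1.5  # seconds of standing before onset / return after peak
    t = np.arange(-pad, T + pad, dt)
    u = np.where(t < 0, 0.0, np.where(t <= T, t / T, np.maximum(2.0 - t / T, 0.0)))
    _, _, trunk = flexion_angle_profiles(params, u)
    w = int(round(smooth_window_s / dt)) | 1
    kernel = np.ones(w) / w
    for _ in range(2):  # acceleration-domain and angle-domain moving averages
        trunk = np.convolve(trunk, kernel, mode="same")
    n_inc = max(int(round(increment_s / dt)), 1)
    core = (t >= -pad + 1.0) & (t <= T / 2)  # ignore convolution edge region
    slope = np.full(t.size, 0.0)
    slope[: t.size - n_inc] = trunk[n_inc:] - trunk[:-n_inc]
    above = np.flatnonzero((slope >= slope_threshold) & core)
    if above.size == 0:
        return 0.0
    below_before = np.flatnonzero((slope[: above[0]] < slope_threshold) & core[: above[0]])
    start_t = t[below_before[-1]] if below_before.size else t[above[0]]
    return float(start_t / T)


def flexion_ground_truth(params: FlexionSimParams) -> FlexionMetrics:
    """Analytic metrics of the prescribed trajectories (no measurement chain).

    Standing values and durations are referenced to the movement start as
    defined by the secant-slope rule applied to the prescribed trunk
    trajectory (see :func:`_analytic_start_fraction`); the cycle end is
    the trunk-angle maximum, i.e. the end of the prescribed movement.
    """
    f = params.lordosis_transition_fraction
    u_start = _analytic_start_fraction(params)
    u = np.array([u_start, f, 1.0])
    pelvic, lumbar, trunk = flexion_angle_profiles(params, u)
    p0, pk, p1 = pelvic
    l0, lk, l1 = lumbar
    t0, _, t1 = trunk
    return FlexionMetrics(
        time_mov=params.movement_time * (1.0 - u_start),
        trunk_RoM=t1 - t0,
        pelvic_RoM=p1 - p0,
        lumbar_RoM=l1 - l0,
        trunk_stand=t0,
        trunk_end=t1,
        pelvic_stand=p0,
        pelvic_end=p1,
        lumbar_stand=l0,
        lumbar_end=l1,
        pelvic_lordosis_end=pk,
        pelvic_RoM_lordosis=pk - p0,
        pelvic_RoM_kyphosis=p1 - pk,
        LOR_dur=(f - u_start) * params.movement_time,
        LOR_dur_norm=100.0 * (f - u_start) / (1.0 - u_start),
        LPR_full=(l1 - l0) / (p1 - p0),
        LPR_lordosis=(lk - l0) / (pk - p0),
        LPR_kyphosis=(l1 - lk) / (p1 - pk),
    )


def _angle_trajectory(params: FlexionSimParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full-trial (pelvic, lumbar) angle time series: rest–rise–hold–return × n."""
    fs = params.sampling_rate
    rest = np.zeros(int(round(params.rest_between * fs)))
    hold = np.ones(int(round(params.hold_top * fs)))
    n_mov = int(round(params.movement_time * fs))
    u_up = np.arange(n_mov) / (n_mov - 1)
    segs = [rest]
    for _ in range(params.n_cycles):
        segs.extend([u_up, hold, u_up[::-1], rest])
    u = np.concatenate(segs)
    pelvic, lumbar, trunk = flexion_angle_profiles(params, u)
    return pelvic, lumbar, trunk


def _gravity_trace(
    theta_deg: np.ndarray,
    sensor_id: str,
    fs: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> AccelTrace:
    theta = np.radians(theta_deg)
    n = theta.size
    ax = np.sin(theta)
    ay = np.zeros(n)
    az = np.cos(theta)
    if noise_sd > 0:
        ax = ax + rng.normal(0.0, noise_sd, n)
        ay = ay + rng.normal(0.0, noise_sd, n)
        az = az + rng.normal(0.0, noise_sd, n)
    return AccelTrace(sensor_id=sensor_id, sampling_rate=fs, t=np.arange(n) / fs, ax=ax, ay=ay, az=az)


def simulate_flexion_trial(
    params: FlexionSimParams,
) -> tuple[AccelTrace, AccelTrace, FlexionMetrics]:
    """Simulate one flexion trial: (S1 trace, T12 trace, ground-truth metrics).

    The pelvic angle follows the standing value plus a minimum-jerk
    excursion; the lumbar angle rises from the standing lordosis with a
    time-warped minimum-jerk shape whose zero crossing lands exactly at
    the prescribed transition fraction; trunk = pelvic + lumbar.  Each
    sensor outputs the gravity unit vector rotated by its segment angle,
    plus white noise.
    """
    pelvic, lumbar, trunk = _angle_trajectory(params)
    if np.abs(trunk).max() > 175.0 or np.abs(pelvic).max() > 175.0:
        raise ValueError("prescribed angles exceed ±175°; unphysical configuration")
    rng = np.random.default_rng(params.seed)
    s1 = _gravity_trace(pelvic, "S1", params.sampling_rate, params.noise_sd, rng)
    t12 = _gravity_trace(trunk, "T12", params.sampling_rate, params.noise_sd, rng)
    return s1, t12, flexion_ground_truth(params)


@dataclass(frozen=True)
class TaskSimParams:
    """Cyclic pointing-task signal parameters (nominal: 0.17 Hz, 32 cycles)."""

    cycle_rate: float = 0.17
    n_cycles: int = 32
    amplitude_jitter_sd: float = 0.0
    period_jitter_sd: float = 0.0
    additive_noise_sd: float = 0.0
    chaos_coupling: float = 0.0
    sampling_rate: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_rate <= 0:
            raise ValueError("cycle_rate must be positive")
        if self.amplitude_jitter_sd < 0 or self.period_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be non-negative")
        if not 0.0 <= self.chaos_coupling <= 1.0:
            raise ValueError("chaos_coupling must be in [0, 1]")


def _cycle_waveform(phase: np.ndarray) -> np.ndarray:
    """Fixed cycle shape (harmonics of the cycle rate), minimum at phase 0."""
    w = (
        (1.0 - np.cos(2 * np.pi * phase))
        + 0.3 * (1.0 - np.cos(4 * np.pi * phase))
        + 0.15 * (1.0 - np.cos(6 * np.pi * phase))
    )
    return w / 2.9  # peak-normalize (max of the bracket is ~2.9)


def simulate_pointing_task(params: TaskSimParams) -> tuple[AccelTrace, np.ndarray]:
    """Simulate the cyclic pointing-task T2 trace.

    Returns ``(trace, boundaries)`` where ``boundaries`` holds the
    ``n_cycles + 1`` exact sample indices of cycle starts/ends.  Each
    cycle's amplitude is scaled by ``1 + N(0, amplitude_jitter_sd)`` and,
    when ``chaos_coupling > 0``, additionally modulated by a standardized
    Lorenz-driven factor; each cycle's period is perturbed by
    ``1 + N(0, period_jitter_sd)``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    T = 1.0 / params.cycle_rate
    periods = T * np.clip(
        1.0 + rng.normal(0.0, params.period_jitter_sd, params.n_cycles), 0.5, 1.5
    )
    amps = 1.0 + rng.normal(0.0, params.amplitude_jitter_sd, params.n_cycles)
    if params.chaos_coupling > 0:
        z = simulate_lorenz(dt=0.01, n=params.n_cycles * 50, seed=params.seed + 1)
        z = z[:: 50][: params.n_cycles]
        z = (z - z.mean()) / z.std()
        amps = amps * (1.0 + 0.3 * params.chaos_coupling * z)

    n_per_cycle = np.round(periods * fs).astype(int)
    boundaries = np.concatenate(([0], np.cumsum(n_per_cycle)))
    n_total = int(boundaries[-1])
    phase = np.empty(n_total)
    amp = np.empty(n_total)
    for i in range(params.n_cycles):
        lo, hi = boundaries[i], boundaries[i + 1]
        phase[lo:hi] = np.arange(hi - lo) / (hi - lo)
        amp[lo:hi] = amps[i]
    w = amp * _cycle_waveform(phase)
    ax = 0.25 * w
    ay = 0.15 * amp * (1.0 - np.cos(2 * np.pi * phase)) / 2.0
    az = 1.0 + 0.35 * w
    if params.additive_noise_sd > 0:
        ax = ax + rng.normal(0.0, params.additive_noise_sd, n_total)
        ay = ay + rng.normal(0.0, params.additive_noise_sd, n_total)
        az = az + rng.normal(0.0, params.additive_noise_sd, n_total)
    trace = AccelTrace(
        sensor_id="T2", sampling_rate=fs, t=np.arange(n_total) / fs, ax=ax, ay=ay, az=az
    )
    return trace, boundaries


def _lorenz_deriv(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def simulate_lorenz(
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    n: int = 30000,
    initial_state: np.ndarray | None = None,
    seed: int | None = None,
    transient: float = 10.0,
) -> np.ndarray:
    """First coordinate of the Lorenz system, fixed-step RK4, transient discarded."""
    if dt > 0.01 + 1e-12 and rho >= 24:
        raise ValueError("dt must be <= 0.01 for the chaotic parameter regime")
    state = np.array([1.0, 1.0, 1.0]) if initial_state is None else np.array(initial_state, float)
    if seed is not None:
        state = state + np.random.default_rng(seed).normal(0.0, 1e-3, 3)
    n_transient = int(round(transient / dt))
    out = np.empty(n)
    for i in range(n_transient + n):
        k1 = _lorenz_deriv(state, sigma, rho, beta)
        k2 = _lorenz_deriv(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_deriv(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_deriv(state + dt * k3, sigma, rho, beta)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError("Lorenz integration diverged")
        if i >= n_transient:
            out[i - n_transient] = state[0]
    return out


def benettin_lyapunov(
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    n_steps: int = 50000,
    seed: int = 0,
    transient: float = 10.0,
) -> float:
    """Largest Lyapunov exponent via tangent-space integration with renormalization.

    Independent oracle for the Kantz estimator: the trajectory and a
    tangent vector (propagated by the Jacobian) are integrated together;
    the tangent vector is renormalized each step and the average log
    stretch per unit time is returned (≈0.906 for the standard
    parameters).
    """
    rng = np.random.default_rng(seed)
    state = np.array([1.0, 1.0, 1.0]) + rng.normal(0.0, 1e-3, 3)

    def jac(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0], [rho - z, -1.0, -x], [y, x, -beta]])

    def step(s: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k1, j1 = _lorenz_deriv(s, sigma, rho, beta), jac(s) @ v
        s2 = s + 0.5 * dt * k1
        k2, j2 = _lorenz_deriv(s2, sigma, rho, beta), jac(s2) @ (v + 0.5 * dt * j1)
        s3 = s + 0.5 * dt * k2
        k3, j3 = _lorenz_deriv(s3, sigma, rho, beta), jac(s3) @ (v + 0.5 * dt * j2)
        s4 = s + dt * k3
        k4, j4 = _lorenz_deriv(s4, sigma, rho, beta), jac(s4) @ (v + dt * j3)
        return (
            s + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4),
            v + dt / 6.0 * (j1 + 2 * j2 + 2 * j3 + j4),
        )

    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    for _ in range(int(round(transient / dt))):
        state, v = step(state, v)
        v /= np.linalg.norm(v)
    log_sum = 0.0
    for _ in range(n_steps):
        state, v = step(state, v)
        nv = np.linalg.norm(v)
        log_sum += math.log(nv)
        v /= nv
    return log_sum / (n_steps * dt)


def simulate_cohort(
    n: int,
    sex_ratio: float = 0.5,
    group_probabilities: tuple[float, float, float] = DEFAULT_GROUP_PROBS,
    effect_specs: dict | None = None,
    noise_sd: float | dict = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Participant table with known additive effects on outcome metrics.

    ``effect_specs`` maps outcome name → dict with keys ``baseline``,
    ``sex`` (female − male difference), ``pain`` (dict per group) and
    ``chronic``; outcomes are drawn as baseline + effects + N(0,
    noise_sd).  Pain ratings are integers consistent with the intended
    group (ASY: all zero; LMP: 1–4 → CPI 10–40; MHP: 5–10 → CPI 50–100).
    """
    if abs(sum(group_probabilities) - 1.0) > 1e-9 or min(group_probabilities) < 0:
        raise ValueError("group probabilities must be non-negative and sum to 1")
    if n < 6:
        raise ValueError("need at least one participant per design cell")
    if effect_specs is None:
        effect_specs = {"outcome": {"baseline": 0.0}}
    rng = np.random.default_rng(seed)

    # guarantee nonempty cells, then fill multinomially
    sexes = ["male", "female"] * 3
    groups = ["ASY", "LMP", "MHP"] * 2
    extra_sex = rng.choice(["male", "female"], n - 6, p=[1 - sex_ratio, sex_ratio])
    extra_grp = rng.choice(["ASY", "LMP", "MHP"], n - 6, p=group_probabilities)
    sex = np.concatenate([sexes, extra_sex])
    grp = np.concatenate([groups, extra_grp])
    order = rng.permutation(n)
    sex, grp = sex[order], grp[order]

    rows = []
    for i in range(n):
        if grp[i] == "ASY":
            ratings = (0, 0, 0)
            duration = 0.0
        elif grp[i] == "LMP":
            ratings = tuple(rng.integers(1, 5, 3))
            duration = float(rng.integers(1, 105))
        else:
            ratings = tuple(rng.integers(5, 11, 3))
            duration = float(rng.integers(1, 105))
        rows.append(
            {
                "id": f"P{i:04d}",
                "sex": sex[i],
                "pain_now": int(ratings[0]),
                "pain_avg": int(ratings[1]),
                "pain_worst": int(ratings[2]),
                "pain_duration_weeks": duration,
            }
        )
    df = pd.DataFrame(rows)
    from trunkmotion.cohort import characteristic_pain_intensity, classify_chronicity

    cpi = df.apply(
        lambda r: characteristic_pain_intensity(r.pain_now, r.pain_avg, r.pain_worst), axis=1
    )
    chronic = np.array(
        [classify_chronicity(d, c) for d, c in zip(df.pain_duration_weeks, cpi)], dtype=float
    )
    for outcome, spec in effect_specs.items():
        sd = noise_sd[outcome] if isinstance(noise_sd, dict) else noise_sd
        vals = np.full(n, float(spec.get("baseline", 0.0)))
        vals += np.where(sex == "female", 0.5, -0.5) * float(spec.get("sex", 0.0))
        pain_eff = spec.get("pain", {})
        vals += np.array([float(pain_eff.get(g, 0.0)) for g in grp])
        vals += chronic * float(spec.get("chronic", 0.0))
        vals += rng.normal(0.0, sd, n)
        df[outcome] = vals
    return df


def cohort_records(df: pd.DataFrame, outcomes: list[str]) -> list[ParticipantRecord]:
    """Convert a participant table to :class:`ParticipantRecord` objects."""
    return [
        ParticipantRecord(
            id=str(r.id),
            sex=str(r.sex),
            pain_now=int(r.pain_now),
            pain_avg=int(r.pain_avg),
            pain_worst=int(r.pain_worst),
            pain_duration_weeks=float(r.pain_duration_weeks),
            outcomes={k: float(getattr(r, k)) for k in outcomes},
        )
        for r in df.itertuples(index=False)
    ]
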