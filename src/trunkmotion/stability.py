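"""Local dynamic stability and variability of cyclic trunk movement.

The analysis chain starts from the T2 accelerometer during a cyclic
pointing task (nominally 0.17 Hz, 32 cycles):

1. low-pass at 20 Hz, subtract the per-axis minima, take the Euclidean
   norm, demean → one-dimensional series ``x(t)``;
2. detect cycle boundaries, keep 30 cycles, time-normalize each to 600
   points (18,000 total);
3. reconstruct state space by delay embedding
   ``S(t) = [x(t), x(t+τ), …, x(t+(m−1)τ)]`` with τ from the first local
   minimum of the average mutual information and m from global false
   nearest neighbors;
4. compute the maximum finite-time Lyapunov exponent λ_max with the
   Kantz algorithm: for every reference point with neighbors inside a
   radius ε (temporal neighbors excluded by a Theiler window), track the
   log of the mean distance to the neighbors' forward images and fit a
   line to the averaged ln(divergence) curve over the first 40 samples;
5. compute MeanSD variability: cycles normalized to 101 points, the
   across-cycle standard deviation at each point, averaged.

Higher λ_max means initially neighboring trajectories separate faster —
the trunk responds less stably to perturbations.  λ_max is reported per
normalized sample (600 samples per cycle) unless the caller converts it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.neighbors import KDTree

from trunkmotion.signal_io import AccelTrace

logger = logging.getLogger(__name__)

POINTS_PER_CYCLE = 600
USED_CYCLES = 30


@dataclass(frozen=True)
class NormSeries:
    """Demeaned acceleration-norm series after per-cycle time normalization."""

    x: np.ndarray
    n_cycles: int
    points_per_cycle: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.x.size != self.n_cycles * self.points_per_cycle:
            raise ValueError("length must equal n_cycles * points_per_cycle")
        if abs(self.x.mean()) > 1e-9 * max(1.0, np.abs(self.x).max()):
            raise ValueError("series must be demeaned")


@dataclass(frozen=True)
class Embedding:
    """Delay-coordinate state-space reconstruction."""

    m: int
    tau: int
    vectors: np.ndarray  # shape (n_vectors, m)

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")


@dataclass(frozen=True)
class DivergenceCurve:
    """Averaged log-divergence curve and its fitted slope (λ_max)."""

    k: np.ndarray
    ln_div: np.ndarray
    fit_range: tuple[int, int]
    lambda_max: float
    n_reference: int
    epsilon: float
    r_squared: float


@dataclass(frozen=True)
class VariabilityResult:
    """Across-cycle standard deviation profile and its mean (MeanSD)."""

    per_point_sd: np.ndarray
    mean_sd: float


def acceleration_norm_series(trace: AccelTrace) -> np.ndarray:
    """One-dimensional norm series: per-axis minima subtracted, norm, demeaned."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    ax = trace.ax - trace.ax.min()
    ay = trace.ay - trace.ay.min()
    az = trace.az - trace.az.min()
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    return norm - norm.mean()


def select_task_cycles(
    series: np.ndarray,
    sampling_rate: float,
    used_cycles: int = USED_CYCLES,
    nominal_rate: float = 0.17,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect cycle boundaries and keep ``used_cycles`` central cycles.

    Boundaries are the valleys of the (lightly smoothed) norm series,
    seeded by the nominal cycle rate: peaks/valleys must be at least 60%
    of the nominal period apart.  Interior valleys delimit complete
    cycles, so the partially observed first and last cycles drop out
    naturally; if more complete cycles remain, the trim is symmetric
    (front first).

    Returns
    -------
    trimmed : ndarray
        ``series`` restricted to the retained cycles.
    boundaries : ndarray of int
        ``used_cycles + 1`` indices into *the original series*; cycle
        ``i`` spans ``boundaries[i] .. boundaries[i+1]``.
    """
    series = np.asarray(series, dtype=float)
    period = sampling_rate / nominal_rate
    # light smoothing for robust valley picking (~5% of a cycle)
    w = max(int(round(period * 0.05)) | 1, 1)
    if w > 1:
        kernel = np.ones(w) / w
        smooth = np.convolve(series, kernel, mode="same")
    else:
        smooth = series
    valleys, _ = find_peaks(-smooth, distance=int(0.6 * period))
    n_complete = valleys.size - 1
    if n_complete < used_cycles:
        raise ValueError(
            f"detected only {max(n_complete, 0)} complete cycles; need {used_cycles}"
        )
    extra = n_complete - used_cycles
    start = (extra + 1) // 2
    boundaries = valleys[start : start + used_cycles + 1]
    trimmed = series[boundaries[0] : boundaries[-1] + 1]
    return trimmed, boundaries


def time_normalize_series(
    series: np.ndarray,
    boundaries: np.ndarray,
    points_per_cycle: int = POINTS_PER_CYCLE,
) -> NormSeries:
    """Resample each cycle to ``points_per_cycle`` and concatenate, then demean.

    Thirty cycles at 600 points each give the 18,000-sample series used
    for state-space reconstruction.
    """
    series = np.asarray(series, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    n_cycles = boundaries.size - 1
    out = np.empty(n_cycles * points_per_cycle)
    grid = np.arange(points_per_cycle) / points_per_cycle  # [0, 1)
    for i in range(n_cycles):
        seg = series[boundaries[i] : boundaries[i + 1] + 1]
        if seg.size < 2:
            raise ValueError(f"cycle {i} has fewer than 2 samples")
        src = np.linspace(0.0, 1.0, seg.size)
        out[i * points_per_cycle : (i + 1) * points_per_cycle] = np.interp(grid, src, seg)
    out -= out.mean()
    return NormSeries(x=out, n_cycles=n_cycles, points_per_cycle=points_per_cycle)


def _equiprobable_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Map samples to quantile-bin indices 0..bins-1 (ties broken by order)."""
    n = x.size
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks * bins) // n


def average_mutual_information(
    x: np.ndarray,
    max_lag: int,
    bins: int = 32,
    min_prominence: float = 0.02,
) -> tuple[np.ndarray, int]:
    """AMI curve (nats) for lags 0..max_lag and the first-local-minimum lag.

    The joint distribution of ``(x(t), x(t+L))`` is estimated on a
    bins × bins grid with equiprobable (quantile) margins.  The returned
    lag is the first local minimum of the curve whose prominence exceeds
    ``min_prominence`` nats — shallow dips of the order of the
    finite-sample estimator noise (~(B−1)²/2n nats) are not embedding
    delays.  If no such minimum exists up to ``max_lag``, the plain
    ``AMI(L−1) > AMI(L) < AMI(L+1)`` rule is tried; failing that,
    ``max_lag`` is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero entropy; AMI undefined")
    if x.size <= max_lag + 1:
        raise ValueError("series too short for the requested maximum lag")
    b = _equiprobable_bins(x, bins)
    ami = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        b0 = b[: x.size - lag]
        b1 = b[lag:]
        joint = np.bincount(b0 * bins + b1, minlength=bins * bins).astype(float)
        joint /= joint.sum()
        px = joint.reshape(bins, bins).sum(axis=1)
        py = joint.reshape(bins, bins).sum(axis=0)
        outer = np.outer(px, py).ravel()
        nz = joint > 0
        ami[lag] = float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))
    minima, _ = find_peaks(-ami, prominence=min_prominence)
    minima = minima[minima >= 1]
    if minima.size:
        return ami, _refine_minimum(ami, int(minima[0]))
    for lag in range(1, max_lag):
        if ami[lag - 1] > ami[lag] < ami[lag + 1]:
            return ami, lag
    logger.warning("no AMI local minimum up to lag %d; returning max_lag", max_lag)
    return ami, max_lag


def _refine_minimum(ami: np.ndarray, lag0: int) -> int:
    """Center of the AMI minimum's basin: smoothed argmin around the raw dip.

    Near a broad flat minimum the raw pointwise argmin jitters with the
    estimator noise; the delay reported is the argmin of the curve
    smoothed over ~lag0/4 within ±lag0/4 of the first prominent dip.
    """
    w = max(int(round(lag0 / 4)) | 1, 1)
    half = max(int(round(lag0 / 4)), 1)
    if w <= 1:
        return lag0
    kernel = np.ones(w) / w
    padded = np.pad(ami, w, mode="edge")
    smooth = np.convolve(padded, kernel, mode="same")[w:-w]
    lo = max(lag0 - half, 1)
    hi = min(lag0 + half, ami.size - 1)
    return lo + int(np.argmin(smooth[lo : hi + 1]))


def delay_embed(x: np.ndarray, m: int, tau: int) -> Embedding:
    """Delay-coordinate embedding ``S(t) = [x(t), x(t+τ), …, x(t+(m−1)τ)]``."""
    x = np.asarray(x, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be >= 1")
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise ValueError(
            f"series of length {x.size} too short for m={m}, tau={tau}"
        )
    vectors = np.column_stack([x[j * tau : j * tau + n_vec] for j in range(m)])
    return Embedding(m=m, tau=tau, vectors=vectors)


def global_false_nearest_neighbors(
    x: np.ndarray,
    tau: int,
    m_max: int,
    ratio_threshold: float = 15.0,
    size_threshold: float = 2.0,
    accept_fraction: float = 0.05,
    theiler: int | None = None,
    n_query: int = 64,
) -> tuple[np.ndarray, int | None]:
    """Kennel-style global false-nearest-neighbor fractions for m = 1..m_max.

    A neighbor pair in m dimensions is *false* when adding the (m+1)-th
    delay coordinate inflates the distance by more than
    ``ratio_threshold``, or when the (m+1)-dimensional distance exceeds
    ``size_threshold`` standard deviations of the series (the loneliness
    criterion — without it, iid noise spuriously "embeds" at small m).
    The minimal sufficient dimension is the first m whose fraction drops
    below ``accept_fraction``; ``None`` if no m qualifies.
    """
    x = np.asarray(x, dtype=float)
    if theiler is None:
        theiler = tau
    sigma = x.std()
    if sigma == 0:
        raise ValueError("constant series")
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        n_vec = x.size - m * tau  # vectors that also have the (m+1)-th coordinate
        if n_vec < 100:
            raise ValueError(f"too few vectors ({n_vec}) for FNN at m={m}")
        emb = delay_embed(x, m, tau).vectors[:n_vec]
        extra = x[m * tau : m * tau + n_vec]
        tree = KDTree(emb)
        k = min(n_query, n_vec)
        dist, idx = tree.query(emb, k=k)
        false = 0
        total = 0
        for i in range(n_vec):
            valid = np.abs(idx[i] - i) > theiler
            if not np.any(valid):
                continue
            j = idx[i][valid][0]
            d_m = dist[i][valid][0]
            d_extra = abs(extra[i] - extra[j])
            d_m1 = np.hypot(d_m, d_extra)
            if d_m < 1e-8 * sigma:
                # duplicate points up to float rounding: the ratio test is
                # meaningless there; only a genuinely large separation counts
                is_false = d_extra / sigma > size_threshold
            else:
                is_false = (d_extra / d_m > ratio_threshold) or (
                    d_m1 / sigma > size_threshold
                )
            false += bool(is_false)
            total += 1
        if total == 0:
            raise ValueError(f"no valid neighbor pairs at m={m} (Theiler window too wide)")
        fractions[m - 1] = false / total
    below = np.flatnonzero(fractions < accept_fraction)
    minimal_m = int(below[0]) + 1 if below.size else None
    return fractions, minimal_m


def kantz_lyapunov(
    embedding: Embedding,
    fit_lo: int = 0,
    fit_hi: int = 40,
    epsilon: float | None = None,
    epsilon_factor: float = 0.05,
    theiler: int | None = None,
    k_max: int | None = None,
    max_neighbors: int = 25,
    min_valid_fraction: float = 0.7,
    max_escalations: int = 3,
) -> DivergenceCurve:
    """Maximum finite-time Lyapunov exponent via the Kantz algorithm.

    For every reference vector with at least one neighbor inside radius
    ``epsilon`` (temporal neighbors within the Theiler window excluded),
    the log of the mean distance between the forward images of reference
    and neighbors is tracked over offsets ``k = 0..k_max`` and averaged
    across references; λ_max is the least-squares slope of this curve
    over ``[fit_lo, fit_hi]``, in units of ln-divergence per sample.

    ``epsilon`` defaults to ``epsilon_factor`` × the standard deviation
    of the embedded series and doubles (up to ``max_escalations`` times)
    until at least ``min_valid_fraction`` of references have a neighbor.
    Neighbor sets are capped at the ``max_neighbors`` nearest inside the
    radius to bound runtime.
    """
    V = embedding.vectors
    n = V.shape[0]
    if n < 500:
        raise ValueError(f"embedding has only {n} vectors; need >= 500")
    if k_max is None:
        k_max = fit_hi
    if k_max < fit_hi:
        raise ValueError("k_max must be >= fit_hi")
    if theiler is None:
        theiler = (embedding.m - 1) * embedding.tau
    sigma = V.std()
    eps = epsilon if epsilon is not None else epsilon_factor * sigma
    if eps <= 0:
        raise ValueError("epsilon must be positive")

    ref_max = n - 1 - k_max  # references must have forward images
    refs = np.arange(ref_max + 1)
    tree = KDTree(V[: ref_max + 1 + k_max])  # neighbors also need forward images

    tried: list[float] = []
    for _ in range(max_escalations + 1):
        tried.append(eps)
        ind = tree.query_radius(V[refs], r=eps)
        ref_ids: list[np.ndarray] = []
        nbr_ids: list[np.ndarray] = []
        n_valid = 0
        for i, neighbors in zip(refs, ind):
            neighbors = neighbors[
                (np.abs(neighbors - i) > theiler) & (neighbors <= ref_max)
            ]
            if neighbors.size == 0:
                continue
            if neighbors.size > max_neighbors:
                d = np.linalg.norm(V[neighbors] - V[i], axis=1)
                neighbors = neighbors[np.argsort(d)[:max_neighbors]]
            ref_ids.append(np.full(neighbors.size, i))
            nbr_ids.append(neighbors)
            n_valid += 1
        if n_valid >= min_valid_fraction * refs.size:
            break
        eps *= 2.0
    if n_valid == 0:
        raise ValueError(
            f"no reference point has neighbors; radii tried: {tried}"
        )

    I = np.concatenate(ref_ids)
    J = np.concatenate(nbr_ids)
    # compact reference ids for per-reference averaging
    uniq, inv = np.unique(I, return_inverse=True)
    counts = np.bincount(inv).astype(float)

    k_offsets = np.arange(k_max + 1)
    ln_div = np.empty(k_max + 1)
    floor = 1e-12 * max(sigma, 1e-30)
    for k in k_offsets:
        d = np.linalg.norm(V[I + k] - V[J + k], axis=1)
        mean_d = np.bincount(inv, weights=d) / counts
        ln_div[k] = np.log(np.maximum(mean_d, floor)).mean()

    fit_k = k_offsets[fit_lo : fit_hi + 1]
    fit_y = ln_div[fit_lo : fit_hi + 1]
    slope, intercept = np.polyfit(fit_k, fit_y, 1)
    resid = fit_y - (slope * fit_k + intercept)
    ss_tot = np.sum((fit_y - fit_y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return DivergenceCurve(
        k=k_offsets,
        ln_div=ln_div,
        fit_range=(fit_lo, fit_hi),
        lambda_max=float(slope),
        n_reference=int(n_valid),
        epsilon=float(eps),
        r_squared=float(r2),
    )


def mean_sd_variability(
    series: np.ndarray,
    boundaries: np.ndarray,
    points_per_cycle: int = 101,
) -> VariabilityResult:
    """MeanSD: mean over cycle time of the across-cycle standard deviation.

    Each cycle of the raw (non-18,000-normalized) norm series is
    resampled to 101 points (0%–100%); the sample standard deviation
    (n−1 denominator) is taken across cycles at every point and averaged.
    Cycles are the half-open segments between consecutive boundaries
    (each cycle owns the samples up to, excluding, the next boundary).
    """
    series = np.asarray(series, dtype=float)
    boundaries = np.asarray(boundaries, dtype=int)
    n_cycles = boundaries.size - 1
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles for variability")
    grid = np.linspace(0.0, 1.0, points_per_cycle)
    stack = np.empty((n_cycles, points_per_cycle))
    for i in range(n_cycles):
        seg = series[boundaries[i] : boundaries[i + 1]]
        if seg.size < 2:
            raise ValueError(f"cycle {i} has fewer than 2 samples")
        stack[i] = np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg)
    per_point_sd = stack.std(axis=0, ddof=1)
    return VariabilityResult(per_point_sd=per_point_sd, mean_sd=float(per_point_sd.mean()))


def analyze_pointing_trial(
    trace: AccelTrace,
    tau: int | None = None,
    m: int | None = None,
    m_max: int = 6,
    max_lag: int | None = None,
    used_cycles: int = USED_CYCLES,
    nominal_rate: float = 0.17,
) -> dict:
    """Full stability pipeline for one pointing-task trace.

    The trace is expected to be low-pass filtered at 20 Hz already.
    Returns a dict with tau, m, lambda_max (per normalized sample), the
    divergence curve, FNN fractions, and mean_sd.  ``tau``/``m`` override
    the automatic AMI/FNN selection when given.
    """
    raw = acceleration_norm_series(trace)
    trimmed, boundaries = select_task_cycles(
        raw, trace.sampling_rate, used_cycles=used_cycles, nominal_rate=nominal_rate
    )
    norm = time_normalize_series(trimmed, boundaries - boundaries[0])
    if max_lag is None:
        max_lag = norm.points_per_cycle // 2
    ami, tau_auto = average_mutual_information(norm.x, max_lag=max_lag)
    tau_use = tau if tau is not None else tau_auto
    fnn, m_auto = global_false_nearest_neighbors(norm.x, tau=tau_use, m_max=m_max)
    m_use = m if m is not None else (m_auto if m_auto is not None else m_max)
    emb = delay_embed(norm.x, m=m_use, tau=tau_use)
    theiler = (m_use - 1) * tau_use + norm.points_per_cycle // 2
    curve = kantz_lyapunov(emb, theiler=theiler)
    var = mean_sd_variability(raw, boundaries)
    return {
        "tau": tau_use,
        "tau_ami": tau_auto,
        "m": m_use,
        "fnn_fractions": fnn,
        "lambda_max": curve.lambda_max,
        "divergence": curve,
        "mean_sd": var.mean_sd,
        "variability": var,
        "norm_series": norm,
        "boundaries": boundaries,
    }
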