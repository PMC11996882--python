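# Methods

## Inclinometry from the gravity vector

During slow trunk flexion the dynamic acceleration is small compared to
gravity, so a body-fixed accelerometer measures (to first order) the
gravity unit vector in its local frame. The sagittal inclination is
`atan2(a_AP, a_long)`; the mediolateral axis is ignored (the task is
planar) and mediolateral tilt is not corrected — a second-order effect
for this movement. The quasi-static assumption is *enforced*, not just
assumed: a trial is rejected whenever the filtered acceleration norm
leaves 1 ± 0.10 g (config `gate.tolerance_g`). Angle extraction is
invariant to a common scaling of all axes, so small calibration errors
in overall gain do not bias angles.

Processing chain, in order: 5 Hz 2nd-order zero-phase Butterworth
(forward–backward `sosfiltfilt`, reflective padding of 3× the effective
filter length), 500 ms centered moving average on the accelerations,
gravity gate, angle extraction, 500 ms centered moving average on the
angles. The width of the second (angle-domain) moving average is not
fixed by the measurement protocol; it defaults to 500 ms and is a
parameter. Moving-average edges use truncated (shrinking) windows so no
data are fabricated at trial boundaries.

## Flexion-cycle segmentation and its ground truth

A cycle ends at a trunk-angle maximum (local maxima ≥ 2 s apart and
above 50% of the global range; flat maxima resolve to their earliest
sample, and a maximum held to the end of a recording counts). The start
is found by scanning backward from the peak: first across the near-peak
deceleration zone (where the 100 ms secant slope has already fallen
below 0.1° per increment), then down the main rise to the last sample
still below threshold — the quiet-standing/movement boundary. Cycles
are resampled to 1,000 points by linear interpolation, averaged
pointwise into a mean trial, and all metrics are computed on the mean
trial (matching the protocol order: normalize, average, then measure).

Two consequences of this rule matter for validation and are mirrored in
the simulator's analytic ground truth:

1. *The start is a threshold construct.* For a trajectory with a gentle
   (minimum-jerk) onset, the 0.1°/100 ms crossing occurs a few hundred
   milliseconds after the prescribed onset; for a steep onset the
   500 ms smoothing smears the rise backward into quiet standing. The
   ground-truth generator therefore applies the same secant rule to the
   smoothed prescribed trajectory, rather than labeling the prescribed
   onset as "the" start. With that construct, the pipeline recovers all
   angles within 1° and all durations within 1% of movement time across
   the tested sweep (pelvic RoM 40–90°, standing lumbar −35° to −10°,
   transition at 20–80%), and within 2° at 0.02 g sensor noise.
2. *A dwell at maximal flexion makes "movement time" ill-defined* under
   the max-angle end rule (smoothing moves the detected end into the
   dwell). The simulator defaults to an immediate return
   (`hold_top = 0`).

Lumbo-pelvic ratios are quotients of angle changes; when a phase's
pelvic change is below 1e-6° the ratio is NaN rather than an extreme
value. In recovery tests LPRs are checked against the 1° angle accuracy
propagated through the quotient, `(1 + |LPR|)/|Δθ_pelvic| × 1°`: with a
phase pelvic excursion of only ~2° (early transitions at small pelvic
RoM) the ratio is intrinsically ill-conditioned and no estimator can do
better than that bound.

## Simulators

*Flexion*: pelvic angle = standing value + RoM × minimum-jerk profile
(10u³ − 15u⁴ + 6u⁵); lumbar angle follows a power-law time warp of the
same profile, `l0 + RoM_l · s(u^β)`, with β chosen so the lumbar zero
crossing lands exactly at the prescribed transition fraction while
keeping zero velocity at both ends. Trunk = pelvic + lumbar. Sensor
output is the gravity unit vector rotated by the segment angle plus
white noise; kinematic (non-gravity) acceleration is omitted — the same
slow-movement assumption the measurement itself relies on, so a green
recovery test validates the processing chain, not the gate's ability to
catch fast movements. Defaults describe a typical adult trial: standing
pelvic tilt 8°, standing lordosis −25°, pelvic RoM 70°, lumbar RoM 45°,
8 s per flexion, 3 repetitions, 3 s rests.

*Pointing task*: a fixed three-harmonic cycle waveform (minimum at
phase 0) at 0.17 Hz, 32 cycles, with per-cycle amplitude factors
(1 + N(0, amplitude_jitter)), per-cycle period perturbations, optional
Lorenz-driven amplitude modulation (`chaos_coupling`), additive noise;
written onto the three axes around a 1 g baseline. Exact cycle
boundaries are returned. What it does **not** emulate: drift in sensor
orientation, movement-strategy changes across cycles, or broadband
physiological tremor — green tests establish estimator correctness on
controlled dynamics, not clinical equivalence.

*Lorenz / Benettin*: fixed-step RK4 integration (dt ≤ 0.01 enforced in
the chaotic regime, 10-time-unit transient discarded). The independent
λ reference propagates a tangent vector through the Jacobian with
per-step renormalization; at (σ=10, ρ=28, β=8/3) it reproduces the
literature value ≈ 0.906 per time unit.

*Cohort*: sex and pain-group labels (default group weights 0.17 / 0.61 /
0.22, emulating a large mixed low-back-pain sample) with integer pain
ratings consistent with each group's CPI band (LMP draws 1–4 → CPI
10–40; MHP draws 5–10 → CPI 50–100); one participant per design cell is
guaranteed. Outcomes are baseline + additive sex / pain / chronicity
effects + Gaussian noise.

## Average mutual information and the embedding delay

AMI(L) is computed from a 32 × 32 joint histogram of (x(t), x(t+L))
with equiprobable (quantile) margins, in nats. Its finite-sample bias
for independent data is ≈ (B−1)²/(2n) ≈ 0.027 nats at n = 18,000 — the
iid test bound (0.035) was frozen from Monte-Carlo runs of this
estimator, not assumed.

The delay is the first *prominent* local minimum (prominence
≥ 0.02 nats), refined to the center of the minimum's basin by a
smoothed argmin over ±L/4: near a broad flat minimum the raw pointwise
argmin jitters with estimator noise. A caveat found during validation:
for an *exactly periodic, noise-free* signal sampled commensurately
(e.g. a pure sinusoid at exactly 600 points/period) the joint
distribution degenerates to a few hundred lattice points and every
coarse-grained MI estimate develops deep spurious dips at small lags —
the quarter-period minimum is unrecoverable in principle for this
estimator class. With a realistic noise floor (≥ ~5% of amplitude) the
quarter-period minimum is recovered within ±5 samples across seeds;
tests therefore validate the noisy case and treat the noise-free
lattice signal as degenerate.

## False nearest neighbors

Kennel-style criteria per candidate dimension m: the nearest neighbor
(outside a Theiler window, default τ) is false when the added
(m+1)-th coordinate inflates the distance by more than R_tol = 15, or
when the (m+1)-dimensional distance exceeds A_tol = 2 standard
deviations of the series. The second (loneliness) criterion is what
keeps iid noise from spuriously "embedding" at small m. Neighbor pairs
whose m-dimensional distance is at machine precision (exact duplicates,
as in noise-free periodic signals) are judged only by the loneliness
criterion — the distance ratio is meaningless there. The minimal
sufficient dimension is the first m with false fraction < 5%.

## Kantz Lyapunov exponent

For every reference vector with ≥ 1 neighbor within radius ε (Theiler
window (m−1)τ, plus half a cycle for cyclic task data), the log of the
*mean* distance between the forward images of reference and neighbors
is averaged over references at each offset k; λ_max is the least-squares
slope over the fit range, in ln-divergence per sample.

Parameter choices (all config):

- ε defaults to 0.05 × the series SD, doubling up to 3 times until 70%
  of references have a neighbor. A radius of 0.5 SD (a plausible first
  guess) proved far too coarse on the Lorenz benchmark — the divergence
  curve starts near saturation and the slope underestimates λ badly.
- Neighbor sets are capped at the 25 nearest inside ε (runtime bound;
  results are insensitive well above ~10).
- A distance floor of 1e-12 ε keeps exact-duplicate pairs (noise-free
  periodic data) from producing −∞ logs; a flat floored curve correctly
  yields λ ≈ 0.
- The fit range must lie in the scaling region. For the pointing-task
  protocol this is offsets 0–40 of the 600-per-cycle normalized series
  (the protocol's own convention, kept as the default). For the Lorenz
  benchmark at dt = 0.01 the first ~0.7 time units are an oscillatory
  alignment transient; the validation fits 75–250 samples (0.75–2.5
  time units), where the curve is linear (r² > 0.99). With that window
  the Kantz estimate agrees with the Benettin oracle within 5% across
  seeds (15% is the acceptance bound).

λ_max is reported per normalized sample. Published trunk-stability
values (≈ 2.5 at 600 samples/cycle over a 0–40 fit) carry an unstated
internal normalization, so no absolute numerical comparison with them
is attempted — validation rests on the known-system oracle, invariance
properties (scale/shift), and the monotone jitter → λ_max dose–response.

## MeanSD

Cycles of the *raw* norm series (not the 18,000-point normalized one)
are the half-open segments between consecutive boundaries, resampled to
101 points; MeanSD is the mean over the 101 points of the across-cycle
sample SD (n−1). Half-open segments make "30 identical cycles → MeanSD
exactly 0" hold exactly. Note that resampling attenuates white
per-sample noise slightly unless the 101-point grid lands on integer
samples; estimator-consistency tests use cycle lengths of 401 samples
(grid stride 4) so the injected noise SD is recovered unattenuated.

## Cycle selection for the pointing task

Boundaries are valleys of the lightly smoothed (5% of a nominal period)
norm series, at least 60% of the nominal period apart. Interior valleys
delimit complete cycles, so the partially recorded first and last
cycles drop out naturally; any surplus beyond 30 cycles is trimmed
symmetrically (front first). Which 2 of the 32 performed cycles to
discard is not fixed by the protocol; dropping the first and last
(familiarization/termination) is the least arbitrary choice.

## Factorial statistics and power

The factorial model is ordinary (optionally cell-variance-reweighted)
least squares — `outcome ~ sex * pain_group + chronic` with sum-to-zero
contrasts and Type-II F tests (no interaction-contaminated main effects
in unbalanced data). The reweighted mode iterates per-cell variance
estimation to convergence (tol 1e-6, ≤ 50 iterations) as a pragmatic
stand-in for a heteroscedastic GLS variance structure; exact
replication of published mixed-model p-values is out of scope. A
degenerate (constant) outcome returns F = 0, p = 1 for every effect
rather than noise-level statistics. BH correction is applied within
each outcome's effect family; the family definition is the caller's
choice.

Sample size: smallest integer N with
`1 − F_ncf(F_crit(α; df1, N−k); df1, N−k, f²·N) ≥ power`, i.e. the
noncentrality convention λ = f²·N (the G*Power fixed-effects ANOVA
convention, *not* f²·(N−k)). CPI grouping assigns any 0 < CPI < 50 to
LMP (ratings are integers, so CPI is a multiple of 10/3 and the open
interval (0, 10/3) is never realized).

## Known limitations

- No 3-D orientation estimation: pure sagittal-plane inclinometry; out
  of plane motion and dynamic acceleration beyond the gate are not
  compensated.
- The flexion simulator's ground truth is defined through the same
  start rule the detector uses (applied analytically to the prescribed
  trajectory); it validates internal consistency of the chain, not the
  rule's agreement with some other onset definition.
- λ_max units are per normalized sample and comparable only within a
  fixed protocol (cycle count, points per cycle, fit range).
- The cell-weighted fit is not a full GLS covariance model; p-values
  under strong heteroscedasticity are approximate.
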