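# trunkmotion

Accelerometer-based analysis of trunk movement for low-back-pain
biomechanics: lumbo-pelvic kinematics during slow trunk flexion,
nonlinear dynamic stability of cyclic trunk movement, and the cohort
statistics around them — with a synthetic-data generator standing in for
raw laboratory recordings so that every stage of the pipeline is
testable against known ground truth.

## What it computes

**Flexion kinematics.** Two tri-axial accelerometers (sacrum S1, T12)
record slow trunk forward bending at 500 Hz. Because the movement is
quasi-static, each sensor's output is the gravity vector in its local
frame, and the sagittal inclination is

θ = atan2(a_AP, a_long) · 180/π,

positive forward of vertical. The lumbar angle is θ_lumbar = θ_trunk −
θ_pelvic (negative = lordosis, positive = kyphosis). Signals are
low-pass filtered (5 Hz, 2nd-order zero-phase Butterworth), smoothed
(500 ms moving average), and trials are kept only when ‖a‖ stays within
1 ± 0.10 g. Three flexion cycles are segmented (end = trunk-angle
maximum; start = last sample whose 100 ms secant slope is below 0.1°),
time-normalized to 1,000 points and averaged; the mean trial yields
ranges of motion, lordosis durations, pelvic phase excursions, and
lumbo-pelvic ratios LPR = Δθ_lumbar / Δθ_pelvic per movement phase.

**Dynamic stability.** A T2 accelerometer records a cyclic pointing task
(0.17 Hz, 32 cycles). The demeaned acceleration-norm series x(t) (30
cycles, 600 points each after per-cycle time normalization) is embedded
by delay coordinates

S(t) = [x(t), x(t+τ), …, x(t+(m−1)τ)],

with τ from the first prominent minimum of the average mutual
information and m from global false nearest neighbors. The maximum
finite-time Lyapunov exponent λ_max is the slope of the Kantz averaged
ln-divergence curve of neighboring state-space trajectories; MeanSD is
the mean across-cycle standard deviation over 101 normalized time
points. Higher λ_max = locally less stable trunk control.

**Cohort statistics.** Characteristic pain intensity CPI = 10 × mean of
three 0–10 ratings; groups ASY (CPI = 0), LMP (1–49), MHP (≥ 50);
chronic = pain ≥ 12 weeks. Outcomes are analyzed with a two-way
factorial linear model (sex × pain group + chronicity covariate,
sum-to-zero coding, Type-II F tests), Benjamini–Hochberg correction, and
an a priori noncentral-F power computation (λ = f²·N).

## Worked example

```python
from trunkmotion import FlexionSimParams, simulate_flexion_trial
from trunkmotion.pipeline import flexion_pipeline

params = FlexionSimParams(pelvic_rom=70.0, standing_lumbar_angle=-25.0,
                          lumbar_rom=45.0, lordosis_transition_fraction=0.45)
s1, t12, truth = simulate_flexion_trial(params)
metrics, mean_cycle, cycles = flexion_pipeline(s1, t12)
print(f"trunk RoM  {metrics.trunk_RoM:6.2f}°  (prescribed {truth.trunk_RoM:6.2f}°)")
print(f"pelvic RoM {metrics.pelvic_RoM:6.2f}°  (prescribed {truth.pelvic_RoM:6.2f}°)")
print(f"LPR_full   {metrics.LPR_full:6.3f}   (prescribed {truth.LPR_full:6.3f})")
```

prints

```
trunk RoM  114.87°  (prescribed 114.98°)
pelvic RoM  69.96°  (prescribed  70.00°)
LPR_full    0.642   (prescribed  0.643)
```

i.e. the full measurement chain recovers the prescribed kinematics to a
tenth of a degree on noise-free input. The numbered scripts under
`analysis/` run the same pipelines at scale: `01` the power analysis,
`02` flexion-metric recovery across a parameter sweep, `03` the Lorenz
λ_max benchmark (Kantz vs tangent-space oracle, within a few percent)
and the jitter → λ_max dose–response, `04` factorial statistics on a
simulated cohort of 306; each writes its tables under `results/`.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the a priori sample sizes for the six-group design from the
noncentral-F distribution (f = 0.20, α = 0.05, power 0.8: the 2-df
pain/interaction contrast and the 1-df sex contrast) and writes them as
JSON.

## Layout

- `src/trunkmotion/` — library: `signal_io`, `inclinometry`, `flexion`,
  `stability`, `cohort`, `simulate`, `pipeline`
- `analysis/` — numbered narrative drivers writing to `results/`
- `tests/` — unit, property and end-to-end acceptance tests
- `docs/methods.md` — models, estimator choices, tolerances, limitations
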