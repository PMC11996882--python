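"""Factorial statistics on a simulated cohort with known injected effects.

Simulates a cohort of 306 participants (the recruited sample size of the
design the power analysis supports) with a sex effect injected into
trunk range of motion and a chronicity effect injected into the maximum
Lyapunov exponent, then fits the two-way factorial model (sex × pain
group + chronicity covariate) per outcome and applies Benjamini–Hochberg
correction across the effect family of each outcome.  Writes
results/cohort_stats.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from trunkmotion.cohort import bh_adjust, factorial_model
from trunkmotion.simulate import simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"

EFFECTS = {
    # degrees; females flex further (positive female-minus-male difference)
    "trunk_RoM": {"baseline": 108.0, "sex": 9.0},
    # dimensionless; chronic pain destabilizes trunk dynamics
    "lambda_max": {"baseline": 2.50, "chronic": 0.12},
    # m/s^2; no true effects
    "mean_sd": {"baseline": 0.37},
}
NOISE = {"trunk_RoM": 16.0, "lambda_max": 0.37, "mean_sd": 0.06}


def _pain(df: pd.DataFrame) -> np.ndarray:
    from trunkmotion.cohort import characteristic_pain_intensity, classify_pain_group

    return np.array(
        [
            classify_pain_group(
                characteristic_pain_intensity(r.pain_now, r.pain_avg, r.pain_worst)
            )
            for r in df.itertuples()
        ]
    )


def _chronic(df: pd.DataFrame) -> np.ndarray:
    from trunkmotion.cohort import characteristic_pain_intensity, classify_chronicity

    return np.array(
        [
            float(
                classify_chronicity(
                    r.pain_duration_weeks,
                    characteristic_pain_intensity(r.pain_now, r.pain_avg, r.pain_worst),
                )
            )
            for r in df.itertuples()
        ]
    )


def main() -> None:
    df = simulate_cohort(306, effect_specs=EFFECTS, noise_sd=NOISE, seed=20250918)
    pain, chronic = _pain(df), _chronic(df)
    rows = []
    for outcome in EFFECTS:
        res = factorial_model(df[outcome].to_numpy(), df["sex"].to_numpy(), pain, chronic)
        ps = {name: t.p for name, t in res.effects.items()}
        adj = bh_adjust(list(ps.values()))
        for (name, t), q in zip(res.effects.items(), adj):
            rows.append(
                {
                    "outcome": outcome,
                    "effect": name,
                    "F": round(t.F, 3),
                    "df_num": int(t.df_num),
                    "df_den": int(t.df_den),
                    "p": round(t.p, 4),
                    "p_bh": round(q, 4),
                }
            )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "cohort_stats.csv", index=False)
    print(table.to_string(index=False))
    sig = table[table.p_bh < 0.05]
    print(
        "\nBH-significant effects: "
        + (", ".join(f"{r.outcome}:{r.effect}" for r in sig.itertuples()) or "none")
        + "\n(injected truth: a 9° sex difference in trunk RoM and a 0.12 chronicity "
        "shift in λ_max against 0.37 residual sd — the latter is a small effect that "
        "a single cohort of 306 detects only sometimes; mean_sd carries no true effect)"
    )


if __name__ == "__main__":
    main()
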