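"""Pain scoring, cohort grouping, factorial statistics and power analysis.

Participants are scored by characteristic pain intensity (CPI): ten
times the mean of three 0–10 ratings (pain right now, average pain,
worst pain over the last three months), a 0–100 scale.  Groups: ASY
(CPI = 0), LMP (0 < CPI < 50), MHP (CPI ≥ 50).  Pain persisting 12 weeks
or longer counts as chronic.

Outcome metrics are analyzed with a fixed-effects two-way factorial
linear model — sex × pain group with interaction and a chronicity
covariate — using sum-to-zero factor coding and Type-II F tests
(optionally iteratively reweighted by per-cell variances).  Post-hoc
families are corrected by the Benjamini–Hochberg step-up procedure.
A priori sample sizes come from the noncentral-F power computation with
noncentrality λ = f²·N (the G*Power fixed-effects ANOVA convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

PAIN_GROUPS = ("ASY", "LMP", "MHP")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: pain scores, grouping, and outcome metrics."""

    id: str
    sex: str
    pain_now: int
    pain_avg: int
    pain_worst: int
    pain_duration_weeks: float
    outcomes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def cpi(self) -> float:
        return characteristic_pain_intensity(self.pain_now, self.pain_avg, self.pain_worst)

    @property
    def pain_group(self) -> str:
        return classify_pain_group(self.cpi)

    @property
    def chronic(self) -> bool:
        return classify_chronicity(self.pain_duration_weeks, self.cpi)


@dataclass(frozen=True)
class EffectTest:
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass(frozen=True)
class FactorialResult:
    """F tests for sex, pain group, interaction and chronicity covariate."""

    effects: dict  # name -> EffectTest
    residual_variance: float
    n: int
    weights: np.ndarray | None = None


@dataclass(frozen=True)
class PowerQuery:
    """A priori fixed-effects ANOVA power query (Cohen's f convention)."""

    effect_size_f: float
    alpha: float = 0.05
    power: float = 0.8
    n_groups: int = 6
    df_numerator: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size must be positive")
        if self.df_numerator < 1 or self.n_groups < 2:
            raise ValueError("df_numerator >= 1 and n_groups >= 2 required")


def characteristic_pain_intensity(now: int, avg: int, worst: int) -> float:
    """CPI: 10 × mean of the three 0–10 ratings (score 0–100)."""
    ratings = (now, avg, worst)
    for r in ratings:
        if r is None or not float(r).is_integer() or not 0 <= r <= 10:
            raise ValueError(f"pain ratings must be integers in [0, 10]; got {ratings}")
    return 10.0 * (now + avg + worst) / 3.0


def classify_pain_group(cpi: float) -> str:
    """ASY (cpi = 0), LMP (0 < cpi < 50) or MHP (cpi ≥ 50)."""
    if not 0 <= cpi <= 100:
        raise ValueError("cpi must be in [0, 100]")
    if cpi == 0:
        return "ASY"
    return "LMP" if cpi < 50 else "MHP"


def classify_chronicity(pain_duration_weeks: float, cpi: float) -> bool:
    """Chronic low-back pain: any pain (cpi > 0) persisting ≥ 12 weeks."""
    if pain_duration_weeks < 0:
        raise ValueError("pain duration cannot be negative")
    return cpi > 0 and pain_duration_weeks >= 12


def participants_to_frame(records: list[ParticipantRecord], outcome: str) -> pd.DataFrame:
    """Tidy DataFrame with sex, pain_group, chronic and one outcome column."""
    rows = []
    for r in records:
        if outcome not in r.outcomes:
            raise KeyError(f"participant {r.id} lacks outcome '{outcome}'")
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "pain_group": r.pain_group,
                "chronic": int(r.chronic),
                "outcome": r.outcomes[outcome],
            }
        )
    return pd.DataFrame(rows)


def factorial_model(
    outcome: np.ndarray,
    sex: np.ndarray,
    pain_group: np.ndarray,
    chronic: np.ndarray | None = None,
    cell_weights: bool = False,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> FactorialResult:
    """Two-way factorial linear model with interaction and chronicity covariate.

    Fits ``outcome ~ sex * pain_group (+ chronic)`` by least squares with
    sum-to-zero factor coding and reports Type-II Wald F tests per
    effect.  With ``cell_weights=True``, per-cell residual variances are
    estimated and the fit iteratively reweighted (a pragmatic stand-in
    for a heteroscedastic GLS variance structure) until the weights
    change by less than ``tol``.
    """
    df = pd.DataFrame(
        {
            "outcome": np.asarray(outcome, dtype=float),
            "sex": pd.Categorical(sex),
            "pain_group": pd.Categorical(pain_group),
        }
    )
    if not np.all(np.isfinite(df["outcome"])):
        raise ValueError("outcome contains non-finite values")
    cells = df.groupby(["sex", "pain_group"], observed=False).size()
    empty = cells[cells == 0]
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty.index)}")

    formula = "outcome ~ C(sex, Sum) * C(pain_group, Sum)"
    if chronic is not None:
        df["chronic"] = np.asarray(chronic, dtype=float)
        formula += " + chronic"

    outcome_arr = df["outcome"].to_numpy()
    if np.std(outcome_arr) <= 1e-12 * max(1.0, np.abs(outcome_arr).max()):
        # degenerate outcome: all effects vanish
        model = smf.ols(formula, data=df).fit()
        names = ["sex", "pain_group", "sex:pain_group"] + (
            ["chronic"] if chronic is not None else []
        )
        effects = {
            nm: EffectTest(F=0.0, df_num=1.0, df_den=float(model.df_resid), p=1.0)
            for nm in names
        }
        return FactorialResult(effects=effects, residual_variance=0.0, n=len(df))

    weights = np.ones(len(df))
    cell_idx = df.groupby(["sex", "pain_group"], observed=True).ngroup().to_numpy()
    fit = smf.ols(formula, data=df).fit()
    if cell_weights:
        for _ in range(max_iter):
            resid = fit.resid.to_numpy()
            cell_var = np.array(
                [resid[cell_idx == c].var(ddof=1) for c in range(cell_idx.max() + 1)]
            )
            new_w = 1.0 / cell_var[cell_idx]
            new_w /= new_w.mean()
            if np.max(np.abs(new_w - weights)) < tol:
                weights = new_w
                break
            weights = new_w
            fit = smf.wls(formula, data=df, weights=weights).fit()
        else:
            raise RuntimeError(
                f"cell-variance reweighting did not converge in {max_iter} iterations"
            )

    table = sm.stats.anova_lm(fit, typ=2)
    label_map = {
        "C(sex, Sum)": "sex",
        "C(pain_group, Sum)": "pain_group",
        "C(sex, Sum):C(pain_group, Sum)": "sex:pain_group",
        "chronic": "chronic",
    }
    df_resid = float(fit.df_resid)
    effects = {}
    for raw, name in label_map.items():
        if raw in table.index:
            row = table.loc[raw]
            effects[name] = EffectTest(
                F=float(row["F"]),
                df_num=float(row["df"]),
                df_den=df_resid,
                p=float(row["PR(>F)"]),
            )
    return FactorialResult(
        effects=effects,
        residual_variance=float(fit.mse_resid),
        n=len(df),
        weights=weights if cell_weights else None,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ncf_power(total_n: int, query: PowerQuery) -> float:
    """Power of the fixed-effects F test at total sample size ``total_n``."""
    df2 = total_n - query.n_groups
    if df2 < 1:
        return 0.0
    crit = stats.f.ppf(1.0 - query.alpha, query.df_numerator, df2)
    nc = query.effect_size_f**2 * total_n
    return float(1.0 - stats.ncf.cdf(crit, query.df_numerator, df2, nc))


def anova_sample_size(query: PowerQuery, n_max: int = 10**6) -> int:
    """Smallest total N reaching the target power of the noncentral-F test.

    N is incremented in steps of 1 from the minimum feasible size;
    denominator df is N − n_groups and the noncentrality is f²·N.
    """
    n = query.n_groups + query.df_numerator + 1
    while n <= n_max:
        if ncf_power(n, query) >= query.power:
            return n
        n += 1
    raise ValueError(f"target power not reachable with N <= {n_max}")
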