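"""Pain scoring, grouping, factorial models, BH correction and power analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trunkmotion.cohort import (
    PowerQuery,
    anova_sample_size,
    bh_adjust,
    characteristic_pain_intensity,
    classify_chronicity,
    classify_pain_group,
    factorial_model,
    ncf_power,
)


class TestPainScoring:
    @pytest.mark.parametrize(
        "ratings,expected", [((0, 0, 0), 0.0), ((5, 5, 5), 50.0), ((2, 3, 4), 30.0)]
    )
    def test_cpi_examples(self, ratings, expected):
        assert characteristic_pain_intensity(*ratings) == pytest.approx(expected)

    def test_out_of_range_rating_raises(self):
        with pytest.raises(ValueError):
            characteristic_pain_intensity(11, 0, 0)

    @pytest.mark.parametrize(
        "cpi,group", [(0.0, "ASY"), (30.0, "LMP"), (50.0, "MHP"), (10 / 3, "LMP"), (100.0, "MHP")]
    )
    def test_group_boundaries(self, cpi, group):
        assert classify_pain_group(cpi) == group

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_every_cpi_maps_to_exactly_one_group(self, a, b, c):
        cpi = characteristic_pain_intensity(a, b, c)
        group = classify_pain_group(cpi)
        assert group in ("ASY", "LMP", "MHP")
        assert (group == "ASY") == (cpi == 0)
        assert (group == "MHP") == (cpi >= 50)

    @pytest.mark.parametrize(
        "weeks,cpi,chronic", [(12, 30, True), (11, 30, False), (52, 0, False)]
    )
    def test_chronicity(self, weeks, cpi, chronic):
        assert classify_chronicity(weeks, cpi) is chronic


def _balanced_anova_oracle(y, A, B):
    """Textbook two-way ANOVA sums of squares for a balanced design."""
    y = np.asarray(y, float)
    a_levels, b_levels = sorted(set(A)), sorted(set(B))
    r = len(y) // (len(a_levels) * len(b_levels))
    ybar = y.mean()
    Ai = {a: y[np.array(A) == a].mean() for a in a_levels}
    Bj = {b: y[np.array(B) == b].mean() for b in b_levels}
    ss_a = sum(len(b_levels) * r * (Ai[a] - ybar) ** 2 for a in a_levels)
    ss_b = sum(len(a_levels) * r * (Bj[b] - ybar) ** 2 for b in b_levels)
    ss_ab = ss_e = 0.0
    for a in a_levels:
        for b in b_levels:
            mask = (np.array(A) == a) & (np.array(B) == b)
            cm = y[mask].mean()
            ss_ab += r * (cm - Ai[a] - Bj[b] + ybar) ** 2
            ss_e += ((y[mask] - cm) ** 2).sum()
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_e = len(y) - len(a_levels) * len(b_levels)
    mse = ss_e / df_e
    return ss_a / df_a / mse, ss_b / df_b / mse, ss_ab / (df_a * df_b) / mse


class TestFactorialModel:
    def _balanced_data(self, seed=5, r=12):
        rng = np.random.default_rng(seed)
        cell_means = np.array([[1.0, 2.0, 3.0], [2.0, 1.0, 4.0]])
        y, A, B = [], [], []
        for i, a in enumerate(["male", "female"]):
            for j, b in enumerate(["ASY", "LMP", "MHP"]):
                y.extend(cell_means[i, j] + rng.normal(0, 1, r))
                A.extend([a] * r)
                B.extend([b] * r)
        return np.array(y), np.array(A), np.array(B)

    def test_matches_closed_form_oracle(self):
        y, A, B = self._balanced_data()
        res = factorial_model(y, A, B)
        F_a, F_b, F_ab = _balanced_anova_oracle(y, A, B)
        assert res.effects["sex"].F == pytest.approx(F_a, abs=1e-8)
        assert res.effects["pain_group"].F == pytest.approx(F_b, abs=1e-8)
        assert res.effects["sex:pain_group"].F == pytest.approx(F_ab, abs=1e-8)

    def test_constant_outcome_degenerate(self):
        y, A, B = self._balanced_data()
        res = factorial_model(np.full(len(y), 3.2), A, B)
        assert all(e.F == 0.0 for e in res.effects.values())

    def test_outcome_shift_invariance(self):
        y, A, B = self._balanced_data()
        chronic = np.random.default_rng(1).integers(0, 2, len(y)).astype(float)
        base = factorial_model(y, A, B, chronic)
        shifted = factorial_model(y + 100.0, A, B, chronic)
        for name in base.effects:
            assert shifted.effects[name].F == pytest.approx(base.effects[name].F, rel=1e-9)

    def test_empty_cell_raises(self):
        y, A, B = self._balanced_data()
        mask = ~((A == "male") & (B == "MHP"))
        with pytest.raises(ValueError, match="cell"):
            factorial_model(y[mask], A[mask], B[mask])

    def test_cell_weighted_fit_converges(self):
        rng = np.random.default_rng(9)
        y, A, B = self._balanced_data(r=40)
        # heteroscedastic cells
        y = y + rng.normal(0, np.where(B == "MHP", 3.0, 0.5))
        res = factorial_model(y, A, B, cell_weights=True)
        assert res.weights is not None
        assert np.all(res.weights > 0)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.03, 0.02]
        q = bh_adjust(p)
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPowerAnalysis:
    def test_returned_n_reaches_target_and_predecessor_does_not(self):
        q = PowerQuery(effect_size_f=0.3, n_groups=4, df_numerator=3)
        n = anova_sample_size(q)
        assert ncf_power(n, q) >= 0.8 > ncf_power(n - 1, q)

    def test_monotone_in_effect_size_and_power(self):
        ns = [
            anova_sample_size(PowerQuery(f, n_groups=3, df_numerator=2))
            for f in (0.15, 0.25, 0.4)
        ]
        assert ns == sorted(ns, reverse=True)
        ns = [
            anova_sample_size(PowerQuery(0.25, power=p, n_groups=3, df_numerator=2))
            for p in (0.7, 0.8, 0.95)
        ]
        assert ns == sorted(ns)

    def test_huge_effect_hits_feasibility_floor(self):
        q = PowerQuery(effect_size_f=2.0, n_groups=6, df_numerator=2)
        n = anova_sample_size(q)
        assert n <= 15
        assert ncf_power(n, q) >= 0.8

    def test_empirical_power_at_returned_n(self):
        """Simulating a one-way design at the returned N reproduces the target power."""
        f, k = 0.25, 3
        q = PowerQuery(effect_size_f=f, n_groups=k, df_numerator=k - 1)
        N = anova_sample_size(q)
        n_per = N // k
        N = n_per * k  # balanced realization
        # group means with Cohen's f = sd(means)/sigma
        means = np.array([-1.0, 0.0, 1.0])
        means *= f / np.sqrt(np.mean(means**2))
        rng = np.random.default_rng(17)
        reps = 2000
        data = rng.normal(0, 1.0, (reps, k, n_per)) + means[None, :, None]
        gm = data.mean(axis=2)
        grand = gm.mean(axis=1)
        ss_b = n_per * ((gm - grand[:, None]) ** 2).sum(axis=1)
        ss_w = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
        F = (ss_b / (k - 1)) / (ss_w / (N - k))
        from scipy.stats import f as fdist

        crit = fdist.ppf(0.95, k - 1, N - k)
        power = np.mean(F > crit)
        assert power == pytest.approx(0.8, abs=0.03)
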