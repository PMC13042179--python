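"""Outcome stratification: group tests, summary ANOVA, survival analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from physiophen.cohort import DEFAULT_ARCHETYPES
from physiophen.cohort.generate import _sample_outcome
from physiophen.outcomes import (anova_from_summary, compare_groups, km_estimate,
                                 logrank, prevalence_at)


class TestCompareGroups:
    def _table(self, rng, shift=0.0):
        rows = []
        for g in range(4):
            vals = rng.normal(g * shift, 1.0, size=50)
            flags = rng.random(50) < 0.3
            for v, f in zip(vals, flags):
                rows.append({"phenotype": f"SP{g+1}", "lab": v, "flag": int(f)})
        return pd.DataFrame(rows)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(0)
        rep = compare_groups(self._table(rng, shift=1.0),
                             {"lab": "continuous", "flag": "categorical"})
        row = rep.results.set_index("variable").loc["lab"]
        assert row["test"] == "kruskal-wallis" and row["p"] < 1e-6

    def test_identical_groups_chi2_zero(self):
        df = pd.DataFrame({"phenotype": ["A"] * 20 + ["B"] * 20,
                           "flag": [0, 1] * 20})
        rep = compare_groups(df, {"flag": "categorical"})
        row = rep.results.iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"phenotype": ["A"] * 10, "v": range(10)})
        with pytest.raises(ValueError):
            compare_groups(df, {"v": "continuous"})


class TestAnovaFromSummary:
    def test_equal_means_null(self):
        f, df, p = anova_from_summary([50, 50], [1.0, 1.0], [2.0, 2.0])
        assert f == 0.0 and p == pytest.approx(1.0)

    def test_matches_raw_anova_to_1e10(self):
        """Summary-statistics ANOVA reproduces the raw-data F test exactly."""
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 2.0, size=n)
                  for m, n in [(0.0, 40), (0.5, 55), (0.2, 30)]]
        f_raw, p_raw = stats.f_oneway(*groups)
        f_sum, _, p_sum = anova_from_summary(
            [len(g) for g in groups], [g.mean() for g in groups],
            [g.std(ddof=1) for g in groups])
        assert abs(p_sum - p_raw) < 1e-10
        assert abs(f_sum - f_raw) < 1e-10

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([10, 10], [0, 1], [1.0, -0.5])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1, 10], [0, 1], [1, 1])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=200)
        curves = km_estimate(t, np.ones(200, int), np.zeros(200, int)).curves[0]
        for q in (2.0, 5.0, 10.0):
            emp = np.mean(t > q)
            km = curves.loc[curves["time"] <= q, "survival"].iloc[-1]
            assert km == pytest.approx(emp, abs=1e-12)

    def test_hand_computed_product_limit(self):
        """times 1, 2+, 3, 4+, 5, 6 (+ censored): S(3) = (5/6)(3/4) = 0.625."""
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 0, 1, 1]
        curve = km_estimate(t, e, np.zeros(6, int)).curves[0]
        s3 = curve.loc[curve["time"] <= 3, "survival"].iloc[-1]
        assert s3 == pytest.approx(0.625, abs=1e-12)

    def test_all_censored_group_flat_at_one(self):
        t = np.concatenate([np.full(20, 28.0), [5.0, 28.0]])
        e = np.concatenate([np.zeros(20, int), [1, 0]])
        g = np.concatenate([np.zeros(20, int), np.ones(2, int)])
        curves = km_estimate(t, e, g).curves
        assert (curves[0]["survival"] == 1.0).all()

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(15, size=100).clip(max=28)
        e = (t < 28).astype(int)
        c = km_estimate(t, e, np.zeros(100, int)).curves[0]
        assert (c["ci_lower"] - 1e-12 <= c["survival"]).all()
        assert (c["survival"] <= c["ci_upper"] + 1e-12).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1], [0, 0])


def _logrank_two_group_oracle(times, events, groups):
    """Textbook observed-vs-expected chi-squared for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_zero(self):
        t = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        e = np.ones(8, int)
        g = np.repeat([0, 1], 4)
        stat, df, p = logrank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 1

    def test_matches_hand_oracle_on_fixture(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        events = [1, 1, 0, 1, 1, 1, 0, 1, 1, 1]
        groups = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        stat, df, _ = logrank(times, events, groups)
        assert stat == pytest.approx(
            _logrank_two_group_oracle(times, events, groups), abs=1e-9)

    def test_hazard_ratio_three_detected(self):
        """Exponential groups with hazard ratio 3 (n=100 each): p < 0.01,
        20-seed majority."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.concatenate([rng.exponential(9.0, 100),
                                rng.exponential(3.0, 100)])
            e = (t <= 28).astype(int)
            t = t.clip(max=28)
            _, _, p = logrank(t, e, np.repeat([0, 1], 100))
            wins += p < 0.01
        assert wins > 10


class TestTypeIError:
    """Under the null, rejection rates at alpha = 0.05 stay in [0.03, 0.07]."""

    REPS = 2000

    def test_kruskal_wallis_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(self.REPS):
            groups = rng.normal(size=(4, 50))
            _, p = stats.kruskal(*groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / self.REPS <= 0.07

    def test_chi_squared_calibrated(self):
        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(self.REPS):
            flags = rng.random((4, 50)) < 0.3
            table = np.stack([flags.sum(axis=1), (~flags).sum(axis=1)])
            res = stats.chi2_contingency(table, correction=False)
            rejections += res.pvalue < 0.05
        assert 0.03 <= rejections / self.REPS <= 0.07

    def test_summary_anova_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(self.REPS):
            groups = rng.normal(size=(4, 50))
            _, _, p = anova_from_summary(
                [50] * 4, groups.mean(axis=1), groups.std(axis=1, ddof=1))
            rejections += p < 0.05
        assert 0.03 <= rejections / self.REPS <= 0.07


class TestPrevalence:
    def _outcome_table(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for name, spec in DEFAULT_ARCHETYPES.items():
            for _ in range(150):
                rows.append({"phenotype": name, **_sample_outcome(rng, spec)})
        return pd.DataFrame(rows)

    def test_rates_monotone_in_horizon(self):
        tab = prevalence_at(self._outcome_table(0))
        for out in ("ss", "vp", "mv"):
            assert (tab[f"{out}2"] <= tab[f"{out}7"] + 1e-12).all()
            assert (tab[f"{out}7"] <= tab[f"{out}28"] + 1e-12).all()

    def test_all_zero_flags(self):
        df = pd.DataFrame({"phenotype": ["A"] * 10, "ss2": 0, "ss7": 0,
                           "ss28": 0})
        tab = prevalence_at(df, outcomes=("ss",))
        assert (tab[["ss2", "ss7", "ss28"]] == 0).all().all()

    def test_highest_shock_archetype_leads(self):
        """The archetype with the highest planted shock probability shows the
        highest 28-day shock rate (10-seed majority)."""
        planted = max(DEFAULT_ARCHETYPES,
                      key=lambda k: DEFAULT_ARCHETYPES[k].shock_probs[2])
        wins = 0
        for seed in range(10):
            tab = prevalence_at(self._outcome_table(seed))
            wins += tab["ss28"].idxmax() == planted
        assert wins > 5
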