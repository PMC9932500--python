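"""Outcome metrics and statistical machinery, checked against independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snakesim.environment import OniSeries, Season
from snakesim.stats import (
    incidence_per_farmer_hour,
    mann_whitney_u,
    percent_change_bootstrap_ci,
    seasonal_oni_regression,
)


def brute_force_u(x, y) -> float:
    """Independent oracle: count pairs with x > y, ties worth one half."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def ols_normal_equations(x, y):
    """Independent oracle: closed-form simple-regression coefficients."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    b1 = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    b0 = y.mean() - b1 * x.mean()
    return b0, b1


class TestIncidence:
    def ledger(self, hours_by_month):
        rows = [(0, 2008, m, 1, h) for m, h in hours_by_month.items()]
        return pd.DataFrame(rows, columns=["farmer_id", "year", "month", "day", "hours"])

    def bites(self, by_month):
        rows = [
            (2008, m, 1, 8, 0, 0, "Naja naja", 0, "x")
            for m, n in by_month.items()
            for _ in range(n)
        ]
        return pd.DataFrame(
            rows,
            columns=["year", "month", "day", "hour", "row", "col", "species", "farmer_id", "scenario"],
        )

    def test_simple_ratio(self):
        rate = incidence_per_farmer_hour(self.bites({1: 10}), self.ledger({1: 1000.0}))
        assert rate == pytest.approx(0.01)

    def test_empty_log_zero(self):
        empty = self.bites({})
        assert incidence_per_farmer_hour(empty, self.ledger({1: 100.0})) == 0.0

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            incidence_per_farmer_hour(self.bites({1: 1}), self.ledger({}))

    def test_window_split_recombines(self):
        """Hour-weighted average of two half-windows equals the whole."""
        bites = self.bites({1: 4, 2: 6, 3: 2})
        ledger = self.ledger({1: 100.0, 2: 300.0, 3: 50.0})
        whole = incidence_per_farmer_hour(bites, ledger)
        r1 = incidence_per_farmer_hour(bites, ledger, window=((2008, 1), (2008, 1)))
        r2 = incidence_per_farmer_hour(bites, ledger, window=((2008, 2), (2008, 3)))
        recombined = (r1 * 100.0 + r2 * 350.0) / 450.0
        assert recombined == pytest.approx(whole)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_symmetry(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n,m", [(2, 3), (5, 5), (8, 8), (10, 7), (10, 10)])
    def test_matches_brute_force_small_samples(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(20):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            u, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(brute_force_u(x, y))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 4, size=15).astype(float)
            u, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(brute_force_u(x, y))


class TestBootstrapPercentChange:
    def test_identical_arms_zero_change(self):
        x = np.linspace(1, 2, 40)
        res = percent_change_bootstrap_ci(x, x, seed=0)
        assert res.percent_change == pytest.approx(0.0)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_exact_scaling_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 3, 60)
        res = percent_change_bootstrap_ci(base, 1.2 * base, seed=1)
        assert res.percent_change == pytest.approx(20.0)

    def test_seed_deterministic(self):
        rng = np.random.default_rng(5)
        b, a = rng.uniform(1, 2, 30), rng.uniform(1.1, 2.2, 30)
        r1 = percent_change_bootstrap_ci(b, a, seed=77)
        r2 = percent_change_bootstrap_ci(b, a, seed=77)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_nested_intervals(self):
        """The 95% interval sits inside the 99% interval on the same draws."""
        rng = np.random.default_rng(6)
        b, a = rng.uniform(1, 2, 50), rng.uniform(1.2, 2.3, 50)
        r99 = percent_change_bootstrap_ci(b, a, level=0.99, seed=8)
        r95 = percent_change_bootstrap_ci(b, a, level=0.95, seed=8)
        assert r99.ci_low <= r95.ci_low and r95.ci_high <= r99.ci_high

    def test_zero_baseline_mean_rejected(self):
        with pytest.raises(ValueError, match="baseline mean"):
            percent_change_bootstrap_ci([0.0, 0.0], [1.0, 2.0])

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            percent_change_bootstrap_ci([1.0], [2.0], reps=10)


def make_oni(values_by_ym) -> OniSeries:
    return OniSeries(dict(values_by_ym))


class TestSeasonalRegression:
    def synthetic_monthly(self, beta0, beta1, seasons_months, noise_sd=0.0, seed=0, years=5):
        rng = np.random.default_rng(seed)
        oni_entries = {}
        rows = []
        for y in range(2008, 2008 + years):
            for m in range(1, 13):
                oni = float(np.sin((y * 12 + m) / 7.0) * 1.5 + rng.normal(0, 0.3))
                oni_entries[(y, m)] = oni
                bites = beta0 + beta1 * oni + rng.normal(0, noise_sd)
                rows.append((y, m, bites))
        return pd.DataFrame(rows, columns=["year", "month", "bites"]), make_oni(oni_entries)

    def test_perfect_linear_fit(self):
        monthly, oni = self.synthetic_monthly(5.0, 2.0, None, noise_sd=0.0, seed=1)
        res = seasonal_oni_regression(monthly, oni, Season.SWM)
        assert res.beta0 == pytest.approx(5.0)
        assert res.beta1 == pytest.approx(2.0)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_null_slope_near_zero(self):
        """Independent response: slope ~0 and adjusted R^2 small, 500 replicates."""
        rng = np.random.default_rng(2)
        slopes, r2s = [], []
        for rep in range(500):
            oni_entries = {(2008 + i // 12, i % 12 + 1): float(rng.normal(0, 1))
                           for i in range(120)}
            rows = [(y, m, float(rng.normal(50, 5))) for (y, m) in oni_entries]
            monthly = pd.DataFrame(rows, columns=["year", "month", "bites"])
            res = seasonal_oni_regression(monthly, make_oni(oni_entries), Season.SWM)
            slopes.append(res.beta1)
            r2s.append(res.adj_r2)
        assert abs(np.mean(slopes)) < 0.2
        assert np.mean(np.asarray(r2s) <= 0.05) > 0.8

    def test_parameter_recovery_within_three_se(self):
        """Known (beta0, beta1) recovered from 60 noisy monthly points."""
        beta0, beta1 = 40.0, 6.0
        rng = np.random.default_rng(3)
        oni_entries = {}
        rows = []
        for i in range(144):  # 12 years -> 60 SWM months
            y, m = 2008 + i // 12, i % 12 + 1
            oni = float(rng.normal(0, 1.2))
            oni_entries[(y, m)] = oni
            rows.append((y, m, beta0 + beta1 * oni + float(rng.normal(0, 8.0))))
        monthly = pd.DataFrame(rows, columns=["year", "month", "bites"])
        res = seasonal_oni_regression(monthly, make_oni(oni_entries), Season.SWM)
        assert res.n == 60
        x = np.array([oni_entries[(int(r.year), int(r.month))] for r in
                      monthly[monthly.month.isin([5, 6, 7, 8, 9])].itertuples()])
        se_slope = 8.0 / (np.sqrt(len(x)) * x.std())
        assert abs(res.beta1 - beta1) < 3 * se_slope

    def test_matches_closed_form_normal_equations(self):
        monthly, oni = self.synthetic_monthly(10.0, -3.0, None, noise_sd=4.0, seed=5)
        res = seasonal_oni_regression(monthly, oni, Season.FIM)
        sub = monthly[monthly.month.isin([3, 4])]
        x = [oni.get(int(r.year), int(r.month)) for r in sub.itertuples()]
        b0, b1 = ols_normal_equations(x, sub["bites"])
        assert res.beta0 == pytest.approx(b0)
        assert res.beta1 == pytest.approx(b1)

    def test_adjusted_r2_formula(self):
        monthly, oni = self.synthetic_monthly(10.0, 2.0, None, noise_sd=3.0, seed=6)
        res = seasonal_oni_regression(monthly, oni, Season.SIM)
        sub = monthly[monthly.month.isin([10, 11])]
        x = np.array([oni.get(int(r.year), int(r.month)) for r in sub.itertuples()])
        y = sub["bites"].to_numpy()
        b0, b1 = ols_normal_equations(x, y)
        ss_res = ((y - b0 - b1 * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        n = len(y)
        assert res.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 2))

    def test_constant_oni_rejected(self):
        rows = [(2008, m, 10.0 + m) for m in range(1, 13)]
        monthly = pd.DataFrame(rows, columns=["year", "month", "bites"])
        oni = make_oni({(2008, m): 0.5 for m in range(1, 13)})
        with pytest.raises(ValueError, match="constant"):
            seasonal_oni_regression(monthly, oni, Season.SWM)

    def test_too_few_points_rejected(self):
        rows = [(2008, 5, 10.0), (2008, 6, 12.0)]
        monthly = pd.DataFrame(rows, columns=["year", "month", "bites"])
        oni = make_oni({(2008, m): float(m) for m in range(1, 13)})
        with pytest.raises(ValueError, match=">= 3"):
            seasonal_oni_regression(monthly, oni, Season.SWM)
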