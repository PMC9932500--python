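"""Outcome metrics and statistical comparisons of simulation arms.

Two run-level outcome metrics are compared between a baseline and an
adapted arm: snakebite incidence per farmer work-hour (bites divided by
hours spent in fields) and the total bite count. Samples are built from
per-replicate, per-month simulation points; arms are compared with a
Mann-Whitney U test and a percentile-bootstrap confidence interval on
the percent change of the mean. Seasonal sensitivity to ENSO is
summarised by ordinary least squares of monthly bite counts on the
monthly ONI, fitted separately within each of the four Sri Lankan
rainfall seasons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .engine import SimulationConfig, SimulationResult, run_simulation
from .environment import OniSeries, Season, month_to_season

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "ExperimentOutcome",
    "incidence_per_farmer_hour",
    "mann_whitney_u",
    "percent_change_bootstrap_ci",
    "seasonal_oni_regression",
    "monthly_outcomes",
    "run_replicates",
    "compare_strategies",
]


@dataclass
class ComparisonResult:
    """Percent-change comparison of one metric between two arms."""

    metric: str
    percent_change: float
    ci_low: float
    ci_high: float
    u_statistic: float
    p_value: float
    n_per_group: int
    level: float = 0.99

    def __post_init__(self) -> None:
        if not self.ci_low <= self.percent_change <= self.ci_high:
            raise ValueError("point estimate must lie inside its confidence interval")


@dataclass
class RegressionResult:
    """OLS of monthly bite counts on the monthly ONI within one season."""

    season: Season
    strategy: str
    beta0: float
    beta1: float
    adj_r2: float
    n: int


def incidence_per_farmer_hour(
    bite_log: pd.DataFrame,
    labor_ledger: pd.DataFrame,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> float:
    """Bites divided by farmer-hours in fields, optionally within a window.

    ``window`` is an inclusive ((year, month), (year, month)) range.
    """
    def in_window(frame: pd.DataFrame) -> pd.DataFrame:
        if window is None:
            return frame
        (y0, m0), (y1, m1) = window
        ym = frame["year"] * 12 + frame["month"]
        return frame[(ym >= y0 * 12 + m0) & (ym <= y1 * 12 + m1)]

    hours = float(in_window(labor_ledger)["hours"].sum())
    if hours <= 0:
        raise ValueError("no farmer-hours in the requested window")
    bites = 0 if bite_log.empty else len(in_window(bite_log))
    return bites / hours


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (pairs with x > y, ties counted half) and two-sided p.

    Exact enumeration for small tie-free samples (both n < 20), otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size < 20 and y.size < 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def percent_change_bootstrap_ci(
    baseline: Sequence[float],
    adapted: Sequence[float],
    level: float = 0.99,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
    metric: str = "incidence_per_farmer_hour",
) -> ComparisonResult:
    """Percent change of the mean with a percentile-bootstrap CI.

    The point estimate is ``(mean(adapted) - mean(baseline)) /
    mean(baseline) * 100``. Equal-length samples (matched replicates) are
    resampled as pairs; unequal samples independently.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    b = np.asarray(baseline, dtype=float)
    a = np.asarray(adapted, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if b.mean() == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    point = (a.mean() - b.mean()) / b.mean() * 100.0
    if a.size == b.size:
        idx = rng.integers(0, b.size, size=(reps, b.size))
        bm = b[idx].mean(axis=1)
        am = a[idx].mean(axis=1)
    else:
        bm = b[rng.integers(0, b.size, size=(reps, b.size))].mean(axis=1)
        am = a[rng.integers(0, a.size, size=(reps, a.size))].mean(axis=1)
    ok = bm != 0
    boots = (am[ok] - bm[ok]) / bm[ok] * 100.0
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    u, p = mann_whitney_u(a, b)
    return ComparisonResult(
        metric=metric,
        percent_change=float(point),
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        u_statistic=u,
        p_value=p,
        n_per_group=int(min(a.size, b.size)),
        level=level,
    )


def seasonal_oni_regression(
    monthly_bites: pd.DataFrame,
    oni: OniSeries,
    season: Season,
    strategy: str = "baseline",
) -> RegressionResult:
    """OLS of monthly bite totals on the monthly ONI within one season.

    ``monthly_bites`` needs columns ``year, month, bites``; months outside
    the season are ignored. Adjusted R^2 uses n - 2 residual degrees of
    freedom (one slope).
    """
    sub = monthly_bites[
        monthly_bites["month"].map(month_to_season) == season
    ]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 monthly points in season {season.value}, got {len(sub)}")
    x = np.array([oni.get(int(r.year), int(r.month)) for r in sub.itertuples()])
    y = sub["bites"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"ONI is constant within season {season.value}; slope unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(y)
    r2 = 0.0 if np.ptp(y) == 0 else model.rsquared  # constant response: nothing to explain
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        season=season,
        strategy=strategy,
        beta0=float(model.params[0]),
        beta1=float(model.params[1]),
        adj_r2=float(adj),
        n=n,
    )


# ---------------------------------------------------------------------------
# experiment orchestration


def monthly_outcomes(result: SimulationResult) -> pd.DataFrame:
    """Per-(year, month) bite counts, hours and incidence for one run.

    Every simulated calendar month appears, including months with no
    field work (zero hours and bites, undefined incidence), so that
    bite-count samples are directly comparable between arms whose
    calendars occupy different months.
    """
    cfg = result.config
    grid = pd.DataFrame(
        [
            (cfg.start_year + i // 12, i % 12 + 1)
            for i in range(cfg.years * 12)
        ],
        columns=["year", "month"],
    )
    hours = result.labor_ledger.groupby(["year", "month"], as_index=False)["hours"].sum()
    out = grid.merge(hours, on=["year", "month"], how="left").fillna({"hours": 0.0})
    if result.bite_log.empty:
        out["bites"] = 0
    else:
        bites = (
            result.bite_log.groupby(["year", "month"], as_index=False)
            .size()
            .rename(columns={"size": "bites"})
        )
        out = out.merge(bites, on=["year", "month"], how="left").fillna({"bites": 0})
    out["bites"] = out["bites"].astype(int)
    out["incidence"] = np.where(out["hours"] > 0, out["bites"] / out["hours"], np.nan)
    return out.sort_values(["year", "month"]).reset_index(drop=True)


def run_replicates(
    config: SimulationConfig, replicates: int, base_seed: int | None = None
) -> list[SimulationResult]:
    """Run independent replicates, one child seed per replicate."""
    seed = config.seed if base_seed is None else base_seed
    out = []
    for r in range(replicates):
        out.append(run_simulation(replace(config, seed=seed + r)))
    return out


def _configs_match(b: SimulationConfig, a: SimulationConfig) -> bool:
    """True iff the two arm configs agree on everything but scenario/label."""
    for name in vars(b):
        if name in ("scenario", "label"):
            continue
        vb, va = getattr(b, name), getattr(a, name)
        if name == "landscape":
            if (vb is None) != (va is None):
                return False
            if vb is not None and not np.array_equal(vb.grid, va.grid):
                return False
        elif name == "climate_params":
            if (vb is None) != (va is None):
                return False
            if vb is not None and (
                not np.array_equal(vb.monthly_mean_rain_mm, va.monthly_mean_rain_mm)
                or not np.array_equal(vb.monthly_mean_rainy_days, va.monthly_mean_rainy_days)
                or vb.enso_gain != va.enso_gain
                or vb.rainy_day_threshold_mm != va.rainy_day_threshold_mm
            ):
                return False
        elif name == "species":
            if vb is not va:
                return False
        elif vb != va:
            return False
    return True


@dataclass
class ExperimentOutcome:
    """Everything a paired-arm experiment produces."""

    incidence: ComparisonResult
    totals: ComparisonResult
    regressions: list[RegressionResult]
    monthly: pd.DataFrame  # tidy per-arm, per-replicate, per-month outcomes
    baseline_results: list[SimulationResult]
    adapted_results: list[SimulationResult]

    def comparisons_frame(self) -> pd.DataFrame:
        rows = [
            (c.metric, c.percent_change, c.ci_low, c.ci_high, c.u_statistic, c.p_value, c.n_per_group)
            for c in (self.incidence, self.totals)
        ]
        return pd.DataFrame(
            rows, columns=["metric", "estimate", "ci_low", "ci_high", "U", "p", "n"]
        )

    def regressions_frame(self) -> pd.DataFrame:
        rows = [
            (r.season.value, r.strategy, r.beta0, r.beta1, r.adj_r2, r.n)
            for r in self.regressions
        ]
        return pd.DataFrame(
            rows, columns=["season", "strategy", "beta0", "beta1", "adj_r2", "n"]
        )


def compare_strategies(
    baseline_config: SimulationConfig,
    adapted_config: SimulationConfig,
    replicates: int = 20,
    bootstrap_reps: int = 10_000,
    bootstrap_seed: int = 0,
) -> ExperimentOutcome:
    """Run both arms with matched seeds and compute all outcome statistics.

    The arms must differ only in the scenario (and label); each replicate
    pair shares a seed, hence climate, landscape, agents and snake
    placement. Samples for the Mann-Whitney and bootstrap comparisons are
    per-replicate, per-month simulation points; ENSO regressions pool
    bite totals across replicates within (year, month).
    """
    b, a = baseline_config, adapted_config
    if not _configs_match(b, a):
        raise ValueError("arm configs must differ only in scenario and label")

    base_results = run_replicates(b, replicates)
    adap_results = run_replicates(a, replicates)

    frames = []
    for arm, results in (("baseline", base_results), ("adapted", adap_results)):
        for r_i, res in enumerate(results):
            m = monthly_outcomes(res)
            m["strategy"] = arm
            m["replicate"] = r_i
            frames.append(m)
    monthly = pd.concat(frames, ignore_index=True)

    # simulation points: one per (replicate, year). Yearly granularity keeps
    # cross-month labour reallocation -- the mechanism the adaptations act
    # through -- inside each point's bites/hours ratio.
    yearly = monthly.groupby(["strategy", "replicate", "year"], as_index=False).agg(
        bites=("bites", "sum"), hours=("hours", "sum")
    )
    yearly["incidence"] = np.where(
        yearly["hours"] > 0, yearly["bites"] / yearly["hours"], np.nan
    )

    def sample(arm: str, col: str) -> np.ndarray:
        sub = yearly[yearly["strategy"] == arm]
        return sub[col].dropna().to_numpy(dtype=float)

    incidence = percent_change_bootstrap_ci(
        sample("baseline", "incidence"),
        sample("adapted", "incidence"),
        seed=bootstrap_seed,
        reps=bootstrap_reps,
        metric="incidence_per_farmer_hour",
    )
    totals = percent_change_bootstrap_ci(
        sample("baseline", "bites"),
        sample("adapted", "bites"),
        seed=bootstrap_seed + 1,
        reps=bootstrap_reps,
        metric="total_bites",
    )

    oni = base_results[0].oni
    pooled = (
        monthly.groupby(["strategy", "year", "month"], as_index=False)["bites"].sum()
    )
    regressions = []
    for arm in ("baseline", "adapted"):
        sub = pooled[pooled["strategy"] == arm]
        for season in Season:
            try:
                regressions.append(seasonal_oni_regression(sub, oni, season, strategy=arm))
            except ValueError:
                continue  # season unidentifiable at this scale (e.g. constant ONI)
    return ExperimentOutcome(
        incidence=incidence,
        totals=totals,
        regressions=regressions,
        monthly=monthly,
        baseline_results=base_results,
        adapted_results=adap_results,
    )
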