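"""Crop-calendar rules resolving adaptation strategies into work schedules.

Three crops, each with a baseline practice and a climate-adaptation
strategy:

* **Rice** — two cultivation cycles per year (Maha, anchored to the
  second-intermonsoon planting window; Yala, anchored to April). The
  baseline plants a conventional variety with a three-month growth period
  and harvest in the fourth cycle month; the adaptation plants a
  short-duration, drought-resistant variety with a two-month growth
  period and harvest in the third month, ending each cycle a month
  earlier.
* **Rubber** — the baseline taps on every non-rainy day (rain
  contaminates the sap), which under the packaged wet-zone climatology
  yields roughly 150 workdays a year; the adaptation is low-frequency
  tapping on a fixed five-day interval irrespective of rainfall.
* **Tea** — the baseline harvests at a constant daily effort year-round;
  the adaptation tracks the rain-yield relationship by adding 0.514
  labour hours per hectare per mm of previous-month rainfall, absorbed
  by longer working days up to the 14-hour ceiling.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import FarmerTraits, WorkSchedule
from .environment import LandCover, detect_monsoon_onset

__all__ = [
    "RicePhase",
    "RiceScenarioParams",
    "RubberScenarioParams",
    "TeaScenarioParams",
    "rice_calendar",
    "rubber_workdays",
    "tea_labor",
    "build_workforce_schedule",
]

log = logging.getLogger(__name__)

TEA_LABOR_SLOPE = 0.514  # labour hours per hectare per mm of lagged monthly rain
MAX_DAILY_HOURS = 14.0


class RicePhase:
    OFF = "off"
    PLANTING = "planting"
    GROWING = "growing"
    HARVEST = "harvest"


@dataclass
class RiceScenarioParams:
    """Rice variety choice and cultivation-calendar anchors.

    The conventional variety grows for three months with harvest in the
    fourth cycle month; the short-duration variety grows for two months
    with harvest in the third. ``growing_presence`` is the fraction of
    growing-phase days a farmer spends in the field (weeding and water
    management); planting and harvest months are full-presence.
    """

    variety: str = "conventional"
    maha_anchor_month: int = 9
    yala_anchor_month: int = 4
    growing_presence: float = 0.15
    use_onset_shift: bool = False

    def __post_init__(self) -> None:
        if self.variety not in ("conventional", "short_duration"):
            raise ValueError("variety must be 'conventional' or 'short_duration'")
        if not 0.0 <= self.growing_presence <= 1.0:
            raise ValueError("growing_presence must lie in [0, 1]")

    @property
    def growth_months(self) -> int:
        return 3 if self.variety == "conventional" else 2

    @property
    def harvest_month_offset(self) -> int:
        return 3 if self.variety == "conventional" else 2

    @property
    def adapted(self) -> bool:
        return self.variety == "short_duration"


@dataclass
class RubberScenarioParams:
    """Rubber tapping routine: non-rainy-day baseline vs fixed-interval tapping."""

    adapted: bool = False
    tapping_interval_days: int = 5


@dataclass
class TeaScenarioParams:
    """Tea harvest-labour rule: constant baseline vs rainfall-tracking labour."""

    adapted: bool = False
    baseline_daily_hours: float = 6.0
    labor_slope: float = TEA_LABOR_SLOPE
    plot_hectares: float = 0.5

    def __post_init__(self) -> None:
        if self.plot_hectares < 0:
            raise ValueError("plot_hectares must be >= 0")
        if not 4.0 <= self.baseline_daily_hours <= MAX_DAILY_HOURS:
            raise ValueError("baseline_daily_hours must lie in [4, 14]")


def _cycle_months(anchor: int, params: RiceScenarioParams) -> dict[int, tuple[str, float]]:
    """Phase and presence intensity for the months of one cultivation cycle."""
    months: dict[int, tuple[str, float]] = {}
    months[(anchor - 1) % 12 + 1] = (RicePhase.PLANTING, 1.0)
    for k in range(1, params.growth_months):
        months[(anchor - 1 + k) % 12 + 1] = (RicePhase.GROWING, params.growing_presence)
    months[(anchor - 1 + params.harvest_month_offset) % 12 + 1] = (RicePhase.HARVEST, 1.0)
    return months


def rice_calendar(
    params: RiceScenarioParams, year: int, climate: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-day field-presence plan for one calendar year of rice farming.

    Returns a frame with one row per day of the year and columns
    ``month, day, phase, intensity``. Two cycles are laid out (Maha and
    Yala); if ``use_onset_shift`` is set and a climate frame is given,
    the Yala anchor shifts to the month of the detected southwest-monsoon
    onset.
    """
    yala = params.yala_anchor_month
    if params.use_onset_shift:
        if climate is None:
            raise ValueError("onset shifting requires a climate frame")
        sub = climate[climate["year"] == year]
        onset = detect_monsoon_onset(sub, earliest=(3, 15), trigger_mm=75.0, window_days=5)
        if onset is not None:
            yala = int(onset.month)

    plan: dict[int, tuple[str, float]] = {}
    for anchor in (params.maha_anchor_month, yala):
        cyc = _cycle_months(anchor, params)
        for m, (phase, inten) in cyc.items():
            if m in plan and plan[m][0] != RicePhase.OFF:
                raise ValueError(
                    f"rice cycles overlap in month {m} (Maha anchor "
                    f"{params.maha_anchor_month}, Yala anchor {yala})"
                )
            plan[m] = (phase, inten)

    rows = []
    for month in range(1, 13):
        phase, inten = plan.get(month, (RicePhase.OFF, 0.0))
        for day in range(1, calendar.monthrange(year, month)[1] + 1):
            rows.append((month, day, phase, inten))
    return pd.DataFrame(rows, columns=["month", "day", "phase", "intensity"])


def rubber_workdays(params: RubberScenarioParams, climate_year: pd.DataFrame) -> np.ndarray:
    """Boolean workday mask over one year of daily climate.

    Baseline: exactly the non-rainy days. Adapted: every
    ``tapping_interval_days``-th day from 1 January irrespective of
    rainfall (73 workdays in a normal year at the default interval).
    """
    n = len(climate_year)
    if n not in (365, 366):
        raise ValueError(f"rubber_workdays needs a full year of daily climate, got {n} days")
    if params.adapted:
        doy = np.arange(n)
        return doy % params.tapping_interval_days == 0
    return ~climate_year["is_rainy"].to_numpy()


def tea_labor(
    params: TeaScenarioParams,
    month: int,
    previous_month_rain_mm: float,
    year: int = 2001,
) -> float:
    """Scheduled tea-harvest labour hours for one farmer for one month.

    Baseline: constant daily effort on every day of the month. Adapted:
    baseline plus ``labor_slope x plot_hectares x previous-month rainfall``,
    capped at 14 hours per workday.
    """
    if previous_month_rain_mm < 0:
        raise ValueError("previous_month_rain_mm must be >= 0")
    workdays = calendar.monthrange(year, month)[1]
    base = params.baseline_daily_hours * workdays
    if not params.adapted:
        return base
    extra = params.labor_slope * params.plot_hectares * previous_month_rain_mm
    return min(base + extra, MAX_DAILY_HOURS * workdays)


ScenarioParams = RiceScenarioParams | RubberScenarioParams | TeaScenarioParams

_SCENARIO_CROP = {
    RiceScenarioParams: LandCover.RICE,
    RubberScenarioParams: LandCover.RUBBER,
    TeaScenarioParams: LandCover.TEA,
}


def scenario_crop(params: ScenarioParams) -> LandCover:
    return _SCENARIO_CROP[type(params)]


def build_workforce_schedule(
    params: ScenarioParams,
    farmers: Sequence[FarmerTraits],
    climate: pd.DataFrame,
    seed: int | np.random.Generator = 0,
) -> WorkSchedule:
    """Resolve a crop scenario into a day-by-day schedule for a workforce.

    Field cells are assigned per workday (uniform over each farmer's own
    fields); extra tea labour is absorbed by raising daily hours toward
    the 14-hour ceiling before any capping is logged.
    """
    crop = scenario_crop(params)
    for f in farmers:
        if f.farmer_type != crop:
            raise ValueError(
                f"farmer {f.farmer_id} grows {f.farmer_type.name}, scenario is {crop.name}"
            )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_days = len(climate)
    sched = WorkSchedule(farmers, n_days)
    years = climate["year"].to_numpy()
    year_list = sorted(set(years.tolist()))

    def assign(fi: int, farmer: FarmerTraits, days: np.ndarray, hours: float | np.ndarray) -> None:
        cells = farmer.field_cells[rng.integers(0, farmer.field_cells.size, size=days.size)]
        sched.hours[fi, days] = hours
        sched.cell[fi, days] = cells

    if isinstance(params, RiceScenarioParams):
        for year in year_list:
            idx = np.flatnonzero(years == year)
            cal = rice_calendar(params, year, climate)
            inten = cal["intensity"].to_numpy()
            for fi, farmer in enumerate(farmers):
                # full-presence months: always on; growing months: thinned
                on = rng.random(len(idx)) < inten
                assign(fi, farmer, idx[on], farmer.daily_hours)

    elif isinstance(params, RubberScenarioParams):
        for year in year_list:
            idx = np.flatnonzero(years == year)
            mask = rubber_workdays(params, climate.iloc[idx])
            for fi, farmer in enumerate(farmers):
                assign(fi, farmer, idx[mask], farmer.daily_hours)

    elif isinstance(params, TeaScenarioParams):
        months = climate["month"].to_numpy()
        monthly_rain = climate.groupby(["year", "month"])["rainfall_mm"].sum()
        for year in year_list:
            for month in range(1, 13):
                idx = np.flatnonzero((years == year) & (months == month))
                if idx.size == 0:
                    continue
                if (year, month - 1) in monthly_rain.index:
                    prev_rain = float(monthly_rain.loc[(year, month - 1)])
                elif month == 1 and (year - 1, 12) in monthly_rain.index:
                    prev_rain = float(monthly_rain.loc[(year - 1, 12)])
                else:
                    prev_rain = 0.0  # no antecedent month at the series start
                for fi, farmer in enumerate(farmers):
                    p = TeaScenarioParams(
                        adapted=params.adapted,
                        baseline_daily_hours=farmer.daily_hours,
                        labor_slope=params.labor_slope,
                        plot_hectares=params.plot_hectares,
                    )
                    month_hours = tea_labor(p, month, prev_rain, year)
                    daily = month_hours / idx.size
                    if daily > MAX_DAILY_HOURS:
                        log.warning(
                            "tea labour demand capped at %s h/day in %d-%02d",
                            MAX_DAILY_HOURS, year, month,
                        )
                        daily = MAX_DAILY_HOURS
                    assign(fi, farmer, idx, daily)
    else:  # pragma: no cover
        raise TypeError(f"unknown scenario parameter type {type(params)!r}")
    return sched
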