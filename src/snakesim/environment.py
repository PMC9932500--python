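"""Synthetic environmental forcing: monsoon rainfall, ENSO index, land cover.

This module generates (or loads) the three environmental inputs that drive
the farmer-snake contact simulation:

* a daily rainfall series with the bimodal monsoon structure of wet-zone
  Sri Lanka, modulated month-by-month by the ENSO state through a
  season-specific sign table;
* a monthly Oceanic Nino Index (ONI) series, either synthetic (a smooth
  multi-year oscillation between El Nino and La Nina phases) or loaded
  from a NOAA-style table;
* a rectangular land-cover grid over the six cover classes the agents
  recognise (rice, tea, rubber, forest, water, homesteads).

Rainfall generation is a standard two-stage weather-generator scheme:
the month's total is drawn around its (ENSO-shifted) climatological mean,
a wet-day count is drawn around the climatological number of rainy days,
and the total is split across the wet days with a symmetric Dirichlet.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "LandCover",
    "ClimateGenParams",
    "OniSeries",
    "Landscape",
    "month_to_season",
    "classify_rainy_day",
    "generate_daily_rainfall",
    "generate_oni_series",
    "generate_landscape",
    "load_rainfall_csv",
    "load_oni_csv",
    "load_landscape",
    "save_landscape",
    "load_default_climatology",
    "monthly_totals",
    "detect_monsoon_onset",
]

# El Nino / La Nina thresholds on the ONI (standard NOAA convention).
ONI_EL_NINO = 0.5
ONI_LA_NINA = -0.5


class Season(Enum):
    """The four Sri Lankan rainfall seasons."""

    NEM = "NEM"  # northeast monsoon, December-February
    FIM = "FIM"  # first intermonsoon, March-April
    SWM = "SWM"  # southwest monsoon, May-September
    SIM = "SIM"  # second intermonsoon, October-November


_MONTH_SEASON = {
    12: Season.NEM, 1: Season.NEM, 2: Season.NEM,
    3: Season.FIM, 4: Season.FIM,
    5: Season.SWM, 6: Season.SWM, 7: Season.SWM, 8: Season.SWM, 9: Season.SWM,
    10: Season.SIM, 11: Season.SIM,
}


def month_to_season(month: int) -> Season:
    """Map a calendar month (1-12) to its Sri Lankan rainfall season."""
    if month not in _MONTH_SEASON:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return _MONTH_SEASON[month]


class LandCover(IntEnum):
    """Land-cover classes of the agricultural landscape."""

    RICE = 0
    TEA = 1
    RUBBER = 2
    FOREST = 3
    WATER = 4
    HOME = 5


# single-character codes used by the ASCII grid format
_COVER_CODE = {
    LandCover.RICE: "R", LandCover.TEA: "T", LandCover.RUBBER: "B",
    LandCover.FOREST: "F", LandCover.WATER: "W", LandCover.HOME: "H",
}
_CODE_COVER = {v: k for k, v in _COVER_CODE.items()}

# ENSO precipitation sign structure by month block:
# (El Nino effect, La Nina effect), each in {-1, 0, +1}.
# Jan-Mar: both phases reduce rainfall; Apr-Jun: El Nino increases,
# La Nina decreases; Jul-Sep: La Nina increases, El Nino decreases
# (September carried with the July-August block); Oct-Dec: El Nino
# increases, La Nina decreases.
DEFAULT_ENSO_SEASON_SIGN: dict[tuple[int, ...], tuple[int, int]] = {
    (1, 2, 3): (-1, -1),
    (4, 5, 6): (+1, -1),
    (7, 8, 9): (-1, +1),
    (10, 11, 12): (+1, -1),
}


def _month_sign_table(table: Mapping[tuple[int, ...], tuple[int, int]]) -> dict[int, tuple[int, int]]:
    out: dict[int, tuple[int, int]] = {}
    for months, signs in table.items():
        for m in months:
            out[m] = tuple(signs)  # type: ignore[assignment]
    if sorted(out) != list(range(1, 13)):
        raise ValueError("enso_season_sign must cover each month 1..12 exactly once")
    return out


@dataclass
class ClimateGenParams:
    """Parameters of the synthetic monsoon rainfall generator.

    Parameters
    ----------
    monthly_mean_rain_mm
        Climatological mean rainfall total for each calendar month, mm,
        each in [0, 1500].
    monthly_mean_rainy_days
        Climatological mean count of rainy days per calendar month,
        each in [0, 31].
    enso_gain
        Rainfall shift (mm of monthly total per unit |ONI|) applied with
        the sign dictated by ``enso_season_sign`` for the active phase.
    rainy_day_threshold_mm
        A day is rainy iff its rainfall is >= this threshold (default
        2.5 mm, a common meteorological convention).
    enso_season_sign
        Month-block -> (El Nino effect, La Nina effect) table.
    monthly_total_shape
        Gamma shape of the realised monthly total around its expectation
        (larger = less interannual variability).
    wet_day_concentration
        Symmetric Dirichlet concentration used to split the monthly
        total across wet days (larger = more even wet days).
    onset_trigger_mm / onset_window_days
        Cumulative-rainfall rule for monsoon onset detection: onset is
        the first day whose trailing window accumulates at least the
        trigger amount.
    """

    monthly_mean_rain_mm: Sequence[float]
    monthly_mean_rainy_days: Sequence[float]
    enso_gain: float = 60.0
    rainy_day_threshold_mm: float = 2.5
    enso_season_sign: Mapping[tuple[int, ...], tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ENSO_SEASON_SIGN)
    )
    monthly_total_shape: float = 12.0
    wet_day_concentration: float = 3.0
    onset_trigger_mm: float = 75.0
    onset_window_days: int = 5

    def __post_init__(self) -> None:
        rain = np.asarray(self.monthly_mean_rain_mm, dtype=float)
        days = np.asarray(self.monthly_mean_rainy_days, dtype=float)
        if rain.shape != (12,) or days.shape != (12,):
            raise ValueError("monthly_mean_rain_mm and monthly_mean_rainy_days need 12 entries")
        if np.any(rain < 0) or np.any(rain > 1500):
            raise ValueError("monthly_mean_rain_mm entries must lie in [0, 1500]")
        if np.any(days < 0) or np.any(days > 31):
            raise ValueError("monthly_mean_rainy_days entries must lie in [0, 31]")
        if self.enso_gain < 0:
            raise ValueError("enso_gain must be >= 0")
        if self.rainy_day_threshold_mm < 0:
            raise ValueError("rainy_day_threshold_mm must be >= 0")
        self.monthly_mean_rain_mm = rain
        self.monthly_mean_rainy_days = days
        self._sign_by_month = _month_sign_table(self.enso_season_sign)

    def enso_shift_mm(self, month: int, oni: float) -> float:
        """Expected rainfall shift (mm) for the month given the ONI value.

        The shift is ``enso_gain * |ONI| * effect_sign`` where the effect
        sign is the table entry for whichever phase is active (El Nino at
        ONI >= +0.5, La Nina at ONI <= -0.5, neutral otherwise).
        """
        if not np.isfinite(oni):
            raise ValueError(f"non-finite ONI value for month {month}")
        el, la = self._sign_by_month[month]
        if oni >= ONI_EL_NINO:
            return self.enso_gain * abs(oni) * el
        if oni <= ONI_LA_NINA:
            return self.enso_gain * abs(oni) * la
        return 0.0


def load_default_climatology() -> ClimateGenParams:
    """The packaged Ratnapura-like monthly climatology fixture."""
    ref = resources.files("snakesim.data") / "climatology_ratnapura_synthetic.csv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, comment="#")
    table = table.sort_values("month")
    return ClimateGenParams(
        monthly_mean_rain_mm=table["mean_rain_mm"].to_numpy(float),
        monthly_mean_rainy_days=table["mean_rainy_days"].to_numpy(float),
    )


def classify_rainy_day(rainfall_mm: float, threshold_mm: float) -> bool:
    """True iff the day's rainfall reaches the rainy-day threshold."""
    if rainfall_mm < 0:
        raise ValueError("rainfall_mm must be >= 0")
    if threshold_mm < 0:
        raise ValueError("threshold_mm must be >= 0")
    return rainfall_mm >= threshold_mm


@dataclass
class OniSeries:
    """A monthly ONI series: one index value per (year, month)."""

    entries: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        years = sorted({y for y, _ in self.entries})
        for y in years:
            months = sorted(m for yy, m in self.entries if yy == y)
            missing = sorted(set(range(1, 13)) - set(months))
            # a partial first (last) year may only miss a leading (trailing)
            # block of months; interior gaps are always an error
            if y == years[0]:
                ok = months == list(range(months[0], 13))
            elif y == years[-1]:
                ok = months == list(range(1, months[-1] + 1))
            else:
                ok = not missing
            if not ok:
                raise ValueError(f"ONI series is missing months {missing} of year {y}")
        for key, v in self.entries.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite ONI value at {key}")

    def get(self, year: int, month: int) -> float:
        try:
            return self.entries[(year, month)]
        except KeyError:
            raise KeyError(f"ONI series has no entry for {year}-{month:02d}") from None

    def covers(self, start_year: int, years: int) -> bool:
        return all(
            (y, m) in self.entries
            for y in range(start_year, start_year + years)
            for m in range(1, 13)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [(y, m, v) for (y, m), v in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["year", "month", "oni"])


def generate_oni_series(
    years: int,
    amplitude: float = 1.8,
    period_months: int = 45,
    seed: int | np.random.Generator = 0,
    start_year: int = 2008,
    noise_sd: float = 0.12,
) -> OniSeries:
    """Generate a smooth synthetic multi-year ENSO oscillation.

    A sinusoid of the given amplitude and period (months), with a random
    seeded phase and a small AR(1)-smoothed noise component, so the series
    crosses between El Nino (positive) and La Nina (negative) phases over
    a multi-year horizon, as the real ONI does.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if period_months < 12:
        raise ValueError("period_months must be >= 12")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = 12 * years
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n)
    base = amplitude * np.sin(2 * np.pi * t / period_months + phase)
    noise = np.zeros(n)
    if amplitude > 0 and noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=n)
        for i in range(1, n):
            noise[i] = 0.8 * noise[i - 1] + eps[i]
    values = base + noise
    entries = {
        (start_year + i // 12, i % 12 + 1): float(values[i]) for i in range(n)
    }
    return OniSeries(entries)


def _days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def generate_daily_rainfall(
    params: ClimateGenParams,
    oni: OniSeries,
    years: int,
    seed: int | np.random.Generator = 0,
    start_year: int = 2008,
) -> pd.DataFrame:
    """Generate a daily rainfall series driven by climatology and ENSO.

    For each month the expected total is the climatological mean shifted
    by ``enso_gain * |ONI| * sign`` for the active ENSO phase; the
    realised total is gamma-distributed around that expectation. A wet-day
    count is drawn from a binomial whose mean is the climatological number
    of rainy days, scaled by the same relative ENSO shift (wetter months
    also have more wet days), and the total is split over the wet days
    with a symmetric Dirichlet. Dry days receive zero rainfall.

    Returns a DataFrame with columns
    ``date, year, month, day, rainfall_mm, is_rainy``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if not oni.covers(start_year, years):
        raise ValueError(
            f"ONI series does not cover {years} year(s) starting {start_year}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    recs: list[tuple[int, int, int, float]] = []
    for year in range(start_year, start_year + years):
        for month in range(1, 13):
            ndays = _days_in_month(year, month)
            mean_total = float(params.monthly_mean_rain_mm[month - 1])
            shift = params.enso_shift_mm(month, oni.get(year, month))
            expected = max(0.0, mean_total + shift)
            if mean_total > 0:
                rel = expected / mean_total
            else:
                rel = 1.0
            mean_wet = float(np.clip(params.monthly_mean_rainy_days[month - 1] * rel, 0, ndays))

            if expected <= 0:
                rain = np.zeros(ndays)
            else:
                shape = params.monthly_total_shape
                total = rng.gamma(shape, expected / shape)
                n_wet = int(rng.binomial(ndays, mean_wet / ndays)) if mean_wet > 0 else 0
                if total > 0 and n_wet == 0:
                    n_wet = 1
                rain = np.zeros(ndays)
                if n_wet > 0:
                    wet_idx = rng.choice(ndays, size=n_wet, replace=False)
                    shares = rng.dirichlet(np.full(n_wet, params.wet_day_concentration))
                    rain[wet_idx] = total * shares
            recs.extend(
                (year, month, d + 1, float(rain[d])) for d in range(ndays)
            )

    frame = pd.DataFrame(recs, columns=["year", "month", "day", "rainfall_mm"])
    frame["is_rainy"] = frame["rainfall_mm"] >= params.rainy_day_threshold_mm
    frame.insert(0, "date", pd.to_datetime(frame[["year", "month", "day"]]))
    return frame


def monthly_totals(climate: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a daily climate frame to per-month totals and wet-day counts."""
    g = climate.groupby(["year", "month"], as_index=False).agg(
        rain_mm=("rainfall_mm", "sum"), rainy_days=("is_rainy", "sum")
    )
    return g


def detect_monsoon_onset(
    climate_year: pd.DataFrame,
    earliest: tuple[int, int],
    trigger_mm: float,
    window_days: int,
) -> pd.Timestamp | None:
    """First day at/after ``earliest`` whose trailing window accumulates the trigger.

    ``earliest`` is a (month, day) pair; returns None if the rule never fires.
    """
    sub = climate_year[
        (climate_year["month"] > earliest[0])
        | ((climate_year["month"] == earliest[0]) & (climate_year["day"] >= earliest[1]))
    ]
    rain = sub["rainfall_mm"].to_numpy()
    csum = np.cumsum(rain)
    for i in range(len(rain)):
        lo = max(0, i - window_days + 1)
        acc = csum[i] - (csum[lo - 1] if lo > 0 else 0.0)
        if acc >= trigger_mm:
            return pd.Timestamp(sub.iloc[i]["date"])
    return None


@dataclass
class Landscape:
    """A rectangular grid of land-cover cells.

    ``grid`` holds :class:`LandCover` codes; ``cell_size_m`` is the linear
    cell size in metres (the default 100 m makes each cell one hectare).
    """

    grid: np.ndarray
    cell_size_m: float = 100.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValueError("landscape grid must be a nonempty 2-D array")
        valid = np.isin(self.grid, [c.value for c in LandCover])
        if not valid.all():
            raise ValueError("landscape grid contains unknown class codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def n_cells(self) -> int:
        return int(self.grid.size)

    @property
    def cell_area_m2(self) -> float:
        return float(self.cell_size_m) ** 2

    def area_fraction(self) -> dict[LandCover, float]:
        """Realised class area fractions (sum to 1)."""
        counts = np.bincount(self.grid.ravel(), minlength=len(LandCover))
        return {c: counts[c.value] / self.n_cells for c in LandCover}

    def cells_of(self, cover: LandCover) -> np.ndarray:
        """Flat indices of cells of the given class."""
        return np.flatnonzero(self.grid.ravel() == cover.value)


def generate_landscape(
    rows: int,
    cols: int,
    class_fractions: Mapping[LandCover, float],
    clustering: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> Landscape:
    """Generate a random land-cover grid with the requested class mix.

    Class counts are allocated exactly (largest-remainder rounding), so the
    realised fraction of every class is within one cell of the request.
    ``clustering`` in [0, 1] interpolates between a uniform random scatter
    (0) and contiguous single-class patches grown from random seeds (1).
    """
    fracs = {c: float(class_fractions.get(c, 0.0)) for c in LandCover}
    vals = np.array(list(fracs.values()))
    if np.any(vals < 0):
        raise ValueError("class fractions must be >= 0")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError(f"class fractions must sum to 1 (got {vals.sum():.6f})")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = rows * cols
    raw = {c: f * n for c, f in fracs.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    # largest remainder; guarantee >=1 cell for any positive fraction
    for c, f in fracs.items():
        if f > 0 and counts[c] == 0:
            counts[c] = 1
    short = n - sum(counts.values())
    order = sorted(LandCover, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)
    i = 0
    while short != 0:
        c = order[i % len(order)]
        if short > 0 and fracs[c] > 0:
            counts[c] += 1
            short -= 1
        elif short < 0 and counts[c] > (1 if fracs[c] > 0 else 0):
            counts[c] -= 1
            short += 1
        i += 1

    labels = np.repeat(
        [c.value for c in LandCover], [counts[c] for c in LandCover]
    ).astype(np.int8)

    if clustering == 0.0:
        grid = labels[rng.permutation(n)].reshape(rows, cols)
        return Landscape(grid)

    # patch growth: each class grows from random seeds; with probability
    # `clustering` the next cell is taken from the class frontier,
    # otherwise from anywhere unfilled.
    grid = np.full((rows, cols), -1, dtype=np.int8)
    unfilled = set(range(n))
    class_order = [c for c in LandCover if counts[c] > 0]
    remaining = {c: counts[c] for c in class_order}
    frontiers: dict[LandCover, set[int]] = {c: set() for c in class_order}

    def neighbours(idx: int) -> list[int]:
        r, q = divmod(idx, cols)
        out = []
        if r > 0:
            out.append(idx - cols)
        if r < rows - 1:
            out.append(idx + cols)
        if q > 0:
            out.append(idx - 1)
        if q < cols - 1:
            out.append(idx + 1)
        return out

    while unfilled:
        for c in class_order:
            if remaining[c] == 0 or not unfilled:
                continue
            cand = frontiers[c] & unfilled
            if cand and rng.random() < clustering:
                idx = int(rng.choice(sorted(cand)))
            else:
                idx = int(rng.choice(sorted(unfilled)))
            grid.ravel()[idx] = c.value
            unfilled.discard(idx)
            frontiers[c].update(neighbours(idx))
            remaining[c] -= 1
    return Landscape(grid)


# ---------------------------------------------------------------------------
# file I/O


def load_rainfall_csv(path: str | Path, threshold_mm: float = 2.5) -> pd.DataFrame:
    """Load a ``date,rainfall_mm`` CSV into a daily climate frame."""
    frame = pd.read_csv(path, comment="#")
    if not {"date", "rainfall_mm"}.issubset(frame.columns):
        raise ValueError(f"{path}: rainfall CSV needs columns date,rainfall_mm")
    if (frame["rainfall_mm"] < 0).any():
        bad = frame.index[frame["rainfall_mm"] < 0][0]
        raise ValueError(f"{path}: negative rainfall at row {bad}")
    date = pd.to_datetime(frame["date"])
    out = pd.DataFrame(
        {
            "date": date,
            "year": date.dt.year,
            "month": date.dt.month,
            "day": date.dt.day,
            "rainfall_mm": frame["rainfall_mm"].astype(float),
        }
    )
    out["is_rainy"] = out["rainfall_mm"] >= threshold_mm
    return out


def save_rainfall_csv(climate: pd.DataFrame, path: str | Path) -> None:
    climate[["date", "rainfall_mm"]].to_csv(path, index=False)


def load_oni_csv(path: str | Path) -> OniSeries:
    """Load a ``year,month,oni`` CSV (NOAA-table-compatible columns)."""
    frame = pd.read_csv(path, comment="#")
    if not {"year", "month", "oni"}.issubset(frame.columns):
        raise ValueError(f"{path}: ONI CSV needs columns year,month,oni")
    entries = {
        (int(r.year), int(r.month)): float(r.oni) for r in frame.itertuples()
    }
    try:
        return OniSeries(entries)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def save_oni_csv(oni: OniSeries, path: str | Path) -> None:
    oni.to_frame().to_csv(path, index=False)


def load_landscape(path: str | Path, cell_size_m: float = 100.0) -> Landscape:
    """Load an ASCII land-cover grid (one row per line, class code letters)."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rows = []
    for i, ln in enumerate(lines):
        row = []
        for j, ch in enumerate(ln):
            if ch not in _CODE_COVER:
                raise ValueError(
                    f"{path}: unknown land-cover code {ch!r} at line {i + 1}, column {j + 1}"
                )
            row.append(_CODE_COVER[ch].value)
        rows.append(row)
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: ragged grid (lines of unequal length)")
    return Landscape(np.array(rows, dtype=np.int8), cell_size_m=cell_size_m)


def save_landscape(landscape: Landscape, path: str | Path) -> None:
    txt = "\n".join(
        "".join(_COVER_CODE[LandCover(v)] for v in row) for row in landscape.grid
    )
    Path(path).write_text(txt + "\n")
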