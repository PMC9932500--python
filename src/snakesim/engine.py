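"""Hourly farmer-snake contact process over the simulated landscape.

The engine advances the coupled system in one-hour steps across the whole
simulated horizon. Each day the snakes relocate (class-level habitat
choice, then a uniform cell of that class) and the day's farmer-snake
cell co-occupancies are resolved; each hour, every co-located
(working farmer, active snake) pair independently yields a bite with
probability

    p = bite_scale * (aggressiveness / 10)
        * daily_activity(hour) * seasonal_activity(monthly rain),

a farmer recording at most one bite per hour (first success). Seasonal
activity follows monthly rainfall with a configurable lag and is
modulated by a same-day wet/dry factor. Hours worked are accumulated in
a labour ledger so that incidence per farmer-hour can be formed from the
bite log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import (
    FarmerTraits,
    SnakeAgent,
    SnakeSpeciesParams,
    WorkSchedule,
    load_default_species,
    sample_snake_population,
    seasonal_activity_probability,
    snake_transition_weights,
)
from .environment import (
    ClimateGenParams,
    Landscape,
    LandCover,
    OniSeries,
    generate_daily_rainfall,
    generate_landscape,
    generate_oni_series,
    load_default_climatology,
)
from .scenarios import ScenarioParams, build_workforce_schedule, scenario_crop

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "BiteEvent",
    "SimulationResult",
    "bite_probability",
    "make_farmers",
    "step_hour",
    "run_simulation",
    "DEFAULT_CLASS_FRACTIONS",
    "DEFAULT_BITE_SCALE",
    "DEFAULT_SNAKE_SCALE_FACTOR",
]

# Landscape mix of the default desk-scale study area (50x50 one-hectare
# cells): three crop classes, forest matrix, water and homesteads.
DEFAULT_CLASS_FRACTIONS = {
    LandCover.RICE: 0.20,
    LandCover.TEA: 0.20,
    LandCover.RUBBER: 0.20,
    LandCover.FOREST: 0.25,
    LandCover.WATER: 0.05,
    LandCover.HOME: 0.10,
}

# Maps point-process intensity (per m^2) to expected agents at the default
# cell size, sized so the default 50x50 grid holds ~300 snakes in all.
DEFAULT_SNAKE_SCALE_FACTOR = 300.0

# Per-contact-hour bite scale; see scripts/derive_bite_scale.py for the
# calibration giving order 10^2-10^3 bites per default 10-year run.
DEFAULT_BITE_SCALE = 0.04


@dataclass
class BiteEvent:
    """One recorded snakebite."""

    year: int
    month: int
    day: int
    hour: int
    row: int
    col: int
    species: str
    farmer_id: int
    scenario: str


@dataclass
class SimulationConfig:
    """Full parameterisation of one simulation run (one arm)."""

    scenario: ScenarioParams
    years: int = 10
    start_year: int = 2008
    rows: int = 50
    cols: int = 50
    n_farmers: int = 30
    bite_scale: float = DEFAULT_BITE_SCALE
    snake_scale_factor: float = DEFAULT_SNAKE_SCALE_FACTOR
    seed: int = 0
    label: str = ""
    climate_params: ClimateGenParams | None = None
    oni: OniSeries | None = None
    landscape: Landscape | None = None
    species: Sequence[SnakeSpeciesParams] | None = None
    activity_lag_months: int | None = None
    class_fractions: dict[LandCover, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    clustering: float = 0.6
    relocation_hour: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.bite_scale <= 1.0:
            raise ValueError("bite_scale must lie in (0, 1]")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.n_farmers < 0:
            raise ValueError("n_farmers must be >= 0")


@dataclass
class SimulationResult:
    """Outputs of one run: the bite log, the labour ledger, run context."""

    bite_log: pd.DataFrame
    labor_ledger: pd.DataFrame
    climate: pd.DataFrame
    oni: OniSeries
    schedule: WorkSchedule
    config: SimulationConfig

    def total_bites(self) -> int:
        return len(self.bite_log)

    def total_hours(self) -> float:
        return float(self.labor_ledger["hours"].sum())


def bite_probability(
    species: SnakeSpeciesParams,
    hour: int,
    monthly_rain_mm: float,
    bite_scale: float = 1.0,
) -> float:
    """Per-contact-hour bite probability for a co-located, working farmer.

    The product of the bite scale, the species' relative aggressiveness
    (scored out of 10), its diel activity at the hour and its seasonal
    activity at the given monthly rainfall.
    """
    from .agents import daily_activity_probability

    p = (
        bite_scale
        * (species.aggressiveness / 10.0)
        * daily_activity_probability(species, hour)
        * seasonal_activity_probability(species, monthly_rain_mm)
    )
    return float(np.clip(p, 0.0, 1.0))


def make_farmers(
    crop: LandCover,
    n: int,
    landscape: Landscape,
    seed: int | np.random.Generator = 0,
    daily_hours: tuple[float, float] | float = (6.0, 10.0),
    fields_per_farmer: int = 3,
) -> list[FarmerTraits]:
    """Create a workforce of one crop: homes, fields and work-habit traits."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    homes = landscape.cells_of(LandCover.HOME)
    fields = landscape.cells_of(crop)
    if n > 0 and fields.size == 0:
        raise ValueError(f"landscape has no {crop.name} cells for {crop.name} farmers")
    out = []
    for i in range(n):
        if isinstance(daily_hours, tuple):
            dh = float(rng.uniform(*daily_hours))
        else:
            dh = float(daily_hours)
        k = min(fields_per_farmer, fields.size)
        out.append(
            FarmerTraits(
                farmer_id=i,
                farmer_type=crop,
                start_hour=int(rng.integers(4, 10)),
                daily_hours=dh,
                home_cell=int(rng.choice(homes)) if homes.size else 0,
                field_cells=rng.choice(fields, size=k, replace=False),
            )
        )
    return out


class SimulationState:
    """Mutable engine state: agents, schedules, forcing and the time cursor."""

    def __init__(
        self,
        config: SimulationConfig,
        landscape: Landscape,
        climate: pd.DataFrame,
        oni: OniSeries,
        species: Sequence[SnakeSpeciesParams],
        activity_lag: int,
        farmers: Sequence[FarmerTraits],
        schedule: WorkSchedule,
        snakes: Sequence[SnakeAgent],
        rng: np.random.Generator,
    ):
        self.config = config
        self.landscape = landscape
        self.climate = climate
        self.oni = oni
        self.species = list(species)
        self.farmers = list(farmers)
        self.schedule = schedule
        self.rng = rng
        self.day = 0
        self.hour = 0

        n_days = len(climate)
        self._day_year = climate["year"].to_numpy()
        self._day_month = climate["month"].to_numpy()
        self._day_dom = climate["day"].to_numpy()
        self._day_wet = climate["is_rainy"].to_numpy()

        # species-level arrays
        ns = len(self.species)
        self._profiles = np.stack([sp.daily_profile for sp in self.species])
        self._agg_p = np.array(
            [config.bite_scale * sp.aggressiveness / 10.0 for sp in self.species]
        )

        # monthly rainfall with lag, padded with climatology means before start
        monthly = climate.groupby(["year", "month"], sort=True)["rainfall_mm"].sum()
        n_months = config.years * 12
        rain_by_m = np.array(
            [
                monthly.loc[(config.start_year + i // 12, i % 12 + 1)]
                for i in range(n_months)
            ]
        )
        clim_means = np.asarray(
            (config.climate_params or load_default_climatology()).monthly_mean_rain_mm
        )
        lagged = np.empty(n_months)
        for i in range(n_months):
            j = i - activity_lag
            if j >= 0:
                lagged[i] = rain_by_m[j]
            else:
                lagged[i] = clim_means[j % 12]
        # effective seasonal activity per (day, species)
        self._eff_seasonal = np.empty((n_days, ns))
        m_idx = (self._day_year - config.start_year) * 12 + self._day_month - 1
        for s, sp in enumerate(self.species):
            base = np.array([sp.seasonal(r) for r in lagged])
            g = np.where(self._day_wet, sp.wet_day_factor, sp.dry_day_factor)
            self._eff_seasonal[:, s] = np.clip(base[m_idx] * g, 0.0, 1.0)

        # snake arrays
        name_to_idx = {sp.name: s for s, sp in enumerate(self.species)}
        self._snake_species = np.array(
            [name_to_idx[a.species.name] for a in snakes], dtype=np.int64
        )
        self._snake_cell = np.array([a.cell for a in snakes], dtype=np.int64)
        # per-species relocation distributions
        self._class_cells = {c: landscape.cells_of(c) for c in LandCover}
        self._cum_weights = []
        self._weight_classes = []
        for sp in self.species:
            w = snake_transition_weights(sp, landscape)
            cls = [c for c in LandCover if w[c] > 0]
            p = np.array([w[c] for c in cls])
            self._weight_classes.append(cls)
            self._cum_weights.append(np.cumsum(p))

        self._todays_pairs: list[tuple[int, np.ndarray]] = []
        self._todays_weights: np.ndarray | None = None
        self.events: list[BiteEvent] = []

    # -- daily phase ------------------------------------------------------

    def begin_day(self, day: int) -> None:
        """Relocate snakes and resolve today's farmer-snake co-occupancies."""
        self.day = day
        self.hour = 0
        rng = self.rng
        # class-level relocation, then a uniform cell of the class
        for s in range(len(self.species)):
            mask = self._snake_species == s
            ns = int(mask.sum())
            if ns == 0:
                continue
            ks = np.searchsorted(self._cum_weights[s], rng.random(ns))
            cells = np.empty(ns, dtype=np.int64)
            for j, c in enumerate(self._weight_classes[s]):
                sel = ks == j
                nsel = int(sel.sum())
                if nsel:
                    pool = self._class_cells[c]
                    cells[sel] = pool[rng.integers(0, pool.size, size=nsel)]
            self._snake_cell[mask] = cells

        sched = self.schedule
        wf = np.flatnonzero(sched.hours[:, day] > 0)
        self._working_today = wf
        self._todays_pairs = []
        if wf.size == 0 or self._snake_cell.size == 0:
            self._todays_weights = None
            return
        fc = sched.cell[wf, day]
        eq = self._snake_cell[None, :] == fc[:, None]
        hits = np.flatnonzero(eq.any(axis=1))
        for k in hits:
            self._todays_pairs.append((int(wf[k]), np.flatnonzero(eq[k])))
        # per-working-farmer hour weights (fractional first/last hour)
        w = np.zeros((wf.size, 24))
        starts = sched.start_hour[wf]
        hours = sched.hours[wf, day]
        for i in range(wf.size):
            lo, span = starts[i], hours[i]
            hi = lo + span
            full_end = int(np.floor(hi))
            w[i, lo:full_end] = 1.0
            if full_end < 24 and hi > full_end:
                w[i, full_end] = hi - full_end
        self._hour_weight_today = {int(wf[i]): w[i] for i in range(wf.size)}

    def has_contacts_today(self) -> bool:
        return bool(self._todays_pairs)


def step_hour(state: SimulationState) -> list[BiteEvent]:
    """Advance one hour: resolve bites for every co-located pair.

    Each (working farmer, snake) pair in a shared cell yields a bite with
    the per-contact-hour probability; the first success per farmer-hour
    is recorded and further snakes in that hour are ignored.
    """
    h = state.hour
    day = state.day
    events: list[BiteEvent] = []
    cfg = state.config
    cols = cfg.cols
    for farmer_idx, snake_idx in state._todays_pairs:
        w = state._hour_weight_today[farmer_idx][h]
        if w <= 0:
            continue
        sidx = state._snake_species[snake_idx]
        # snake active this hour?
        u_active = state.rng.random(snake_idx.size)
        active = u_active < state._profiles[sidx, h] * state._eff_seasonal[day, sidx]
        if not active.any():
            continue
        # bite attempt per active snake; first success caps the farmer-hour
        u_bite = state.rng.random(snake_idx.size)
        bites = active & (u_bite < state._agg_p[sidx] * w)
        if not bites.any():
            continue
        first = int(np.flatnonzero(bites)[0])
        cell = int(state.schedule.cell[farmer_idx, day])
        events.append(
            BiteEvent(
                year=int(state._day_year[day]),
                month=int(state._day_month[day]),
                day=int(state._day_dom[day]),
                hour=h,
                row=cell // cols,
                col=cell % cols,
                species=state.species[int(sidx[first])].name,
                farmer_id=state.farmers[farmer_idx].farmer_id,
                scenario=cfg.label,
            )
        )
    state.events.extend(events)
    state.hour = h + 1
    return events


def build_state(config: SimulationConfig) -> SimulationState:
    """Assemble forcing, landscape, agents and schedules for a run.

    A single seed expands into independent substreams (climate, landscape,
    farmer traits, snake placement, scheduling, contact process) so that
    matched arms differing only in the scenario share every other input.
    """
    ss = np.random.SeedSequence(config.seed)
    s_climate, s_land, s_farm, s_snake, s_sched, s_contact = [
        np.random.default_rng(c) for c in ss.spawn(6)
    ]

    climate_params = config.climate_params or load_default_climatology()
    oni = config.oni or generate_oni_series(
        config.years, seed=s_climate, start_year=config.start_year
    )
    climate = generate_daily_rainfall(
        climate_params, oni, config.years, seed=s_climate, start_year=config.start_year
    )
    landscape = config.landscape or generate_landscape(
        config.rows, config.cols, config.class_fractions, config.clustering, seed=s_land
    )
    if config.landscape is not None:
        config.rows, config.cols = landscape.shape

    if config.species is None:
        species, lag_default = load_default_species()
    else:
        species, lag_default = list(config.species), 2
    lag = config.activity_lag_months if config.activity_lag_months is not None else lag_default

    crop = scenario_crop(config.scenario)
    from .scenarios import TeaScenarioParams

    if isinstance(config.scenario, TeaScenarioParams):
        dh: tuple[float, float] | float = config.scenario.baseline_daily_hours
    else:
        dh = (6.0, 10.0)
    farmers = make_farmers(crop, config.n_farmers, landscape, seed=s_farm, daily_hours=dh)
    schedule = build_workforce_schedule(config.scenario, farmers, climate, seed=s_sched)

    snakes: list[SnakeAgent] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp in species:
            snakes.extend(
                sample_snake_population(sp, landscape, config.snake_scale_factor, seed=s_snake)
            )
    if config.n_farmers == 0 and not snakes:
        warnings.warn("simulation has zero farmers and zero snakes", stacklevel=2)

    return SimulationState(
        config, landscape, climate, oni, species, lag, farmers, schedule, snakes, s_contact
    )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the full horizon: hourly contact steps over years of days.

    Deterministic for a fixed seed. Returns the bite log, the labour
    ledger (hours actually spent in fields per farmer per day) and the
    generated forcing.
    """
    state = build_state(config)
    n_days = len(state.climate)
    for day in range(n_days):
        state.begin_day(day)
        if not state.has_contacts_today():
            continue
        for _ in range(24):
            step_hour(state)

    bite_log = pd.DataFrame(
        [vars(e) for e in state.events],
        columns=["year", "month", "day", "hour", "row", "col", "species", "farmer_id", "scenario"],
    )
    fi, di = np.nonzero(state.schedule.hours > 0)
    labor_ledger = pd.DataFrame(
        {
            "farmer_id": [state.farmers[i].farmer_id for i in fi],
            "year": state._day_year[di],
            "month": state._day_month[di],
            "day": state._day_dom[di],
            "hours": state.schedule.hours[fi, di],
        }
    )
    return SimulationResult(
        bite_log=bite_log,
        labor_ledger=labor_ledger,
        climate=state.climate,
        oni=state.oni,
        schedule=state.schedule,
        config=config,
    )
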