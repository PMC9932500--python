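"""Snake and farmer agents and their behavioural primitives.

Snakes carry per-species ecology: an abundance intensity (a homogeneous
point-process rate per m^2), a seasonal activity curve driven by monthly
rainfall, a 24-hour diel activity profile, an aggressiveness score (the
relative propensity to bite on contact) and per-land-cover habitat
association weights. Movement is class-level: a snake relocates by
sampling a destination cover class with probability proportional to
(association x class area), then a uniform cell of that class.

Farmers carry a crop type, a fixed daily start hour, a daily working
duration, a home cell and the field cells of their crop. Their day-by-day
presence in fields is resolved by the scenario layer into a
:class:`WorkSchedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .environment import Landscape, LandCover

__all__ = [
    "SeasonalActivityCurve",
    "SnakeSpeciesParams",
    "SnakeAgent",
    "FarmerTraits",
    "WorkSchedule",
    "load_default_species",
    "load_species_yaml",
    "seasonal_activity_probability",
    "daily_activity_probability",
    "snake_transition_weights",
    "sample_snake_population",
    "is_farmer_working",
]

MAX_ABUNDANCE_INTENSITY = 3e-8   # individuals per m^2
MAX_LAND_ASSOCIATION = 2.429
SPECIES_NAMES = ("Daboia russelii", "Naja naja", "Hypnale hypnale")


@dataclass
class SeasonalActivityCurve:
    """Logistic response of monthly activity probability to rainfall.

    ``floor + (ceiling - floor) / (1 + exp(-(rain - midpoint)/slope))``,
    a smooth, monotone, bounded precipitation-activity relationship.
    """

    floor: float = 0.2
    ceiling: float = 0.9
    midpoint_mm: float = 250.0
    slope_mm: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor <= self.ceiling <= 1.0:
            raise ValueError("need 0 <= floor <= ceiling <= 1")
        if self.slope_mm <= 0:
            raise ValueError("slope_mm must be > 0")

    def __call__(self, monthly_rain_mm: float) -> float:
        if monthly_rain_mm < 0:
            raise ValueError("monthly rainfall must be >= 0")
        z = (monthly_rain_mm - self.midpoint_mm) / self.slope_mm
        return float(self.floor + (self.ceiling - self.floor) / (1.0 + np.exp(-z)))


@dataclass
class SnakeSpeciesParams:
    """Ecological and behavioural trait set of one snake species."""

    name: str
    abundance_intensity: float
    seasonal: SeasonalActivityCurve
    daily_profile: Sequence[float]
    aggressiveness: float
    land_association: Mapping[LandCover, float]
    wet_day_factor: float = 1.3
    dry_day_factor: float = 0.85

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance_intensity <= MAX_ABUNDANCE_INTENSITY:
            raise ValueError(
                f"{self.name}: abundance_intensity must lie in [0, {MAX_ABUNDANCE_INTENSITY}]"
            )
        prof = np.asarray(self.daily_profile, dtype=float)
        if prof.shape != (24,):
            raise ValueError(f"{self.name}: daily_profile needs exactly 24 entries")
        if np.any(prof < 0) or np.any(prof > 1):
            raise ValueError(f"{self.name}: daily_profile values must lie in [0, 1]")
        if not 1.0 <= self.aggressiveness <= 10.0:
            raise ValueError(f"{self.name}: aggressiveness must lie in [1, 10]")
        assoc = {LandCover(k): float(v) for k, v in self.land_association.items()}
        missing = set(LandCover) - set(assoc)
        if missing:
            raise ValueError(f"{self.name}: land_association missing {sorted(missing)}")
        for c, w in assoc.items():
            if not 0.0 <= w <= MAX_LAND_ASSOCIATION:
                raise ValueError(
                    f"{self.name}: land_association[{c.name}] must lie in [0, {MAX_LAND_ASSOCIATION}]"
                )
        self.daily_profile = prof
        self.land_association = assoc


@dataclass
class SnakeAgent:
    """One snake: a species reference, a current grid cell, an activity flag."""

    species: SnakeSpeciesParams
    cell: int
    active: bool = False


def seasonal_activity_probability(species: SnakeSpeciesParams, monthly_rain_mm: float) -> float:
    """Probability that the species is seasonally active at the given monthly rainfall."""
    return species.seasonal(monthly_rain_mm)


def daily_activity_probability(species: SnakeSpeciesParams, hour: int) -> float:
    """Hourly activity probability from the species' 24-hour diel profile."""
    if not 0 <= int(hour) <= 23 or int(hour) != hour:
        raise ValueError(f"hour must be an integer in 0..23, got {hour!r}")
    return float(species.daily_profile[int(hour)])


def snake_transition_weights(
    species: SnakeSpeciesParams, landscape: Landscape
) -> dict[LandCover, float]:
    """Class-level movement distribution: association x class area, normalised."""
    fracs = landscape.area_fraction()
    weights = {c: species.land_association[c] * fracs[c] for c in LandCover}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(
            f"{species.name}: no admissible habitat (all association x area weights are zero)"
        )
    return {c: w / total for c, w in weights.items()}


def sample_snake_population(
    species: SnakeSpeciesParams,
    landscape: Landscape,
    scale_factor: float,
    seed: int | np.random.Generator = 0,
) -> list[SnakeAgent]:
    """Draw a snake population from a homogeneous point process.

    The count is Poisson with mean ``intensity x landscape area x
    scale_factor``; initial cells follow the class-level movement
    distribution (uniform within the destination class).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    area = landscape.n_cells * landscape.cell_area_m2
    lam = species.abundance_intensity * area * scale_factor
    if lam <= 0:
        import warnings

        warnings.warn(f"{species.name}: expected population is zero", stacklevel=2)
        return []
    n = int(rng.poisson(lam))
    weights = snake_transition_weights(species, landscape)
    classes = [c for c in LandCover if weights[c] > 0]
    probs = np.array([weights[c] for c in classes])
    agents: list[SnakeAgent] = []
    if n == 0:
        return agents
    picks = rng.choice(len(classes), size=n, p=probs)
    for k in picks:
        cells = landscape.cells_of(classes[k])
        agents.append(SnakeAgent(species=species, cell=int(rng.choice(cells))))
    return agents


@dataclass
class FarmerTraits:
    """Static traits of one farmer agent (Table-1-style ranges enforced)."""

    farmer_id: int
    farmer_type: LandCover
    start_hour: int
    daily_hours: float
    home_cell: int
    field_cells: np.ndarray
    work_index: float = 55.0

    def __post_init__(self) -> None:
        if self.farmer_type not in (LandCover.RICE, LandCover.RUBBER, LandCover.TEA):
            raise ValueError("farmer_type must be Rice, Rubber or Tea")
        if not 4 <= self.start_hour <= 9:
            raise ValueError("start_hour must lie in 4..9 (AM)")
        if not 4.0 <= self.daily_hours <= 14.0:
            raise ValueError("daily_hours must lie in [4, 14]")
        if not 0.0 <= self.work_index <= 110.0:
            raise ValueError("work_index must lie in [0, 110]")
        self.field_cells = np.asarray(self.field_cells, dtype=np.int64)
        if self.field_cells.size == 0:
            raise ValueError("field_cells must be nonempty")


class WorkSchedule:
    """Per-farmer, per-day field presence over the simulated horizon.

    Backed by dense arrays over (farmer, day): ``hours`` is 0 on off-days,
    ``cell`` is the field cell the farmer works that day (-1 when off).
    Start hours are a fixed per-farmer trait.
    """

    def __init__(self, farmers: Sequence[FarmerTraits], n_days: int):
        self.farmers = list(farmers)
        f = len(self.farmers)
        self.hours = np.zeros((f, n_days), dtype=float)
        self.cell = np.full((f, n_days), -1, dtype=np.int64)
        self.start_hour = np.array([fa.start_hour for fa in self.farmers], dtype=np.int64)

    @property
    def n_days(self) -> int:
        return self.hours.shape[1]

    def set_workday(self, farmer_idx: int, day: int, hours: float, cell: int) -> None:
        if not 4.0 <= hours <= 14.0:
            raise ValueError(f"working hours must lie in [4, 14], got {hours}")
        self.hours[farmer_idx, day] = hours
        self.cell[farmer_idx, day] = cell

    def total_hours(self) -> float:
        return float(self.hours.sum())


def is_farmer_working(schedule: WorkSchedule, farmer_idx: int, day: int, hour: int) -> bool:
    """True iff the farmer is in a field during [hour, hour+1) on the given day.

    Working hours form the half-open interval
    ``[start_hour, start_hour + daily_hours)``.
    """
    h = schedule.hours[farmer_idx, day]
    if h <= 0:
        return False
    start = schedule.start_hour[farmer_idx]
    return start <= hour < start + h


# ---------------------------------------------------------------------------
# species parameter files


def _species_from_dict(block: dict, lag_default: int) -> SnakeSpeciesParams:
    assoc = {LandCover[k.upper()]: float(v) for k, v in block["land_association"].items()}
    return SnakeSpeciesParams(
        name=block["name"],
        abundance_intensity=float(block["abundance_intensity"]),
        seasonal=SeasonalActivityCurve(
            floor=float(block["seasonal"]["floor"]),
            ceiling=float(block["seasonal"]["ceiling"]),
            midpoint_mm=float(block["seasonal"]["midpoint_mm"]),
            slope_mm=float(block["seasonal"]["slope_mm"]),
        ),
        daily_profile=block["daily_profile"],
        aggressiveness=float(block["aggressiveness"]),
        land_association=assoc,
        wet_day_factor=float(block.get("wet_day_factor", 1.3)),
        dry_day_factor=float(block.get("dry_day_factor", 0.85)),
    )


def load_species_yaml(path: str | Path) -> tuple[list[SnakeSpeciesParams], int]:
    """Load a species parameter file; returns (species list, activity lag in months)."""
    raw = yaml.safe_load(Path(path).read_text())
    lag = int(raw.get("activity_lag_months", 2))
    species = [_species_from_dict(b, lag) for b in raw["species"]]
    return species, lag


def load_default_species() -> tuple[list[SnakeSpeciesParams], int]:
    """The packaged default trait sets for the three Sri Lankan species."""
    ref = resources.files("snakesim.data") / "species_defaults.yaml"
    with resources.as_file(ref) as path:
        return load_species_yaml(path)
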