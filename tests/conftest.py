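"""Shared fixtures: small landscapes, neutral forcing, toy species."""

from __future__ import annotations

import numpy as np
import pytest

from snakesim.agents import SeasonalActivityCurve, SnakeSpeciesParams
from snakesim.environment import (
    ClimateGenParams,
    Landscape,
    LandCover,
    OniSeries,
    generate_daily_rainfall,
)


@pytest.fixture
def climatology() -> ClimateGenParams:
    from snakesim.environment import load_default_climatology

    return load_default_climatology()


def neutral_oni(years: int, start_year: int = 2008) -> OniSeries:
    return OniSeries(
        {(start_year + i // 12, i % 12 + 1): 0.0 for i in range(12 * years)}
    )


@pytest.fixture
def oni_zero() -> OniSeries:
    return neutral_oni(3)


@pytest.fixture
def one_year_climate(climatology, oni_zero):
    return generate_daily_rainfall(climatology, neutral_oni(1), 1, seed=42)


def flat_species(
    name: str = "Testus testus",
    profile_value: float = 1.0,
    aggressiveness: float = 10.0,
    association: dict | None = None,
    floor: float = 1.0,
    ceiling: float = 1.0,
) -> SnakeSpeciesParams:
    """A species with constant activity, handy for analytic oracles."""
    assoc = {c: 1.0 for c in LandCover}
    if association:
        assoc.update(association)
    return SnakeSpeciesParams(
        name=name,
        abundance_intensity=2e-8,
        seasonal=SeasonalActivityCurve(floor=floor, ceiling=ceiling),
        daily_profile=[profile_value] * 24,
        aggressiveness=aggressiveness,
        land_association=assoc,
        wet_day_factor=1.0,
        dry_day_factor=1.0,
    )


@pytest.fixture
def checker_landscape() -> Landscape:
    """A 4x4 landscape with rice, home and forest cells."""
    grid = np.array(
        [
            [LandCover.RICE, LandCover.RICE, LandCover.FOREST, LandCover.HOME],
            [LandCover.RICE, LandCover.RICE, LandCover.FOREST, LandCover.HOME],
            [LandCover.TEA, LandCover.TEA, LandCover.RUBBER, LandCover.RUBBER],
            [LandCover.TEA, LandCover.TEA, LandCover.RUBBER, LandCover.WATER],
        ],
        dtype=np.int8,
    )
    return Landscape(grid)
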