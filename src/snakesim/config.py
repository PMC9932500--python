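"""Experiment presets, configuration validation and orchestration.

A preset bundles everything one paired adaptation experiment needs: the
packaged climatology, the default species trait sets, a landscape mix,
the crop workforce and the baseline/adapted scenario pair. The two arms
of a preset differ only in the adaptation flag; they share the seed, so
climate, landscape, farmers and snakes are matched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import MAX_ABUNDANCE_INTENSITY, MAX_LAND_ASSOCIATION, load_default_species
from .engine import SimulationConfig
from .environment import generate_oni_series
from .scenarios import (
    RiceScenarioParams,
    RubberScenarioParams,
    TeaScenarioParams,
)
from .stats import ExperimentOutcome, compare_strategies

__all__ = [
    "PRESET_NAMES",
    "ExperimentPreset",
    "build_preset",
    "validate_config",
    "run_experiment",
]

log = logging.getLogger(__name__)

PRESET_NAMES = ("rice", "rubber", "tea")


@dataclass
class ExperimentPreset:
    """A paired baseline/adapted experiment specification."""

    name: str
    baseline: SimulationConfig
    adapted: SimulationConfig
    replicates: int = 20

    def __post_init__(self) -> None:
        if self.name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.name!r}; valid presets: {PRESET_NAMES}")


def build_preset(
    name: str,
    years: int = 10,
    replicates: int = 20,
    seed: int = 0,
    n_farmers: int = 30,
) -> ExperimentPreset:
    """Construct the packaged experiment preset for one crop.

    The ONI series is generated once from the seed and shared by every
    replicate of both arms, mirroring a single observed ENSO decade.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; valid presets: {PRESET_NAMES}")
    oni = generate_oni_series(years, seed=np.random.SeedSequence((seed, 0xE15)).generate_state(1)[0])
    pairs = {
        "rice": (
            RiceScenarioParams(variety="conventional"),
            RiceScenarioParams(variety="short_duration"),
        ),
        "rubber": (RubberScenarioParams(adapted=False), RubberScenarioParams(adapted=True)),
        "tea": (TeaScenarioParams(adapted=False), TeaScenarioParams(adapted=True)),
    }
    base_sc, adap_sc = pairs[name]
    common = dict(years=years, seed=seed, n_farmers=n_farmers, oni=oni)
    return ExperimentPreset(
        name=name,
        baseline=SimulationConfig(scenario=base_sc, label=f"{name}-baseline", **common),
        adapted=SimulationConfig(scenario=adap_sc, label=f"{name}-adapted", **common),
        replicates=replicates,
    )


def validate_config(config: SimulationConfig) -> list[str]:
    """Itemised validation of a run configuration against the trait ranges.

    Returns an empty list when the configuration is valid.
    """
    errors: list[str] = []
    if not 0.0 < config.bite_scale <= 1.0:
        errors.append(f"bite_scale {config.bite_scale} outside (0, 1]")
    if config.years < 1:
        errors.append(f"years {config.years} must be >= 1")
    if config.n_farmers < 0:
        errors.append(f"n_farmers {config.n_farmers} must be >= 0")
    species = config.species
    if species is None:
        species, _ = load_default_species()
    for sp in species:
        if not 0 <= sp.abundance_intensity <= MAX_ABUNDANCE_INTENSITY:
            errors.append(
                f"{sp.name}: abundance intensity {sp.abundance_intensity} "
                f"outside [0, {MAX_ABUNDANCE_INTENSITY}]"
            )
        if not 1 <= sp.aggressiveness <= 10:
            errors.append(f"{sp.name}: aggressiveness {sp.aggressiveness} outside 1-10")
        for cover, w in sp.land_association.items():
            if not 0 <= w <= MAX_LAND_ASSOCIATION:
                errors.append(
                    f"{sp.name}: land association {w} for {cover.name} "
                    f"outside 0-{MAX_LAND_ASSOCIATION}"
                )
    if isinstance(config.scenario, TeaScenarioParams):
        if not 4 <= config.scenario.baseline_daily_hours <= 14:
            errors.append(
                f"tea baseline_daily_hours {config.scenario.baseline_daily_hours} outside 4-14"
            )
    return errors


def validate_farmer_fields(start_hour: int, daily_hours: float) -> list[str]:
    """Range checks for farmer trait values (start hour 4-9, hours 4-14)."""
    errors = []
    if not 4 <= start_hour <= 9:
        errors.append(f"start_hour {start_hour} outside allowed range 4-9")
    if not 4 <= daily_hours <= 14:
        errors.append(f"daily_hours {daily_hours} outside allowed range 4-14")
    return errors


def _config_digest(preset: ExperimentPreset) -> str:
    def enc(cfg: SimulationConfig) -> dict:
        d = {}
        for f in dataclasses.fields(cfg):
            v = getattr(cfg, f.name)
            if f.name in ("oni", "landscape", "species", "climate_params"):
                continue
            if dataclasses.is_dataclass(v):
                v = dataclasses.asdict(v)
            if isinstance(v, dict):
                v = {str(k): val for k, val in v.items()}
            d[f.name] = v
        return d

    payload = json.dumps(
        {"name": preset.name, "replicates": preset.replicates,
         "baseline": enc(preset.baseline), "adapted": enc(preset.adapted)},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(
    preset: str | ExperimentPreset,
    out_dir: str | Path,
    years: int = 10,
    replicates: int = 20,
    seed: int = 0,
    adapted_only: bool = False,
    baseline_only: bool = False,
    make_plots: bool = True,
) -> ExperimentOutcome | None:
    """Run a preset end to end and write its artifacts to ``out_dir``.

    Writes bite logs and labour ledgers per arm, tidy ``comparisons.csv``
    and ``regressions.csv``, diagnostic plots and a run-metadata JSON
    embedding the config digest and seed. With ``adapted_only`` or
    ``baseline_only`` a single arm is simulated and the comparison stage
    is skipped (returns None).
    """
    if isinstance(preset, str):
        preset = build_preset(preset, years=years, replicates=replicates, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for cfg in (preset.baseline, preset.adapted):
        errs = validate_config(cfg)
        if errs:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errs))

    if adapted_only or baseline_only:
        from .stats import monthly_outcomes, run_replicates

        cfg = preset.adapted if adapted_only else preset.baseline
        results = run_replicates(cfg, preset.replicates)
        for i, res in enumerate(results):
            res.bite_log.to_csv(out / f"bites_{cfg.label}_rep{i}.csv", index=False)
            res.labor_ledger.to_csv(out / f"ledger_{cfg.label}_rep{i}.csv", index=False)
        frames = [monthly_outcomes(r).assign(replicate=i) for i, r in enumerate(results)]
        pd.concat(frames, ignore_index=True).to_csv(out / f"monthly_{cfg.label}.csv", index=False)
        outcome = None
    else:
        outcome = compare_strategies(
            preset.baseline, preset.adapted, replicates=preset.replicates,
            bootstrap_seed=seed,
        )
        outcome.comparisons_frame().to_csv(out / "comparisons.csv", index=False)
        outcome.regressions_frame().to_csv(out / "regressions.csv", index=False)
        outcome.monthly.to_csv(out / "monthly_outcomes.csv", index=False)
        for arm, results in (
            ("baseline", outcome.baseline_results),
            ("adapted", outcome.adapted_results),
        ):
            bites = [r.bite_log.assign(replicate=i) for i, r in enumerate(results)]
            pd.concat(bites, ignore_index=True).to_csv(out / f"bites_{arm}.csv", index=False)
        if make_plots:
            _write_plots(outcome, out, preset.name)

    meta = {
        "preset": preset.name,
        "seed": seed,
        "years": preset.baseline.years,
        "replicates": preset.replicates,
        "config_digest": _config_digest(preset),
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return outcome


def _write_plots(outcome: ExperimentOutcome, out: Path, name: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    annual = (
        outcome.monthly.groupby(["strategy", "year"], as_index=False)["bites"].sum()
    )
    fig, ax = plt.subplots(figsize=(7, 4))
    for arm, sub in annual.groupby("strategy"):
        ax.plot(sub["year"], sub["bites"], marker="o", label=arm)
    ax.set_xlabel("year")
    ax.set_ylabel("total bites (all replicates)")
    ax.set_title(f"{name}: annual snakebites by strategy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "annual_bites.png", dpi=120)
    plt.close(fig)

    oni = outcome.baseline_results[0].oni
    from .environment import Season, month_to_season

    pooled = outcome.monthly.groupby(["strategy", "year", "month"], as_index=False)["bites"].sum()
    pooled["season"] = pooled["month"].map(lambda m: month_to_season(m).value)
    pooled["oni"] = [oni.get(int(r.year), int(r.month)) for r in pooled.itertuples()]
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, season in zip(axes.ravel(), Season):
        sub = pooled[pooled["season"] == season.value]
        for arm, ss in sub.groupby("strategy"):
            ax.scatter(ss["oni"], ss["bites"], s=12, label=arm, alpha=0.7)
        ax.set_title(season.value)
    axes[0, 0].legend()
    for ax in axes[-1]:
        ax.set_xlabel("ONI")
    for ax in axes[:, 0]:
        ax.set_ylabel("monthly bites")
    fig.tight_layout()
    fig.savefig(out / "seasonal_oni.png", dpi=120)
    plt.close(fig)
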