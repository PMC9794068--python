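"""Scenario matrix and replicated multi-year experiment runner.

The mitigation-scenario matrix crosses three insecticide lethality classes
(LR90/LR50/LR25), spray-drift reduction (50 % baseline, 90 % tested for
LR90 only) and grassy field margins on/off, for each of two environmental
half-lives (1.3 and 25 days at 20 degC): 16 scenarios in total, with the
worst case (LR90, 50 % drift reduction, no margins) as the per-half-life
baseline.

Replicates share the landscape geometry and weather but redraw the beetle
placement, rotation starting points and event-timing draws. A replicate's
random stream is keyed on (master seed, replicate) and shared by every
scenario — common random numbers, so scenario contrasts at equal
replicate are paired — and each run re-creates its generator from the
key, so results are bit-reproducible and independent of scenario
execution order.
"""

from __future__ import annotations

import copy
import logging
import zlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abm, endpoints
from .abm import BeetleParams, PopulationState
from .exposure import DriftCurve, ExposureGrid, PesticideProduct
from .farms import (
    FarmingSystem,
    ScheduledEvent,
    advance_rotation,
    current_crop,
    init_rotation_start,
    load_farming_system,
    schedule_year,
)
from .landscape import (
    FarmUnit,
    FieldParcel,
    LandscapeConfig,
    LandscapeGrid,
    add_field_margins,
    add_water_buffers,
    generate_landscape,
)
from .weather import DAYS_PER_YEAR, WeatherSeries, generate_weather

logger = logging.getLogger(__name__)

LR_CLASSES = ("LR90", "LR50", "LR25")
DT50_CLASSES = (25.0, 1.3)
MARGIN_FRACTION = 0.5
MARGIN_WIDTH_M = 4.0


@dataclass(frozen=True)
class Scenario:
    """One mitigation-measure combination."""

    lr_class: str
    drift_reduction: float
    margins_on: bool
    dt50: float

    def __post_init__(self) -> None:
        if self.lr_class not in LR_CLASSES:
            raise ValueError(f"unknown lethality class {self.lr_class!r}")
        if self.drift_reduction not in (0.5, 0.9):
            raise ValueError("drift reduction must be 0.5 or 0.9")
        if self.drift_reduction == 0.9 and self.lr_class != "LR90":
            raise ValueError("90% drift reduction is only combined with LR90")

    @property
    def id(self) -> str:
        fm = "FMON" if self.margins_on else "FMOFF"
        dt = f"{self.dt50:g}"
        return f"{self.lr_class}_DR{int(self.drift_reduction * 100)}_{fm}_DT{dt}"

    @property
    def is_baseline(self) -> bool:
        return (
            self.lr_class == "LR90"
            and self.drift_reduction == 0.5
            and not self.margins_on
        )


def build_matrix() -> list[Scenario]:
    """The full 16-scenario matrix (8 combinations per half-life class)."""
    out: list[Scenario] = []
    for dt50 in DT50_CLASSES:
        for margins in (False, True):
            out.append(Scenario("LR90", 0.5, margins, dt50))
            out.append(Scenario("LR90", 0.9, margins, dt50))
            out.append(Scenario("LR50", 0.5, margins, dt50))
            out.append(Scenario("LR25", 0.5, margins, dt50))
    return out


@dataclass
class ExperimentConfig:
    """Experiment-level settings (desk-scale defaults)."""

    landscape: LandscapeConfig = dc_field(default_factory=LandscapeConfig)
    n_replicates: int = 3
    n_years: int = 5
    master_seed: int = 1
    endpoint_day: int = endpoints.ENDPOINT_DAY
    density_super_per_km2: float = 2000.0   # 200 000 per 100 km^2, area-scaled
    margin_fraction: float = MARGIN_FRACTION
    margin_width_m: float = MARGIN_WIDTH_M
    beetle: BeetleParams = dc_field(default_factory=BeetleParams)
    farming_config: str | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_years < 1:
            raise ValueError("need at least one replicate and one year")


def study_scale_config(master_seed: int = 1) -> ExperimentConfig:
    """The study-scale profile: 10 x 10 km at 1-m cells, 30 years, 10
    replicates (long-running; desk profile is the default)."""
    return ExperimentConfig(
        landscape=LandscapeConfig(
            width_m=10_000.0, height_m=10_000.0, cell_size_m=1.0, n_fields=2000
        ),
        n_replicates=10,
        n_years=30,
        master_seed=master_seed,
    )


def _stream(master_seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic RNG stream keyed on strings/ints (order-independent
    with respect to which other streams were created)."""
    ints = [master_seed & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) & 0x7FFFFFFF)
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


@dataclass
class LandscapeBundle:
    grid: LandscapeGrid
    parcels: list[FieldParcel]
    farms: list[FarmUnit]


def prepare_landscapes(config: ExperimentConfig) -> dict[bool, LandscapeBundle]:
    """Build the shared geometry in both margin variants (False/True).

    The two variants differ only in the margin layer: margins are carved
    from the buffered base landscape with a seed independent of scenarios.
    """
    rng = _stream(config.master_seed, "landscape")
    grid, parcels, farms = generate_landscape(
        config.landscape, seed=int(rng.integers(2**31))
    )
    grid = add_water_buffers(grid)
    base = LandscapeBundle(grid, parcels, farms)

    parcels_on = copy.deepcopy(parcels)
    grid_on = add_field_margins(
        grid,
        parcels_on,
        fraction=config.margin_fraction,
        width_m=config.margin_width_m,
        seed=_stream(config.master_seed, "margins"),
    )
    return {False: base, True: LandscapeBundle(grid_on, parcels_on, farms)}


def run_replicate(
    scenario: Scenario,
    replicate: int,
    bundle: LandscapeBundle,
    weather: WeatherSeries,
    system: FarmingSystem,
    config: ExperimentConfig,
) -> list[endpoints.EndpointRecord]:
    """Run one replicate of one scenario and return its yearly endpoints.

    The stream is keyed on (master seed, replicate) only: a replicate is a
    set of initial conditions (beetle placement, rotation phases, event
    timing draws) shared by every scenario, so scenario contrasts at equal
    replicate are paired (common random numbers) and execution order still
    cannot affect any output.
    """
    rng = _stream(config.master_seed, "replicate", replicate)
    grid = bundle.grid
    parcels = copy.deepcopy(bundle.parcels)
    farm_of = {f.id: f for f in bundle.farms}
    for p in parcels:
        init_rotation_start(p, rng)

    state = abm.init_population(
        grid,
        rng=rng,
        density_super_per_km2=config.density_super_per_km2,
        super_factor=config.beetle.super_factor,
    )
    product = PesticideProduct("insecticide", scenario.lr_class, scenario.dt50)
    curve = DriftCurve(reduction=scenario.drift_reduction)
    exposure = ExposureGrid.zeros_like(grid)

    # 5-day running mean temperature for the spring dispersal trigger
    kernel = np.ones(config.beetle.movement.spring_window_days)
    run_mean = np.convolve(weather.tmean_c, kernel / kernel.size, mode="full")[
        : len(weather.tmean_c)
    ]
    trigger_c = config.beetle.movement.spring_trigger_c

    records: list[endpoints.EndpointRecord] = []
    for year in range(config.n_years):
        events_by_day: dict[int, list[ScheduledEvent]] = {}
        for p in parcels:
            crop = current_crop(p, farm_of[p.farm_id], system)
            plan = system.plans[crop]
            for ev in schedule_year(plan, year, weather, rng, field_id=p.id):
                events_by_day.setdefault(ev.day, []).append(ev)
        for doy in range(1, DAYS_PER_YEAR + 1):
            t_idx = weather.day_index(year, doy)
            today = (
                float(weather.tmean_c[t_idx]),
                float(weather.wind_ms[t_idx]),
                float(weather.precip_mm[t_idx]),
            )
            abm.step_day(
                state,
                grid,
                exposure,
                events_by_day.get(doy, ()),
                today,
                rng,
                params=config.beetle,
                product=product,
                curve=curve,
                spring_wake=bool(run_mean[t_idx] >= trigger_c),
            )
            if doy == config.endpoint_day:
                records.append(
                    endpoints.measure(state, grid, scenario.id, replicate)
                )
        for p in parcels:
            advance_rotation(p)
    return records


def run_experiment(
    config: ExperimentConfig,
    scenarios: list[Scenario] | None = None,
    outdir: str | Path | None = None,
    progress=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run scenario x replicate simulations and aggregate the endpoints.

    Returns (endpoint records, scenario summary, AOR deltas). AOR deltas
    are computed against the matching-half-life baseline where that
    baseline is part of the run. With ``outdir`` set, tables are written
    as CSV; on a mid-run failure the partial records are flushed next to a
    ``FAILED`` marker before the exception propagates.
    """
    scenarios = scenarios if scenarios is not None else build_matrix()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    system = load_farming_system(config.farming_config)
    bundles = prepare_landscapes(config)
    weather = generate_weather(config.n_years, _stream(config.master_seed, "weather"))

    records: list[endpoints.EndpointRecord] = []
    try:
        for scenario in scenarios:
            for rep in range(config.n_replicates):
                if progress is not None:
                    progress(f"{scenario.id} replicate {rep}")
                records.extend(
                    run_replicate(
                        scenario, rep, bundles[scenario.margins_on], weather,
                        system, config,
                    )
                )
    except Exception:
        if outdir is not None and records:
            endpoints.records_to_frame(records).to_csv(
                outdir / "endpoints_partial.csv", index=False
            )
            (outdir / "FAILED").write_text("run aborted; partial results flushed\n")
        raise

    rec_df = endpoints.records_to_frame(records)
    summary = endpoints.summarize(rec_df)

    aor_frames = []
    for dt50 in sorted({s.dt50 for s in scenarios}):
        baseline = next(
            (s for s in scenarios if s.dt50 == dt50 and s.is_baseline), None
        )
        if baseline is None:
            continue
        group_ids = [s.id for s in scenarios if s.dt50 == dt50]
        sub = summary[summary["scenario_id"].isin(group_ids)]
        aor_frames.append(endpoints.aor_table(sub, baseline.id))
    aor = (
        pd.concat(aor_frames, ignore_index=True)
        if aor_frames
        else pd.DataFrame(columns=["scenario_id", "d_occupancy", "d_abundance", "d_density"])
    )

    if outdir is not None:
        rec_df.to_csv(outdir / "endpoints.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        aor.to_csv(outdir / "aor.csv", index=False)
    return rec_df, summary, aor
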