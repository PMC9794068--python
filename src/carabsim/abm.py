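"""Daily-time-step super-individual model of *Bembidion lampros*.

Each agent is a super-individual representing (by default) 100 real
beetles and belongs to one of four life stages: egg, larva, pupa or adult
female (males are not followed). Immature development happens beneath the
soil surface and is driven by degree-days above a base temperature; adults
forage and reproduce in fields and their edges, migrate to overwintering
habitat (margins, semi-natural vegetation) in autumn, hibernate, and
disperse back into fields when spring temperatures rise.

Population regulation follows an intraspecific-predation rule: within the
3 m x 3 m square surrounding any beetle at most two adults and two larvae
may be present; surplus agents are removed at random. Mortality sources
are farm operations (soil cultivation, harvest), overwintering, a daily
juvenile background rate, and threshold-trigger insecticide exposure for
surface-active adults.

The population is stored as a structure of arrays and every daily
operation is vectorized, which keeps multi-year landscape-scale runs
tractable on one CPU.

Quantitative life-history defaults (degree-day requirements, fecundity,
operation and overwinter mortalities, migration parameters) are
literature-typical, clearly-labelled configuration values — all
overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .exposure import ExposureGrid, PesticideProduct, TRIGGER_THRESHOLD
from .farms import ScheduledEvent
from .landscape import (
    CROPPED_ELEMENTS,
    ElementType,
    FORAGE_ELEMENTS,
    LandscapeGrid,
    OVERWINTER_ELEMENTS,
)

# life stages
EGG, LARVA, PUPA, ADULT = 0, 1, 2, 3
STAGE_NAMES = ("egg", "larva", "pupa", "adult_female")

# adult behavioural modes
FORAGE, AUTUMN_MIGRATION, HIBERNATING, SPRING_DISPERSAL = 0, 1, 2, 3

#: intraspecific-predation cap: two adults and two larvae per 3 m x 3 m window
DENSITY_CAP_ADULTS = 2
DENSITY_CAP_LARVAE = 2
DENSITY_WINDOW_M = 3.0

AUTUMN_START_DOY = 274  # October 1


@dataclass
class DevelopmentModel:
    """Temperature-driven development of the immature stages (defaults are
    configurable literature-magnitude values, not printed in any source)."""

    base_temperature_c: float = 3.0
    dd_requirement: dict[int, float] = dc_field(
        default_factory=lambda: {EGG: 90.0, LARVA: 220.0, PUPA: 130.0}
    )
    juvenile_daily_mortality: dict[int, float] = dc_field(
        default_factory=lambda: {EGG: 0.03, LARVA: 0.04, PUPA: 0.02}
    )


@dataclass
class MovementModel:
    """Movement rule parameters: step limit, directional bias, habitat
    acceptance, and the seasonal migration triggers."""

    max_step_m: float = 14.0
    bias_weight: float = 0.9
    p_accept_suboptimal: float = 0.1
    n_tries: int = 3
    autumn_daily_start_p: float = 0.08
    spring_trigger_c: float = 7.0
    spring_window_days: int = 5


@dataclass
class MortalityTable:
    """Death probabilities by farm-operation type and stage group, plus
    overwintering mortality by habitat situation."""

    operation: dict[str, dict[str, float]] = dc_field(
        default_factory=lambda: {
            "plough": {"adult": 0.25, "juvenile": 0.50},
            "harrow": {"adult": 0.20, "juvenile": 0.40},
            "sow": {"adult": 0.10, "juvenile": 0.25},
            "harvest": {"adult": 0.10, "juvenile": 0.10},
            "grass_cut": {"adult": 0.15, "juvenile": 0.10},
            "fertilize": {"adult": 0.0, "juvenile": 0.0},
            "insecticide_spray": {"adult": 0.0, "juvenile": 0.0},
            "fungicide_spray": {"adult": 0.0, "juvenile": 0.0},
            "herbicide_spray": {"adult": 0.0, "juvenile": 0.0},
        }
    )
    overwinter_in_habitat: float = 0.40
    overwinter_exposed: float = 0.95
    juvenile_winter: float = 0.90
    adult_daily_background: float = 0.004


@dataclass
class BeetleParams:
    """Bundle of all beetle model parameters."""

    development: DevelopmentModel = dc_field(default_factory=DevelopmentModel)
    movement: MovementModel = dc_field(default_factory=MovementModel)
    mortality: MortalityTable = dc_field(default_factory=MortalityTable)
    fecundity_mean: float = 1.5          # egg super-individuals / female / day
    breeding_window: tuple[int, int] = (135, 196)
    egg_cell_cap: int = 6                # numerical guard, see methods note
    super_factor: int = 100              # real beetles per agent
    overwinter_mortality_doy: int = 335


class InitializationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# landscape-derived static fields (cached per grid object)


def _density_window_radius(cell_size_m: float) -> int:
    """Half-width (cells) of the density window: the smallest odd cell count
    covering at least 3 m, so a coarse raster is never more permissive than
    the 1-m rule."""
    n = math.ceil(DENSITY_WINDOW_M / cell_size_m)
    if n % 2 == 0:
        n += 1
    return (n - 1) // 2


class LandscapeFields:
    """Pre-computed per-cell lookups for one landscape."""

    def __init__(self, grid: LandscapeGrid):
        elem = grid.element
        self.grid = grid
        self.forage_ok = np.isin(elem, FORAGE_ELEMENTS)
        self.forbidden = np.isin(elem, (ElementType.WATER, ElementType.BUILT_UP))
        self.overwinter = np.isin(elem, OVERWINTER_ELEMENTS)
        self.cropped = np.isin(elem, CROPPED_ELEMENTS)
        self.breeding = self.cropped | np.isin(
            elem, (ElementType.FIELD_MARGIN, ElementType.CROP_FREE_BUFFER)
        )
        self.window_radius = _density_window_radius(grid.cell_size_m)
        cell = grid.cell_size_m
        # nearest-target cell centres for directed (autumn/spring) movement
        if self.overwinter.any():
            _, idx = ndimage.distance_transform_edt(~self.overwinter, return_indices=True)
            self.ow_target_y = (idx[0] + 0.5) * cell
            self.ow_target_x = (idx[1] + 0.5) * cell
        else:
            self.ow_target_y = self.ow_target_x = None
        if self.cropped.any():
            _, idx = ndimage.distance_transform_edt(~self.cropped, return_indices=True)
            self.field_target_y = (idx[0] + 0.5) * cell
            self.field_target_x = (idx[1] + 0.5) * cell
        else:
            self.field_target_y = self.field_target_x = None


_FIELDS_CACHE: dict[int, LandscapeFields] = {}


def landscape_fields(grid: LandscapeGrid) -> LandscapeFields:
    key = id(grid)
    cached = _FIELDS_CACHE.get(key)
    if cached is None or cached.grid is not grid:
        _FIELDS_CACHE.clear()
        cached = LandscapeFields(grid)
        _FIELDS_CACHE[key] = cached
    return cached


# ---------------------------------------------------------------------------
# population state


class PopulationState:
    """Structure-of-arrays container for all living agents."""

    __slots__ = ("x", "y", "stage", "dev", "mode", "day_of_year", "year",
                 "super_factor", "balance")

    def __init__(self, super_factor: int = 100):
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.stage = np.empty(0, dtype=np.int8)
        self.dev = np.empty(0, dtype=np.float64)
        self.mode = np.empty(0, dtype=np.int8)
        self.day_of_year = 1
        self.year = 0
        self.super_factor = super_factor
        self.balance: dict[str, int] = {}

    @property
    def n_agents(self) -> int:
        return len(self.stage)

    def stage_counts(self) -> dict[str, int]:
        c = np.bincount(self.stage, minlength=4)
        return {STAGE_NAMES[i]: int(c[i]) for i in range(4)}

    def cells(self, grid: LandscapeGrid) -> tuple[np.ndarray, np.ndarray]:
        """Row/col cell indices of all agents."""
        cell = grid.cell_size_m
        ny, nx = grid.shape
        iy = np.minimum((self.y / cell).astype(np.int64), ny - 1)
        ix = np.minimum((self.x / cell).astype(np.int64), nx - 1)
        return iy, ix

    def keep(self, mask: np.ndarray) -> int:
        """Drop agents where ``mask`` is False; return the number removed."""
        removed = int(len(mask) - mask.sum())
        if removed:
            self.x = self.x[mask]
            self.y = self.y[mask]
            self.stage = self.stage[mask]
            self.dev = self.dev[mask]
            self.mode = self.mode[mask]
        return removed

    def append(self, x, y, stage, mode) -> int:
        n = len(x)
        if n:
            self.x = np.concatenate([self.x, x])
            self.y = np.concatenate([self.y, y])
            self.stage = np.concatenate([self.stage, np.full(n, stage, dtype=np.int8)])
            self.dev = np.concatenate([self.dev, np.zeros(n)])
            self.mode = np.concatenate([self.mode, np.full(n, mode, dtype=np.int8)])
        return n


def init_population(
    grid: LandscapeGrid,
    n_super: int | None = None,
    rng: np.random.Generator | int = 0,
    density_super_per_km2: float = 2000.0,
    super_factor: int = 100,
) -> PopulationState:
    """Place adult females uniformly at random over suitable habitat.

    The default density, 2000 super-individuals per km^2, is the study
    density of 200 000 per 100 km^2 scaled by area. Agents start in the
    hibernating mode (simulations begin on January 1).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    fields = landscape_fields(grid)
    suitable = np.flatnonzero(fields.forage_ok | fields.overwinter)
    if suitable.size == 0:
        raise InitializationError("landscape has no suitable habitat for beetles")
    if n_super is None:
        area_km2 = grid.width_m * grid.height_m / 1e6
        n_super = int(round(density_super_per_km2 * area_km2))
    chosen = rng.choice(suitable, size=n_super, replace=True)
    ny, nx = grid.shape
    iy, ix = np.divmod(chosen, nx)
    cell = grid.cell_size_m
    state = PopulationState(super_factor=super_factor)
    state.x = (ix + rng.random(n_super)) * cell
    state.y = (iy + rng.random(n_super)) * cell
    state.stage = np.full(n_super, ADULT, dtype=np.int8)
    state.dev = np.zeros(n_super)
    state.mode = np.full(n_super, HIBERNATING, dtype=np.int8)
    return state


# ---------------------------------------------------------------------------
# daily processes


def develop(state: PopulationState, temp_c: float, model: DevelopmentModel) -> np.ndarray:
    """Accumulate degree-days for juveniles and promote completed stages.

    Returns a mask of agents that just emerged as adults (their behavioural
    mode is set to foraging). The degree-day counter resets at each stage
    transition.
    """
    gain = max(0.0, temp_c - model.base_temperature_c)
    juvenile = state.stage < ADULT
    emerged = np.zeros(state.n_agents, dtype=bool)
    if gain > 0 and juvenile.any():
        state.dev[juvenile] += gain
        for stage in (PUPA, LARVA, EGG):  # promote top-down so one step/day
            req = model.dd_requirement[stage]
            done = (state.stage == stage) & (state.dev >= req)
            if done.any():
                state.stage[done] += 1
                state.dev[done] = 0.0
                if stage == PUPA:
                    state.mode[done] = FORAGE
                    emerged |= done
    return emerged


def _random_unit(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    theta = rng.uniform(0, 2 * np.pi, n)
    return np.cos(theta), np.sin(theta)


def move(
    state: PopulationState,
    grid: LandscapeGrid,
    rng: np.random.Generator,
    model: MovementModel,
    fields: LandscapeFields | None = None,
) -> None:
    """One day of adult movement (juveniles and hibernators do not move).

    Foraging: uniform random heading and step length up to the daily
    maximum; unsuitable destinations are re-drawn up to ``n_tries`` times,
    sub-optimal habitat is accepted with a fixed probability, water and
    built-up cells never. Autumn migration: heading biased toward the
    nearest overwintering cell, capped so the target is not overshot;
    arrival switches the agent to hibernation. Spring dispersal: the same
    biased walk toward the nearest cropped field cell, ending in foraging.
    """
    fields = fields or landscape_fields(grid)
    cell = grid.cell_size_m
    ny, nx = grid.shape
    xmax = nx * cell - 1e-9
    ymax = ny * cell - 1e-9

    def clip(x, y):
        return np.clip(x, 0.0, xmax), np.clip(y, 0.0, ymax)

    def cells_of(x, y):
        return (y / cell).astype(np.int64), (x / cell).astype(np.int64)

    # --- foraging walk
    idx = np.flatnonzero((state.stage == ADULT) & (state.mode == FORAGE))
    if idx.size and model.max_step_m > 0:
        undecided = idx.copy()
        for _ in range(model.n_tries):
            if not undecided.size:
                break
            n = undecided.size
            ux, uy = _random_unit(n, rng)
            L = rng.uniform(0, model.max_step_m, n)
            cx, cy = clip(state.x[undecided] + ux * L, state.y[undecided] + uy * L)
            ciy, cix = cells_of(cx, cy)
            good = fields.forage_ok[ciy, cix]
            sub = ~good & ~fields.forbidden[ciy, cix]
            accept = good | (sub & (rng.random(n) < model.p_accept_suboptimal))
            tgt = undecided[accept]
            state.x[tgt] = cx[accept]
            state.y[tgt] = cy[accept]
            undecided = undecided[~accept]

    # --- directed seasonal movement
    for mode, tx, ty, arrive_mask, arrive_mode in (
        (AUTUMN_MIGRATION, fields.ow_target_x, fields.ow_target_y,
         fields.overwinter, HIBERNATING),
        (SPRING_DISPERSAL, fields.field_target_x, fields.field_target_y,
         fields.cropped, FORAGE),
    ):
        idx = np.flatnonzero((state.stage == ADULT) & (state.mode == mode))
        if not idx.size or model.max_step_m <= 0:
            continue
        if tx is None:
            state.mode[idx] = FORAGE  # no target habitat anywhere
            continue
        iy, ix = cells_of(state.x[idx], state.y[idx])
        dx = tx[iy, ix] - state.x[idx]
        dy = ty[iy, ix] - state.y[idx]
        dist = np.hypot(dx, dy)
        near = dist < 1e-9
        dx = np.where(near, 1.0, dx)
        dist_safe = np.where(near, 1.0, dist)
        uxt, uyt = dx / dist_safe, dy / dist_safe
        rx, ry = _random_unit(idx.size, rng)
        w = model.bias_weight
        hx = w * uxt + (1 - w) * rx
        hy = w * uyt + (1 - w) * ry
        norm = np.hypot(hx, hy)
        flat = norm < 1e-9
        hx = np.where(flat, uxt, hx / np.where(flat, 1.0, norm))
        hy = np.where(flat, uyt, hy / np.where(flat, 1.0, norm))
        L = np.minimum(model.max_step_m, dist)
        cx, cy = clip(state.x[idx] + hx * L, state.y[idx] + hy * L)
        ciy, cix = cells_of(cx, cy)
        bad = fields.forbidden[ciy, cix]
        if bad.any():  # fall back to the straight-line heading, else stay
            bidx = np.flatnonzero(bad)
            cx2, cy2 = clip(
                state.x[idx[bidx]] + uxt[bidx] * L[bidx],
                state.y[idx[bidx]] + uyt[bidx] * L[bidx],
            )
            c2y, c2x = cells_of(cx2, cy2)
            ok2 = ~fields.forbidden[c2y, c2x]
            cx[bidx] = np.where(ok2, cx2, state.x[idx[bidx]])
            cy[bidx] = np.where(ok2, cy2, state.y[idx[bidx]])
        state.x[idx] = cx
        state.y[idx] = cy
        ciy, cix = cells_of(cx, cy)
        arrived = arrive_mask[ciy, cix]
        state.mode[idx[arrived]] = arrive_mode


def reproduce(
    state: PopulationState,
    grid: LandscapeGrid,
    rng: np.random.Generator,
    params: BeetleParams,
    fields: LandscapeFields | None = None,
) -> int:
    """Poisson daily egg production by foraging females in breeding habitat
    within the breeding window. Eggs are laid in the mother's cell. Returns
    the number of egg agents created."""
    lo, hi = params.breeding_window
    if not lo <= state.day_of_year <= hi or params.fecundity_mean <= 0:
        return 0
    fields = fields or landscape_fields(grid)
    iy, ix = state.cells(grid)
    mothers = (state.stage == ADULT) & (state.mode == FORAGE) & fields.breeding[iy, ix]
    n_mothers = int(mothers.sum())
    if not n_mothers:
        return 0
    clutch = rng.poisson(params.fecundity_mean, n_mothers)
    total = int(clutch.sum())
    if not total:
        return 0
    rep = np.repeat(np.flatnonzero(mothers), clutch)
    return state.append(state.x[rep].copy(), state.y[rep].copy(), EGG, FORAGE)


def _agent_window_counts(
    iy: np.ndarray, ix: np.ndarray, nx: int, ny: int, r: int
) -> np.ndarray:
    """Number of same-group agents inside the (2r+1)-cell square window
    centred on each agent's cell (the agent itself included).

    Works on the sparse set of occupied cells only: one searchsorted per
    window offset, independent of the raster size.
    """
    lin = iy.astype(np.int64) * nx + ix
    uniq, inv, cnt = np.unique(lin, return_inverse=True, return_counts=True)
    if r == 0:
        return cnt[inv]
    row = uniq // nx
    col = uniq % nx
    win = np.zeros(uniq.size, dtype=np.int64)
    for dy in range(-r, r + 1):
        row_ok = (row + dy >= 0) & (row + dy < ny)
        for dx in range(-r, r + 1):
            tgt = uniq + dy * nx + dx
            ok = row_ok & (col + dx >= 0) & (col + dx < nx)
            pos = np.searchsorted(uniq, tgt)
            pos_c = np.minimum(pos, uniq.size - 1)
            hit = ok & (uniq[pos_c] == tgt)
            win[hit] += cnt[pos_c[hit]]
    return win[inv]


def density_dependence(
    state: PopulationState,
    grid: LandscapeGrid,
    rng: np.random.Generator,
    params: BeetleParams | None = None,
) -> int:
    """Enforce the 3 m x 3 m density caps; return the number removed.

    After enforcement every window centred on a remaining adult (larva)
    holds at most two adults (larvae). Surplus agents are thinned at
    random: each member of an over-full window is removed with probability
    excess/occupancy, iterating until the predicate holds (with a forced
    single removal per stuck iteration to guarantee progress). Eggs are
    additionally capped per cell (numerical guard; surplus eggs would be
    removed as larvae anyway).
    """
    params = params or BeetleParams()
    fields = landscape_fields(grid)
    r = fields.window_radius
    ny, nx = grid.shape
    removed_total = 0

    for stage, cap in ((ADULT, DENSITY_CAP_ADULTS), (LARVA, DENSITY_CAP_LARVAE)):
        for _ in range(200):
            idx = np.flatnonzero(state.stage == stage)
            if idx.size <= cap:
                break
            iy, ix = state.cells(grid)
            win = _agent_window_counts(iy[idx], ix[idx], nx, ny, r)
            excess = win - cap
            viol = excess > 0
            if not viol.any():
                break
            occ = excess + cap
            p_remove = np.where(viol, excess / occ, 0.0)
            kill = rng.random(idx.size) < p_remove
            if not kill.any():
                kill[rng.choice(np.flatnonzero(viol))] = True
            keep = np.ones(state.n_agents, dtype=bool)
            keep[idx[kill]] = False
            removed_total += state.keep(keep)

    cap_e = params.egg_cell_cap
    eggs = np.flatnonzero(state.stage == EGG)
    if cap_e and eggs.size > cap_e:
        iy, ix = state.cells(grid)
        lin = iy[eggs] * nx + ix[eggs]
        perm = rng.permutation(eggs.size)
        order = perm[np.argsort(lin[perm], kind="stable")]
        sorted_lin = lin[order]
        first = np.r_[True, sorted_lin[1:] != sorted_lin[:-1]]
        group_start = np.maximum.accumulate(np.where(first, np.arange(order.size), 0))
        rank = np.arange(order.size) - group_start
        drop = eggs[order[rank >= cap_e]]
        if drop.size:
            keep = np.ones(state.n_agents, dtype=bool)
            keep[drop] = False
            removed_total += state.keep(keep)
    return removed_total


def check_density_predicate(state: PopulationState, grid: LandscapeGrid) -> bool:
    """True iff the window caps hold around every adult and larva."""
    fields = landscape_fields(grid)
    r = fields.window_radius
    ny, nx = grid.shape
    iy, ix = state.cells(grid)
    for stage, cap in ((ADULT, DENSITY_CAP_ADULTS), (LARVA, DENSITY_CAP_LARVAE)):
        sel = state.stage == stage
        if not sel.any():
            continue
        if (_agent_window_counts(iy[sel], ix[sel], nx, ny, r) > cap).any():
            return False
    return True


def farm_operation_mortality(
    state: PopulationState,
    grid: LandscapeGrid,
    field_id: int,
    event_type: str,
    table: MortalityTable,
    rng: np.random.Generator,
) -> int:
    """Kill agents on the cropped cells of one field according to the
    (event type, stage group) death probabilities. Margin and buffer cells
    are not cultivated and their occupants are unaffected."""
    try:
        probs = table.operation[event_type]
    except KeyError:
        raise KeyError(f"no mortality entry configured for event {event_type!r}") from None
    p_adult, p_juv = probs["adult"], probs["juvenile"]
    if p_adult == 0 and p_juv == 0:
        return 0
    iy, ix = state.cells(grid)
    on_field = (grid.field_id[iy, ix] == field_id) & np.isin(
        grid.element[iy, ix], CROPPED_ELEMENTS
    )
    if not on_field.any():
        return 0
    p = np.where(state.stage == ADULT, p_adult, p_juv)
    die = on_field & (rng.random(state.n_agents) < p)
    return state.keep(~die)


def overwinter_mortality(
    state: PopulationState,
    grid: LandscapeGrid,
    table: MortalityTable,
    rng: np.random.Generator,
) -> int:
    """Apply once-per-winter mortality: hibernators in overwintering
    habitat die with the habitat probability, adults caught elsewhere with
    the (higher) exposed probability; juveniles still immature this late
    rarely survive winter."""
    fields = landscape_fields(grid)
    iy, ix = state.cells(grid)
    adult = state.stage == ADULT
    sheltered = adult & (state.mode == HIBERNATING) & fields.overwinter[iy, ix]
    p = np.where(adult, np.where(sheltered, table.overwinter_in_habitat,
                                 table.overwinter_exposed),
                 table.juvenile_winter)
    die = rng.random(state.n_agents) < p
    return state.keep(~die)


# ---------------------------------------------------------------------------
# the daily step


def step_day(
    state: PopulationState,
    grid: LandscapeGrid,
    exposure: ExposureGrid | None,
    events_today: list[ScheduledEvent],
    weather_today: tuple[float, float, float],
    rng: np.random.Generator,
    params: BeetleParams | None = None,
    product: PesticideProduct | None = None,
    curve=None,
    spring_wake: bool = False,
) -> PopulationState:
    """Advance the population by one day.

    Fixed sub-step order: (1) farm operations and spray applications,
    (2) exposure decay then threshold-trigger mortality, (3) development
    and juvenile background mortality, (4) reproduction, (5) movement and
    seasonal mode changes, (6) density dependence. The order puts sprays
    before movement because at spraying time the population is largely
    in-field. ``weather_today`` is (temperature degC, wind m/s, precip mm).

    A per-step balance (start + births - deaths - removals = end) is kept
    in ``state.balance`` and asserted.
    """
    from .exposure import apply_application, daily_decay, exposure_mortality_mask

    params = params or BeetleParams()
    fields = landscape_fields(grid)
    temp_c = weather_today[0]
    n_start = state.n_agents
    births = deaths = removals = 0

    # (1) farm operations + spray applications
    for ev in events_today:
        if ev.type == "insecticide_spray":
            if exposure is not None and product is not None and curve is not None:
                apply_application(exposure, grid, ev.field_id, product, curve)
        deaths += farm_operation_mortality(state, grid, ev.field_id, ev.type,
                                           params.mortality, rng)

    # (2) environmental decay, then trigger-threshold mortality of
    # surface-active adults (juveniles are beneath the soil surface,
    # hibernating adults are in untreated refuges)
    if exposure is not None and product is not None:
        daily_decay(exposure, temp_c, product)
        if exposure.max_concentration >= TRIGGER_THRESHOLD:
            iy, ix = state.cells(grid)
            active = (state.stage == ADULT) & (state.mode != HIBERNATING)
            conc = np.where(active, exposure.concentration[iy, ix], 0.0)
            die = exposure_mortality_mask(conc, product, rng)
            deaths += state.keep(~die)

    # (3) development + juvenile background mortality + adult background
    develop(state, temp_c, params.development)
    p_bg = np.zeros(state.n_agents)
    for stage, p in params.development.juvenile_daily_mortality.items():
        p_bg[state.stage == stage] = p
    active_adult = (state.stage == ADULT) & (state.mode != HIBERNATING)
    p_bg[active_adult] = params.mortality.adult_daily_background
    die = rng.random(state.n_agents) < p_bg
    deaths += state.keep(~die)

    # (4) reproduction
    births += reproduce(state, grid, rng, params, fields)

    # (5) seasonal mode switches, then movement
    if state.day_of_year >= AUTUMN_START_DOY:
        foragers = np.flatnonzero((state.stage == ADULT) & (state.mode == FORAGE))
        if foragers.size:
            start = rng.random(foragers.size) < params.movement.autumn_daily_start_p
            state.mode[foragers[start]] = AUTUMN_MIGRATION
    if spring_wake and state.day_of_year < AUTUMN_START_DOY:
        asleep = (state.stage == ADULT) & (state.mode == HIBERNATING)
        state.mode[asleep] = SPRING_DISPERSAL
    move(state, grid, rng, params.movement, fields)

    # (6) density dependence
    removals += density_dependence(state, grid, rng, params)

    # once-per-winter mortality on its configured day
    if state.day_of_year == params.overwinter_mortality_doy:
        deaths += overwinter_mortality(state, grid, params.mortality, rng)

    state.balance = {
        "start": n_start,
        "births": births,
        "deaths": deaths,
        "density_removals": removals,
        "end": state.n_agents,
    }
    assert n_start + births - deaths - removals == state.n_agents, state.balance

    state.day_of_year += 1
    if state.day_of_year > 365:
        state.day_of_year = 1
        state.year += 1
    return state
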