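from types import SimpleNamespace

import numpy as np
import pytest

from carabsim import abm
from carabsim.abm import (
    ADULT,
    AUTUMN_MIGRATION,
    BeetleParams,
    DevelopmentModel,
    EGG,
    FORAGE,
    HIBERNATING,
    LARVA,
    MortalityTable,
    MovementModel,
    PUPA,
    PopulationState,
    check_density_predicate,
    density_dependence,
    develop,
    farm_operation_mortality,
    init_population,
    move,
    overwinter_mortality,
    reproduce,
    step_day,
)
from carabsim.exposure import ExposureGrid
from carabsim.landscape import ElementType, LandscapeGrid
from conftest import single_field_grid


def open_grid(n=20, cell=1.0, element=ElementType.ARABLE_FIELD):
    elem = np.full((n, n), element, dtype=np.int8)
    fid = np.ones((n, n), dtype=np.int32) if element in (
        ElementType.ARABLE_FIELD, ElementType.MANAGED_GRASSLAND
    ) else np.zeros((n, n), dtype=np.int32)
    return LandscapeGrid(cell, elem, fid)


def place_agents(grid, xs, ys, stage=ADULT, mode=FORAGE, super_factor=100):
    state = PopulationState(super_factor=super_factor)
    state.x = np.asarray(xs, dtype=float)
    state.y = np.asarray(ys, dtype=float)
    n = len(state.x)
    state.stage = np.full(n, stage, dtype=np.int8)
    state.dev = np.zeros(n)
    state.mode = np.full(n, mode, dtype=np.int8)
    return state


class TestInitPopulation:
    def test_area_scaled_count(self):
        grid = open_grid(n=100, cell=10.0)  # 1 km^2
        state = init_population(grid, rng=1)
        assert state.n_agents == 2000  # 200 000 per 100 km^2, area-scaled
        assert (state.stage == ADULT).all()

    def test_no_suitable_habitat_raises(self):
        grid = open_grid(n=10, element=ElementType.WATER)
        with pytest.raises(abm.InitializationError):
            init_population(grid, n_super=10, rng=0)

    def test_seeds_change_placement_not_count(self):
        grid = open_grid(n=50)
        a = init_population(grid, n_super=200, rng=1)
        b = init_population(grid, n_super=200, rng=2)
        assert a.n_agents == b.n_agents == 200
        assert not np.array_equal(a.x, b.x)

    def test_agents_only_on_suitable_cells(self):
        grid = open_grid(n=20)
        grid.element[:10] = ElementType.WATER
        grid.field_id[:10] = 0
        state = init_population(grid, n_super=300, rng=0)
        assert (state.y >= 10.0).all()


class TestDevelopment:
    def test_no_progress_at_or_below_base(self):
        grid = open_grid()
        state = place_agents(grid, [5.0], [5.0], stage=EGG)
        model = DevelopmentModel()
        for _ in range(50):
            develop(state, model.base_temperature_c, model)
        assert state.dev[0] == 0.0
        assert state.stage[0] == EGG

    def test_transition_day_matches_arithmetic(self):
        model = DevelopmentModel(
            base_temperature_c=3.0, dd_requirement={EGG: 100.0, LARVA: 200.0, PUPA: 100.0}
        )
        grid = open_grid()
        state = place_agents(grid, [5.0], [5.0], stage=EGG)
        for day in range(1, 11):
            develop(state, 13.0, model)  # 10 degree-days per day
        assert state.stage[0] == LARVA
        assert state.dev[0] == 0.0  # counter reset at transition

    def test_full_juvenile_development_duration(self):
        """Egg to adult at constant warmth takes ceil(req/inc) days summed
        over the three immature stages."""
        model = DevelopmentModel(
            base_temperature_c=3.0,
            dd_requirement={EGG: 90.0, LARVA: 220.0, PUPA: 130.0},
        )
        inc = 10.0
        expected_days = sum(
            int(np.ceil(model.dd_requirement[s] / inc)) for s in (EGG, LARVA, PUPA)
        )
        grid = open_grid()
        state = place_agents(grid, [5.0], [5.0], stage=EGG)
        days = 0
        while state.stage[0] != ADULT:
            develop(state, 13.0, model)
            days += 1
            assert days < 200
        assert days == expected_days
        assert state.mode[0] == FORAGE


class TestMovement:
    def test_zero_max_step_freezes_positions(self, rng):
        grid = open_grid(n=30)
        state = place_agents(grid, [10.0, 20.0], [10.0, 15.0])
        move(state, grid, rng, MovementModel(max_step_m=0.0))
        np.testing.assert_array_equal(state.x, [10.0, 20.0])

    def test_displacement_never_exceeds_max_step(self, rng):
        grid = open_grid(n=50, cell=2.0)
        state = init_population(grid, n_super=500, rng=3)
        state.mode[:] = FORAGE
        model = MovementModel(max_step_m=14.0)
        for _ in range(20):
            x0, y0 = state.x.copy(), state.y.copy()
            move(state, grid, rng, model)
            disp = np.hypot(state.x - x0, state.y - y0)
            assert (disp <= 14.0 + 1e-9).all()

    def test_mean_foraging_displacement_positive_and_bounded(self, rng):
        grid = open_grid(n=100)
        state = init_population(grid, n_super=1000, rng=4)
        state.mode[:] = FORAGE
        disps = []
        for _ in range(10):
            x0, y0 = state.x.copy(), state.y.copy()
            move(state, grid, rng, MovementModel())
            disps.append(np.hypot(state.x - x0, state.y - y0))
        mean_disp = np.concatenate(disps).mean()
        assert 0.0 < mean_disp <= 14.0

    def test_full_bias_reaches_adjacent_overwintering_cell(self, rng):
        grid = open_grid(n=10)
        grid.element[5, 6] = ElementType.HERBACEOUS
        grid.field_id[5, 6] = 0
        state = place_agents(grid, [5.5], [5.5], mode=AUTUMN_MIGRATION)
        move(state, grid, rng, MovementModel(bias_weight=1.0))
        assert state.mode[0] == HIBERNATING
        assert int(state.x[0]) == 6 and int(state.y[0]) == 5

    def test_no_agent_on_water_or_built_up_after_moving(self, rng):
        grid = open_grid(n=40)
        grid.element[:, 15:25] = ElementType.WATER
        grid.field_id[:, 15:25] = 0
        state = init_population(grid, n_super=400, rng=5)
        state.mode[:] = FORAGE
        for _ in range(30):
            move(state, grid, rng, MovementModel())
            iy, ix = state.cells(grid)
            assert not np.isin(
                grid.element[iy, ix], (ElementType.WATER, ElementType.BUILT_UP)
            ).any()


class TestReproduction:
    def test_outside_window_no_eggs(self, rng):
        grid = open_grid()
        state = place_agents(grid, [5.0], [5.0])
        state.day_of_year = 40
        assert reproduce(state, grid, rng, BeetleParams()) == 0

    def test_zero_fecundity_no_eggs(self, rng):
        grid = open_grid()
        state = place_agents(grid, [5.0], [5.0])
        state.day_of_year = 150
        params = BeetleParams(fecundity_mean=0.0)
        assert reproduce(state, grid, rng, params) == 0

    def test_daily_egg_mean_matches_fecundity(self, rng):
        """1e4 female-days at Poisson mean 2 -> 2.0 +/- 0.05 eggs/female."""
        grid = open_grid(n=110)
        state = init_population(grid, n_super=10_000, rng=6)
        state.mode[:] = FORAGE
        state.day_of_year = 150
        params = BeetleParams(fecundity_mean=2.0, egg_cell_cap=0)
        n_eggs = reproduce(state, grid, rng, params)
        assert n_eggs / 10_000 == pytest.approx(2.0, abs=0.05)

    def test_eggs_inherit_mother_cell(self, rng):
        grid = open_grid()
        state = place_agents(grid, [7.3], [2.8])
        state.day_of_year = 160
        reproduce(state, grid, rng, BeetleParams(fecundity_mean=5.0))
        eggs = state.stage == EGG
        assert eggs.any()
        assert (state.x[eggs] == 7.3).all() and (state.y[eggs] == 2.8).all()


def brute_force_window_ok(state, grid, stage, cap):
    """Independent O(n^2) check of the 3 m x 3 m cap around every agent."""
    r = abm._density_window_radius(grid.cell_size_m)
    iy, ix = state.cells(grid)
    sel = np.flatnonzero(state.stage == stage)
    for i in sel:
        count = 0
        for j in sel:
            if abs(int(iy[j]) - int(iy[i])) <= r and abs(int(ix[j]) - int(ix[i])) <= r:
                count += 1
        if count > cap:
            return False
    return True


class TestDensityDependence:
    def test_five_adults_one_cell_two_survive(self, rng):
        grid = open_grid()
        state = place_agents(grid, [5.1] * 5, [5.1] * 5)
        removed = density_dependence(state, grid, rng)
        assert removed == 3
        assert state.n_agents == 2

    def test_at_cap_nothing_removed(self, rng):
        grid = open_grid()
        xs = [5.1, 5.2, 5.3, 5.4]
        state = place_agents(grid, xs, [5.1] * 4)
        state.stage[2:] = LARVA
        assert density_dependence(state, grid, rng) == 0
        assert state.n_agents == 4

    @pytest.mark.parametrize("cell_size", [1.0, 2.0])
    def test_random_configurations_satisfy_brute_force_predicate(self, cell_size):
        """Post-enforcement states pass an independent window scan."""
        rng = np.random.default_rng(77)
        grid = open_grid(n=20, cell=cell_size)
        for trial in range(5):
            n = 150
            state = place_agents(
                grid,
                rng.uniform(0, 20 * cell_size, n),
                rng.uniform(0, 20 * cell_size, n),
            )
            state.stage[rng.random(n) < 0.5] = LARVA
            density_dependence(state, grid, rng)
            assert brute_force_window_ok(state, grid, ADULT, 2)
            assert brute_force_window_ok(state, grid, LARVA, 2)
            assert check_density_predicate(state, grid)

    def test_egg_cell_cap_enforced(self, rng):
        grid = open_grid()
        state = place_agents(grid, [5.1] * 20, [5.1] * 20, stage=EGG)
        density_dependence(state, grid, rng, BeetleParams(egg_cell_cap=6))
        assert state.n_agents == 6


class TestOperationMortality:
    def test_probability_zero_no_deaths(self, rng):
        grid, _, _ = single_field_grid(n_cells=10, cell=1.0)
        state = place_agents(grid, [5.0, 6.0], [5.0, 6.0])
        table = MortalityTable()
        assert farm_operation_mortality(state, grid, 1, "fertilize", table, rng) == 0

    def test_certain_plough_kills_infield_spares_margin(self, rng):
        grid, _, _ = single_field_grid(n_cells=10, cell=1.0, border=2)
        grid.element[2, 2:12] = ElementType.FIELD_MARGIN  # bottom row of parcel
        table = MortalityTable()
        table.operation["plough"] = {"adult": 1.0, "juvenile": 1.0}
        state = place_agents(grid, [5.0, 5.0], [5.5, 2.5])  # in-crop, on margin
        farm_operation_mortality(state, grid, 1, "plough", table, rng)
        assert state.n_agents == 1
        assert state.y[0] == 2.5  # the margin occupant survived

    def test_kill_fraction_matches_probability(self, rng):
        grid, _, _ = single_field_grid(n_cells=100, cell=1.0, border=0)
        state = place_agents(grid, rng.uniform(0, 100, 10_000), rng.uniform(0, 100, 10_000))
        table = MortalityTable()
        table.operation["harrow"] = {"adult": 0.4, "juvenile": 0.4}
        killed = farm_operation_mortality(state, grid, 1, "harrow", table, rng)
        assert killed / 10_000 == pytest.approx(0.40, abs=0.01)

    def test_missing_table_entry_raises(self, rng):
        grid, _, _ = single_field_grid()
        state = place_agents(grid, [5.0], [5.0])
        table = MortalityTable(operation={})
        with pytest.raises(KeyError):
            farm_operation_mortality(state, grid, 1, "plough", table, rng)


class TestOverwinterMortality:
    @pytest.mark.parametrize("p,expected", [(0.0, 10_000), (1.0, 0)])
    def test_degenerate_probabilities(self, rng, p, expected):
        grid = open_grid(n=100, element=ElementType.HERBACEOUS)
        state = init_population(grid, n_super=10_000, rng=1)
        state.mode[:] = HIBERNATING
        table = MortalityTable(
            overwinter_in_habitat=p, overwinter_exposed=p, juvenile_winter=p
        )
        overwinter_mortality(state, grid, table, rng)
        assert state.n_agents == expected

    def test_half_probability_kill_fraction(self, rng):
        grid = open_grid(n=100, element=ElementType.HERBACEOUS)
        state = init_population(grid, n_super=10_000, rng=1)
        state.mode[:] = HIBERNATING
        table = MortalityTable(overwinter_in_habitat=0.5)
        overwinter_mortality(state, grid, table, rng)
        assert state.n_agents / 10_000 == pytest.approx(0.5, abs=0.01)

    def test_exposed_adults_use_higher_probability(self, rng):
        grid = open_grid(n=50)  # all arable: no overwintering habitat
        state = init_population(grid, n_super=5000, rng=2)
        state.mode[:] = FORAGE
        table = MortalityTable(overwinter_in_habitat=0.0, overwinter_exposed=1.0)
        overwinter_mortality(state, grid, table, rng)
        assert state.n_agents == 0


class TestStepDay:
    def test_empty_state_only_calendar_advances(self, rng):
        grid = open_grid()
        state = PopulationState()
        step_day(state, grid, None, [], (10.0, 3.0, 0.0), rng)
        assert state.n_agents == 0
        assert state.day_of_year == 2

    def test_certain_exposure_everywhere_drives_extinction(self, rng):
        grid = open_grid(n=20)
        state = init_population(grid, n_super=200, rng=1)
        state.mode[:] = FORAGE
        exposure = ExposureGrid.zeros_like(grid)
        exposure.concentration[:] = 5.0
        product = SimpleNamespace(daily_p=1.0, dt50_20c=1e9)
        for _ in range(3):
            step_day(state, grid, exposure, [], (15.0, 3.0, 0.0), rng,
                     product=product, curve=None)
        assert state.n_agents == 0

    def test_balance_identity_holds_each_step(self, rng):
        grid = open_grid(n=50, cell=2.0)
        state = init_population(grid, n_super=500, rng=2)
        state.mode[:] = FORAGE
        state.day_of_year = 150  # breeding season: births and removals occur
        for _ in range(30):
            step_day(state, grid, None, [], (16.0, 3.0, 0.0), rng)
            b = state.balance
            assert b["start"] + b["births"] - b["deaths"] - b["density_removals"] == b["end"]

    def test_trajectories_bit_identical_for_fixed_seed(self):
        grid = open_grid(n=40, cell=2.0)

        def run(seed):
            rng = np.random.default_rng(seed)
            state = init_population(grid, n_super=300, rng=np.random.default_rng(seed))
            state.mode[:] = FORAGE
            state.day_of_year = 140
            for _ in range(40):
                step_day(state, grid, None, [], (16.0, 3.0, 0.0), rng)
            return state

        a, b, c = run(9), run(9), run(10)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.stage, b.stage)
        assert (a.n_agents != c.n_agents) or not np.array_equal(a.x, c.x)

    def test_density_predicate_after_every_step(self, rng):
        grid = open_grid(n=30)
        state = init_population(grid, n_super=400, rng=3)
        state.mode[:] = FORAGE
        state.day_of_year = 150
        for _ in range(20):
            step_day(state, grid, None, [], (17.0, 3.0, 0.0), rng)
            assert check_density_predicate(state, grid)


class TestPersistence:
    def test_population_persists_without_pesticides(self):
        """Benign conditions on the standard small landscape: no
        extinction over 10 simulated years (smoke property)."""
        from carabsim.scenarios import ExperimentConfig, Scenario, run_experiment
        from carabsim.landscape import LandscapeConfig

        cfg = ExperimentConfig(
            landscape=LandscapeConfig(width_m=400.0, height_m=400.0, n_fields=16),
            n_replicates=1,
            n_years=10,
            master_seed=5,
        )
        # LR25 with zero-probability sprays: build a no-insecticide system
        scen = Scenario("LR25", 0.5, False, 25.0)
        cfg.beetle.fecundity_mean = 1.5
        rec, _, _ = run_experiment(cfg, [scen])
        assert (rec.overall_density > 0).all()
        assert rec.overall_density.iloc[-1] > 0
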