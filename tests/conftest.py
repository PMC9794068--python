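import numpy as np
import pytest

from carabsim.landscape import (
    ElementType,
    FarmUnit,
    FieldParcel,
    LandscapeConfig,
    LandscapeGrid,
    generate_landscape,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        width_m=200.0, height_m=200.0, cell_size_m=2.0, n_fields=8,
        n_water_ditches=1,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    """A small generated landscape shared by read-only tests."""
    return generate_landscape(small_config, seed=42)


def single_field_grid(n_cells: int = 100, cell: float = 1.0, border: int = 2):
    """One square parcel surrounded by a strip of non-field cells."""
    size = n_cells + 2 * border
    element = np.full((size, size), ElementType.OTHER, dtype=np.int8)
    field_id = np.zeros((size, size), dtype=np.int32)
    sl = slice(border, border + n_cells)
    element[sl, sl] = ElementType.ARABLE_FIELD
    field_id[sl, sl] = 1
    grid = LandscapeGrid(cell_size_m=cell, element=element, field_id=field_id)
    area = (n_cells * cell) ** 2 / 1e4
    parcel = FieldParcel(id=1, farm_id=1, area_ha=area, perimeter_m=4 * n_cells * cell)
    farm = FarmUnit(id=1, farm_type="arable", field_ids=[1])
    return grid, [parcel], [farm]
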