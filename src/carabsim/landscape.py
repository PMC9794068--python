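"""Synthetic raster agricultural landscapes and heterogeneity metrics.

The landscape is a categorical raster (one element type per cell) plus a
parallel integer raster of field identities. Fields are axis-aligned
rectangles produced by seeded binary splits, grouped into farm units of a
configurable type mix; a fraction of the blocks is converted to semi-natural
habitat (herbaceous / woodland / built-up) and narrow water ditches can be
cut across the landscape. Mitigation layers — grassy in-field margins and
1-m crop-free buffers along water — are applied as post-processing steps.

Coordinate convention: cell (row 0, col 0) sits at the lower-left corner,
cell extents are half-open, all distances in metres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


class ElementType(IntEnum):
    """Landscape element types (one per raster cell)."""

    OTHER = 0
    ARABLE_FIELD = 1
    MANAGED_GRASSLAND = 2
    HERBACEOUS = 3          # herbaceous semi-natural habitat
    WOODLAND = 4
    WATER = 5
    BUILT_UP = 6
    FIELD_MARGIN = 7        # grassy in-field margin, never sprayed/cultivated
    CROP_FREE_BUFFER = 8    # 1-m fallow strip along water, never sprayed


#: element types that carry a positive field_id
FIELD_ELEMENTS = (ElementType.ARABLE_FIELD, ElementType.MANAGED_GRASSLAND)
#: cultivated (sprayable) cells of a parcel
CROPPED_ELEMENTS = FIELD_ELEMENTS
#: habitat classes a beetle can forage in
FORAGE_ELEMENTS = (
    ElementType.ARABLE_FIELD,
    ElementType.MANAGED_GRASSLAND,
    ElementType.HERBACEOUS,
    ElementType.FIELD_MARGIN,
    ElementType.CROP_FREE_BUFFER,
)
#: habitat classes suitable for overwintering aggregations
OVERWINTER_ELEMENTS = (
    ElementType.HERBACEOUS,
    ElementType.FIELD_MARGIN,
    ElementType.CROP_FREE_BUFFER,
)

# Six aggregate categories used by the landscape diversity / shape metrics:
# arable land (fields in rotation + managed grassland), herbaceous
# semi-natural (incl. margins and buffers), woodland, built-up, water, other.
_N_CATEGORIES = 6
_CATEGORY_OF = np.zeros(9, dtype=np.int8)
_CATEGORY_OF[[ElementType.ARABLE_FIELD, ElementType.MANAGED_GRASSLAND]] = 0
_CATEGORY_OF[
    [ElementType.HERBACEOUS, ElementType.FIELD_MARGIN, ElementType.CROP_FREE_BUFFER]
] = 1
_CATEGORY_OF[ElementType.WOODLAND] = 2
_CATEGORY_OF[ElementType.BUILT_UP] = 3
_CATEGORY_OF[ElementType.WATER] = 4
_CATEGORY_OF[ElementType.OTHER] = 5


class ConfigurationError(ValueError):
    """Raised for infeasible landscape generator configurations."""


@dataclass
class LandscapeGrid:
    """Categorical raster landscape with a parallel field-identity layer.

    ``element`` and ``field_id`` are ``(n_rows, n_cols)`` arrays; row index
    increases northwards (lower-left origin).
    """

    cell_size_m: float
    element: np.ndarray      # int8, ElementType codes
    field_id: np.ndarray     # int32, 0 = not a field

    def __post_init__(self) -> None:
        if self.element.shape != self.field_id.shape:
            raise ValueError("element and field_id rasters must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.element.shape

    @property
    def width_m(self) -> float:
        return self.element.shape[1] * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.element.shape[0] * self.cell_size_m

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(self.cell_size_m, self.element.copy(), self.field_id.copy())

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        elem = self.element
        fid = self.field_id
        if not np.isin(elem, list(ElementType)).all():
            raise ValueError("unknown element codes present")
        is_field = np.isin(elem, FIELD_ELEMENTS)
        if not (fid[is_field] > 0).all():
            raise ValueError("field cells must carry a positive field_id")
        ancillary = np.isin(elem, (ElementType.FIELD_MARGIN, ElementType.CROP_FREE_BUFFER))
        bad = (fid > 0) & ~is_field & ~ancillary
        if bad.any():
            raise ValueError("field_id > 0 on non-field, non-margin/buffer cells")
        if not (fid[ancillary] > 0).all():
            raise ValueError("margin/buffer cells must keep their parcel's field_id")


@dataclass
class FieldParcel:
    """One field parcel (agriculturally managed unit of a farm)."""

    id: int
    farm_id: int
    area_ha: float
    perimeter_m: float
    soil_type: str = "sand"
    rotation_index: int = 0
    has_margin: bool = False


@dataclass
class FarmUnit:
    """A farm: a set of fields managed under one rotation scheme."""

    id: int
    farm_type: str
    field_ids: list[int] = field(default_factory=list)


@dataclass
class HeterogeneityMetrics:
    """Landscape- and farmland-heterogeneity summary of one landscape."""

    coverage_herbaceous: float      # % of landscape
    coverage_woodland: float        # % of landscape
    landscape_shannon: float        # >= 0
    landscape_shape_index: float    # >= 1
    farming_shannon: float          # >= 0
    share_animal_farms: float       # % of farms
    n_fields: int
    mean_field_size: float          # ha
    field_boundary_density: float   # 1/m


# intensive mixed-arable mix: the farming system the mitigation measures
# target (potato / vegetable / bulb growing with little permanent grassland)
DEFAULT_FARM_TYPE_MIX: dict[str, float] = {
    "animal_grazing": 0.10,
    "arable": 0.30,
    "arable_vegetable": 0.25,
    "starch_potato": 0.15,
    "flower": 0.10,
    "other": 0.10,
}

SOIL_TYPES = ("sand", "clay", "peat")


@dataclass
class LandscapeConfig:
    """Generator parameters for a synthetic landscape.

    Defaults give the desk-scale landscape: 1 km x 1 km at 2-m cells with
    ~100 fields, a field-size / count mix inside the ranges observed for
    Dutch 10 x 10 km study areas when scaled by area.
    """

    width_m: float = 1000.0
    height_m: float = 1000.0
    cell_size_m: float = 2.0
    n_fields: int = 100
    seminatural_fraction: float = 0.04   # herbaceous patch area share
    boundary_strip_fraction: float = 0.6  # parcels with a 1-cell grassy verge
    woodland_fraction: float = 0.03
    built_up_fraction: float = 0.02
    n_water_ditches: int = 3             # 1-cell-wide ditch lines
    fields_per_farm: int = 5
    farm_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FARM_TYPE_MIX)
    )

    def validate(self) -> None:
        if self.width_m < 100 or self.height_m < 100:
            raise ConfigurationError("extent must be at least 100 m x 100 m")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.n_fields < 1:
            raise ConfigurationError("need at least one field")
        nonfield = self.seminatural_fraction + self.woodland_fraction + self.built_up_fraction
        if nonfield >= 0.9:
            raise ConfigurationError("non-field fractions leave too little arable area")
        area_ha = self.width_m * self.height_m / 1e4
        mean_size = area_ha * (1 - nonfield) / self.n_fields
        # a parcel needs to be at least a few cells across to be meaningful
        if mean_size * 1e4 < 9 * self.cell_size_m**2:
            raise ConfigurationError(
                f"target of {self.n_fields} fields on {area_ha:.0f} ha yields "
                "parcels smaller than a 3x3-cell block"
            )


def _bsp_blocks(nx: int, ny: int, n_blocks: int, rng: np.random.Generator) -> list[tuple[int, int, int, int]]:
    """Split (0,0)-(nx,ny) into ``n_blocks`` rectangles by recursive binary
    splits of the currently largest block at a seeded 35-65% position."""
    blocks = [(0, 0, nx, ny)]  # (x0, y0, x1, y1) half-open, cell units
    while len(blocks) < n_blocks:
        areas = [(b[2] - b[0]) * (b[3] - b[1]) for b in blocks]
        i = int(np.argmax(areas))
        x0, y0, x1, y1 = blocks.pop(i)
        w, h = x1 - x0, y1 - y0
        if max(w, h) < 2:  # cannot split further
            blocks.append((x0, y0, x1, y1))
            break
        frac = rng.uniform(0.35, 0.65)
        if w >= h:
            cut = x0 + max(1, min(w - 1, int(round(frac * w))))
            blocks += [(x0, y0, cut, y1), (cut, y0, x1, y1)]
        else:
            cut = y0 + max(1, min(h - 1, int(round(frac * h))))
            blocks += [(x0, y0, x1, cut), (x0, cut, x1, y1)]
    return blocks


def _perimeter_and_area(mask: np.ndarray, cell: float) -> tuple[float, float]:
    """Exact raster perimeter (cell-edge counting, incl. map boundary) and
    area of a boolean mask."""
    area = mask.sum() * cell * cell
    edges = 0
    edges += np.count_nonzero(mask[:, :-1] != mask[:, 1:])
    edges += np.count_nonzero(mask[:-1, :] != mask[1:, :])
    edges += mask[0, :].sum() + mask[-1, :].sum() + mask[:, 0].sum() + mask[:, -1].sum()
    return float(edges * cell), float(area)


def generate_landscape(
    config: LandscapeConfig, seed: int
) -> tuple[LandscapeGrid, list[FieldParcel], list[FarmUnit]]:
    """Generate a synthetic agricultural landscape.

    Deterministic for a fixed seed. The realized field count stays within
    +/-20 % of ``config.n_fields`` (ditches may merge or split blocks at the
    margin of that tolerance only for extreme configurations).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    nx = int(round(config.width_m / config.cell_size_m))
    ny = int(round(config.height_m / config.cell_size_m))
    cell = config.cell_size_m

    nonfield_frac = (
        config.seminatural_fraction + config.woodland_fraction + config.built_up_fraction
    )
    # blocks for fields plus proportionally many for non-field patches
    n_blocks = max(config.n_fields, int(round(config.n_fields / max(1e-9, 1 - nonfield_frac))))
    blocks = _bsp_blocks(nx, ny, n_blocks, rng)
    order = rng.permutation(len(blocks))

    element = np.full((ny, nx), ElementType.OTHER, dtype=np.int8)
    field_id = np.zeros((ny, nx), dtype=np.int32)

    total_cells = nx * ny
    budgets = {
        ElementType.HERBACEOUS: config.seminatural_fraction * total_cells,
        ElementType.WOODLAND: config.woodland_fraction * total_cells,
        ElementType.BUILT_UP: config.built_up_fraction * total_cells,
    }
    field_blocks: list[tuple[int, int, int, int]] = []
    spent = {k: 0.0 for k in budgets}
    for idx in order:
        x0, y0, x1, y1 = blocks[idx]
        a = (x1 - x0) * (y1 - y0)
        placed = False
        for etype, budget in budgets.items():
            if spent[etype] + a <= budget * 1.10 and spent[etype] < budget:
                element[y0:y1, x0:x1] = etype
                spent[etype] += a
                placed = True
                break
        if not placed:
            field_blocks.append(blocks[idx])

    if not field_blocks:
        raise ConfigurationError("no area left for fields after non-field allocation")

    # assign parcels; a seeded fraction keeps a 1-cell grassy verge ring
    # (herbaceous field boundary, the beetle's main overwintering habitat)
    next_id = 1
    for x0, y0, x1, y1 in field_blocks:
        element[y0:y1, x0:x1] = ElementType.ARABLE_FIELD
        field_id[y0:y1, x0:x1] = next_id
        if rng.random() < config.boundary_strip_fraction and (x1 - x0) > 2 and (y1 - y0) > 2:
            ring = np.zeros((y1 - y0, x1 - x0), dtype=bool)
            ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
            element[y0:y1, x0:x1][ring] = ElementType.HERBACEOUS
            field_id[y0:y1, x0:x1][ring] = 0
        next_id += 1

    # water ditches: 1-cell lines along the edges of seeded field blocks
    # (field ditches follow parcel boundaries, so parcels stay connected)
    if config.n_water_ditches and field_blocks:
        picks = rng.choice(len(field_blocks), size=config.n_water_ditches, replace=True)
        for bi in picks:
            x0, y0, x1, y1 = field_blocks[bi]
            side = rng.integers(4)
            if side == 0:
                sl = (slice(y0, y0 + 1), slice(x0, x1))
            elif side == 1:
                sl = (slice(y1 - 1, y1), slice(x0, x1))
            elif side == 2:
                sl = (slice(y0, y1), slice(x0, x0 + 1))
            else:
                sl = (slice(y0, y1), slice(x1 - 1, x1))
            element[sl] = ElementType.WATER
            field_id[sl] = 0

    # drop parcels fully consumed by ditches, renumber compactly
    parcels: list[FieldParcel] = []
    keep_ids = [i for i in range(1, next_id) if (field_id == i).any()]
    remap = np.zeros(next_id, dtype=np.int32)
    for new, old in enumerate(keep_ids, start=1):
        remap[old] = new
    field_id = remap[field_id]

    n_parcels = len(keep_ids)
    # farms: group spatially contiguous runs of parcels (parcel order follows
    # the BSP layout, which is spatially coherent)
    n_farms = max(1, round(n_parcels / config.fields_per_farm))
    types, probs = zip(*config.farm_type_mix.items())
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    farm_types = rng.choice(types, size=n_farms, p=probs)
    farms = [FarmUnit(id=i + 1, farm_type=t) for i, t in enumerate(farm_types)]

    for pidx in range(1, n_parcels + 1):
        mask = field_id == pidx
        perim, area = _perimeter_and_area(mask, cell)
        farm = farms[(pidx - 1) * n_farms // n_parcels]
        farm.field_ids.append(pidx)
        parcels.append(
            FieldParcel(
                id=pidx,
                farm_id=farm.id,
                area_ha=area / 1e4,
                perimeter_m=perim,
                soil_type=str(rng.choice(SOIL_TYPES)),
            )
        )
        if farm.farm_type == "animal_grazing":
            element[mask] = ElementType.MANAGED_GRASSLAND
    farms = [f for f in farms if f.field_ids]

    grid = LandscapeGrid(cell_size_m=cell, element=element, field_id=field_id)
    grid.validate()
    realized = len(parcels)
    if not 0.8 * config.n_fields <= realized <= 1.2 * config.n_fields:
        logger.warning(
            "realized field count %d outside +/-20%% of target %d",
            realized,
            config.n_fields,
        )
    return grid, parcels, farms


def add_field_margins(
    grid: LandscapeGrid,
    parcels: list[FieldParcel],
    fraction: float,
    width_m: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> LandscapeGrid:
    """Carve grassy in-field margins into a seeded random subset of parcels.

    ``round(fraction * n_parcels)`` parcels receive an inner ring of
    ``field_margin`` cells of the given width, taken from the cropped area.
    Parcels too small to keep a non-empty interior are skipped (logged).
    Parcels already carrying a margin count toward the quota, which makes a
    second application with the same fraction a no-op.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be within [0, 1]")
    if width_m < grid.cell_size_m:
        raise ValueError("margin width must be at least one cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = grid.copy()
    target = round(fraction * len(parcels))
    have = [p for p in parcels if p.has_margin]
    todo = target - len(have)
    if todo <= 0:
        return grid
    candidates = [p for p in parcels if not p.has_margin]
    order = rng.permutation(len(candidates))
    width_cells = width_m / grid.cell_size_m
    done = 0
    for i in order:
        if done >= todo:
            break
        parcel = candidates[i]
        mask = (grid.field_id == parcel.id) & np.isin(grid.element, CROPPED_ELEMENTS)
        if not mask.any():
            continue
        # distance (in cells) from each parcel cell to the nearest non-parcel cell
        inner = ndimage.distance_transform_edt(mask)
        interior = inner > width_cells
        if not interior.any():
            logger.info("parcel %d too small for a %.0f-m margin; skipped", parcel.id, width_m)
            continue
        ring = mask & ~interior
        grid.element[ring] = ElementType.FIELD_MARGIN
        parcel.has_margin = True
        done += 1
    grid.validate()
    return grid


def add_water_buffers(grid: LandscapeGrid) -> LandscapeGrid:
    """Turn every cropped cell 4-adjacent to water into a crop-free buffer.

    The buffer keeps its parcel's field_id but is never sprayed or
    cultivated; applying the operation twice changes nothing.
    """
    grid = grid.copy()
    water = grid.element == ElementType.WATER
    if not water.any():
        return grid
    adjacent = np.zeros_like(water)
    adjacent[1:, :] |= water[:-1, :]
    adjacent[:-1, :] |= water[1:, :]
    adjacent[:, 1:] |= water[:, :-1]
    adjacent[:, :-1] |= water[:, 1:]
    target = adjacent & np.isin(grid.element, CROPPED_ELEMENTS)
    grid.element[target] = ElementType.CROP_FREE_BUFFER
    grid.validate()
    return grid


def _shannon(proportions: np.ndarray) -> float:
    p = proportions[proportions > 0]
    return float(-(p * np.log(p)).sum())


def compute_metrics(
    grid: LandscapeGrid, parcels: list[FieldParcel], farms: list[FarmUnit]
) -> HeterogeneityMetrics:
    """Compute the heterogeneity metric set of a landscape.

    Landscape diversity is Shannon's index over the six aggregate categories
    (arable, herbaceous semi-natural, woodland, built-up, water, other); the
    landscape shape index is the FRAGSTATS raster convention
    ``0.25 * E / sqrt(A)`` with cell-edge counting that includes the map
    boundary; farming diversity is Shannon's index over farm types weighted
    by field area.
    """
    cat = _CATEGORY_OF[grid.element]
    counts = np.bincount(cat.ravel(), minlength=_N_CATEGORIES).astype(float)
    total = counts.sum()
    props = counts / total
    landscape_shannon = _shannon(props)

    cell = grid.cell_size_m
    edges = 0
    edges += np.count_nonzero(cat[:, :-1] != cat[:, 1:])
    edges += np.count_nonzero(cat[:-1, :] != cat[1:, :])
    ny, nx = cat.shape
    edges += 2 * (nx + ny)  # landscape boundary
    total_edge = edges * cell
    total_area = total * cell * cell
    lsi = 0.25 * total_edge / math.sqrt(total_area)

    area_by_type: dict[str, float] = {}
    parcel_by_id = {p.id: p for p in parcels}
    for farm in farms:
        a = sum(parcel_by_id[i].area_ha for i in farm.field_ids)
        area_by_type[farm.farm_type] = area_by_type.get(farm.farm_type, 0.0) + a
    farm_areas = np.array(list(area_by_type.values()), dtype=float)
    farming_shannon = _shannon(farm_areas / farm_areas.sum()) if farm_areas.sum() else 0.0

    n_animal = sum(1 for f in farms if f.farm_type == "animal_grazing")
    share_animal = 100.0 * n_animal / len(farms) if farms else 0.0

    areas = np.array([p.area_ha for p in parcels], dtype=float)
    perims = np.array([p.perimeter_m for p in parcels], dtype=float)
    cultivated_m2 = areas.sum() * 1e4

    return HeterogeneityMetrics(
        coverage_herbaceous=100.0 * props[1],
        coverage_woodland=100.0 * props[2],
        landscape_shannon=landscape_shannon,
        landscape_shape_index=lsi,
        farming_shannon=farming_shannon,
        share_animal_farms=share_animal,
        n_fields=len(parcels),
        mean_field_size=float(areas.mean()) if len(areas) else 0.0,
        field_boundary_density=float(perims.sum() / cultivated_m2) if cultivated_m2 else 0.0,
    )
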