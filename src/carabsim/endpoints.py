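"""Population endpoints: overall density, Occupancy, Abundance, AOR deltas.

Endpoints are extracted on a fixed sampling day (day-of-year 59, March 1)
from the adult-female population. The landscape is partitioned into
50 m x 50 m aggregation cells (partial boundary cells are dropped); a cell
is occupied iff it holds at least 100 adult females, i.e. at least one
super-individual at the default representation factor. Occupancy is the
occupied proportion of aggregation cells, Abundance the mean female
density inside occupied cells, and overall density the total female count
over the whole landscape area. Scenario effects are reported as percentage
changes of the 30-year/replicate means relative to the worst-case
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import ADULT, PopulationState
from .landscape import LandscapeGrid

logger = logging.getLogger(__name__)

ENDPOINT_DAY = 59               # March 1 on the 365-day calendar
AGGREGATION_CELL_M = 50.0
OCCUPANCY_THRESHOLD_BEETLES = 100


@dataclass
class EndpointRecord:
    """Per-year, per-replicate endpoint triple for one scenario."""

    scenario_id: str
    replicate: int
    year: int
    overall_density: float      # adult females per hectare, whole landscape
    occupancy: float            # proportion of aggregation cells occupied
    abundance: float            # mean females per hectare in occupied cells


@dataclass
class AORDelta:
    """Relative change (%) of the endpoint means versus the baseline."""

    scenario_id: str
    d_occupancy: float | None
    d_abundance: float | None
    d_density: float | None


def measure(
    state: PopulationState,
    grid: LandscapeGrid,
    scenario_id: str = "",
    replicate: int = 0,
    agg_cell_m: float = AGGREGATION_CELL_M,
) -> EndpointRecord:
    """Extract the endpoint triple from the current population state.

    Only whole aggregation cells are used; a partial strip at the
    landscape boundary is dropped. Abundance is defined as 0 when no cell
    is occupied (logged).
    """
    adult = state.stage == ADULT
    n_cols = int(grid.width_m // agg_cell_m)
    n_rows = int(grid.height_m // agg_cell_m)
    if n_cols < 1 or n_rows < 1:
        raise ValueError("landscape smaller than one aggregation cell")
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    if adult.any():
        cx = (state.x[adult] / agg_cell_m).astype(np.int64)
        cy = (state.y[adult] / agg_cell_m).astype(np.int64)
        inside = (cx < n_cols) & (cy < n_rows)
        np.add.at(counts, (cy[inside], cx[inside]), 1)

    females = counts * state.super_factor
    needed_super = -(-OCCUPANCY_THRESHOLD_BEETLES // state.super_factor)  # ceil
    occupied = counts >= needed_super
    n_occ = int(occupied.sum())
    occupancy = n_occ / counts.size

    area_ha = grid.width_m * grid.height_m / 1e4
    total_females = int(adult.sum()) * state.super_factor
    overall_density = total_females / area_ha

    cell_area_ha = agg_cell_m**2 / 1e4
    if n_occ:
        abundance = float(females[occupied].mean()) / cell_area_ha
    else:
        abundance = 0.0
        logger.info("no occupied aggregation cells; abundance reported as 0")

    # partition identity: total mass = occupied mass + sub-threshold mass
    assert females.sum() == females[occupied].sum() + females[~occupied].sum()

    return EndpointRecord(
        scenario_id=scenario_id,
        replicate=replicate,
        year=state.year,
        overall_density=overall_density,
        occupancy=occupancy,
        abundance=abundance,
    )


def records_to_frame(records: list[EndpointRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def summarize(records: list[EndpointRecord] | pd.DataFrame) -> pd.DataFrame:
    """Scenario-level means and coefficients of variation.

    Years are averaged within each replicate first; the scenario mean and
    cv (sample-sd convention, ddof = 1; 0 for a single replicate) are then
    taken across replicate means.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no endpoint records to summarize")
    per_rep = df.groupby(["scenario_id", "replicate"])[
        ["overall_density", "occupancy", "abundance"]
    ].mean()

    def _cv(x: pd.Series) -> float:
        m = x.mean()
        if not m or len(x) < 2:
            return 0.0
        return float(x.std(ddof=1) / m)

    out = per_rep.groupby("scenario_id").agg(
        mean_density=("overall_density", "mean"),
        cv_density=("overall_density", _cv),
        mean_occupancy=("occupancy", "mean"),
        cv_occupancy=("occupancy", _cv),
        mean_abundance=("abundance", "mean"),
        cv_abundance=("abundance", _cv),
        n_replicates=("occupancy", "size"),
    )
    return out.reset_index()


def relative_change(scenario_row: pd.Series, baseline_row: pd.Series) -> AORDelta:
    """Percentage change of each endpoint mean versus the baseline.

    A zero baseline value makes the corresponding delta undefined (None).
    """

    def _delta(col: str) -> float | None:
        base = baseline_row[col]
        if base == 0:
            logger.warning("baseline %s is 0; relative change undefined", col)
            return None
        return 100.0 * (scenario_row[col] - base) / base

    return AORDelta(
        scenario_id=str(scenario_row["scenario_id"]),
        d_occupancy=_delta("mean_occupancy"),
        d_abundance=_delta("mean_abundance"),
        d_density=_delta("mean_density"),
    )


def aor_table(summary: pd.DataFrame, baseline_id: str) -> pd.DataFrame:
    """AOR delta table of all scenarios in ``summary`` vs one baseline."""
    base = summary.loc[summary["scenario_id"] == baseline_id]
    if base.empty:
        raise ValueError(f"baseline scenario {baseline_id!r} not in summary")
    base_row = base.iloc[0]
    rows = [relative_change(row, base_row).__dict__ for _, row in summary.iterrows()]
    return pd.DataFrame(rows)
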