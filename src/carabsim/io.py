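"""Raster and table import/export.

Rasters go out as ESRI ASCII grids (portable text) or single-band TIFF;
parcels, farms and event logs as CSV with documented headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .farms import ScheduledEvent
from .landscape import FarmUnit, FieldParcel, LandscapeGrid


def write_ascii_grid(path: str | Path, array: np.ndarray, cell_size_m: float,
                     nodata: int = -9999) -> None:
    """Write one band as an ESRI ASCII grid (row 0 of the array is the
    southern edge; the file is written north-to-south as the format
    requires)."""
    ny, nx = array.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cell_size_m}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in array[::-1]:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array with row 0 south, cellsize)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        rows: list[list[int]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([int(float(v)) for v in parts])
    arr = np.array(rows[::-1])
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match its header")
    return arr, float(header["cellsize"])


def export_landscape(grid: LandscapeGrid, outdir: str | Path, fmt: str = "asc") -> None:
    """Export the element-type and field-id bands.

    ``fmt='asc'`` writes ESRI ASCII text grids; ``fmt='tiff'`` writes
    single-band TIFFs (no georeferencing tags).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "asc":
        write_ascii_grid(outdir / "element_type.asc", grid.element, grid.cell_size_m)
        write_ascii_grid(outdir / "field_id.asc", grid.field_id, grid.cell_size_m)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(outdir / "element_type.tif", grid.element)
        tifffile.imwrite(outdir / "field_id.tif", grid.field_id)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def parcels_to_frame(parcels: list[FieldParcel]) -> pd.DataFrame:
    """Columns: id, farm_id, area_ha, perimeter_m, soil_type,
    rotation_index, has_margin."""
    return pd.DataFrame([p.__dict__ for p in parcels])


def farms_to_frame(farms: list[FarmUnit]) -> pd.DataFrame:
    """Columns: id, farm_type, n_fields, field_ids (semicolon-joined)."""
    return pd.DataFrame(
        [
            {
                "id": f.id,
                "farm_type": f.farm_type,
                "n_fields": len(f.field_ids),
                "field_ids": ";".join(map(str, f.field_ids)),
            }
            for f in farms
        ]
    )


def events_to_frame(events: list[ScheduledEvent]) -> pd.DataFrame:
    """Columns: field_id, year, day, type, product."""
    return pd.DataFrame([e.__dict__ for e in events])
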