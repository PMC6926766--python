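"""1-km assessment units: tessellation, quadrant sectors, area accounting.

The raster is tiled into square blocks of ``unit_size_m`` (default 1 km —
the basic assessment unit). Each unit carries its per-class areas ``A_ki``
obtained by exact cell counting, so sums over units reconcile with
whole-raster tallies to the last cell. Blocks truncated at the raster edge
are kept with their true, smaller area.

Quadrant sectors (N, NE, …, NW) are the eight 45° azimuth bins of the unit
centroid around a center point, measured clockwise from grid north, with N
spanning [-22.5°, +22.5°).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classes import ALL_CLASSES
from .raster import LandUseGrid

__all__ = ["AssessmentUnitSet", "tessellate", "assign_quadrants", "QUADRANTS"]

QUADRANTS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class AssessmentUnitSet:
    """Tessellation of a raster into assessment units.

    ``table`` has one row per unit with columns: ``unit_id``, ``unit_row``,
    ``unit_col``, half-open cell-index bounds ``row0/row1/col0/col1``,
    total area ``a_k_km2``, per-class areas ``area_<code>``, ``nodata_km2``,
    centroid map coordinates and (after :func:`assign_quadrants`) the
    ``quadrant`` label.
    """

    table: pd.DataFrame
    cell_size_m: float
    unit_size_m: float
    n_unit_rows: int
    n_unit_cols: int
    year: int | None = None

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cells_per_unit_side(self) -> int:
        return int(round(self.unit_size_m / self.cell_size_m))

    def area_columns(self) -> list[str]:
        return [f"area_{c}" for c in ALL_CLASSES]

    def class_area_totals_km2(self) -> dict[int, float]:
        """Σ over units of A_ki per class (for conservation checks)."""
        return {c: float(self.table[f"area_{c}"].sum()) for c in ALL_CLASSES}

    def unit_slices(self) -> list[tuple[int, slice, slice]]:
        """(unit_id, row slice, col slice) for every unit, table order."""
        t = self.table
        return [
            (int(uid), slice(int(r0), int(r1)), slice(int(c0), int(c1)))
            for uid, r0, r1, c0, c1 in zip(
                t["unit_id"], t["row0"], t["row1"], t["col0"], t["col1"]
            )
        ]

    def broadcast_to_cells(self, values: pd.Series, shape: tuple[int, int],
                           fill: float = np.nan) -> np.ndarray:
        """Materialize a per-unit value as a cell-level array."""
        out = np.full(shape, fill, dtype=float)
        lookup = values.to_dict()
        for uid, rs, cs in self.unit_slices():
            if uid in lookup:
                out[rs, cs] = lookup[uid]
        return out

    # -- export -------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_geojson(self, path: str | Path, nrows: int) -> None:
        """Write unit blocks as GeoJSON polygons in map coordinates."""
        cs = self.cell_size_m
        feats = []
        for _, row in self.table.iterrows():
            r0, r1, c0, c1 = (int(row[k]) for k in ("row0", "row1", "col0", "col1"))
            x0 = self._origin_x + c0 * cs
            x1 = self._origin_x + c1 * cs
            y1 = self._origin_y + (nrows - r0) * cs
            y0 = self._origin_y + (nrows - r1) * cs
            ring = [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
            props = {
                k: (row[k] if not isinstance(row[k], (np.integer, np.floating))
                    else row[k].item())
                for k in self.table.columns
            }
            feats.append(
                {"type": "Feature", "geometry": {"type": "Polygon",
                 "coordinates": [ring]}, "properties": props}
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    _origin_x: float = field(default=0.0)
    _origin_y: float = field(default=0.0)


def tessellate(grid: LandUseGrid, unit_size_m: float = 1000.0) -> AssessmentUnitSet:
    """Tile a raster into square assessment units and count class areas.

    ``unit_size_m`` must be a positive multiple of the cell size and at
    least one cell. Per-class areas are exact cell counts times the cell
    area, so ``Σ_units A_ki`` equals the whole-raster class area and
    ``Σ_i A_ki = A_k − nodata area`` for every unit.
    """
    k = unit_size_m / grid.cell_size_m
    if unit_size_m <= 0 or abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"unit_size_m={unit_size_m} must be a positive integer multiple "
            f"of cell_size_m={grid.cell_size_m}"
        )
    k = int(round(k))
    nrows, ncols = grid.shape
    n_ur = -(-nrows // k)  # ceil division: edge blocks kept
    n_uc = -(-ncols // k)

    rows_idx, cols_idx = np.indices(grid.shape)
    unit_index = (rows_idx // k) * n_uc + (cols_idx // k)

    # cross-tabulate unit x class with one bincount
    codes = list(ALL_CLASSES)
    code_to_slot = {c: i for i, c in enumerate(codes)}
    slot = np.full(grid.shape, len(codes), dtype=np.int64)  # last slot = nodata/other
    for c in codes:
        slot[grid.data == c] = code_to_slot[c]
    n_slots = len(codes) + 1
    counts = np.bincount(
        (unit_index * n_slots + slot).ravel(), minlength=n_ur * n_uc * n_slots
    ).reshape(n_ur * n_uc, n_slots)

    cell_area = grid.cell_area_km2
    recs = []
    xs, ys = grid.cell_centers()
    for uid in range(n_ur * n_uc):
        ur, uc = divmod(uid, n_uc)
        r0, r1 = ur * k, min((ur + 1) * k, nrows)
        c0, c1 = uc * k, min((uc + 1) * k, ncols)
        n_cells = (r1 - r0) * (c1 - c0)
        rec = {
            "unit_id": uid,
            "unit_row": ur,
            "unit_col": uc,
            "row0": r0,
            "row1": r1,
            "col0": c0,
            "col1": c1,
            "a_k_km2": n_cells * cell_area,
            "nodata_km2": counts[uid, -1] * cell_area,
            "centroid_x": xs[r0:r1, c0:c1].mean(),
            "centroid_y": ys[r0:r1, c0:c1].mean(),
        }
        for c in codes:
            rec[f"area_{c}"] = counts[uid, code_to_slot[c]] * cell_area
        recs.append(rec)

    units = AssessmentUnitSet(
        table=pd.DataFrame.from_records(recs),
        cell_size_m=grid.cell_size_m,
        unit_size_m=unit_size_m,
        n_unit_rows=n_ur,
        n_unit_cols=n_uc,
        year=grid.year,
    )
    units._origin_x = grid.xllcorner
    units._origin_y = grid.yllcorner
    return units


def assign_quadrants(
    units: AssessmentUnitSet, center: tuple[float, float] | None = None
) -> AssessmentUnitSet:
    """Label every unit with its 45° azimuth sector around ``center``.

    ``center`` is (x, y) in map coordinates; the default is the centroid of
    the unit set extent. Azimuth is measured clockwise from grid north; a
    unit whose centroid coincides with the center is labelled N by
    convention.
    """
    t = units.table
    if center is None:
        center = (float(t["centroid_x"].mean()), float(t["centroid_y"].mean()))
    dx = t["centroid_x"].to_numpy() - center[0]
    dy = t["centroid_y"].to_numpy() - center[1]
    az = np.degrees(np.arctan2(dx, dy)) % 360.0  # clockwise from north (+y)
    sector = np.floor(((az + 22.5) % 360.0) / 45.0).astype(int)
    labels = np.array(QUADRANTS)[sector]
    labels[(dx == 0) & (dy == 0)] = "N"
    units.table = t.assign(quadrant=labels)
    return units
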