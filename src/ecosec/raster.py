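"""Categorical land-use rasters and ESRI ASCII grid I/O.

A :class:`LandUseGrid` is a rectangular integer raster of the eight
land-use class codes plus a nodata code, with square cells and a lower-left
map origin. Rows follow the raster convention: row 0 is the north edge.

The on-disk format is the plain-text ESRI ASCII grid
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header followed
by whitespace-separated rows, north first), which round-trips integer
rasters exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .classes import ALL_CLASSES, NODATA
from .errors import GeometryMismatchError

__all__ = [
    "LandUseGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_raster",
    "ensure_same_geometry",
]


@dataclass
class LandUseGrid:
    """A categorical raster with geometry metadata.

    Parameters
    ----------
    data
        2-D integer array of class codes (or any integer field, e.g. zone
        codes — the container is reused for all categorical rasters).
    cell_size_m
        Side length of the square cells, metres.
    xllcorner, yllcorner
        Map coordinates of the lower-left corner of the lower-left cell.
    year
        Optional time label.
    nodata
        Integer nodata code.
    """

    data: np.ndarray
    cell_size_m: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    year: int | None = None
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("raster data must be integer-coded")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def same_geometry(self, other: "LandUseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each shaped like data."""
        nrows, ncols = self.shape
        cs = self.cell_size_m
        x = self.xllcorner + (np.arange(ncols) + 0.5) * cs
        y = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * cs
        return np.meshgrid(x, y)

    def with_data(self, data: np.ndarray, year: int | None = None) -> "LandUseGrid":
        return replace(self, data=np.asarray(data), year=self.year if year is None else year)

    # -- accounting ---------------------------------------------------
    def class_areas_km2(self, classes: Iterable[int] = ALL_CLASSES) -> dict[int, float]:
        """Whole-raster area per class in km² by direct cell counting."""
        out = {}
        for c in classes:
            out[c] = int(np.count_nonzero(self.data == c)) * self.cell_area_km2
        return out

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata


def ensure_same_geometry(a: LandUseGrid, b: LandUseGrid) -> None:
    """Raise :class:`GeometryMismatchError` unless a and b are co-registered."""
    if not a.same_geometry(b):
        raise GeometryMismatchError(
            f"raster geometry mismatch: shape {a.shape} vs {b.shape}, "
            f"cell {a.cell_size_m} vs {b.cell_size_m}, "
            f"origin ({a.xllcorner},{a.yllcorner}) vs ({b.xllcorner},{b.yllcorner})"
        )


def write_ascii_grid(grid: LandUseGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid with the canonical six-line header."""
    nrows, ncols = grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.xllcorner:.6f}\n"
        f"yllcorner {grid.yllcorner:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.data:
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path: str | Path, year: int | None = None) -> LandUseGrid:
    """Read an ESRI ASCII grid into a :class:`LandUseGrid`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([int(round(float(v))) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {req!r}")
    data = np.asarray(rows, dtype=np.int32)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return LandUseGrid(
        data=data,
        cell_size_m=header["cellsize"],
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        year=year,
        nodata=int(header.get("nodata_value", NODATA)),
    )


def load_raster(
    path: str | Path,
    expected_classes: Iterable[int] = ALL_CLASSES,
    year: int | None = None,
    reference: LandUseGrid | None = None,
) -> LandUseGrid:
    """Read a land-use raster and sanitize unexpected class codes.

    Codes outside ``expected_classes`` (and not nodata) are mapped to the
    nodata code; a warning reports how many cells were affected. If
    ``reference`` is given, the geometry must match it exactly.
    """
    grid = read_ascii_grid(path, year=year)
    expected = set(expected_classes) | {grid.nodata}
    illegal = ~np.isin(grid.data, list(expected))
    n_bad = int(np.count_nonzero(illegal))
    if n_bad:
        warnings.warn(
            f"{path}: {n_bad} cell(s) with codes outside the expected class "
            "set mapped to nodata",
            stacklevel=2,
        )
        data = grid.data.copy()
        data[illegal] = grid.nodata
        grid = grid.with_data(data)
    if reference is not None:
        ensure_same_geometry(grid, reference)
    return grid
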