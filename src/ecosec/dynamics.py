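"""Land-use change accounting: transfer matrices, grassland degradation and
restoration intensities, and patch statistics.

The transfer matrix cross-tabulates co-registered rasters at two dates into
per-class transition areas (km²); its marginals reconcile exactly with the
class areas at either date. Degradation intensity K1 of a grassland class
is the fraction of its initial area moving per year to lower-coverage
grassland, construction land or saline-alkali land; restoration intensity
K2 counts moves to higher-coverage grassland, water or woodland.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label

from .classes import (
    ALL_CLASSES,
    CONSTRUCTION,
    GRASS_COVERAGE_RANK,
    GRASSLAND_CLASSES,
    SALINE,
    WATER,
    WOODLAND,
)
from .raster import LandUseGrid, ensure_same_geometry

__all__ = [
    "TransferMatrix",
    "PatchStats",
    "transfer_matrix",
    "grassland_intensities",
    "patch_stats",
]


@dataclass
class TransferMatrix:
    """Area (km²) transitioning between classes over an interval of dt years.

    ``matrix`` is an 8×8 DataFrame indexed by source class code with
    destination class codes as columns; entry (i, j) is the area that was
    class i at the first date and class j at the second.
    """

    matrix: pd.DataFrame
    dt: float

    def row_sums(self) -> pd.Series:
        """Class areas at the first date."""
        return self.matrix.sum(axis=1)

    def col_sums(self) -> pd.Series:
        """Class areas at the second date."""
        return self.matrix.sum(axis=0)

    def to_csv(self, path) -> None:
        out = self.matrix.copy()
        out.index = [f"from_{c}" for c in out.index]
        out.columns = [f"to_{c}" for c in out.columns]
        out.to_csv(path)


def transfer_matrix(
    grid_t1: LandUseGrid, grid_t2: LandUseGrid, dt: float | None = None
) -> TransferMatrix:
    """Cross-tabulate two co-registered rasters into a transfer matrix.

    Cells that are nodata at either date are excluded. ``dt`` defaults to
    the difference of the grids' year labels and must be positive.
    """
    ensure_same_geometry(grid_t1, grid_t2)
    if dt is None:
        if grid_t1.year is None or grid_t2.year is None:
            raise ValueError("dt not given and year labels missing")
        dt = float(grid_t2.year - grid_t1.year)
    if dt <= 0:
        raise ValueError(f"dt={dt} must be positive")

    codes = list(ALL_CLASSES)
    k = len(codes)
    a = grid_t1.data.ravel()
    b = grid_t2.data.ravel()
    valid = np.isin(a, codes) & np.isin(b, codes)
    ai = np.searchsorted(codes, a[valid])
    bi = np.searchsorted(codes, b[valid])
    counts = np.bincount(ai * k + bi, minlength=k * k).reshape(k, k)
    mat = pd.DataFrame(counts * grid_t1.cell_area_km2, index=codes, columns=codes)
    return TransferMatrix(matrix=mat, dt=dt)


def _degradation_targets(grass_class: int) -> list[int]:
    rank = GRASS_COVERAGE_RANK[grass_class]
    lower_grass = [g for g in GRASSLAND_CLASSES if GRASS_COVERAGE_RANK[g] < rank]
    return lower_grass + [CONSTRUCTION, SALINE]


def _restoration_targets(grass_class: int) -> list[int]:
    rank = GRASS_COVERAGE_RANK[grass_class]
    higher_grass = [g for g in GRASSLAND_CLASSES if GRASS_COVERAGE_RANK[g] > rank]
    return higher_grass + [WATER, WOODLAND]


def grassland_intensities(tm: TransferMatrix) -> pd.DataFrame:
    """Per-class and aggregate grassland degradation/restoration intensities.

    Returns a DataFrame indexed by grassland class code plus an ``all``
    row, with columns ``k1`` (degradation, yr⁻¹) and ``k2`` (restoration,
    yr⁻¹). A class absent at the first date has undefined intensities,
    reported as NaN rather than 0. For the aggregate row the denominator is
    the total grassland area at the first date and internal coverage
    downgrades/upgrades count once.
    """
    rows = {}
    agg_num1 = agg_num2 = 0.0
    agg_area = 0.0
    for g in GRASSLAND_CLASSES:
        s_it = float(tm.matrix.loc[g].sum())
        num1 = float(tm.matrix.loc[g, _degradation_targets(g)].sum())
        num2 = float(tm.matrix.loc[g, _restoration_targets(g)].sum())
        if s_it > 0:
            rows[g] = (num1 / s_it / tm.dt, num2 / s_it / tm.dt)
        else:
            rows[g] = (np.nan, np.nan)
        agg_num1 += num1
        agg_num2 += num2
        agg_area += s_it
    if agg_area > 0:
        rows["all"] = (agg_num1 / agg_area / tm.dt, agg_num2 / agg_area / tm.dt)
    else:
        rows["all"] = (np.nan, np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["k1", "k2"])


@dataclass
class PatchStats:
    """Per-class patch counts, areas and fragmentation (patches per km²).

    ``table`` is indexed by class code with columns ``n_patches``,
    ``area_km2`` and ``fragmentation`` (= n_patches / area_km2, NaN for
    absent classes).
    """

    table: pd.DataFrame
    connectivity: int


def patch_stats(grid: LandUseGrid, connectivity: int = 8) -> PatchStats:
    """Count connected components per class and derive patch density.

    ``connectivity`` is 4 (edge-sharing neighbors) or 8 (edge or corner),
    the landscape-ecology default being 8.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 1 if connectivity == 4 else 2
    rows = {}
    for c in ALL_CLASSES:
        mask = grid.data == c
        n_cells = int(mask.sum())
        if n_cells == 0:
            rows[c] = (0, 0.0, np.nan)
            continue
        n_patches = int(_cc_label(mask, connectivity=conn, return_num=True)[1])
        area = n_cells * grid.cell_area_km2
        rows[c] = (n_patches, area, n_patches / area)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_patches", "area_km2", "fragmentation"]
    )
    table["n_patches"] = table["n_patches"].astype(int)
    return PatchStats(table=table, connectivity=connectivity)
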