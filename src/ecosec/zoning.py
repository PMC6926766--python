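"""Time–space overlay zoning and MCR cost-distance protection delineation.

Two partitions are combined. The *overlay* partition classifies every
assessment unit from its hotspot history (two assessment years plus an
optimized final-year field) into warning zones (core/key restoration, risk
prevention, risk supervisory, ecological potential) and protection seeds
(core/bottom-line/ideal protection). The *MCR* step then builds a
resistance surface as 0.5·(land-use resistance rank) + 0.5·(overlay-zone
resistance rank), accumulates minimum cumulative resistance

    MCR = min Σ D_ij · R_i

from the ecological sources by exact Dijkstra over the 8-connected cell
graph (step cost = mean of the two cells' resistance × step length), and
extends the protection area to cells under the core/potential source cost
thresholds, labelling construction land and farmland inside it as
ecological conflict and the unzoned remainder as ecological buffer.
Warning zones are never overwritten by the protection step.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .classes import (
    CONSTRUCTION,
    FARMLAND,
    HIGH_GRASS,
    LOW_GRASS,
    MEDIUM_GRASS,
    SALINE,
    WATER,
    WOODLAND,
)
from .errors import ConfigError
from .raster import LandUseGrid, ensure_same_geometry
from .units import AssessmentUnitSet
from .autocorr import GRADES, HotspotField, grade_sign

__all__ = [
    "Zone",
    "WARNING_ZONES",
    "PROTECTION_ZONES",
    "ZoneMap",
    "ResistanceSurface",
    "CostField",
    "default_overlay_rules",
    "overlay_partition",
    "build_resistance",
    "mcr_cost_distance",
    "protection_partition",
    "area_report",
    "LANDUSE_RESISTANCE",
    "ZONE_RESISTANCE",
]


class Zone(IntEnum):
    """Integer zone codes used in zone rasters and reports."""

    OTHER = 0
    CORE_RESTORATION = 1
    KEY_RESTORATION = 2
    RISK_PREVENTION = 3
    RISK_SUPERVISORY = 4
    ECOLOGICAL_POTENTIAL = 5
    IDEAL_PROTECTION = 6
    CORE_PROTECTION = 7
    BOTTOM_LINE_PROTECTION = 8
    ECOLOGICAL_BUFFER = 9
    ECOLOGICAL_CONFLICT = 10


#: the five warning zones whose areas sum to the risk warning total
WARNING_ZONES = frozenset({
    Zone.CORE_RESTORATION, Zone.KEY_RESTORATION, Zone.RISK_PREVENTION,
    Zone.RISK_SUPERVISORY, Zone.ECOLOGICAL_POTENTIAL,
})
#: zones whose areas sum to the protection total
PROTECTION_ZONES = frozenset({
    Zone.IDEAL_PROTECTION, Zone.CORE_PROTECTION, Zone.BOTTOM_LINE_PROTECTION,
    Zone.ECOLOGICAL_BUFFER, Zone.ECOLOGICAL_CONFLICT,
})

#: land-use resistance ranks (water most permeable, construction least)
LANDUSE_RESISTANCE: dict[int, float] = {
    WATER: 1, WOODLAND: 2, HIGH_GRASS: 3, MEDIUM_GRASS: 4, LOW_GRASS: 5,
    FARMLAND: 6, SALINE: 7, CONSTRUCTION: 8,
}
#: overlay-zone resistance ranks (protection cores most permeable)
ZONE_RESISTANCE: dict[Zone, float] = {
    Zone.CORE_PROTECTION: 1, Zone.BOTTOM_LINE_PROTECTION: 1,
    Zone.ECOLOGICAL_POTENTIAL: 2, Zone.IDEAL_PROTECTION: 3,
    Zone.OTHER: 4, Zone.RISK_SUPERVISORY: 5, Zone.RISK_PREVENTION: 6,
    Zone.KEY_RESTORATION: 7, Zone.CORE_RESTORATION: 8,
    # buffer/conflict only exist after the MCR step; rank as unzoned space
    Zone.ECOLOGICAL_BUFFER: 4, Zone.ECOLOGICAL_CONFLICT: 4,
}


@dataclass
class ZoneMap:
    """Per-unit and/or per-cell zone membership."""

    unit_zones: pd.Series | None  # indexed by unit_id, Zone values
    cell_zones: np.ndarray | None  # int array of Zone codes, raster shape
    cell_size_m: float | None = None

    def as_grid(self, template: LandUseGrid) -> LandUseGrid:
        if self.cell_zones is None:
            raise ValueError("zone map has no cell-level representation")
        return LandUseGrid(
            data=self.cell_zones.astype(np.int16),
            cell_size_m=template.cell_size_m,
            xllcorner=template.xllcorner,
            yllcorner=template.yllcorner,
            year=template.year,
            nodata=-1,
        )


# ---------------------------------------------------------------------------
# overlay partition

_INTENSITY_TO_ZONE = {"low": Zone.RISK_PREVENTION, "middle": Zone.KEY_RESTORATION,
                      "high": Zone.CORE_RESTORATION}


def default_overlay_rules() -> dict[tuple[str, str, str], Zone]:
    """The shipped overlay rule table over (sign_y1, grade_y2, sign_opt).

    Keys cover all 3 × 7 × 3 combinations of the first-year hot/cold/ns
    sign, the full second-year seven-grade label, and the optimized-field
    sign. Persistently hot units become core protection (promoted to
    bottom-line protection for water-dominant units, applied after
    lookup); newly hot units become ideal protection; doubly
    not-significant units that the optimized analysis flags hot become
    ecological potential; persistently cold units grade into risk
    prevention / key restoration / core restoration by second-year cold
    intensity; newly cold units become risk supervisory; everything else
    is unzoned ("other").
    """
    rules: dict[tuple[str, str, str], Zone] = {}
    for s1 in ("hot", "ns", "cold"):
        for g2 in GRADES:
            s2 = grade_sign(g2)
            for so in ("hot", "ns", "cold"):
                if s1 == "hot" and s2 == "hot":
                    zone = Zone.CORE_PROTECTION
                elif s2 == "hot":
                    zone = Zone.IDEAL_PROTECTION
                elif s1 == "ns" and s2 == "ns" and so == "hot":
                    zone = Zone.ECOLOGICAL_POTENTIAL
                elif s1 == "cold" and s2 == "cold":
                    zone = _INTENSITY_TO_ZONE[g2.split("-")[1]]
                elif s2 == "cold":
                    zone = Zone.RISK_SUPERVISORY
                else:
                    zone = Zone.OTHER
                rules[(s1, g2, so)] = zone
    return rules


def overlay_partition(
    hotspots_y1: HotspotField,
    hotspots_y2: HotspotField,
    optimized_y2: HotspotField,
    units: AssessmentUnitSet,
    rules: Mapping[tuple[str, str, str], Zone] | None = None,
) -> ZoneMap:
    """Classify units into risk/protection zones from their hotspot history.

    All three hotspot fields must cover the same units. The rule table maps
    (first-year sign, second-year grade, optimized sign) to a zone; a
    user-supplied table must cover every combination that occurs. Units
    assigned core protection whose dominant land-use class is water are
    promoted to bottom-line protection.
    """
    g1 = hotspots_y1.grades()
    g2 = hotspots_y2.grades()
    go = optimized_y2.grades()
    ids = units.table["unit_id"].to_numpy()
    for g, name in ((g1, "y1"), (g2, "y2"), (go, "optimized")):
        if not np.array_equal(np.sort(g.index.to_numpy()), np.sort(ids)):
            raise ValueError(f"hotspot field {name} does not cover the unit set")
    rules = dict(rules) if rules is not None else default_overlay_rules()

    triples = [(grade_sign(g1[u]), g2[u], grade_sign(go[u])) for u in ids]
    uncovered = sorted({t for t in triples if t not in rules})
    if uncovered:
        raise ConfigError(f"overlay rule table does not cover: {uncovered}")

    zones = pd.Series([rules[t] for t in triples], index=ids, dtype=object)

    # water-dominance promotion of persistent-hot units
    area_cols = {c: f"area_{c}" for c in LANDUSE_RESISTANCE}
    t = units.table.set_index("unit_id")
    for u in ids:
        if zones[u] == Zone.CORE_PROTECTION:
            areas = {c: t.loc[u, col] for c, col in area_cols.items()}
            dominant = max(areas, key=areas.get)
            if dominant == WATER:
                zones[u] = Zone.BOTTOM_LINE_PROTECTION

    return ZoneMap(unit_zones=zones, cell_zones=None, cell_size_m=units.cell_size_m)


def broadcast_zones(zonemap: ZoneMap, units: AssessmentUnitSet,
                    shape: tuple[int, int]) -> ZoneMap:
    """Materialize unit-level zones as a cell-level integer grid."""
    if zonemap.unit_zones is None:
        raise ValueError("no unit-level zones to broadcast")
    cells = np.full(shape, int(Zone.OTHER), dtype=np.int16)
    lookup = zonemap.unit_zones.to_dict()
    for uid, rs, cs in units.unit_slices():
        cells[rs, cs] = int(lookup[uid])
    return ZoneMap(unit_zones=zonemap.unit_zones, cell_zones=cells,
                   cell_size_m=units.cell_size_m)


# ---------------------------------------------------------------------------
# resistance surface and cost distance


@dataclass
class ResistanceSurface:
    """Per-cell resistance in [1, 8], NaN where land use is undefined."""

    values: np.ndarray
    cell_size_m: float


def build_resistance(
    grid: LandUseGrid,
    overlay_zones: ZoneMap,
    landuse_resistance: Mapping[int, float] | None = None,
    zone_resistance: Mapping[Zone, float] | None = None,
    weights: tuple[float, float] = (0.5, 0.5),
) -> ResistanceSurface:
    """Weighted sum of land-use and overlay-zone resistance ranks."""
    if overlay_zones.cell_zones is None:
        raise ValueError("overlay zones must be cell-level (broadcast first)")
    if overlay_zones.cell_zones.shape != grid.shape:
        raise ValueError("overlay zone grid shape does not match land-use grid")
    lu_res = dict(landuse_resistance or LANDUSE_RESISTANCE)
    zn_res = {int(k): float(v) for k, v in (zone_resistance or ZONE_RESISTANCE).items()}

    present_classes = set(np.unique(grid.data[grid.valid_mask()]).tolist())
    missing = present_classes - set(lu_res)
    if missing:
        raise ConfigError(f"land-use classes {sorted(missing)} missing from "
                          "resistance table")
    present_zones = set(np.unique(overlay_zones.cell_zones).tolist())
    missing_z = present_zones - set(zn_res)
    if missing_z:
        raise ConfigError(f"zones {sorted(missing_z)} missing from resistance table")

    w_lu, w_zn = weights
    out = np.full(grid.shape, np.nan)
    for c in present_classes:
        out[grid.data == c] = w_lu * lu_res[c]
    for z in present_zones:
        out[overlay_zones.cell_zones == z] += w_zn * zn_res[z]  # NaN propagates
    out[~grid.valid_mask()] = np.nan
    return ResistanceSurface(values=out, cell_size_m=grid.cell_size_m)


@dataclass
class CostField:
    """Accumulated minimum cost from the nearest source cell.

    ``cost`` is 0 on sources, +inf where unreachable, NaN where resistance
    is undefined; ``nearest_source`` holds the flat cell index of the
    minimizing source (−1 where undefined/unreachable).
    """

    cost: np.ndarray
    nearest_source: np.ndarray
    cell_size_m: float


def mcr_cost_distance(
    resistance: ResistanceSurface,
    sources: np.ndarray,
    connectivity: int = 8,
) -> CostField:
    """Exact Dijkstra accumulation of resistance-weighted distance.

    The cell graph links 4- or 8-neighbors with edge weight
    (R_a + R_b)/2 × step length, the step length being the cell size
    (×√2 for diagonals). ``sources`` is a boolean mask; it must be
    non-empty and lie on defined resistance. All resistances must be
    positive.
    """
    r = resistance.values
    src = np.asarray(sources, dtype=bool)
    if src.shape != r.shape:
        raise ValueError("sources mask shape mismatch")
    if not src.any():
        raise ValueError("source set is empty")
    valid = np.isfinite(r)
    if np.any(r[valid] <= 0):
        raise ValueError("resistances must be positive")
    if np.any(src & ~valid):
        raise ValueError("sources must lie on defined resistance")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    nrows, ncols = r.shape
    node = -np.ones(r.shape, dtype=np.int64)
    node[valid] = np.arange(valid.sum())
    n = int(valid.sum())
    cs = resistance.cell_size_m

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    rows_i, cols_j, data = [], [], []
    for dr, dc, mult in offsets:
        r0s = slice(max(0, -dr), min(nrows, nrows - dr))
        c0s = slice(max(0, -dc), min(ncols, ncols - dc))
        r1s = slice(max(0, dr), min(nrows, nrows + dr))
        c1s = slice(max(0, dc), min(ncols, ncols + dc))
        a = node[r0s, c0s]
        b = node[r1s, c1s]
        ra = r[r0s, c0s]
        rb = r[r1s, c1s]
        ok = (a >= 0) & (b >= 0)
        rows_i.append(a[ok])
        cols_j.append(b[ok])
        data.append(0.5 * (ra[ok] + rb[ok]) * cs * mult)
    graph = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_j))),
        shape=(n, n),
    ).tocsr()

    src_nodes = node[src & valid]
    dist, _, src_of = _dijkstra(graph, directed=False, indices=src_nodes,
                                min_only=True, return_predecessors=True)
    cost = np.full(r.shape, np.nan)
    nearest = np.full(r.shape, -1, dtype=np.int64)
    flat_of_node = np.flatnonzero(valid.ravel())
    cost[valid] = dist
    reach = np.isfinite(dist)
    nearest_valid = np.full(n, -1, dtype=np.int64)
    nearest_valid[reach] = flat_of_node[src_of[reach]]
    nearest[valid] = nearest_valid
    return CostField(cost=cost, nearest_source=nearest, cell_size_m=cs)


# ---------------------------------------------------------------------------
# protection partition and area accounting


def protection_partition(
    cost_core: CostField,
    cost_potential: CostField | None,
    grid: LandUseGrid,
    overlay_cells: ZoneMap,
    thresholds: tuple[float, float] = (30_000.0, 14_000.0),
) -> ZoneMap:
    """Extend the protection area by cost thresholds and label its interior.

    A cell joins the protection area when its accumulated cost from the
    core sources is below ``thresholds[0]``, or from the potential sources
    below ``thresholds[1]``, or it lies in an ideal-protection zone.
    Within the protection area, previously unzoned cells become ecological
    conflict (construction land or farmland) or ecological buffer; source
    and warning-zone cells keep their labels. Negative thresholds are
    invalid; zero gives the sources ∪ ideal limit case.
    """
    thr_core, thr_pot = thresholds
    if thr_core < 0 or thr_pot < 0:
        raise ValueError("thresholds must be non-negative")
    if overlay_cells.cell_zones is None:
        raise ValueError("overlay zones must be cell-level")
    zones = overlay_cells.cell_zones.copy()

    with np.errstate(invalid="ignore"):
        prot = cost_core.cost < thr_core
        if cost_potential is not None:
            prot |= cost_potential.cost < thr_pot
    prot |= zones == int(Zone.IDEAL_PROTECTION)

    unzoned = (zones == int(Zone.OTHER)) & prot & grid.valid_mask()
    conflict = unzoned & np.isin(grid.data, [CONSTRUCTION, FARMLAND])
    zones[conflict] = int(Zone.ECOLOGICAL_CONFLICT)
    zones[unzoned & ~conflict] = int(Zone.ECOLOGICAL_BUFFER)
    return ZoneMap(unit_zones=overlay_cells.unit_zones, cell_zones=zones,
                   cell_size_m=grid.cell_size_m)


def area_report(zonemap: ZoneMap, cell_size_m: float | None = None) -> pd.Series:
    """Km² per zone plus warning/protection/classified totals.

    The warning total sums its five member zones and the protection total
    its five; ``classified_km2`` is the full mapped extent, so member sums
    reconcile exactly with the per-zone entries.
    """
    cs = cell_size_m or zonemap.cell_size_m
    if zonemap.cell_zones is not None:
        if cs is None:
            raise ValueError("cell size required for cell-level report")
        cell_area = (cs / 1000.0) ** 2
        counts = {z: int(np.count_nonzero(zonemap.cell_zones == int(z)))
                  for z in Zone}
        areas = {z.name.lower(): c * cell_area for z, c in counts.items()}
    elif zonemap.unit_zones is not None:
        raise ValueError("area report requires a cell-level zone map")
    else:
        areas = {z.name.lower(): 0.0 for z in Zone}
    out = pd.Series(areas, dtype=float)
    out["warning_total_km2"] = sum(out[z.name.lower()] for z in WARNING_ZONES)
    out["protection_total_km2"] = sum(out[z.name.lower()] for z in PROTECTION_ZONES)
    out["classified_km2"] = sum(out[z.name.lower()] for z in Zone)
    return out
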