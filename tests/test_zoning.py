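"""Resistance surfaces, MCR cost distance, overlay and protection zoning.

The cost-distance oracle enumerates simple paths depth-first with
branch-and-bound pruning (exact: pruning only discards prefixes already
costlier than a known path) and is independent of the Dijkstra
implementation; networkx provides a second, library-independent check.
"""

import numpy as np
import pandas as pd
import pytest

from ecosec import classes as C
from ecosec.autocorr import classify_seven_grades
from ecosec.errors import ConfigError
from ecosec.units import tessellate
from ecosec.zoning import (
    LANDUSE_RESISTANCE,
    PROTECTION_ZONES,
    WARNING_ZONES,
    ResistanceSurface,
    Zone,
    area_report,
    broadcast_zones,
    build_resistance,
    default_overlay_rules,
    mcr_cost_distance,
    overlay_partition,
    protection_partition,
)

from conftest import make_grid


def brute_cost_field(resistance, sources, cell_size, connectivity=8):
    """Exhaustive DFS over simple paths with cost pruning (exact)."""
    nrows, ncols = resistance.shape
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    best = np.full(resistance.shape, np.inf)
    for sr, sc in zip(*np.nonzero(sources)):
        best[sr, sc] = 0.0

    def dfs(r, c, cost, visited):
        for dr, dc in offs:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols) or (nr, nc) in visited:
                continue
            step = (0.5 * (resistance[r, c] + resistance[nr, nc]) * cell_size
                    * (np.sqrt(2.0) if dr and dc else 1.0))
            nxt = cost + step
            if nxt >= best[nr, nc] - 1e-12:
                continue  # provably non-optimal prefix
            best[nr, nc] = nxt
            dfs(nr, nc, nxt, visited | {(nr, nc)})

    for sr, sc in zip(*np.nonzero(sources)):
        dfs(sr, sc, 0.0, {(sr, sc)})
    return best


def hotspot_field(grades, units, year=None):
    """Build a HotspotField carrying the given grade labels verbatim."""
    z_for = {"cold-high": -3.0, "cold-middle": -2.2, "cold-low": -1.7,
             "not significant": 0.0, "hot-low": 1.7, "hot-middle": 2.2,
             "hot-high": 3.0}
    z = [z_for[g] for g in grades]
    hf = classify_seven_grades(z, unit_ids=units.table["unit_id"].to_numpy(),
                               year=year)
    assert list(hf.table["grade"]) == list(grades)
    return hf


class TestResistance:
    @staticmethod
    def _zone_cells(zone, shape):
        from ecosec.zoning import ZoneMap
        return ZoneMap(unit_zones=None,
                       cell_zones=np.full(shape, int(zone), dtype=np.int16),
                       cell_size_m=100.0)

    def test_weighted_sum_examples(self):
        """Water in core protection 1.0; construction in core restoration
        8.0; farmland in unzoned space 5.0."""
        cases = [
            (C.WATER, Zone.CORE_PROTECTION, 1.0),
            (C.CONSTRUCTION, Zone.CORE_RESTORATION, 8.0),
            (C.FARMLAND, Zone.OTHER, 5.0),
        ]
        for cls, zone, expect in cases:
            grid = make_grid(np.full((2, 2), cls), cell_size_m=100.0)
            rs = build_resistance(grid, self._zone_cells(zone, (2, 2)))
            np.testing.assert_allclose(rs.values, expect)

    def test_values_within_rank_range(self):
        rng = np.random.default_rng(0)
        grid = make_grid(rng.choice(list(C.ALL_CLASSES), size=(6, 6)), 100.0)
        zones = self._zone_cells(Zone.RISK_PREVENTION, (6, 6))
        rs = build_resistance(grid, zones)
        assert np.nanmin(rs.values) >= 1.0 and np.nanmax(rs.values) <= 8.0

    def test_missing_class_in_table_rejected(self):
        grid = make_grid(np.full((2, 2), C.WATER), 100.0)
        with pytest.raises(ConfigError):
            build_resistance(grid, self._zone_cells(Zone.OTHER, (2, 2)),
                             landuse_resistance={C.FARMLAND: 6.0})

    def test_nodata_propagates(self):
        data = np.full((2, 2), C.WATER)
        data[0, 0] = C.NODATA
        rs = build_resistance(make_grid(data, 100.0),
                              self._zone_cells(Zone.OTHER, (2, 2)))
        assert np.isnan(rs.values[0, 0])
        assert np.isfinite(rs.values[1, 1])


class TestCostDistance:
    def test_sources_have_zero_cost(self):
        rs = ResistanceSurface(np.full((4, 4), 2.0), 100.0)
        src = np.zeros((4, 4), bool)
        src[1, 1] = src[3, 0] = True
        cf = mcr_cost_distance(rs, src)
        assert cf.cost[1, 1] == 0.0 and cf.cost[3, 0] == 0.0

    def test_uniform_resistance_manhattan_geodesic(self):
        """Uniform resistance 1, 4-connectivity, unit cell: cost equals the
        Manhattan distance from the source."""
        rs = ResistanceSurface(np.ones((5, 5)), 1.0)
        src = np.zeros((5, 5), bool)
        src[0, 0] = True
        cf = mcr_cost_distance(rs, src, connectivity=4)
        rows, cols = np.indices((5, 5))
        np.testing.assert_allclose(cf.cost, rows + cols, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        res = rng.uniform(1.0, 8.0, size=(4, 4))
        src = np.zeros((4, 4), bool)
        src[rng.integers(4), rng.integers(4)] = True
        cf = mcr_cost_distance(ResistanceSurface(res, 100.0), src)
        expect = brute_cost_field(res, src, 100.0)
        np.testing.assert_allclose(cf.cost, expect, atol=1e-9)

    def test_matches_networkx_dijkstra(self):
        """Independent-library cross-check on a larger instance."""
        import networkx as nx
        rng = np.random.default_rng(42)
        res = rng.uniform(1.0, 8.0, size=(8, 8))
        src = np.zeros((8, 8), bool)
        src[0, 0] = True
        cf = mcr_cost_distance(ResistanceSurface(res, 100.0), src)
        g = nx.Graph()
        for r in range(8):
            for c in range(8):
                for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < 8 and 0 <= nc < 8:
                        wt = (0.5 * (res[r, c] + res[nr, nc]) * 100.0
                              * (np.sqrt(2.0) if dr and dc else 1.0))
                        g.add_edge((r, c), (nr, nc), weight=wt)
        dist = nx.single_source_dijkstra_path_length(g, (0, 0))
        for (r, c), d in dist.items():
            assert cf.cost[r, c] == pytest.approx(d, abs=1e-9)

    def test_raising_resistance_never_lowers_cost(self):
        rng = np.random.default_rng(5)
        res = rng.uniform(1.0, 4.0, size=(5, 5))
        src = np.zeros((5, 5), bool)
        src[2, 2] = True
        base = mcr_cost_distance(ResistanceSurface(res.copy(), 100.0), src).cost
        for _ in range(10):
            res2 = res.copy()
            res2[rng.integers(5), rng.integers(5)] += rng.uniform(0.5, 4.0)
            bumped = mcr_cost_distance(ResistanceSurface(res2, 100.0), src).cost
            assert (bumped >= base - 1e-9).all()

    def test_error_cases(self):
        rs = ResistanceSurface(np.ones((3, 3)), 100.0)
        with pytest.raises(ValueError, match="empty"):
            mcr_cost_distance(rs, np.zeros((3, 3), bool))
        src = np.zeros((3, 3), bool)
        src[0, 0] = True
        with pytest.raises(ValueError, match="positive"):
            mcr_cost_distance(ResistanceSurface(np.zeros((3, 3)), 100.0), src)

    def test_unreachable_cells_infinite(self):
        res = np.ones((3, 3))
        res[1, :] = np.nan  # barrier of undefined resistance
        src = np.zeros((3, 3), bool)
        src[0, 0] = True
        cf = mcr_cost_distance(ResistanceSurface(res, 100.0), src)
        assert np.isinf(cf.cost[2, 2])
        assert np.isnan(cf.cost[1, 1])


class TestOverlayPartition:
    @staticmethod
    def _units(n=3):
        g = make_grid(np.full((n * 2, n * 2), C.HIGH_GRASS), cell_size_m=500.0)
        return tessellate(g, unit_size_m=1000.0), g

    def test_rule_table_is_complete(self):
        rules = default_overlay_rules()
        assert len(rules) == 3 * 7 * 3
        assert set(rules.values()) <= set(Zone)

    def test_persistent_hot_water_promotes_to_bottom_line(self):
        units, g = self._units(2)
        # make unit 0 water-dominant
        g.data[:2, :2] = C.WATER
        units = tessellate(g, unit_size_m=1000.0)
        n = len(units)
        grades = ["hot-high"] + ["not significant"] * (n - 1)
        zm = overlay_partition(hotspot_field(grades, units),
                               hotspot_field(grades, units),
                               hotspot_field(["not significant"] * n, units),
                               units)
        assert zm.unit_zones[0] == Zone.BOTTOM_LINE_PROTECTION

    def test_narrative_branches(self):
        units, _ = self._units(2)
        n = len(units)
        ns = ["not significant"] * n

        def one(g1, g2, go):
            zm = overlay_partition(
                hotspot_field([g1] + ns[1:], units),
                hotspot_field([g2] + ns[1:], units),
                hotspot_field([go] + ns[1:], units),
                units)
            return zm.unit_zones[0]

        assert one("hot-low", "hot-high", "not significant") == Zone.CORE_PROTECTION
        assert one("not significant", "hot-middle", "not significant") == Zone.IDEAL_PROTECTION
        assert one("not significant", "not significant", "hot-low") == Zone.ECOLOGICAL_POTENTIAL
        assert one("cold-low", "cold-low", "not significant") == Zone.RISK_PREVENTION
        assert one("cold-high", "cold-middle", "cold-high") == Zone.KEY_RESTORATION
        assert one("cold-low", "cold-high", "not significant") == Zone.CORE_RESTORATION
        assert one("not significant", "cold-high", "cold-high") == Zone.RISK_SUPERVISORY
        assert one("hot-high", "not significant", "not significant") == Zone.OTHER

    def test_all_not_significant_all_other(self):
        units, _ = self._units(2)
        n = len(units)
        ns = hotspot_field(["not significant"] * n, units)
        zm = overlay_partition(ns, ns, ns, units)
        assert (zm.unit_zones == Zone.OTHER).all()

    def test_incomplete_rule_table_lists_uncovered(self):
        units, _ = self._units(2)
        n = len(units)
        hot = hotspot_field(["hot-high"] * n, units)
        with pytest.raises(ConfigError, match="cover"):
            overlay_partition(hot, hot, hot, units, rules={})


class TestProtectionPartition:
    @staticmethod
    def _setup(landuse, zones_cells, cost):
        from ecosec.zoning import CostField, ZoneMap
        grid = make_grid(landuse, cell_size_m=100.0)
        zm = ZoneMap(unit_zones=None,
                     cell_zones=np.asarray(zones_cells, dtype=np.int16),
                     cell_size_m=100.0)
        cf = CostField(cost=np.asarray(cost, float),
                       nearest_source=np.full(grid.shape, -1), cell_size_m=100.0)
        return grid, zm, cf

    def test_infinite_threshold_covers_reachable(self):
        grid, zm, cf = self._setup(
            np.full((2, 3), C.WATER), np.zeros((2, 3)), np.full((2, 3), 5.0))
        out = protection_partition(cf, None, grid, zm, (np.inf, np.inf))
        assert (out.cell_zones == int(Zone.ECOLOGICAL_BUFFER)).all()

    def test_zero_threshold_sources_and_ideal_only(self):
        zones = np.zeros((2, 3))
        zones[0, 0] = int(Zone.CORE_PROTECTION)
        zones[1, 2] = int(Zone.IDEAL_PROTECTION)
        cost = np.full((2, 3), 3.0)
        cost[0, 0] = 0.0
        grid, zm, cf = self._setup(np.full((2, 3), C.WATER), zones, cost)
        out = protection_partition(cf, None, grid, zm, (0.0, 0.0))
        prot = np.isin(out.cell_zones, [int(z) for z in PROTECTION_ZONES])
        assert prot[0, 0] and prot[1, 2] and prot.sum() == 2

    def test_farmland_under_threshold_is_conflict(self):
        landuse = np.full((1, 3), C.WATER)
        landuse[0, 1] = C.FARMLAND
        cost = np.array([[0.0, 10.0, 30.0]])
        grid, zm, cf = self._setup(landuse, np.zeros((1, 3)), cost)
        out = protection_partition(cf, None, grid, zm, (20.0, 20.0))
        assert out.cell_zones[0, 1] == int(Zone.ECOLOGICAL_CONFLICT)
        assert out.cell_zones[0, 0] == int(Zone.ECOLOGICAL_BUFFER)
        assert out.cell_zones[0, 2] == int(Zone.OTHER)

    def test_warning_zones_not_overwritten(self):
        zones = np.full((1, 3), int(Zone.CORE_RESTORATION))
        grid, zm, cf = self._setup(np.full((1, 3), C.FARMLAND), zones,
                                   np.zeros((1, 3)))
        out = protection_partition(cf, None, grid, zm, (np.inf, np.inf))
        assert (out.cell_zones == int(Zone.CORE_RESTORATION)).all()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        cost = rng.uniform(0, 100, size=(5, 5))
        grid, zm, cf = self._setup(
            np.full((5, 5), C.WATER), np.zeros((5, 5)), cost)
        prev = 0
        for thr in (10.0, 40.0, 80.0, np.inf):
            out = protection_partition(cf, None, grid, zm, (thr, thr))
            n = np.isin(out.cell_zones,
                        [int(z) for z in PROTECTION_ZONES]).sum()
            assert n >= prev
            prev = n

    def test_negative_threshold_rejected(self):
        grid, zm, cf = self._setup(
            np.full((2, 2), C.WATER), np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            protection_partition(cf, None, grid, zm, (-1.0, 5.0))


class TestAreaReport:
    def test_hand_built_map(self):
        from ecosec.zoning import ZoneMap
        cells = np.array([
            [Zone.CORE_RESTORATION, Zone.CORE_RESTORATION],
            [Zone.ECOLOGICAL_BUFFER, Zone.OTHER],
            [Zone.RISK_PREVENTION, Zone.CORE_PROTECTION],
        ], dtype=np.int16)
        rep = area_report(ZoneMap(None, cells, cell_size_m=1000.0))
        assert rep["core_restoration"] == pytest.approx(2.0)
        assert rep["ecological_buffer"] == pytest.approx(1.0)
        assert rep["warning_total_km2"] == pytest.approx(3.0)
        assert rep["protection_total_km2"] == pytest.approx(2.0)
        assert rep["classified_km2"] == pytest.approx(6.0)

    def test_totals_reconcile_with_members(self):
        rng = np.random.default_rng(1)
        from ecosec.zoning import ZoneMap
        cells = rng.choice([int(z) for z in Zone], size=(10, 10)).astype(np.int16)
        rep = area_report(ZoneMap(None, cells, cell_size_m=500.0))
        warn = sum(rep[z.name.lower()] for z in WARNING_ZONES)
        prot = sum(rep[z.name.lower()] for z in PROTECTION_ZONES)
        assert rep["warning_total_km2"] == pytest.approx(warn)
        assert rep["protection_total_km2"] == pytest.approx(prot)
        assert rep["classified_km2"] == pytest.approx(100 * 0.25)

    def test_all_other_map_zero_totals(self):
        from ecosec.zoning import ZoneMap
        rep = area_report(ZoneMap(None, np.zeros((4, 4), dtype=np.int16),
                                  cell_size_m=1000.0))
        assert rep["warning_total_km2"] == 0.0
        assert rep["protection_total_km2"] == 0.0
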