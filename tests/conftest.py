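"""Shared fixtures: toy rasters and session-scoped pipeline runs.

The two full pipeline runs (degrade-only and stable presets) are expensive
(~15 s each), so they are computed once per session and shared between the
pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecosec import classes as C
from ecosec.pipeline import PipelineConfig, PipelineResult, run_pipeline
from ecosec.raster import LandUseGrid


def make_grid(data, cell_size_m=100.0, year=None, **kw) -> LandUseGrid:
    return LandUseGrid(data=np.asarray(data, dtype=np.int16),
                       cell_size_m=cell_size_m, year=year, **kw)


def random_landuse(rng, shape, cell_size_m=100.0, year=None) -> LandUseGrid:
    data = rng.choice(list(C.ALL_CLASSES), size=shape).astype(np.int16)
    return LandUseGrid(data=data, cell_size_m=cell_size_m, year=year)


# ---------------------------------------------------------------------------
# preset pipeline runs (shared, read-only)


@pytest.fixture(scope="session")
def degrade_cfg() -> PipelineConfig:
    return PipelineConfig(scenario="degrade_only")


@pytest.fixture(scope="session")
def degrade_run(degrade_cfg) -> PipelineResult:
    return run_pipeline(degrade_cfg)


@pytest.fixture(scope="session")
def stable_run() -> PipelineResult:
    return run_pipeline(PipelineConfig(scenario="stable"))


# ---------------------------------------------------------------------------
# recovery-metric helpers


def strip_unit_ids(res: PipelineResult, cfg: PipelineConfig) -> set[int]:
    """Units with at least half their cells inside the planted strip."""
    r0, r1, c0, c1 = cfg.resolve_scenario().strip
    out = set()
    for uid, rs, cs in res.units.unit_slices():
        rows = np.arange(rs.start, rs.stop)
        cols = np.arange(cs.start, cs.stop)
        inside = (((rows >= r0) & (rows < r1)).sum()
                  * ((cols >= c0) & (cols < c1)).sum())
        if inside >= 0.5 * len(rows) * len(cols):
            out.add(uid)
    return out


def far_highgrass_units(res: PipelineResult, halo_units: int = 2) -> list[int]:
    """High-grass-dominant units at least ``halo_units`` outside the strip.

    Dominance is by final-year class areas; the strip occupies unit rows
    3–12 and columns 6–9 in the shipped presets.
    """
    t = res.units.table.set_index("unit_id")
    out = []
    for uid in t.index:
        ur, uc = int(t.loc[uid, "unit_row"]), int(t.loc[uid, "unit_col"])
        near = (3 - halo_units <= ur <= 12 + halo_units
                and 6 - halo_units <= uc <= 9 + halo_units)
        if near:
            continue
        areas = {c: t.loc[uid, f"area_{c}"] for c in C.ALL_CLASSES}
        if max(areas, key=areas.get) == C.HIGH_GRASS:
            out.append(int(uid))
    return out
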