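"""Synthetic multi-year land-use scenarios and socio-economic tables.

The generator emulates the structure the assessment assumes about a
resource-city urban fringe: a spatially autocorrelated 8-class mosaic, a
contiguous low-security "oilfield strip" where grassland salinizes over
time, optional post-policy restoration of farmland to high-coverage
grassland outside the strip, and a citywide socio-economic series with a
rise-then-decline oil production curve.

Everything is seeded and deterministic: class placement uses rank-order
thresholding of a smoothed Gaussian noise field (ties broken by cell
index), and all temporal transitions are integer-coded Bernoulli draws from
substreams derived from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .classes import (
    ALL_CLASSES,
    CONSTRUCTION,
    FARMLAND,
    GRASSLAND_CLASSES,
    HIGH_GRASS,
    LOW_GRASS,
    MEDIUM_GRASS,
    SALINE,
    WATER,
    WOODLAND,
)
from .errors import ConfigError
from .raster import LandUseGrid

__all__ = [
    "ScenarioConfig",
    "SocioEconomicSeries",
    "generate_landscape_series",
    "generate_socioeconomic",
    "get_preset",
    "PRESET_NAMES",
]

#: class placement order along the moisture-like noise gradient; adjacent
#: classes in this order form contiguous transitions (water next to
#: grassland, construction next to saline), which keeps patches realistic.
_GRADIENT_ORDER = (WATER, WOODLAND, HIGH_GRASS, MEDIUM_GRASS, LOW_GRASS,
                   FARMLAND, CONSTRUCTION, SALINE)

_DEFAULT_MIX: dict[int, float] = {
    FARMLAND: 0.30,
    HIGH_GRASS: 0.22,
    MEDIUM_GRASS: 0.12,
    LOW_GRASS: 0.06,
    WATER: 0.10,
    WOODLAND: 0.08,
    CONSTRUCTION: 0.07,
    SALINE: 0.05,
}

_OILFIELD_STRIP_MIX: dict[int, float] = {
    HIGH_GRASS: 0.40,
    MEDIUM_GRASS: 0.30,
    LOW_GRASS: 0.20,
    SALINE: 0.05,
    CONSTRUCTION: 0.05,
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic land-use scenario.

    ``strip`` is the (row0, row1, col0, col1) half-open cell-index bounds
    of the oilfield analogue. ``degradation_rate`` is the per-step fraction
    of strip grassland converted directly to saline-alkali land;
    ``coverage_downgrade_rate`` additionally steps surviving strip
    grassland one coverage level down (high→medium→low), mirroring the
    coverage loss around expanding saline patches. ``restoration_rate``
    converts external farmland to high-coverage grassland per step once the
    step's end year exceeds ``policy_year``. A "step" is the transition
    between two consecutive entries of ``years``.
    """

    grid_rows: int = 160
    grid_cols: int = 160
    cell_size_m: float = 30.0
    years: tuple[int, ...] = (1980, 1990, 2000, 2010, 2017)
    strip: tuple[int, int, int, int] | None = None
    degradation_rate: float = 0.0
    coverage_downgrade_rate: float = 0.0
    restoration_rate: float = 0.0
    policy_year: int = 2000
    class_mix: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    strip_mix: Mapping[int, float] | None = None
    autocorrelation_range: float = 4.0
    seed: int = 0
    # socio-economic shape
    economy: str = "growth"  # "growth" | "flat"
    oil_peak_year: int | None = None
    epi_categories: tuple[str, ...] = ("wastewater", "so2", "energy")

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigError("grid dimensions must be positive")
        if len(self.years) < 1 or any(
            b <= a for a, b in zip(self.years, self.years[1:])
        ):
            raise ConfigError("years must be strictly increasing")
        for name in ("degradation_rate", "coverage_downgrade_rate", "restoration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must be in [0, 1]")
        for mix, label in ((self.class_mix, "class_mix"), (self.strip_mix, "strip_mix")):
            if mix is None:
                continue
            if set(mix) - set(ALL_CLASSES):
                raise ConfigError(f"{label} contains unknown class codes")
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{label} must sum to 1 (got {total})")
        if self.strip is not None:
            r0, r1, c0, c1 = self.strip
            if not (0 <= r0 < r1 <= self.grid_rows and 0 <= c0 < c1 <= self.grid_cols):
                raise ConfigError(f"strip {self.strip} outside grid")
        if self.economy not in {"growth", "flat"}:
            raise ConfigError(f"unknown economy preset {self.economy!r}")

    def strip_mask(self) -> np.ndarray:
        mask = np.zeros((self.grid_rows, self.grid_cols), dtype=bool)
        if self.strip is not None:
            r0, r1, c0, c1 = self.strip
            mask[r0:r1, c0:c1] = True
        return mask


@dataclass
class SocioEconomicSeries:
    """Citywide socio-economic table, one row per scenario year.

    Columns: city and national GDP and urbanization indices, population,
    city and national oil production and secondary-industry output,
    ecological-construction investment, and paired ``<cat>_city`` /
    ``<cat>_national`` pollutant/consumption totals per EPI category.
    Monetary units are arbitrary but consistent within a column.
    """

    table: pd.DataFrame  # indexed by year
    epi_categories: tuple[str, ...]

    def __post_init__(self) -> None:
        num = self.table.select_dtypes("number")
        if (num < 0).any().any():
            raise ConfigError("socio-economic values must be non-negative")

    def year(self, y: int) -> pd.Series:
        if y not in self.table.index:
            raise KeyError(f"year {y} missing from socio-economic series")
        return self.table.loc[y]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="year")

    @classmethod
    def from_csv(cls, path, epi_categories: Sequence[str]) -> "SocioEconomicSeries":
        df = pd.read_csv(path, index_col="year")
        return cls(table=df, epi_categories=tuple(epi_categories))


# ---------------------------------------------------------------------------
# landscape generation


def _smoothed_field(rng: np.random.Generator, shape, range_cells: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if range_cells > 0:
        noise = gaussian_filter(noise, sigma=range_cells, mode="reflect")
    return noise


def _classify_by_rank(field_vals: np.ndarray, mix: Mapping[int, float],
                      mask: np.ndarray) -> np.ndarray:
    """Assign classes to masked cells by field rank with exact target counts.

    Cells are ordered by field value (stable sort, ties broken by cell
    index — the comparison path is a pure ordering, so the result only
    depends on the rank structure). Class counts use largest-remainder
    rounding of the target proportions.
    """
    idx = np.flatnonzero(mask)
    order = idx[np.argsort(field_vals.ravel()[idx], kind="stable")]
    n = len(idx)
    codes = [c for c in _GRADIENT_ORDER if mix.get(c, 0.0) > 0]
    exact = np.array([mix[c] * n for c in codes])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    frac_order = np.argsort(-(exact - np.floor(exact)), kind="stable")
    counts[frac_order[:remainder]] += 1
    out = np.zeros(field_vals.shape, dtype=np.int16).ravel()
    pos = 0
    for c, cnt in zip(codes, counts):
        out[order[pos:pos + cnt]] = c
        pos += cnt
    return out.reshape(field_vals.shape)


def generate_landscape_series(config: ScenarioConfig) -> list[LandUseGrid]:
    """Generate one co-registered land-use raster per scenario year.

    The first year is a rank-thresholded smoothed-noise mosaic with the
    configured class mix (a separate mosaic with ``strip_mix`` inside the
    strip). Each subsequent step applies, inside the strip, direct
    grassland→saline conversion at ``degradation_rate`` and a one-level
    coverage downgrade at ``coverage_downgrade_rate`` on the surviving
    grassland; outside the strip, farmland→high-coverage-grassland
    restoration at ``restoration_rate`` for steps ending after
    ``policy_year``. Re-running with the same config is bit-identical.
    """
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    shape = (config.grid_rows, config.grid_cols)
    strip = config.strip_mask()

    base_field = _smoothed_field(rng, shape, config.autocorrelation_range)
    data = _classify_by_rank(base_field, config.class_mix, ~strip if
                             config.strip_mix is not None else np.ones(shape, bool))
    if config.strip_mix is not None and strip.any():
        strip_field = _smoothed_field(rng, shape, config.autocorrelation_range)
        data = data + _classify_by_rank(strip_field, config.strip_mix, strip)

    grids = [LandUseGrid(data=data.astype(np.int16), cell_size_m=config.cell_size_m,
                         year=config.years[0])]
    grass_set = set(GRASSLAND_CLASSES)
    downgrade_to = {HIGH_GRASS: MEDIUM_GRASS, MEDIUM_GRASS: LOW_GRASS,
                    LOW_GRASS: LOW_GRASS}
    for end_year in config.years[1:]:
        data = grids[-1].data.copy()
        u_deg = rng.random(shape)
        u_down = rng.random(shape)
        u_res = rng.random(shape)
        if config.degradation_rate > 0 or config.coverage_downgrade_rate > 0:
            is_grass = np.isin(data, list(grass_set)) & strip
            to_saline = is_grass & (u_deg < config.degradation_rate)
            survives = is_grass & ~to_saline & (u_down < config.coverage_downgrade_rate)
            data[to_saline] = SALINE
            for src, dst in downgrade_to.items():
                data[survives & (grids[-1].data == src)] = dst
        if config.restoration_rate > 0 and end_year > config.policy_year:
            restore = (data == FARMLAND) & ~strip & (u_res < config.restoration_rate)
            data[restore] = HIGH_GRASS
        grids.append(LandUseGrid(data=data, cell_size_m=config.cell_size_m,
                                 year=end_year))
    return grids


# ---------------------------------------------------------------------------
# socio-economic generation


def generate_socioeconomic(config: ScenarioConfig) -> SocioEconomicSeries:
    """Generate the citywide socio-economic table for the scenario years.

    Oil production follows a Gaussian rise-then-decline curve peaking at
    ``oil_peak_year`` (default: the middle scenario year); GDP, population
    and urbanization grow smoothly; pollutant totals scale with city
    activity. The ``flat`` economy preset holds every column constant.
    """
    years = np.asarray(config.years, dtype=float)
    rng = np.random.default_rng(np.random.PCG64(config.seed + 10_000))
    n = len(years)

    if config.economy == "flat":
        rows = {
            "city_gdp": np.full(n, 500.0),
            "national_gdp": np.full(n, 50_000.0),
            "population": np.full(n, 2.5e6),
            "oil_production": np.full(n, 4.0e7),
            "national_oil_production": np.full(n, 2.0e8),
            "secondary_industry": np.full(n, 300.0),
            "national_secondary_industry": np.full(n, 20_000.0),
            "urbanization_city": np.full(n, 0.6),
            "urbanization_national": np.full(n, 0.4),
            "eco_investment": np.full(n, 5.0),
        }
        for cat in config.epi_categories:
            rows[f"{cat}_city"] = np.full(n, 100.0)
            rows[f"{cat}_national"] = np.full(n, 10_000.0)
        table = pd.DataFrame(rows, index=config.years)
        table.index.name = "year"
        return SocioEconomicSeries(table=table, epi_categories=config.epi_categories)

    t = (years - years[0]) / max(years[-1] - years[0], 1.0)
    peak = config.oil_peak_year if config.oil_peak_year is not None else \
        config.years[len(config.years) // 2]
    width = max((years[-1] - years[0]) / 3.0, 1.0)
    oil = 5.0e7 * np.exp(-(((years - peak) / width) ** 2))

    growth = np.exp(2.2 * t)  # city GDP roughly e^2.2-fold over the window
    noise = 1.0 + 0.03 * rng.standard_normal(n)
    rows = {
        "city_gdp": 300.0 * growth * np.abs(noise),
        "national_gdp": 20_000.0 * np.exp(2.6 * t),
        "population": 1.8e6 * (1.0 + 0.5 * t),
        "oil_production": oil,
        "national_oil_production": 1.5e8 * (1.0 + 0.8 * t),
        "secondary_industry": 180.0 * growth,
        "national_secondary_industry": 9_000.0 * np.exp(2.8 * t),
        "urbanization_city": 0.45 + 0.35 * t,
        "urbanization_national": 0.20 + 0.38 * t,
        "eco_investment": 1.0 + 14.0 * t ** 2,  # response ramps up late
    }
    for i, cat in enumerate(config.epi_categories):
        intensity = 1.0 + 0.3 * np.sin(1.5 * t + i)  # mild category-specific shape
        rows[f"{cat}_city"] = 80.0 * growth * intensity
        rows[f"{cat}_national"] = 6_000.0 * np.exp(2.5 * t)
    table = pd.DataFrame(rows, index=config.years)
    table.index.name = "year"
    return SocioEconomicSeries(table=table, epi_categories=config.epi_categories)


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("stable", "degrade_only", "degrade_then_restore")

_PRESET_STRIP = (30, 130, 60, 100)  # cells; vertical strip west of center


def get_preset(name: str, seed: int | None = None) -> ScenarioConfig:
    """Named study scenarios used by the test and acceptance suites.

    All presets use a 160×160 grid of 100-m cells (16×16 one-km units) and
    the years 1980–2017. ``stable`` is a fine-grained homogeneous mosaic
    with no strip and no change; ``degrade_only`` plants a
    grassland-dominated strip that salinizes step by step;
    ``degrade_then_restore`` adds post-2000 farmland restoration outside
    the strip.
    """
    common = dict(grid_rows=160, grid_cols=160, cell_size_m=100.0,
                  years=(1980, 1990, 2000, 2010, 2017))
    if name == "stable":
        cfg = ScenarioConfig(**common, autocorrelation_range=2.0, seed=11)
    elif name == "degrade_only":
        cfg = ScenarioConfig(
            **common,
            strip=_PRESET_STRIP,
            strip_mix=dict(_OILFIELD_STRIP_MIX),
            degradation_rate=0.35,
            coverage_downgrade_rate=0.2,
            autocorrelation_range=3.0,
            seed=7,
        )
    elif name == "degrade_then_restore":
        cfg = ScenarioConfig(
            **common,
            strip=_PRESET_STRIP,
            strip_mix=dict(_OILFIELD_STRIP_MIX),
            degradation_rate=0.35,
            coverage_downgrade_rate=0.2,
            restoration_rate=0.25,
            policy_year=2000,
            autocorrelation_range=3.0,
            seed=13,
        )
    else:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
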