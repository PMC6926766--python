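"""Land-use classification system.

Eight second-level classes grouped into ecological land (woodland, the
three grassland coverage levels, water) and non-ecological land (farmland,
construction land, saline-alkali land and other unused land). Integer codes
are stable across the whole package; rasters additionally carry a nodata
code.
"""

from __future__ import annotations

WOODLAND = 1
HIGH_GRASS = 2
MEDIUM_GRASS = 3
LOW_GRASS = 4
WATER = 5
FARMLAND = 6
CONSTRUCTION = 7
SALINE = 8  # saline-alkali land and other unused land

ALL_CLASSES: tuple[int, ...] = (
    WOODLAND,
    HIGH_GRASS,
    MEDIUM_GRASS,
    LOW_GRASS,
    WATER,
    FARMLAND,
    CONSTRUCTION,
    SALINE,
)

CLASS_NAMES: dict[int, str] = {
    WOODLAND: "woodland",
    HIGH_GRASS: "high_coverage_grassland",
    MEDIUM_GRASS: "medium_coverage_grassland",
    LOW_GRASS: "low_coverage_grassland",
    WATER: "water",
    FARMLAND: "farmland",
    CONSTRUCTION: "construction_land",
    SALINE: "saline_alkali_and_others",
}

#: ecological / non-ecological split of the classification system
ECOLOGICAL_CLASSES: frozenset[int] = frozenset(
    {WOODLAND, HIGH_GRASS, MEDIUM_GRASS, LOW_GRASS, WATER}
)
NON_ECOLOGICAL_CLASSES: frozenset[int] = frozenset({FARMLAND, CONSTRUCTION, SALINE})

#: grassland coverage ordering used by degradation/restoration accounting;
#: higher value = higher coverage
GRASSLAND_CLASSES: tuple[int, ...] = (HIGH_GRASS, MEDIUM_GRASS, LOW_GRASS)
GRASS_COVERAGE_RANK: dict[int, int] = {LOW_GRASS: 1, MEDIUM_GRASS: 2, HIGH_GRASS: 3}

#: default raster nodata code (ESRI ASCII grid convention)
NODATA = -9999
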