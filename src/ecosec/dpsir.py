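"""DPSIR composite landscape eco-security index.

The assessment system has five weighted dimensions — Driving forces,
Pressure, State, Impact, Response — with eleven indicators:

====  ================================================  ========  ========
code  indicator                                         weight    polarity
====  ================================================  ========  ========
D1    urbanization growth intensity (UGI)               0.5       +
D2    per-capita GDP                                    0.5       +
P1    resource curse coefficient (ES)                   0.5       +
P2    environmental performance index (EPI)             0.5       +
S1    grassland degradation intensity (K1)              0.25      −
S2    grassland restoration intensity (K2)              0.25      +
S3    proportion of non-ecological land (U)             0.5       −
I1    ecological risk index (ERI)                       0.5       −
I2    ecological resilience (ECO_res)                   0.25      +
I3    ecosystem service value (ESV)                     0.25      +
R1    intensity of ecological-construction input (IEC)  1.0       +
====  ================================================  ========  ========

Dimension weights: D 0.05, P 0.2, S 0.2, I 0.5, R 0.05. Raw indicators are
min-max normalized with polarity over a pooled reference set; the index is
the doubly weighted sum of normalized values, bounded in [0, 1].

The per-class coefficient tables (interference E, vulnerability F,
elasticity P, ESV value coefficient VC) shipped as defaults are documented
synthetic stand-ins ordered by ecological intuition — construction and
saline land most disturbing and least resilient, water and woodland most
valuable; real applications should supply calibrated tables via config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .classes import (
    ALL_CLASSES,
    CONSTRUCTION,
    FARMLAND,
    HIGH_GRASS,
    LOW_GRASS,
    MEDIUM_GRASS,
    NON_ECOLOGICAL_CLASSES,
    SALINE,
    WATER,
    WOODLAND,
)
from .dynamics import PatchStats
from .errors import ConfigError
from .synthetic import SocioEconomicSeries

__all__ = [
    "IndicatorConfig",
    "minmax_normalize",
    "socio_indicators",
    "eri",
    "eco_res",
    "esv",
    "nonecological_proportion",
    "ahp_weights",
    "consistent_matrix",
    "aggregate_index",
]

DIMENSIONS = ("D", "P", "S", "I", "R")
INDICATORS = ("D1", "D2", "P1", "P2", "S1", "S2", "S3", "I1", "I2", "I3", "R1")

_DEFAULT_DIM_WEIGHTS = {"D": 0.05, "P": 0.2, "S": 0.2, "I": 0.5, "R": 0.05}
_DEFAULT_IND_WEIGHTS = {
    "D1": 0.5, "D2": 0.5,
    "P1": 0.5, "P2": 0.5,
    "S1": 0.25, "S2": 0.25, "S3": 0.5,
    "I1": 0.5, "I2": 0.25, "I3": 0.25,
    "R1": 1.0,
}
_DEFAULT_POLARITY = {
    "D1": +1, "D2": +1, "P1": +1, "P2": +1,
    "S1": -1, "S2": +1, "S3": -1,
    "I1": -1, "I2": +1, "I3": +1,
    "R1": +1,
}

# synthetic stand-in coefficient tables (see module docstring)
_DEFAULT_E = {WOODLAND: 1.0, HIGH_GRASS: 2.0, MEDIUM_GRASS: 3.0, LOW_GRASS: 4.0,
              WATER: 1.0, FARMLAND: 5.0, CONSTRUCTION: 8.0, SALINE: 7.0}
_DEFAULT_F = {WOODLAND: 0.20, HIGH_GRASS: 0.30, MEDIUM_GRASS: 0.40, LOW_GRASS: 0.50,
              WATER: 0.25, FARMLAND: 0.60, CONSTRUCTION: 0.80, SALINE: 0.90}
_DEFAULT_P = {WOODLAND: 0.90, HIGH_GRASS: 0.80, MEDIUM_GRASS: 0.60, LOW_GRASS: 0.40,
              WATER: 0.80, FARMLAND: 0.40, CONSTRUCTION: 0.10, SALINE: 0.20}
_DEFAULT_VC = {WOODLAND: 3.0, HIGH_GRASS: 2.0, MEDIUM_GRASS: 1.3, LOW_GRASS: 0.7,
               WATER: 5.5, FARMLAND: 0.9, CONSTRUCTION: 0.0, SALINE: 0.1}


@dataclass
class IndicatorConfig:
    """Weights, polarities and per-class coefficient tables."""

    dimension_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIM_WEIGHTS))
    indicator_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_IND_WEIGHTS))
    polarity: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_POLARITY))
    e_interference: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_E))
    f_vulnerability: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_F))
    p_elasticity: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_P))
    vc_esv: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_VC))
    epi_categories: tuple[str, ...] = ("wastewater", "so2", "energy")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.dimension_weights.values()) - 1.0) > 1e-9:
            raise ConfigError("dimension weights must sum to 1")
        for dim in DIMENSIONS:
            inds = self.dimension_indicators(dim)
            s = sum(self.indicator_weights[i] for i in inds)
            if abs(s - 1.0) > 1e-9:
                raise ConfigError(
                    f"indicator weights within dimension {dim} sum to {s}, not 1")
        for ind in INDICATORS:
            if self.polarity.get(ind) not in (-1, +1):
                raise ConfigError(f"polarity of {ind} must be +1 or -1")
        for name, tbl in (("e_interference", self.e_interference),
                          ("f_vulnerability", self.f_vulnerability),
                          ("p_elasticity", self.p_elasticity),
                          ("vc_esv", self.vc_esv)):
            missing = set(ALL_CLASSES) - set(tbl)
            if missing:
                raise ConfigError(f"{name} missing classes {sorted(missing)}")
            if name == "vc_esv" and any(v < 0 for v in tbl.values()):
                raise ConfigError("ESV value coefficients must be non-negative")

    @staticmethod
    def dimension_of(indicator: str) -> str:
        return indicator[0]

    def dimension_indicators(self, dim: str) -> list[str]:
        return [i for i in INDICATORS if i[0] == dim]

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "dimension_weights": dict(self.dimension_weights),
            "indicator_weights": dict(self.indicator_weights),
            "polarity": dict(self.polarity),
            "e_interference": {int(k): float(v) for k, v in self.e_interference.items()},
            "f_vulnerability": {int(k): float(v) for k, v in self.f_vulnerability.items()},
            "p_elasticity": {int(k): float(v) for k, v in self.p_elasticity.items()},
            "vc_esv": {int(k): float(v) for k, v in self.vc_esv.items()},
            "epi_categories": list(self.epi_categories),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "IndicatorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["epi_categories"] = tuple(payload.get("epi_categories", ()))
        for key in ("e_interference", "f_vulnerability", "p_elasticity", "vc_esv"):
            payload[key] = {int(k): float(v) for k, v in payload[key].items()}
        return cls(**payload)


# ---------------------------------------------------------------------------
# normalization


def minmax_normalize(values, polarity: int = +1,
                     pool: Sequence[float] | None = None) -> np.ndarray:
    """Linear min-max normalization with polarity.

    Positive polarity maps the minimum to 0 and the maximum to 1; negative
    polarity reverses the scale. The min/max are taken over ``pool`` when
    given (e.g. all units and years jointly), else over ``values``; NaNs
    are ignored for the range and propagate through. A degenerate range
    (max == min) maps every defined value to 0.5 with a warning.
    """
    x = np.asarray(values, dtype=float)
    ref = x if pool is None else np.asarray(pool, dtype=float)
    if np.all(np.isnan(ref)):
        return np.full_like(x, np.nan)
    lo, hi = np.nanmin(ref), np.nanmax(ref)
    if hi == lo:
        warnings.warn("degenerate indicator range (max == min); mapping to 0.5",
                      stacklevel=2)
        out = np.where(np.isnan(x), np.nan, 0.5)
        return out
    if polarity >= 0:
        y = (x - lo) / (hi - lo)
    else:
        y = (hi - x) / (hi - lo)
    return np.clip(y, 0.0, 1.0)


# ---------------------------------------------------------------------------
# citywide (scalar) indicators


def socio_indicators(series: SocioEconomicSeries, year_a: int, year_b: int,
                     config: IndicatorConfig | None = None) -> dict[str, float]:
    """Compute the citywide D, P and R indicators for (year_a, year_b].

    * UGI (D1): ratio of the city's urbanization-index change to the
      national change over the interval; undefined (NaN) when the national
      index did not change.
    * per-capita GDP (D2): city GDP over population at year_b.
    * resource curse coefficient ES (P1): the city's share of national
      resource production divided by its share of national
      secondary-industry output at year_b.
    * EPI (P2): mean over the configured categories of the city's
      consumption/pollution intensity per unit GDP relative to the
      national intensity, at year_b.
    * IEC (R1): ecological-construction investment over city GDP at year_b.
    """
    config = config or IndicatorConfig()
    a, b = series.year(year_a), series.year(year_b)
    if b["city_gdp"] <= 0 or b["national_gdp"] <= 0:
        raise ValueError("GDP must be positive")

    du_nation = b["urbanization_national"] - a["urbanization_national"]
    du_city = b["urbanization_city"] - a["urbanization_city"]
    ugi = np.nan if du_nation == 0 else du_city / du_nation

    d2 = b["city_gdp"] / b["population"]

    oil_share = b["oil_production"] / b["national_oil_production"]
    si_share = b["secondary_industry"] / b["national_secondary_industry"]
    es = oil_share / si_share

    ratios = []
    for cat in config.epi_categories:
        city_intensity = b[f"{cat}_city"] / b["city_gdp"]
        nat_intensity = b[f"{cat}_national"] / b["national_gdp"]
        ratios.append(city_intensity / nat_intensity)
    epi = float(np.mean(ratios)) if ratios else np.nan

    iec = b["eco_investment"] / b["city_gdp"]
    return {"D1": float(ugi), "D2": float(d2), "P1": float(es),
            "P2": float(epi), "R1": float(iec)}


# ---------------------------------------------------------------------------
# per-unit indicators


def _area_map(areas: Mapping[int, float]) -> dict[int, float]:
    return {int(c): float(a) for c, a in areas.items()}


def eri(areas_km2: Mapping[int, float], config: IndicatorConfig) -> float:
    """Landscape ecological risk index of one unit.

    ERI = Σ_i (A_ki / A_k) · E_i · F_i over the classes present, where A_k
    is the valid (non-nodata) unit area; NaN for an all-nodata unit. The
    value always lies between the smallest and largest per-class E·F.
    """
    areas = _area_map(areas_km2)
    missing = set(areas) - set(config.e_interference)
    if missing - {c for c, a in areas.items() if a == 0}:
        raise ConfigError(f"classes {sorted(missing)} missing from coefficients")
    a_k = sum(areas.values())
    if a_k <= 0:
        return np.nan
    return sum(
        (a / a_k) * config.e_interference[c] * config.f_vulnerability[c]
        for c, a in areas.items()
    )


def eco_res(patches: PatchStats, config: IndicatorConfig) -> float:
    """Ecological resilience: Σ_i A_i · P_i / C_i over classes present.

    With fragmentation C_i = N_i / A_i this equals Σ_i P_i · A_i² / N_i —
    large, coherent patches of elastic classes score highest. NaN when no
    class is present.
    """
    t = patches.table
    present = t[t["area_km2"] > 0]
    if present.empty:
        return np.nan
    total = 0.0
    for c, row in present.iterrows():
        if row["fragmentation"] <= 0 or np.isnan(row["fragmentation"]):
            raise ValueError(f"class {c}: fragmentation must be positive")
        total += row["area_km2"] * config.p_elasticity[int(c)] / row["fragmentation"]
    return total


def esv(areas_km2: Mapping[int, float], config: IndicatorConfig) -> float:
    """Ecosystem service value: Σ_i A_i · VC_i (VC per km², config units)."""
    areas = _area_map(areas_km2)
    return sum(a * config.vc_esv[c] for c, a in areas.items())


def nonecological_proportion(areas_km2: Mapping[int, float]) -> float:
    """Share of the unit's valid area in non-ecological classes.

    Farmland, construction land and saline-alkali/other land count as
    non-ecological per the classification system; NaN for an all-nodata
    unit.
    """
    areas = _area_map(areas_km2)
    a_k = sum(areas.values())
    if a_k <= 0:
        return np.nan
    return sum(a for c, a in areas.items() if c in NON_ECOLOGICAL_CLASSES) / a_k


# ---------------------------------------------------------------------------
# AHP weights

#: Saaty random consistency index by matrix size
_SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
             8: 1.41, 9: 1.45, 10: 1.49}


def ahp_weights(pairwise: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic-hierarchy-process weights from a pairwise comparison matrix.

    Returns the normalized principal eigenvector and the consistency ratio
    CR = ((λ_max − n) / (n − 1)) / RI(n). The matrix must be square (size
    2–10), positive and reciprocal (a_ji = 1/a_ij); CR > 0.1 triggers a
    warning (the conventional inconsistency threshold). For n = 2 the CR
    is 0 by convention.
    """
    m = np.asarray(pairwise, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError("pairwise matrix must be square")
    n = m.shape[0]
    if not 2 <= n <= 10:
        raise ConfigError("pairwise matrix size must be between 2 and 10")
    if np.any(m <= 0):
        raise ConfigError("pairwise matrix entries must be positive")
    if not np.allclose(m * m.T, 1.0, rtol=1e-6):
        raise ConfigError("pairwise matrix is not reciprocal (a_ji != 1/a_ij)")

    eigvals, eigvecs = np.linalg.eig(m)
    i_max = int(np.argmax(eigvals.real))
    lam = float(eigvals[i_max].real)
    w = np.abs(eigvecs[:, i_max].real)
    w = w / w.sum()
    if n <= 2:
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        cr = ci / _SAATY_RI[n]
        cr = max(cr, 0.0)
    if cr > 0.1:
        warnings.warn(f"AHP consistency ratio {cr:.3f} exceeds 0.1", stacklevel=2)
    return w, cr


def consistent_matrix(weights: Sequence[float]) -> np.ndarray:
    """Build the perfectly consistent pairwise matrix a_ij = w_i / w_j."""
    w = np.asarray(weights, dtype=float)
    return w[:, None] / w[None, :]


# ---------------------------------------------------------------------------
# aggregation


def aggregate_index(normalized: pd.DataFrame,
                    config: IndicatorConfig | None = None) -> pd.Series:
    """Doubly weighted DPSIR sum of normalized indicators, in [0, 1].

    ``normalized`` has one column per indicator code (subset of the eleven)
    and one row per assessment scope (unit-year, quadrant, whole area).
    Missing (NaN) indicators are handled by renormalizing the remaining
    indicator weights within their dimension — and, when a whole dimension
    is missing, the remaining dimension weights — so the index is not
    biased toward 0 by data gaps. Rows missing every indicator yield NaN.
    """
    config = config or IndicatorConfig()
    unknown = set(normalized.columns) - set(INDICATORS)
    if unknown:
        raise ConfigError(f"unknown indicator columns {sorted(unknown)}")
    bad = normalized.select_dtypes("number")
    if ((bad < -1e-9) | (bad > 1 + 1e-9)).any().any():
        raise ValueError("normalized indicators must lie in [0, 1]")

    idx = pd.Series(0.0, index=normalized.index)
    dim_weight_present = pd.Series(0.0, index=normalized.index)
    for dim in DIMENSIONS:
        inds = [i for i in config.dimension_indicators(dim) if i in normalized.columns]
        if not inds:
            continue
        sub = normalized[inds]
        w = np.array([config.indicator_weights[i] for i in inds])
        present = sub.notna().to_numpy()
        w_eff = present * w  # zero weight where missing
        w_sum = w_eff.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dim_score = np.where(
                w_sum > 0,
                np.nansum(sub.to_numpy() * w_eff, axis=1) / w_sum,
                np.nan,
            )
        has_dim = w_sum > 0
        w_dim = config.dimension_weights[dim]
        idx += np.where(has_dim, w_dim * dim_score, 0.0)
        dim_weight_present += np.where(has_dim, w_dim, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = idx / dim_weight_present.replace(0.0, np.nan)
    return out
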