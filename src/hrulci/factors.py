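"""Geographic correction factors and the per-HRU export weight.

Eight factors modulate the standard-farmland export baseline of each HRU:

====  =========================== ==========================================
L     source-sink landscape type  categorical, per land-use class
P     slope                       degrees, classed below/above 25
R     annual precipitation        mm/yr, classed around the 400-800 band
D     effective distance          m to the nearest water cell, linear decay
                                  to zero at a 20 km cap
N     NDVI                        vegetation density, classed, inhibiting
S     soil texture                sandy / loam / clay
F     fertilizer application      kg/ha/yr, classed around 375-525
A     effective soil moisture     low / moderate / high runoff potential
====  =========================== ==========================================

The raw weight is the product W = L*P*R*D*N*S*F*A, so the standard-farmland
reference plot (every factor in its baseline class, coefficient 1) has
exactly W = 1 and any HRU's raw weight reads directly as a multiple of the
standard-farmland export.  Weights are then normalised by the basin maximum
for mapping (max weight 1).  An additive composition (mean of the eight
coefficients) is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .grids import CategoricalGrid, Grid, assert_aligned
from .hydro import HRU

__all__ = [
    "FACTOR_NAMES",
    "POLLUTANTS",
    "CoefficientTable",
    "CoefficientTableError",
    "load_coefficient_table",
    "default_coefficient_table",
    "compute_ndvi",
    "compute_slope",
    "distance_coefficient",
    "classify_factor",
    "hru_factor_values",
    "build_factor_stack",
    "hru_weight",
    "normalize_weights",
]

FACTOR_NAMES = ("L", "P", "R", "D", "N", "S", "F", "A")
POLLUTANTS = ("TN", "TP", "COD")
_CATEGORICAL_FACTORS = {"L", "S", "A"}
_CONTINUOUS_FACTORS = {"P", "R", "N", "F"}


class CoefficientTableError(ValueError):
    """Raised for malformed or non-covering coefficient configurations."""


@dataclass
class CoefficientTable:
    """Per-pollutant factor-class -> coefficient mapping.

    ``tables[pollutant][factor]`` is a list of class dicts (categorical:
    ``names`` + ``coef``; continuous: ``min``/``max`` + ``coef``); the
    distance factor D is a dict ``{"type": "linear_decay", "cap_m": ...}``.
    """

    tables: dict[str, dict[str, Any]]
    baseline_export: dict[str, float] = field(default_factory=dict)
    composition: str = "product"  # or "additive"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for pol, factors in self.tables.items():
            for f in FACTOR_NAMES:
                if f not in factors:
                    raise CoefficientTableError(f"{pol}: missing factor {f}")
            for f, spec in factors.items():
                if f == "D":
                    if not (isinstance(spec, Mapping) and spec.get("type") == "linear_decay"
                            and float(spec.get("cap_m", 0)) > 0):
                        raise CoefficientTableError(f"{pol}/D: expected linear_decay with cap_m > 0")
                    continue
                if not spec:
                    raise CoefficientTableError(f"{pol}/{f}: empty class list")
                baselines = [c for c in spec if c.get("baseline")]
                if len(baselines) != 1:
                    raise CoefficientTableError(f"{pol}/{f}: exactly one baseline class required")
                if baselines[0]["coef"] != 1.0:
                    raise CoefficientTableError(f"{pol}/{f}: baseline class must have coef 1")
                for c in spec:
                    coef = float(c["coef"])
                    if not (math.isfinite(coef) and coef >= 0):
                        raise CoefficientTableError(f"{pol}/{f}: coefficient must be finite and >= 0")
                if f in _CONTINUOUS_FACTORS:
                    ivs = sorted(((float(c["min"]), float(c["max"])) for c in spec))
                    for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
                        if a1 > b0:
                            raise CoefficientTableError(f"{pol}/{f}: overlapping intervals")
                        if a1 < b0:
                            raise CoefficientTableError(f"{pol}/{f}: gap between {a1} and {b0}")
                else:
                    seen: set[str] = set()
                    for c in spec:
                        for name in c["names"]:
                            if name in seen:
                                raise CoefficientTableError(f"{pol}/{f}: class {name!r} listed twice")
                            seen.add(name)

    def distance_cap(self, pollutant: str) -> float:
        return float(self.tables[pollutant]["D"]["cap_m"])


def load_coefficient_table(path: str | Path) -> CoefficientTable:
    """Load and validate a coefficient table from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _table_from_mapping(raw)


def _table_from_mapping(raw: Mapping[str, Any]) -> CoefficientTable:
    if "pollutants" not in raw:
        raise CoefficientTableError("config missing top-level 'pollutants' key")
    return CoefficientTable(
        tables={p: dict(f) for p, f in raw["pollutants"].items()},
        baseline_export=dict(raw.get("baseline_export_kg_ha_yr", {})),
        composition=raw.get("composition", "product"),
    )


def default_coefficient_table() -> CoefficientTable:
    """The shipped default table (ordinal structure with stand-in magnitudes)."""
    text = resources.files("hrulci").joinpath("data/default_coefficients.yaml").read_text()
    return _table_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# derived surfaces
# ---------------------------------------------------------------------------

def compute_ndvi(red: Grid, nir: Grid) -> Grid:
    """(NIR - red) / (NIR + red); zero-sum cells become nodata."""
    assert_aligned([red, nir], names=["red", "nir"])
    denom = nir.values + red.values
    bad = red.nodata_mask | nir.nodata_mask | (denom == 0) | ~np.isfinite(denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(bad, np.nan, (nir.values - red.values) / denom)
    return Grid(ndvi, bad, red.cell_size, red.origin)


def compute_slope(dem: Grid) -> Grid:
    """Horn 3x3 finite-difference slope in degrees, edge-replicated border."""
    z = np.pad(dem.values, 1, mode="edge")
    cs = dem.cell_size
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    mask = dem.nodata_mask.copy()
    return Grid(np.where(mask, np.nan, slope), mask, cs, dem.origin)


def distance_coefficient(distance_m: float, cap_m: float = 20000.0) -> float:
    """Linear decay of pollutant influence with distance to the water body:
    1 at the water's edge, exactly 0 at and beyond the cap (default 20 km)."""
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    if not cap_m > 0:
        raise ValueError("distance cap must be positive")
    return max(0.0, 1.0 - distance_m / cap_m)


# ---------------------------------------------------------------------------
# classification and weights
# ---------------------------------------------------------------------------

def classify_factor(factor: str, value: Any, table: CoefficientTable,
                    pollutant: str = "TN") -> tuple[str, float]:
    """Resolve one factor value to its (class label, coefficient).

    Continuous factors use lower-closed, upper-open [min, max) intervals;
    categorical factors match by class name; D evaluates the distance decay
    (label reports the cap).
    """
    if factor not in FACTOR_NAMES:
        raise ValueError(f"unknown factor {factor!r}")
    spec = table.tables[pollutant][factor]
    if factor == "D":
        cap = float(spec["cap_m"])
        return (f"linear decay, cap {cap / 1000:g} km", distance_coefficient(float(value), cap))
    if factor in _CATEGORICAL_FACTORS:
        name = str(value)
        for c in spec:
            if name in c["names"]:
                return ("/".join(c["names"]), float(c["coef"]))
        raise CoefficientTableError(f"{pollutant}/{factor}: no class covers {value!r}")
    v = float(value)
    for c in spec:
        if float(c["min"]) <= v < float(c["max"]):
            return (c.get("label", f"[{c['min']}, {c['max']})"), float(c["coef"]))
    raise CoefficientTableError(f"{pollutant}/{factor}: no interval covers {v}")


def _majority_code(codes: np.ndarray) -> int:
    vals, counts = np.unique(codes, return_counts=True)
    return int(vals[np.argmax(counts)])


def hru_factor_values(hru: HRU, rasters: Mapping[str, Grid],
                      landuse: CategoricalGrid, soil: CategoricalGrid,
                      soil_moisture: CategoricalGrid | None = None) -> dict[str, Any] | None:
    """One FactorStack row for an HRU.

    Continuous surfaces (``slope``, ``precip``, ``ndvi``, ``distance``,
    ``fertilizer``) are averaged over the HRU's cells (cells are equal-area,
    so the plain mean is the area-weighted mean); land use and soil come
    from the HRU's single codes; soil moisture, a separate classed raster,
    is taken by majority vote.  Returns None (incomplete) when any
    continuous factor has no data on the HRU.
    """
    rows = np.array([rc[0] for rc in hru.cells])
    cols = np.array([rc[1] for rc in hru.cells])
    out: dict[str, Any] = {
        "hru_id": hru.id,
        "subbasin_id": hru.subbasin_id,
        "landuse_class": landuse.legend[hru.landuse_code],
        "soil_texture_class": soil.legend[hru.soil_code],
        "area_ha": hru.area_ha,
    }
    names = {"slope": "slope_deg", "precip": "precip_mm", "ndvi": "ndvi",
             "distance": "distance_m", "fertilizer": "fertilizer_kg_ha"}
    for key, col in names.items():
        g = rasters[key]
        vals = g.values[rows, cols]
        ok = ~g.nodata_mask[rows, cols] & np.isfinite(vals)
        if not ok.any():
            return None
        out[col] = float(vals[ok].mean())
    if soil_moisture is not None:
        ok = ~soil_moisture.nodata_mask[rows, cols]
        if not ok.any():
            return None
        code = _majority_code(soil_moisture.codes[rows, cols][ok])
        out["soil_moisture_class"] = soil_moisture.legend[code]
    else:
        out["soil_moisture_class"] = "moderate"
    return out


def build_factor_stack(hrus: list[HRU], rasters: Mapping[str, Grid],
                       landuse: CategoricalGrid, soil: CategoricalGrid,
                       soil_moisture: CategoricalGrid | None = None) -> pd.DataFrame:
    """FactorStack rows for all HRUs; incomplete HRUs are dropped with a warning."""
    import warnings

    rows = []
    dropped = []
    for h in hrus:
        row = hru_factor_values(h, rasters, landuse, soil, soil_moisture)
        if row is None:
            dropped.append(h.id)
        else:
            rows.append(row)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} HRUs with no factor data: {dropped[:10]}")
    return pd.DataFrame(rows)


def hru_weight(stack_row: Mapping[str, Any], table: CoefficientTable,
               pollutant: str) -> float:
    """Raw weight of one HRU: the composition of the eight coefficients.

    With the default multiplicative composition, W = L*P*R*D*N*S*F*A, a
    value of 1 means "exports like standard farmland at the water's edge".
    """
    values = {
        "L": stack_row["landuse_class"],
        "P": stack_row["slope_deg"],
        "R": stack_row["precip_mm"],
        "D": stack_row["distance_m"],
        "N": stack_row["ndvi"],
        "S": stack_row["soil_texture_class"],
        "F": stack_row["fertilizer_kg_ha"],
        "A": stack_row["soil_moisture_class"],
    }
    coefs = [classify_factor(f, values[f], table, pollutant)[1] for f in FACTOR_NAMES]
    if table.composition == "additive":
        return float(np.mean(coefs))
    return float(np.prod(coefs))


def normalize_weights(weights: np.ndarray | list[float]) -> np.ndarray:
    """Divide raw weights by their maximum so the map scales to [0, 1];
    the ordering (and argmax) of HRUs is preserved."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or not np.any(w > 0):
        raise ValueError("need at least one positive weight to normalise")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w / w.max()
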