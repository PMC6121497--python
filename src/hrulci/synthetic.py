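"""Seeded generators for a small synthetic basin.

The generators stand in for the real inputs of a basin-scale study — a
drainable DEM, a patchy six-class land-use map, a soil-texture map, smooth
precipitation, per-class NDVI (with consistent red/NIR reflectances), and a
fertilizer surface — so the whole pipeline runs without any external
download.  All randomness flows from a single ``numpy`` Generator seeded by
:class:`ScenarioSpec`; the same spec + seed yields bit-identical layers.

Default study conditions (a small intensively farmed coastal basin):

* 64 x 64 cells of 30 m;
* six land-use classes dominated by forest, with cultivated land, orchards,
  residential land, water and unused land;
* precipitation gradient 500-900 mm/yr across the grid;
* NDVI class means: forest 0.80, orchard 0.55, cultivated 0.35, unused
  0.20, residential 0.10, water -0.10 (sd 0.05);
* fertilizer 600 kg/ha/yr on cultivated land (above the 375-525
  standard-farmland band, reflecting intensive application), 450 on
  orchards, zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import CategoricalGrid, Grid

__all__ = [
    "LANDUSE_LEGEND",
    "SOIL_LEGEND",
    "MOISTURE_LEGEND",
    "ScenarioSpec",
    "synth_dem",
    "synth_landuse",
    "synth_soil",
    "synth_factor_surfaces",
    "standard_farmland_fixture",
]

LANDUSE_LEGEND = {1: "forest", 2: "residential", 3: "cultivated",
                  4: "water", 5: "unused", 6: "orchard"}
SOIL_LEGEND = {1: "sandy", 2: "loam", 3: "clay"}
MOISTURE_LEGEND = {1: "low", 2: "moderate", 3: "high"}

_DEFAULT_NDVI_MEANS = {"forest": 0.80, "orchard": 0.55, "cultivated": 0.35,
                       "unused": 0.20, "residential": 0.10, "water": -0.10}
_DEFAULT_PROPORTIONS = {"forest": 0.45, "cultivated": 0.25, "orchard": 0.10,
                        "residential": 0.10, "water": 0.05, "unused": 0.05}


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions of a synthetic basin; fully determines every layer
    together with ``seed``."""

    shape: tuple[int, int] = (64, 64)
    cell_size: float = 30.0
    seed: int = 0
    n_landuse_classes: int = 6
    patch_clustering: float = 0.6
    relief: float = 80.0
    roughness: float = 0.4
    precip_range: tuple[float, float] = (500.0, 900.0)
    ndvi_class_means: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NDVI_MEANS))
    ndvi_sd: float = 0.05
    fertilizer_kg_ha: dict[str, float] = field(
        default_factory=lambda: {"cultivated": 600.0, "orchard": 450.0})

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError("scenario grid must be at least 4 x 4")
        if not 2 <= self.n_landuse_classes <= 6:
            raise ValueError("between 2 and 6 land-use classes supported")
        if not 0.0 <= self.patch_clustering <= 1.0:
            raise ValueError("patch_clustering must lie in [0, 1]")
        if not self.relief > 0:
            raise ValueError("relief must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per layer."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def synth_dem(spec: ScenarioSpec) -> Grid:
    """Inclined plane plus smooth seeded bumps.

    The plane tilts toward the south border (amplitude ``relief`` m, plus a
    mild cross-tilt), so at least one border outlet always exists;
    ``roughness`` scales the bump amplitude as a fraction of the relief
    (0 gives a strictly monotone plane).
    """
    rng = spec.rng(1)
    nr, nc = spec.shape
    rows = np.arange(nr)[:, None].astype(float)
    cols = np.arange(nc)[None, :].astype(float)
    base = (nr - 1 - rows) * (spec.relief / max(nr - 1, 1))
    base = base + cols * (spec.relief * 0.1 / max(nc - 1, 1))
    bumps = ndimage.gaussian_filter(rng.normal(size=spec.shape), sigma=max(nr, nc) / 12)
    if bumps.std() > 0 and spec.roughness > 0:
        bumps = bumps / bumps.std() * spec.relief * spec.roughness * 0.5
        base = base + bumps
    return Grid(base, np.zeros(spec.shape, dtype=bool), spec.cell_size)


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int],
                    clustering: float) -> np.ndarray:
    noise = rng.uniform(size=shape)
    sigma = clustering * min(shape) / 8.0
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
    return noise


def _categorical_from_field(field_: np.ndarray, codes: list[int],
                            proportions: list[float]) -> np.ndarray:
    """Quantile-threshold a continuous field into classes with the requested
    area proportions (so every requested class is present)."""
    q = np.cumsum(proportions)[:-1] / sum(proportions)
    cuts = np.quantile(field_, q)
    return np.asarray(codes, dtype=np.int64)[np.searchsorted(cuts, field_, side="right")]


def synth_landuse(spec: ScenarioSpec, max_retries: int = 8) -> CategoricalGrid:
    """Patchy land-use map by smoothed-noise quantile thresholding.

    ``patch_clustering`` 0 gives i.i.d. cells; 1 gives a few large patches.
    All requested classes are guaranteed present (quantile cuts; on a
    pathological tiny grid the seed is incremented and the draw retried).
    """
    codes = list(LANDUSE_LEGEND)[: spec.n_landuse_classes]
    names = [LANDUSE_LEGEND[c] for c in codes]
    props = [_DEFAULT_PROPORTIONS[n] for n in names]
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, attempt]))
        field_ = _smoothed_field(rng, spec.shape, spec.patch_clustering)
        cat = _categorical_from_field(field_, codes, props)
        if set(np.unique(cat)) == set(codes):
            legend = {c: LANDUSE_LEGEND[c] for c in codes}
            return CategoricalGrid(cat, np.zeros(spec.shape, bool), spec.cell_size, legend)
    raise RuntimeError("could not realise all land-use classes on this grid")


def synth_soil(spec: ScenarioSpec) -> CategoricalGrid:
    """Three-class soil-texture map (sandy / loam / clay), loam dominant."""
    rng = spec.rng(3)
    field_ = _smoothed_field(rng, spec.shape, max(spec.patch_clustering, 0.4))
    cat = _categorical_from_field(field_, [1, 2, 3], [0.2, 0.6, 0.2])
    return CategoricalGrid(cat, np.zeros(spec.shape, bool), spec.cell_size, dict(SOIL_LEGEND))


def _synth_soil_moisture(spec: ScenarioSpec) -> CategoricalGrid:
    rng = spec.rng(4)
    field_ = _smoothed_field(rng, spec.shape, max(spec.patch_clustering, 0.4))
    cat = _categorical_from_field(field_, [1, 2, 3], [0.2, 0.6, 0.2])
    return CategoricalGrid(cat, np.zeros(spec.shape, bool), spec.cell_size, dict(MOISTURE_LEGEND))


def synth_factor_surfaces(spec: ScenarioSpec, landuse: CategoricalGrid) -> dict[str, Grid | CategoricalGrid]:
    """All factor input layers consistent with the land-use map.

    Returns ``precip`` (smooth west-east gradient over ``precip_range``),
    ``ndvi`` (per-class mean + noise, clipped to [-1, 1]), matching ``red``
    and ``nir`` reflectances (fixed total reflectance 0.6, so recomputing
    NDVI from the bands reproduces the target map exactly), ``fertilizer``
    (positive only on cultivated land and orchards), ``soil`` and
    ``soil_moisture`` class maps.
    """
    nr, nc = spec.shape
    rng = spec.rng(5)
    lo, hi = spec.precip_range
    cols = np.arange(nc)[None, :] / max(nc - 1, 1)
    precip = lo + (hi - lo) * (cols + 0.05 * ndimage.gaussian_filter(
        rng.normal(size=spec.shape), sigma=6))
    precip = np.clip(precip, min(lo, hi) * 0.5, None)

    name_of = landuse.legend
    ndvi = np.empty(spec.shape)
    for code in np.unique(landuse.codes):
        mean = spec.ndvi_class_means.get(name_of[int(code)], 0.2)
        sel = landuse.codes == code
        ndvi[sel] = mean
    ndvi = np.clip(ndvi + rng.normal(scale=spec.ndvi_sd, size=spec.shape), -1.0, 1.0)

    total = 0.6  # red + nir reflectance; NDVI = (nir - red) / total
    nir = total * (1.0 + ndvi) / 2.0
    red = total - nir

    fert = np.zeros(spec.shape)
    for code, name in name_of.items():
        if name in spec.fertilizer_kg_ha:
            sel = landuse.codes == code
            fert[sel] = np.maximum(
                spec.fertilizer_kg_ha[name] + rng.normal(scale=30.0, size=int(sel.sum())), 0.0)

    no = np.zeros(spec.shape, dtype=bool)
    cs = spec.cell_size
    return {
        "precip": Grid(precip, no.copy(), cs),
        "ndvi": Grid(ndvi, no.copy(), cs),
        "red": Grid(red, no.copy(), cs),
        "nir": Grid(nir, no.copy(), cs),
        "fertilizer": Grid(fert, no.copy(), cs),
        "soil": synth_soil(spec),
        "soil_moisture": _synth_soil_moisture(spec),
    }


def standard_farmland_fixture() -> dict[str, object]:
    """The reference plot every coefficient table is anchored to: one
    cultivated-land HRU on a flat plain, loam soil, moderate moisture,
    600 mm precipitation, 450 kg/ha fertilizer, at the water's edge
    (distance 0).  Its raw weight under any valid table is exactly 1.
    """
    from .hydro import HRU

    hru = HRU(id=1, subbasin_id=1, landuse_code=3, soil_code=2,
              cells=[(0, 0), (0, 1), (1, 0), (1, 1)], cell_size=30.0)
    stack_row = {
        "hru_id": 1,
        "subbasin_id": 1,
        "landuse_class": "cultivated",
        "soil_texture_class": "loam",
        "soil_moisture_class": "moderate",
        "area_ha": hru.area_ha,
        "slope_deg": 0.0,
        "precip_mm": 600.0,
        "distance_m": 0.0,
        "ndvi": 0.35,
        "fertilizer_kg_ha": 450.0,
    }
    return {"hru": hru, "stack_row": stack_row}
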