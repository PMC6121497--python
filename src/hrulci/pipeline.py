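"""End-to-end runner: layers -> HRUs -> factors -> index tables.

``run_scenario`` executes the whole chain on a synthetic basin and is the
programmatic equivalent of running the CLI steps in sequence; ``run_basin``
does the same from user-supplied layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import factors as fmod
from . import hydro, index, synthetic
from .factors import CoefficientTable, build_factor_stack, default_coefficient_table
from .grids import CategoricalGrid, Grid, assert_aligned, euclidean_distance_to

__all__ = ["BasinResult", "run_basin", "run_scenario"]

#: default stream-extraction threshold as a fraction of the basin cell count
DEFAULT_STREAM_FRACTION = 0.02
#: default minimum HRU size in cells before merging
DEFAULT_MIN_HRU_CELLS = 5


@dataclass
class BasinResult:
    """Everything the pipeline produced for one basin."""

    layers: dict[str, Grid | CategoricalGrid]
    flow: hydro.FlowField
    accumulation: Grid
    streams: np.ndarray
    subbasins: hydro.SubbasinMap
    hrus: list[hydro.HRU]
    factor_stack: pd.DataFrame
    table: CoefficientTable
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def subbasin_scores(self, pollutant: str | None = None) -> pd.DataFrame:
        return index.subbasin_index(self.records, pollutant)

    def per_area_by_landuse(self, pollutant: str = "TN") -> pd.Series:
        """Mean per-unit-area index (standard-farmland multiples) by land use."""
        df = self.records[self.records["pollutant"] == pollutant]
        return df.groupby("landuse_class")["per_area_index"].mean()


def run_basin(dem: Grid, landuse: CategoricalGrid, soil: CategoricalGrid,
              precip: Grid, red: Grid | None = None, nir: Grid | None = None,
              ndvi: Grid | None = None, fertilizer: Grid | None = None,
              soil_moisture: CategoricalGrid | None = None,
              table: CoefficientTable | None = None,
              stream_threshold: float | None = None,
              min_hru_cells: int = DEFAULT_MIN_HRU_CELLS,
              pollutants: tuple[str, ...] = ("TN", "TP", "COD")) -> BasinResult:
    """Run delineation, factor classification and the index on real layers.

    NDVI may be given directly or as red/NIR bands.  The water mask for the
    effective distance combines extracted stream cells with water-class
    land-use cells.  ``stream_threshold`` is in cells (default 2% of the
    grid).
    """
    if ndvi is None:
        if red is None or nir is None:
            raise ValueError("provide either ndvi or red + nir")
        ndvi = fmod.compute_ndvi(red, nir)
    if fertilizer is None:
        fertilizer = Grid(np.zeros(dem.shape), np.zeros(dem.shape, bool), dem.cell_size, dem.origin)
    layers: dict[str, Grid | CategoricalGrid] = {
        "dem": dem, "landuse": landuse, "soil": soil, "precip": precip,
        "ndvi": ndvi, "fertilizer": fertilizer,
    }
    if soil_moisture is not None:
        layers["soil_moisture"] = soil_moisture
    assert_aligned(list(layers.values()), names=list(layers))

    filled = hydro.fill_sinks(dem)
    flow = hydro.d8_flow_direction(filled)
    acc = hydro.flow_accumulation(flow)
    if stream_threshold is None:
        stream_threshold = max(2.0, DEFAULT_STREAM_FRACTION * dem.shape[0] * dem.shape[1])
    streams = hydro.extract_streams(acc, stream_threshold)
    subbasins = hydro.delineate_subbasins(flow, streams)
    hrus = hydro.build_hrus(subbasins, landuse, soil)
    hrus = hydro.merge_small_hrus(hrus, min_hru_cells * dem.cell_size ** 2, shape=dem.shape)

    water_codes = [c for c, n in landuse.legend.items() if n == "water"]
    water_mask = streams.copy()
    for c in water_codes:
        water_mask |= (landuse.codes == c) & ~landuse.nodata_mask
    distance = euclidean_distance_to(water_mask, dem.cell_size, dem.origin)
    slope = fmod.compute_slope(dem)
    layers.update({"slope": slope, "distance": distance, "filled_dem": filled})

    rasters = {"slope": slope, "precip": precip, "ndvi": ndvi,
               "distance": distance, "fertilizer": fertilizer}
    stack = build_factor_stack(hrus, rasters, landuse, soil, soil_moisture)
    if table is None:
        table = default_coefficient_table()
    records = index.hrulci_table(hrus, stack, table, pollutants)
    return BasinResult(layers, flow, acc, streams, subbasins, hrus, stack, table, records)


def run_scenario(spec: synthetic.ScenarioSpec | None = None,
                 table: CoefficientTable | None = None,
                 **kwargs) -> BasinResult:
    """Generate a synthetic basin from ``spec`` and run the full pipeline."""
    if spec is None:
        spec = synthetic.ScenarioSpec()
    dem = synthetic.synth_dem(spec)
    landuse = synthetic.synth_landuse(spec)
    surfaces = synthetic.synth_factor_surfaces(spec, landuse)
    return run_basin(
        dem, landuse, surfaces["soil"], surfaces["precip"],
        ndvi=surfaces["ndvi"], fertilizer=surfaces["fertilizer"],
        soil_moisture=surfaces["soil_moisture"], table=table, **kwargs)
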