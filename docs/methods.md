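# Methods

## The index

The analysis unit is the hydrological response unit (HRU): a contiguous
group of cells inside one sub-basin sharing a single land-use class and a
single soil class. Working on HRUs instead of fixed grid cells keeps each
unit internally homogeneous in exactly the properties that drive pollutant
export, and sidesteps the arbitrary-scale problem of grid-based contrast
indices.

Per HRU *i* and pollutant (TN, TP or COD) the location-weighted landscape
contrast index is `HRULCI_i = W_i × A_i` with `A_i` the area in hectares
and `W_i` a generation/inhibition weight. The weight is composed from
eight per-factor correction coefficients, each obtained by classing the
HRU's factor value in a coefficient table:

* **Composition.** `W = L·P·R·D·N·S·F·A` (multiplicative). The product is
  the standard export-coefficient correction scheme: coefficients are
  independent multipliers on a baseline export, the baseline plot gets
  exactly 1, and a zero coefficient (distance beyond the cap) annihilates
  the weight, as it should. An additive composition (mean of the eight) is
  available via `composition: additive` in the config for sensitivity
  analysis.
* **Anchor.** The baseline is the Chinese standard-farmland plot: plain
  (slope < 25°), wheat cropland, loam, 375–525 kg/ha/yr fertilizer,
  400–800 mm precipitation, at the water's edge. Each factor's class
  containing this plot is required (and validated) to carry coefficient
  exactly 1, so raw weights are multiples of the standard-farmland export.
* **Normalisation.** For mapping, weights are divided by the basin maximum
  per pollutant (global normalisation; max weight 1, ordering preserved).
  Per-land-use-class normalisation would also be defensible; global was
  chosen because sub-basin scores should be comparable across the whole
  basin. Since normalisation rescales all HRUs alike, the threshold-of-1
  interpretation lives in a separate `per_area_index` column holding the
  raw (baseline-relative) weight.
* **Aggregation.** Pollutant indices of an HRU add; sub-basin scores are
  sums over member HRUs (checked to 1e-9 relative in the tests).

### Factor details and defaults

The shipped coefficient table (`data/default_coefficients.yaml`) encodes
the ordinal structure the science dictates — cultivated ≥ orchard ≥ other
≥ forest for L; steeper, wetter, more-fertilized, wetter-soil classes ≥ 1;
denser vegetation ≤ 1 — with stand-in magnitudes meant to be replaced by
locally calibrated values. Classing conventions:

* Intervals are lower-closed, upper-open `[min, max)`; the table is
  validated to be covering and non-overlapping per factor, with exactly
  one baseline class of coefficient 1.
* **D** is not classed: it decays linearly from 1 at distance 0 to exactly
  0 at a 20 km cap (the farthest distance at which NPS pollutants affect
  the water body) and stays 0 beyond. Distance is center-to-center
  Euclidean to the nearest water cell (stream network ∪ water land use);
  flow-path distance would be a natural extension.
* **N** (NDVI) is classed stepwise like the other factors rather than as a
  continuous ramp: a classed factor can carry the validated baseline
  class (coefficient exactly 1 for cropland-level NDVI ≈ 0.15–0.45),
  which a ramp anchored at NDVI ≤ 0 cannot, and the anchor property —
  standard farmland has raw weight exactly 1 — is worth more here than a
  smooth response. Coefficients are non-increasing in NDVI, so denser
  vegetation never increases a weight.
* **F** (fertilizer) classes are stored in kg/ha/yr with bounds 375 and
  525 — the standard-farmland band; per-mu bounds of 25 and 35 kg are the
  same band in the customary Chinese unit (1 mu = 1/15 ha).
* Slope is the Horn 3×3 finite-difference estimator in degrees with
  edge-replicated borders; continuous factors are averaged over the HRU's
  cells before classing (equal-area cells, so the plain mean); soil
  moisture, a classed raster, enters by majority vote over the HRU.

## HRU delineation

Standard single-flow-direction workflow: priority-flood depression filling
(minimal raise, no epsilon — every cell ends at `max(z, spill)`), D8
steepest-descent directions with drop/distance slopes (diagonal distance
√2·cell) and a fixed E, SE, S, SW, W, NW, N, NE tie-break, flats drained by
breadth-first growth from their spill cells, flow accumulation in
topological order, stream extraction by an accumulation threshold, and
sub-basins as the catchments of stream segments split at junctions. D8 was
chosen as the default of the GIS hydrology toolchains this mirrors;
multi-direction routing is out of scope.

HRUs are the connected components (8-connected by default) of the
(sub-basin, land use, soil) overlay. Contiguity — rather than SWAT-style
scattered same-code unions — is required because the distance factor is
evaluated per HRU and only makes sense for a spatially coherent unit.
HRUs below a minimum area (default 5 cells; 1 ha at 30 m resolution is a
typical field-scale choice) are merged into the same-sub-basin neighbour
sharing the longest rook boundary (ties: larger area, then lower id),
iterating until none remain; absorbed cells adopt the absorber's land-use
and soil codes so the single-code property survives, which means post-merge
HRU codes may disagree with the underlying rasters on absorbed cells — a
deliberate trade of raster fidelity for unit homogeneity. A sub-threshold
HRU that fills its whole sub-basin has no absorber and is left in place.

## Landscape metrics

Eight patch-mosaic metrics: NP, PD (per 100 ha), LPI, LSI, AWMSI, ENN_MN,
IJI and AI. Conventions: patches 8-connected (configurable), cell
adjacency for AI/IJI by the rook rule, grid border neutral (counts toward
patch perimeter, excluded from the inter-class edge totals of LSI and
IJI). LSI uses the equal-area-circle normalisation `E / (2√(πA))`; AWMSI
uses the raster square normalisation `0.25p/√a` so a square patch scores
exactly 1; ENN is the center-to-center distance between cell sets of
distinct same-class patches, classes with a single patch excluded; IJI is
computed at landscape level over class-pair edge lengths and is undefined
below three classes; AI uses the largest-integer-square packing bound for
`max_g_ii`, a single-cell class counting as fully aggregated. All eight
are verified cell-for-cell against brute-force enumerations on random
rasters in the test suite.

## Synthetic basin

The generator emulates a small, intensively farmed coastal basin so the
full chain runs and is tested without external data. All layers derive
from one seeded `numpy` Generator (independent streams per layer); the
same `ScenarioSpec` + seed reproduces every layer bit for bit.

* **DEM** — inclined plane (relief 80 m over 64 rows, default) toward the
  south border plus Gaussian-smoothed bumps (`roughness` × relief); the
  tilt guarantees a border outlet.
* **Land use** — Gaussian-smoothed uniform noise cut at quantiles into the
  six classes with fixed shares (forest 45 %, cultivated 25 %, orchard and
  residential 10 % each, water and unused 5 % each); `patch_clustering`
  maps smoothing radius, 0 giving i.i.d. cells and 1 a few large patches.
  Soil texture (sandy/loam/clay, loam-dominant) and soil moisture
  (low/moderate/high, moderate-dominant) are drawn the same way.
* **Climate and management** — precipitation as a smooth west–east
  gradient over 500–900 mm/yr; NDVI per land-use class (means: forest
  0.80, orchard 0.55, cultivated 0.35, unused 0.20, residential 0.10,
  water −0.10; sd 0.05, clipped to [−1, 1]) with red/NIR bands constructed
  at a fixed total reflectance of 0.6 so recomputing NDVI from the bands
  reproduces the map exactly; fertilizer 600 kg/ha/yr on cultivated land
  (above the standard band, as is typical of intensive coastal
  agriculture), 450 on orchards, zero elsewhere.

What the generator does **not** emulate: realistic drainage-network
geometry (no carved valleys), spatial autocorrelation between soil and
terrain, mixed pixels and classification error, seasonal NDVI, or any
radiative-transfer realism in the bands. Passing tests therefore
demonstrate the algebra, conservation properties and orderings of the
method — not predictive skill on real basins, which would require
calibrated coefficients and real layers.

## Numerical choices and degenerate inputs

* Default problem sizes: 64×64 cells for end-to-end runs and 20-basin
  sweeps, ≤ 20×20 for brute-force oracle comparisons; these keep the whole
  suite and the acceptance script in the tens of seconds while being large
  enough to produce ~30 sub-basins and ~175 HRUs.
* Stream threshold defaults to 2 % of the cell count (≥ 2 cells); the
  right value is basin-specific and both the CLI and API expose it.
* Nodata: −9999 on continuous writes; code 0 reserved for categorical
  nodata. All-nodata inputs raise; cells draining off-grid without
  touching a stream join the nearest labelled segment so sub-basins stay a
  partition.
* Raster I/O is CRS-agnostic: cell size in meters is the only geometry the
  computation uses; GeoTIFF georeferencing tags are written for GIS
  interoperability but never interpreted. Reprojection and resampling are
  out of scope — layers must be co-registered (checked, with tolerances
  1e-6 on cell size and 1e-3 map units on origin).
* Kappa is undefined (returned as NaN) when chance agreement is 1;
  ENN_MN/IJI return NaN when their preconditions (repeated classes, ≥ 3
  classes) fail, and the report propagates the flags.

## Known limitations

Coefficient magnitudes are ordinal stand-ins, not calibrated values; the
index is a relative contrast measure, not a load estimate in kg; D8 cannot
represent divergent flow on ridges; Euclidean effective distance ignores
flow barriers; the per-mu/per-ha reading of the fertilizer classes is an
interpretation (documented above); and merged HRUs intentionally override
the land-use/soil codes of absorbed cells.
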