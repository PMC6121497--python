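"""Raster data model and I/O.

Every layer in the pipeline (DEM, land use, soil, precipitation, NDVI,
distance, slope) is a 2-D grid of square cells with an explicit nodata mask
and a cell size in meters.  The model is deliberately CRS-agnostic: cell size
is the only geometry any of the downstream math needs, so GeoTIFF CRS
metadata is never interpreted (georeferencing tags are written so files stay
usable in GIS software).

Supported on-disk formats are GeoTIFF (via :mod:`tifffile`, using the
standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags) and the ESRI
ASCII grid (plain-text ``ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value`` header).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "CategoricalGrid",
    "GridFormatError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "assert_aligned",
    "euclidean_distance_to",
]

#: nodata fill value used when writing continuous rasters
CONTINUOUS_NODATA = -9999.0
#: code 0 is reserved for nodata in categorical rasters and is illegal as a class
CATEGORICAL_NODATA = 0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridFormatError(ValueError):
    """Raised for malformed raster files or invalid grid contents."""


class AlignmentError(ValueError):
    """Raised when co-registered layers disagree in shape, cell size or origin."""


@dataclass
class Grid:
    """A continuous single-band raster.

    Parameters
    ----------
    values : ndarray of float, shape (rows, cols)
        Cell values.  Values under the nodata mask are ignored by all
        operations.
    nodata_mask : ndarray of bool, same shape
        True where the cell carries no data.
    cell_size : float
        Edge length of a (square) cell in meters.
    origin : (float, float)
        Map coordinates (x, y) of the top-left corner of the top-left cell.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise GridFormatError("grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise GridFormatError(
                f"values shape {self.values.shape} != mask shape {self.nodata_mask.shape}"
            )
        if not self.cell_size > 0:
            raise GridFormatError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        """Area of one cell in m**2."""
        return self.cell_size ** 2

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.nodata_mask)

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.nodata_mask.copy(), self.cell_size, self.origin)


@dataclass
class CategoricalGrid:
    """An integer-coded categorical raster (land use, soil, sub-basin labels).

    Codes are positive integers; 0 is reserved for nodata.  ``legend`` maps
    every code that may appear to a class name.
    """

    codes: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float
    legend: Mapping[int, str] = field(default_factory=dict)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            flt = np.asarray(self.codes, dtype=float)
            if not np.all(np.isfinite(flt[~np.asarray(self.nodata_mask, bool)])) or np.any(
                flt[~np.asarray(self.nodata_mask, bool)] != np.round(flt[~np.asarray(self.nodata_mask, bool)])
            ):
                raise GridFormatError("categorical grid has non-integer cell values")
            self.codes = np.round(flt).astype(np.int64)
        else:
            self.codes = self.codes.astype(np.int64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.codes.ndim != 2:
            raise GridFormatError("grid codes must be 2-D")
        if self.codes.shape != self.nodata_mask.shape:
            raise GridFormatError("codes and nodata_mask shapes differ")
        if not self.cell_size > 0:
            raise GridFormatError(f"cell_size must be positive, got {self.cell_size}")
        if not self.legend:
            present = np.unique(self.codes[~self.nodata_mask])
            self.legend = {int(c): f"class_{int(c)}" for c in present}
        for code in self.legend:
            if not (isinstance(code, (int, np.integer)) and code > 0):
                raise GridFormatError(f"legend codes must be positive integers, got {code!r}")
        present = set(np.unique(self.codes[~self.nodata_mask]).tolist())
        missing = present - set(int(c) for c in self.legend)
        if missing:
            raise GridFormatError(f"codes {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def cell_size_m(self) -> float:
        return self.cell_size

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    # duck-typed alias so alignment checks treat both grid kinds uniformly
    @property
    def values(self) -> np.ndarray:
        return self.codes

    def copy(self) -> "CategoricalGrid":
        return CategoricalGrid(
            self.codes.copy(), self.nodata_mask.copy(), self.cell_size, dict(self.legend), self.origin
        )


AnyGrid = Union[Grid, CategoricalGrid]


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_ascii(path: Path) -> tuple[np.ndarray, float, float, tuple[float, float]]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    nodata = CONTINUOUS_NODATA
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS:
                header[key] = float(parts[1])
            elif not data_lines and key == "nodata_value":
                nodata = float(parts[1])
            else:
                data_lines.append(line)
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise GridFormatError(f"{path}: missing ESRI ASCII header field {key!r}")
    arr = np.loadtxt(data_lines, dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (nrows, ncols):
        raise GridFormatError(f"{path}: data shape {arr.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return arr, nodata, cell, origin


def _write_ascii(path: Path, values: np.ndarray, nodata: float, cell_size: float,
                 origin: tuple[float, float], integer: bool) -> None:
    nrows, ncols = values.shape
    xll = origin[0]
    yll = origin[1] - nrows * cell_size
    fmt = "%d" if integer else "%.10g"
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {cell_size:.10g}\n")
        fh.write(f"NODATA_value {fmt % nodata}\n")
        np.savetxt(fh, values, fmt=fmt)


# ---------------------------------------------------------------------------
# GeoTIFF (tifffile)
# ---------------------------------------------------------------------------

def _read_geotiff(path: Path) -> tuple[np.ndarray, float | None, float, tuple[float, float]]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        if arr.ndim != 2:
            raise GridFormatError(f"{path}: expected a single-band raster")
        tags = page.tags
        cell = 1.0
        origin = (0.0, 0.0)
        nodata: float | None = None
        t = tags.get(_TAG_MODEL_PIXEL_SCALE)
        if t is not None:
            cell = float(t.value[0])
        t = tags.get(_TAG_MODEL_TIEPOINT)
        if t is not None and len(t.value) >= 6:
            origin = (float(t.value[3]), float(t.value[4]))
        t = tags.get(_TAG_GDAL_NODATA)
        if t is not None:
            try:
                nodata = float(str(t.value).strip("\x00 "))
            except ValueError:
                nodata = None
    return np.asarray(arr), nodata, cell, origin


def _write_geotiff(path: Path, values: np.ndarray, nodata: float, cell_size: float,
                   origin: tuple[float, float]) -> None:
    import tifffile

    nodata_str = ("%d" % nodata) if float(nodata).is_integer() else repr(float(nodata))
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(cell_size), float(cell_size), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _looks_like_tiff(path: Path) -> bool:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return True
    if suffix in (".asc", ".txt"):
        return False
    with open(path, "rb") as fh:
        magic = fh.read(4)
    return magic[:2] in (b"II", b"MM")


def read_raster(path: str | Path, kind: str = "continuous",
                legend: Mapping[int, str] | None = None) -> AnyGrid:
    """Read a GeoTIFF or ESRI ASCII raster.

    Parameters
    ----------
    kind : {'continuous', 'categorical'}
        'categorical' returns a :class:`CategoricalGrid` and rejects
        non-integer cell values.
    legend : optional
        Code-to-name mapping for categorical rasters; defaults to
        auto-generated ``class_<code>`` names.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")

    if _looks_like_tiff(path):
        arr, nodata, cell, origin = _read_geotiff(path)
        arr = np.asarray(arr, dtype=float)
        if nodata is None:
            mask = ~np.isfinite(arr)
        else:
            mask = (arr == nodata) | ~np.isfinite(arr)
    else:
        arr, nodata, cell, origin = _read_ascii(path)
        mask = (arr == nodata) | ~np.isfinite(arr)

    if kind == "categorical":
        valid = arr[~mask]
        if valid.size and np.any(valid != np.round(valid)):
            raise GridFormatError(f"{path}: non-integer values under kind='categorical'")
        codes = np.where(mask, CATEGORICAL_NODATA, np.round(arr)).astype(np.int64)
        mask = mask | (codes == CATEGORICAL_NODATA)
        return CategoricalGrid(codes, mask, cell, legend or {}, origin)
    vals = np.where(mask, np.nan, arr)
    return Grid(vals, mask, cell, origin)


def write_raster(grid: AnyGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as GeoTIFF or ESRI ASCII (inferred from extension if
    ``format`` is None).  Continuous nodata is written as -9999, categorical
    nodata as code 0."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii"
    if format not in ("geotiff", "ascii"):
        raise ValueError(f"format must be 'geotiff' or 'ascii', got {format!r}")

    categorical = isinstance(grid, CategoricalGrid)
    if categorical:
        out = np.where(grid.nodata_mask, CATEGORICAL_NODATA, grid.codes).astype(np.int32)
        nodata = float(CATEGORICAL_NODATA)
    else:
        out = np.where(grid.nodata_mask, CONTINUOUS_NODATA, grid.values).astype(np.float64)
        nodata = CONTINUOUS_NODATA

    try:
        if format == "geotiff":
            _write_geotiff(path, out, nodata, grid.cell_size, grid.origin)
        else:
            _write_ascii(path, out, nodata, grid.cell_size, grid.origin, integer=categorical)
    except OSError as exc:
        raise IOError(f"cannot write raster to {path}: {exc}") from exc


def assert_aligned(grids: Sequence[AnyGrid], names: Sequence[str] | None = None) -> None:
    """Check that all layers share shape, cell size and origin.

    Raises :class:`AlignmentError` naming the first offending layer.
    Tolerances: 1e-6 on cell size, 1e-3 map units on origin.
    """
    if len(grids) == 0:
        raise ValueError("assert_aligned needs at least one grid")
    if names is None:
        names = [f"layer {i}" for i in range(len(grids))]
    ref = grids[0]
    for name, g in zip(names[1:], grids[1:]):
        if g.shape != ref.shape:
            raise AlignmentError(f"{name}: shape {g.shape} != {ref.shape} of {names[0]}")
        if not math.isclose(g.cell_size, ref.cell_size, abs_tol=1e-6):
            raise AlignmentError(
                f"{name}: cell_size {g.cell_size} != {ref.cell_size} of {names[0]}"
            )
        if abs(g.origin[0] - ref.origin[0]) > 1e-3 or abs(g.origin[1] - ref.origin[1]) > 1e-3:
            raise AlignmentError(f"{name}: origin {g.origin} != {ref.origin} of {names[0]}")


def euclidean_distance_to(mask: np.ndarray, cell_size: float,
                          origin: tuple[float, float] = (0.0, 0.0)) -> Grid:
    """Center-to-center Euclidean distance (m) to the nearest True cell.

    True cells get distance 0.  Used for the effective-distance factor: the
    distance from each HRU to the nearest water cell.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("distance target mask has no true cell")
    if not cell_size > 0:
        raise ValueError("cell_size must be positive")
    dist = ndimage.distance_transform_edt(~mask, sampling=cell_size)
    return Grid(dist, np.zeros_like(mask, dtype=bool), cell_size, origin)
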