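"""FRAGSTATS-style landscape pattern metrics on categorical rasters.

Implements the eight composition/configuration metrics commonly used to
track fragmentation and aggregation of a source-sink landscape mosaic:

====== =========================================================
NP     number of patches
PD     patch density (patches per 100 ha)
LPI    largest patch index (% of landscape in the largest patch)
LSI    landscape shape index (total edge vs. equal-area circle)
AWMSI  area-weighted mean shape index
ENN_MN mean Euclidean nearest-neighbour distance (m)
IJI    interspersion and juxtaposition index (%)
AI     aggregation index (%), class level and area-weighted landscape level
====== =========================================================

Conventions (configurable where noted): patches are 8-connected by default,
cell adjacency for AI/IJI uses the rook (4-neighbour) rule, and the grid
border is neutral — it contributes to patch perimeters but not to the
inter-class edge totals used by LSI and IJI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import CategoricalGrid

__all__ = [
    "Patch",
    "PatchSet",
    "AdjacencyTable",
    "label_patches",
    "patch_geometry",
    "adjacency_table",
    "np_pd_lpi",
    "lsi",
    "awmsi",
    "enn_mn",
    "iji",
    "ai",
    "metric_report",
    "NOT_AVAILABLE",
]

#: sentinel for metrics that are undefined on the given landscape
NOT_AVAILABLE = float("nan")

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class Patch:
    patch_id: int
    class_code: int
    cells: tuple[tuple[int, int], ...]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class PatchSet:
    """Connected components of a categorical raster.

    ``label_grid`` carries a unique positive patch id per cell (0 = nodata),
    which the geometry routines operate on vectorised.
    """

    patches: list[Patch]
    connectivity: int
    cell_size: float
    label_grid: np.ndarray
    class_of_patch: dict[int, int]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class AdjacencyTable:
    """Shared cell-edge lengths (m) between class pairs, rook adjacency,
    each edge counted once.  Code 0 is the border/nodata pseudo-class."""

    codes: list[int]
    edge_length: np.ndarray  # (k+1, k+1), index 0 = border/nodata

    def pair(self, a: int, b: int) -> float:
        ia = 0 if a == 0 else self.codes.index(a) + 1
        ib = 0 if b == 0 else self.codes.index(b) + 1
        return float(self.edge_length[ia, ib])

    @property
    def total_interclass_edge(self) -> float:
        """Total edge between distinct real classes (border/nodata excluded)."""
        inner = self.edge_length[1:, 1:]
        return float(np.triu(inner, k=1).sum())


def label_patches(grid: CategoricalGrid, connectivity: int = 8) -> PatchSet:
    """Connected-component patches per class; nodata cells belong to none."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    codes = grid.codes
    valid = ~grid.nodata_mask
    label_grid = np.zeros(codes.shape, dtype=np.int64)
    patches: list[Patch] = []
    class_of_patch: dict[int, int] = {}
    next_id = 1
    for code in np.unique(codes[valid]):
        mask = (codes == code) & valid
        lab, n = ndimage.label(mask, structure=struct)
        for j in range(1, n + 1):
            cells_rc = np.argwhere(lab == j)
            pid = next_id
            next_id += 1
            label_grid[lab == j] = pid
            patches.append(Patch(pid, int(code), tuple(map(tuple, cells_rc.tolist()))))
            class_of_patch[pid] = int(code)
    return PatchSet(patches, connectivity, grid.cell_size, label_grid, class_of_patch)


def patch_geometry(patchset: PatchSet) -> pd.DataFrame:
    """Per-patch area (m^2) and perimeter (m).

    Perimeter counts every cell edge adjacent to a different class, to
    nodata, or to the grid border.
    """
    lab = patchset.label_grid
    cs = patchset.cell_size
    padded = np.pad(lab, 1, constant_values=0)
    perim = np.zeros(int(lab.max()) + 1, dtype=np.int64)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nb = padded[1 + dr:padded.shape[0] - 1 + dr, 1 + dc:padded.shape[1] - 1 + dc]
        diff = (core != nb) & (core > 0)
        np.add.at(perim, core[diff], 1)
    rows = [
        {
            "patch_id": p.patch_id,
            "class_code": p.class_code,
            "n_cells": p.n_cells,
            "area_m2": p.n_cells * cs ** 2,
            "perimeter_m": int(perim[p.patch_id]) * cs,
        }
        for p in patchset.patches
    ]
    return pd.DataFrame(rows)


def adjacency_table(grid: CategoricalGrid) -> AdjacencyTable:
    """Rook-adjacency shared-edge lengths between classes, single count.

    Index 0 of the matrix is the border/nodata pseudo-class: edges between a
    real cell and the outside world or a nodata cell.
    """
    codes = np.where(grid.nodata_mask, 0, grid.codes)
    present = sorted(int(c) for c in np.unique(codes) if c != 0)
    k = len(present)
    lut = np.zeros(max(present, default=0) + 1, dtype=np.int64)
    for i, c in enumerate(present):
        lut[c] = i + 1
    idx = lut[np.pad(codes, 1, constant_values=0)]
    mat = np.zeros((k + 1, k + 1), dtype=float)
    # horizontal and vertical neighbour pairs, each unordered pair once
    for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
        keep = ~((a == 0) & (b == 0))
        np.add.at(mat, (a[keep], b[keep]), 1.0)
    sym = mat + mat.T
    np.fill_diagonal(sym, np.diag(mat))
    sym *= grid.cell_size
    return AdjacencyTable(present, sym)


def np_pd_lpi(patchset: PatchSet, landscape_area: float) -> tuple[int, float, float]:
    """NP (count), PD (patches per 100 ha), LPI (%).

    ``landscape_area`` is the total non-nodata area in m^2.
    """
    if not landscape_area > 0:
        raise ValueError("landscape area must be positive")
    n = len(patchset)
    cs2 = patchset.cell_size ** 2
    max_area = max((p.n_cells * cs2 for p in patchset.patches), default=0.0)
    area_ha = landscape_area / 1e4
    pd_val = n / area_ha * 100.0
    lpi = 100.0 * max_area / landscape_area
    return n, pd_val, lpi


def lsi(patchset: PatchSet, landscape_area: float) -> float:
    """Landscape shape index: E / (2 sqrt(pi A)).

    E is the summed patch perimeter with grid-border edges excluded; a
    one-class landscape therefore has LSI = 0.
    """
    if not landscape_area > 0:
        raise ValueError("landscape area must be positive")
    geom = patch_geometry(patchset)
    total_perim = float(geom["perimeter_m"].sum()) if len(geom) else 0.0
    border = _border_edge_length(patchset)
    e = total_perim - border
    return e / (2.0 * math.sqrt(math.pi * landscape_area))


def _border_edge_length(patchset: PatchSet) -> float:
    """Length of patch edges on the outer grid border (not nodata edges)."""
    lab = patchset.label_grid
    cs = patchset.cell_size
    edges = int((lab[0, :] > 0).sum() + (lab[-1, :] > 0).sum()
                + (lab[:, 0] > 0).sum() + (lab[:, -1] > 0).sum())
    return edges * cs


def awmsi(patchset: PatchSet) -> float:
    """Area-weighted mean shape index.

    Per-patch SHAPE = 0.25 p / sqrt(a) with p in cell edges and a in cells
    (raster square normalisation: a square patch scores exactly 1); patches
    weighted by area share.
    """
    if len(patchset) == 0:
        raise ValueError("AWMSI undefined on an empty patch set")
    geom = patch_geometry(patchset)
    cs = patchset.cell_size
    p_edges = geom["perimeter_m"].to_numpy() / cs
    a_cells = geom["n_cells"].to_numpy().astype(float)
    shape = 0.25 * p_edges / np.sqrt(a_cells)
    w = a_cells / a_cells.sum()
    return float((shape * w).sum())


def enn_mn(patchset: PatchSet) -> float:
    """Mean Euclidean nearest-neighbour distance (m), FRAGSTATS style.

    Per patch: the minimum center-to-center distance from any of its cells to
    any cell of a *different* patch of the same class.  Classes with a single
    patch are excluded; returns NaN (not available) when no class has two
    patches.
    """
    cs = patchset.cell_size
    by_class: dict[int, list[Patch]] = {}
    for p in patchset.patches:
        by_class.setdefault(p.class_code, []).append(p)
    dists: list[float] = []
    for code, plist in by_class.items():
        if len(plist) < 2:
            continue
        coords = {p.patch_id: np.array(p.cells, dtype=float) for p in plist}
        for p in plist:
            mine = coords[p.patch_id]
            best = math.inf
            for q in plist:
                if q.patch_id == p.patch_id:
                    continue
                other = coords[q.patch_id]
                d2 = ((mine[:, None, :] - other[None, :, :]) ** 2).sum(-1)
                best = min(best, float(np.sqrt(d2.min())))
            dists.append(best * cs)
    if not dists:
        return NOT_AVAILABLE
    return float(np.mean(dists))


def iji(adjacency: AdjacencyTable) -> float:
    """Interspersion and juxtaposition index (%), landscape level.

    Shannon evenness of inter-class edge lengths over all class pairs,
    normalised by the maximum ln(t(t-1)/2) for t classes; 100 when every
    pair shares equal edge, 0 when a single pair holds all edge.  Undefined
    (NaN) for fewer than 3 classes.
    """
    t = len(adjacency.codes)
    if t < 3:
        return NOT_AVAILABLE
    inner = adjacency.edge_length[1:, 1:]
    iu = np.triu_indices(t, k=1)
    e_pair = inner[iu]
    e_total = e_pair.sum()
    if e_total <= 0:
        return NOT_AVAILABLE
    frac = e_pair[e_pair > 0] / e_total
    h = -(frac * np.log(frac)).sum()
    return float(h / math.log(t * (t - 1) / 2.0) * 100.0)


def _max_like_adjacencies(n_cells: int) -> int:
    """Largest attainable single-count like-adjacency count for ``n`` cells
    (largest-integer-square packing, as used by the aggregation index)."""
    n = int(math.isqrt(n_cells))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def ai(grid: CategoricalGrid) -> tuple[dict[int, float], float]:
    """Aggregation index (%) per class and area-weighted landscape AI.

    AI_i = 100 g_ii / max_g_ii with g_ii the single-count rook
    like-adjacencies of class i; a single-cell class (max_g = 0) counts as
    fully aggregated (100).
    """
    valid = ~grid.nodata_mask
    if not valid.any():
        raise ValueError("AI undefined on an all-nodata grid")
    codes = np.where(valid, grid.codes, 0)
    per_class: dict[int, float] = {}
    areas: dict[int, int] = {}
    for code in np.unique(codes[codes > 0]):
        mask = codes == code
        g = int((mask[:, :-1] & mask[:, 1:]).sum() + (mask[:-1, :] & mask[1:, :]).sum())
        n = int(mask.sum())
        gmax = _max_like_adjacencies(n)
        per_class[int(code)] = 100.0 if gmax == 0 else 100.0 * g / gmax
        areas[int(code)] = n
    total = sum(areas.values())
    landscape = sum(per_class[c] * areas[c] for c in per_class) / total
    return per_class, float(landscape)


def metric_report(grid: CategoricalGrid, connectivity: int = 8) -> pd.DataFrame:
    """All eight metrics in one table.

    Returns a DataFrame with columns ``metric, level, class, value``; class
    is NaN at landscape level, value is NaN where a metric is not available
    (e.g. ENN_MN with no repeated class, IJI with < 3 classes).
    """
    ps = label_patches(grid, connectivity)
    landscape_area = int((~grid.nodata_mask).sum()) * grid.cell_size ** 2
    n, pd_val, lpi_val = np_pd_lpi(ps, landscape_area)
    rows = [
        {"metric": "NP", "level": "landscape", "class": None, "value": float(n)},
        {"metric": "PD", "level": "landscape", "class": None, "value": pd_val},
        {"metric": "LPI", "level": "landscape", "class": None, "value": lpi_val},
        {"metric": "LSI", "level": "landscape", "class": None, "value": lsi(ps, landscape_area)},
        {"metric": "AWMSI", "level": "landscape", "class": None, "value": awmsi(ps)},
        {"metric": "ENN_MN", "level": "landscape", "class": None, "value": enn_mn(ps)},
        {"metric": "IJI", "level": "landscape", "class": None, "value": iji(adjacency_table(grid))},
    ]
    per_class, landscape_ai = ai(grid)
    rows.append({"metric": "AI", "level": "landscape", "class": None, "value": landscape_ai})
    rows.extend(
        {"metric": "AI", "level": "class", "class": c, "value": v} for c, v in sorted(per_class.items())
    )
    return pd.DataFrame(rows)
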