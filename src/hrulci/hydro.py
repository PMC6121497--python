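"""HRU delineation from a DEM: depression filling, D8 routing, stream
extraction, sub-basin delineation and the land-use/soil overlay.

The hydrological response unit (HRU) is the minimum analysis unit of the
index: a contiguous area inside one sub-basin with exactly one land-use
class and one soil class.  The chain is the classic single-flow-direction
workflow:

1. ``fill_sinks`` — priority-flood depression filling (minimal raise);
2. ``d8_flow_direction`` — steepest-descent of the eight neighbours, flats
   drained toward their spill cells;
3. ``flow_accumulation`` — upstream cell counts in topological order;
4. ``extract_streams`` — threshold on accumulation;
5. ``delineate_subbasins`` — stream segments split at junctions, each cell
   labelled by the first segment its flow path reaches;
6. ``build_hrus`` + ``merge_small_hrus`` — overlay of sub-basins, land use
   and soil, with sub-threshold units absorbed by their largest-boundary
   neighbour.

Direction codes follow the neighbour order E, SE, S, SW, W, NW, N, NE
(codes 1..8); ties in steepest descent are broken by that order.  Code 0
marks an outlet, -1 nodata.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import AlignmentError, CategoricalGrid, Grid, assert_aligned

__all__ = [
    "FlowField",
    "SubbasinMap",
    "HRU",
    "OUTLET",
    "NODATA_DIR",
    "D8_OFFSETS",
    "fill_sinks",
    "d8_flow_direction",
    "flow_accumulation",
    "extract_streams",
    "delineate_subbasins",
    "build_hrus",
    "merge_small_hrus",
]

# neighbour order also serves as the deterministic tie-break order
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 1 E
    (1, 1),    # 2 SE
    (1, 0),    # 3 S
    (1, -1),   # 4 SW
    (0, -1),   # 5 W
    (-1, -1),  # 6 NW
    (-1, 0),   # 7 N
    (-1, 1),   # 8 NE
)
_DIST = tuple(np.hypot(dr, dc) for dr, dc in D8_OFFSETS)
OUTLET = 0
NODATA_DIR = -1


@dataclass
class FlowField:
    """Per-cell D8 direction codes (1..8 = E..NE, 0 = outlet, -1 = nodata)."""

    direction: np.ndarray
    cell_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    def receiver(self, r: int, c: int) -> tuple[int, int] | None:
        d = int(self.direction[r, c])
        if d <= 0:
            return None
        dr, dc = D8_OFFSETS[d - 1]
        return r + dr, c + dc

    def receivers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised receiver row/col indices (-1 where none)."""
        d = self.direction
        rr = np.full(d.shape, -1, dtype=np.int64)
        cc = np.full(d.shape, -1, dtype=np.int64)
        rows, cols = np.indices(d.shape)
        for k, (dr, dc) in enumerate(D8_OFFSETS, start=1):
            sel = d == k
            rr[sel] = rows[sel] + dr
            cc[sel] = cols[sel] + dc
        return rr, cc


@dataclass
class SubbasinMap:
    """Sub-basin labels (1..k) partitioning the drainable area."""

    labels: CategoricalGrid
    outlet_cells: dict[int, tuple[int, int]] = field(default_factory=dict)


@dataclass
class HRU:
    """Contiguous unit with a single land-use and a single soil class."""

    id: int
    subbasin_id: int
    landuse_code: int
    soil_code: int
    cells: list[tuple[int, int]]
    cell_size: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area_m2(self) -> float:
        return self.n_cells * self.cell_size ** 2

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 1e4


def _neighbors(r: int, c: int, shape: tuple[int, int]):
    for k, (dr, dc) in enumerate(D8_OFFSETS, start=1):
        rr, cc = r + dr, c + dc
        if 0 <= rr < shape[0] and 0 <= cc < shape[1]:
            yield k, rr, cc


def fill_sinks(dem: Grid) -> Grid:
    """Priority-flood depression filling (minimal raise, no epsilon).

    Floods inward from the border of the valid area; every cell ends at
    ``max(original, spill level)``, so no interior cell remains a strict
    local minimum.  Flats introduced by the fill are drained later by the
    flow-direction step.
    """
    valid = ~dem.nodata_mask
    if not valid.any():
        raise ValueError("cannot fill an all-nodata DEM")
    z = dem.values.copy()
    nrows, ncols = z.shape
    filled = np.where(valid, np.inf, np.nan)
    closed = np.zeros_like(valid)
    heap: list[tuple[float, int, int]] = []
    # seeds: valid cells on the grid border or touching nodata
    on_border = np.zeros_like(valid)
    on_border[0, :] = on_border[-1, :] = on_border[:, 0] = on_border[:, -1] = True
    touches_nodata = ndimage.binary_dilation(
        ~valid, structure=ndimage.generate_binary_structure(2, 2)) & valid
    for r, c in np.argwhere(valid & (on_border | touches_nodata)):
        heapq.heappush(heap, (z[r, c], int(r), int(c)))
        closed[r, c] = True
        filled[r, c] = z[r, c]
    while heap:
        level, r, c = heapq.heappop(heap)
        for _, rr, cc in _neighbors(r, c, (nrows, ncols)):
            if not valid[rr, cc] or closed[rr, cc]:
                continue
            closed[rr, cc] = True
            filled[rr, cc] = max(z[rr, cc], level)
            heapq.heappush(heap, (filled[rr, cc], rr, cc))
    return Grid(np.where(valid, filled, z), dem.nodata_mask.copy(), dem.cell_size, dem.origin)


def d8_flow_direction(filled_dem: Grid) -> FlowField:
    """Steepest-descent D8 directions on a filled DEM.

    Drop is (z_cell - z_neighbour) / distance with diagonal distance
    sqrt(2)*cell; ties pick the first neighbour in E,SE,S,SW,W,NW,N,NE
    order.  Cells with no strictly lower neighbour are either part of a flat
    (resolved by breadth-first growth from the flat's spill cells, so every
    flat cell points toward descending ground) or outlets.
    """
    z = filled_dem.values
    valid = ~filled_dem.nodata_mask
    nrows, ncols = z.shape
    direction = np.full(z.shape, NODATA_DIR, dtype=np.int8)
    unresolved: list[tuple[int, int]] = []
    for r, c in np.argwhere(valid):
        r, c = int(r), int(c)
        best_k, best_slope = 0, 0.0
        for k, rr, cc in _neighbors(r, c, (nrows, ncols)):
            if not valid[rr, cc]:
                continue
            slope = (z[r, c] - z[rr, cc]) / _DIST[k - 1]
            if slope > best_slope:
                best_slope, best_k = slope, k
        if best_k:
            direction[r, c] = best_k
        else:
            unresolved.append((r, c))

    # flats: BFS from flat cells that can step onto an already-resolved cell
    # of equal elevation (the flat's spill side); remaining cells are outlets
    from collections import deque

    queue: deque[tuple[int, int]] = deque()
    pending = set(unresolved)
    for r, c in unresolved:
        for k, rr, cc in _neighbors(r, c, (nrows, ncols)):
            if valid[rr, cc] and direction[rr, cc] > 0 and z[rr, cc] == z[r, c]:
                direction[r, c] = k
                queue.append((r, c))
                break
        else:
            continue
        pending.discard((r, c))
    while queue:
        r, c = queue.popleft()
        for k, rr, cc in _neighbors(r, c, (nrows, ncols)):
            if (rr, cc) in pending and z[rr, cc] == z[r, c]:
                # point the flat neighbour back at the resolved cell
                back = ((k - 1 + 4) % 8) + 1
                direction[rr, cc] = back
                pending.discard((rr, cc))
                queue.append((rr, cc))
    for r, c in pending:
        direction[r, c] = OUTLET
    return FlowField(direction, filled_dem.cell_size)


def flow_accumulation(flow: FlowField) -> Grid:
    """Number of cells draining through each cell, itself included (>= 1).

    Computed by Kahn's algorithm on the receiver graph; a cycle (which the
    fill + flat resolution should make impossible) raises RuntimeError.
    """
    d = flow.direction
    valid = d >= 0
    rr, cc = flow.receivers()
    nrows, ncols = d.shape
    acc = np.where(valid, 1.0, np.nan)
    indeg = np.zeros(d.shape, dtype=np.int64)
    has_rec = rr >= 0
    np.add.at(indeg, (rr[has_rec], cc[has_rec]), 1)
    from collections import deque

    queue = deque(map(tuple, np.argwhere(valid & (indeg == 0)).tolist()))
    processed = 0
    while queue:
        r, c = queue.popleft()
        processed += 1
        if rr[r, c] >= 0:
            tr, tc = rr[r, c], cc[r, c]
            acc[tr, tc] += acc[r, c]
            indeg[tr, tc] -= 1
            if indeg[tr, tc] == 0:
                queue.append((tr, tc))
    if processed != int(valid.sum()):
        raise RuntimeError("cycle detected in flow field")
    return Grid(acc, ~valid, flow.cell_size)


def extract_streams(acc: Grid, threshold: float) -> np.ndarray:
    """Boolean stream mask: accumulation >= threshold (threshold >= 1)."""
    if threshold < 1:
        raise ValueError("stream threshold must be >= 1 cell")
    return (~acc.nodata_mask) & (acc.values >= threshold)


def delineate_subbasins(flow: FlowField, streams: np.ndarray) -> SubbasinMap:
    """Label every drainable cell by the stream segment its flow first reaches.

    The stream network is split at junctions (stream cells receiving flow
    from >= 2 stream cells); a junction cell starts a new downstream
    segment.  Each non-stream cell inherits the label of the first stream
    cell on its flow path; stream cells keep their segment label.  Labels
    partition the drainable area.
    """
    streams = np.asarray(streams, dtype=bool)
    if not streams.any():
        raise ValueError("empty stream mask")
    d = flow.direction
    valid = d >= 0
    rr, cc = flow.receivers()
    # stream inflow counts
    inflow = np.zeros(d.shape, dtype=np.int64)
    sr, sc = np.nonzero(streams)
    for r, c in zip(sr.tolist(), sc.tolist()):
        tr, tc = rr[r, c], cc[r, c]
        if tr >= 0 and streams[tr, tc]:
            inflow[tr, tc] += 1
    labels = np.zeros(d.shape, dtype=np.int64)
    outlet_cells: dict[int, tuple[int, int]] = {}
    next_label = 1
    # segment heads: stream cells with 0 stream inflow; junctions start new ones
    heads = [(int(r), int(c)) for r, c in zip(sr.tolist(), sc.tolist())
             if inflow[r, c] == 0 or inflow[r, c] >= 2]
    for r, c in heads:
        if labels[r, c] != 0:
            continue
        lbl = next_label
        next_label += 1
        cur = (r, c)
        while True:
            labels[cur] = lbl
            outlet_cells[lbl] = cur
            tr, tc = rr[cur], cc[cur]
            if tr < 0 or not streams[tr, tc] or inflow[tr, tc] >= 2 or labels[tr, tc] != 0:
                break
            cur = (int(tr), int(tc))
    # non-stream cells: walk down to the first stream cell, memoised
    for r, c in map(tuple, np.argwhere(valid & ~streams).tolist()):
        path = []
        cur = (r, c)
        while labels[cur] == 0 and not streams[cur]:
            path.append(cur)
            tr, tc = rr[cur], cc[cur]
            if tr < 0:
                break  # drains off-grid before reaching a stream
            cur = (int(tr), int(tc))
        lbl = labels[cur]
        if lbl == 0 and streams[cur]:  # stream cell left unlabelled (shouldn't happen)
            lbl = labels[cur]
        for cell in path:
            labels[cell] = lbl
    # cells draining off-grid without touching a stream join the segment of
    # their outlet's nearest labelled neighbour; label them by nearest stream
    # segment via EDT to keep the partition total
    unlabelled = valid & (labels == 0)
    if unlabelled.any():
        idx = ndimage.distance_transform_edt(labels == 0, return_distances=False,
                                             return_indices=True)
        labels[unlabelled] = labels[idx[0][unlabelled], idx[1][unlabelled]]
    legend = {int(l): f"subbasin_{int(l)}" for l in np.unique(labels[labels > 0])}
    lab_grid = CategoricalGrid(labels, ~valid | (labels == 0), flow.cell_size, legend)
    return SubbasinMap(lab_grid, outlet_cells)


def build_hrus(subbasins: SubbasinMap, landuse: CategoricalGrid,
               soil: CategoricalGrid, connectivity: int = 8) -> list[HRU]:
    """Connected components of the (sub-basin, land use, soil) intersection.

    Every cell carrying all three labels lands in exactly one HRU; each HRU
    has by construction a single land-use and a single soil code.
    """
    try:
        assert_aligned([subbasins.labels, landuse, soil],
                       names=["subbasins", "landuse", "soil"])
    except AlignmentError:
        raise
    sb = subbasins.labels.codes
    lu = landuse.codes
    so = soil.codes
    valid = (~subbasins.labels.nodata_mask) & (~landuse.nodata_mask) & (~soil.nodata_mask)
    # unique triple encoding
    key = np.zeros(sb.shape, dtype=np.int64)
    key[valid] = ((sb[valid].astype(np.int64) * (lu.max() + 1) + lu[valid])
                  * (so.max() + 1) + so[valid]) + 1
    struct = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    hrus: list[HRU] = []
    next_id = 1
    for k in np.unique(key[key > 0]):
        mask = key == k
        lab, n = ndimage.label(mask, structure=struct)
        for j in range(1, n + 1):
            cells = [tuple(x) for x in np.argwhere(lab == j).tolist()]
            r0, c0 = cells[0]
            hrus.append(HRU(next_id, int(sb[r0, c0]), int(lu[r0, c0]), int(so[r0, c0]),
                            cells, landuse.cell_size))
            next_id += 1
    return hrus


def _hru_label_grid(hrus: list[HRU], shape: tuple[int, int]) -> np.ndarray:
    lab = np.zeros(shape, dtype=np.int64)
    for h in hrus:
        for r, c in h.cells:
            lab[r, c] = h.id
    return lab


def merge_small_hrus(hrus: list[HRU], min_area_m2: float,
                     shape: tuple[int, int] | None = None) -> list[HRU]:
    """Iteratively absorb HRUs below ``min_area_m2`` into a neighbour.

    The absorber is the neighbouring HRU *in the same sub-basin* sharing the
    longest rook boundary (ties: larger area, then lower id); absorbed cells
    adopt the absorber's land-use and soil codes so the single-code
    invariant survives.  Total area is conserved.  A sub-threshold HRU that
    has no same-sub-basin neighbour (it fills its whole sub-basin) is left
    in place.
    """
    if not hrus:
        return []
    if not any(h.area_m2 >= min_area_m2 for h in hrus):
        raise ValueError("no HRU reaches the minimum area; nothing can absorb the rest")
    if shape is None:
        nr = max(r for h in hrus for r, _ in h.cells) + 1
        nc = max(c for h in hrus for _, c in h.cells) + 1
        shape = (nr, nc)
    by_id: dict[int, HRU] = {h.id: HRU(h.id, h.subbasin_id, h.landuse_code, h.soil_code,
                                       list(h.cells), h.cell_size) for h in hrus}
    lab = _hru_label_grid(list(by_id.values()), shape)

    def boundary_lengths(h: HRU) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r, c in h.cells:
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr_, cc_ = r + dr, c + dc
                if 0 <= rr_ < shape[0] and 0 <= cc_ < shape[1]:
                    other = int(lab[rr_, cc_])
                    if other != 0 and other != h.id:
                        counts[other] = counts.get(other, 0) + 1
        return counts

    changed = True
    while changed:
        changed = False
        small = sorted((h for h in by_id.values() if h.area_m2 < min_area_m2),
                       key=lambda h: (h.area_m2, h.id))
        for h in small:
            if h.id not in by_id:
                continue
            counts = boundary_lengths(h)
            same_basin = {i: n for i, n in counts.items()
                          if by_id[i].subbasin_id == h.subbasin_id}
            if not same_basin:
                continue
            absorber_id = max(same_basin,
                              key=lambda i: (same_basin[i], by_id[i].area_m2, -i))
            absorber = by_id[absorber_id]
            for r, c in h.cells:
                lab[r, c] = absorber.id
            absorber.cells.extend(h.cells)
            del by_id[h.id]
            changed = True
    return sorted(by_id.values(), key=lambda h: h.id)
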