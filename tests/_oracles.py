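"""Brute-force reference implementations used only by the tests.

Everything here is written for clarity over speed (explicit loops,
all-pairs scans) and stays independent of the library code paths it
verifies.
"""

from __future__ import annotations

import math

import numpy as np

NEIGH4 = ((0, 1), (0, -1), (1, 0), (-1, 0))
NEIGH8 = NEIGH4 + ((1, 1), (1, -1), (-1, 1), (-1, -1))


def bf_label_patches(codes: np.ndarray, valid: np.ndarray, connectivity: int) -> np.ndarray:
    """Flood-fill patch labels (1..k), 0 where nodata."""
    offs = NEIGH4 if connectivity == 4 else NEIGH8
    nr, nc = codes.shape
    labels = np.zeros(codes.shape, dtype=int)
    nxt = 1
    for r0 in range(nr):
        for c0 in range(nc):
            if not valid[r0, c0] or labels[r0, c0]:
                continue
            stack = [(r0, c0)]
            labels[r0, c0] = nxt
            while stack:
                r, c = stack.pop()
                for dr, dc in offs:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nr and 0 <= cc < nc and valid[rr, cc]
                            and not labels[rr, cc] and codes[rr, cc] == codes[r, c]):
                        labels[rr, cc] = nxt
                        stack.append((rr, cc))
            nxt += 1
    return labels


def bf_patch_perimeter(labels: np.ndarray, patch_id: int) -> int:
    """Cell edges of a patch adjacent to another label, nodata or border."""
    nr, nc = labels.shape
    edges = 0
    for r in range(nr):
        for c in range(nc):
            if labels[r, c] != patch_id:
                continue
            for dr, dc in NEIGH4:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc) or labels[rr, cc] != patch_id:
                    edges += 1
    return edges


def bf_like_adjacencies(codes: np.ndarray, valid: np.ndarray, code: int) -> int:
    """Single-count rook adjacencies between same-class cells."""
    nr, nc = codes.shape
    count = 0
    for r in range(nr):
        for c in range(nc):
            if not valid[r, c] or codes[r, c] != code:
                continue
            for dr, dc in ((0, 1), (1, 0)):  # count each pair once
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and valid[rr, cc] and codes[rr, cc] == code:
                    count += 1
    return count


def bf_pair_edges(codes: np.ndarray, valid: np.ndarray, a: int, b: int) -> int:
    """Single-count rook edges between class a and class b (a != b)."""
    nr, nc = codes.shape
    count = 0
    for r in range(nr):
        for c in range(nc):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nr and 0 <= cc < nc):
                    continue
                if not (valid[r, c] and valid[rr, cc]):
                    continue
                pair = {codes[r, c], codes[rr, cc]}
                if pair == {a, b}:
                    count += 1
    return count


def bf_enn_mn(labels: np.ndarray, class_of: dict[int, int], cell_size: float) -> float:
    """All-pairs mean nearest-neighbour distance over patches of repeated classes."""
    cells = {pid: np.argwhere(labels == pid) for pid in class_of}
    by_class: dict[int, list[int]] = {}
    for pid, code in class_of.items():
        by_class.setdefault(code, []).append(pid)
    dists = []
    for code, pids in by_class.items():
        if len(pids) < 2:
            continue
        for p in pids:
            best = math.inf
            for q in pids:
                if q == p:
                    continue
                for ra, ca in cells[p]:
                    for rb, cb in cells[q]:
                        d = math.hypot(ra - rb, ca - cb)
                        best = min(best, d)
            dists.append(best * cell_size)
    return float(np.mean(dists)) if dists else float("nan")


def bf_distance_transform(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs minimum Euclidean distance to a True cell."""
    targets = np.argwhere(mask)
    nr, nc = mask.shape
    out = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            out[r, c] = min(math.hypot(r - tr, c - tc) for tr, tc in targets) * cell_size
    return out


def bf_fill_sinks(dem: np.ndarray) -> np.ndarray:
    """Fixed-point relaxation fill: filled = max(dem, min over neighbour fills),
    border cells pinned to the terrain."""
    nr, nc = dem.shape
    filled = np.full_like(dem, np.inf, dtype=float)
    filled[0, :] = dem[0, :]
    filled[-1, :] = dem[-1, :]
    filled[:, 0] = dem[:, 0]
    filled[:, -1] = dem[:, -1]
    changed = True
    while changed:
        changed = False
        for r in range(nr):
            for c in range(nc):
                lowest = math.inf
                for dr, dc in NEIGH8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        lowest = min(lowest, filled[rr, cc])
                new = max(dem[r, c], lowest)
                if new < filled[r, c]:
                    filled[r, c] = new
                    changed = True
    return filled


def bf_accumulation(direction: np.ndarray, offsets: tuple[tuple[int, int], ...]) -> np.ndarray:
    """Per-cell upstream-set size by following every cell's path downstream."""
    nr, nc = direction.shape
    acc = np.zeros((nr, nc), dtype=float)
    for r0 in range(nr):
        for c0 in range(nc):
            if direction[r0, c0] < 0:
                acc[r0, c0] = np.nan
                continue
            r, c = r0, c0
            seen = set()
            while True:
                acc[r, c] += 1
                d = direction[r, c]
                if d <= 0:
                    break
                assert (r, c) not in seen, "cycle in flow field"
                seen.add((r, c))
                dr, dc = offsets[d - 1]
                r, c = r + dr, c + dc
    return acc
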