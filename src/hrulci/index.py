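"""The location-weighted landscape contrast index (HRULCI) and companions.

Per HRU *i* and pollutant, the index is ``HRULCI_i = W_i * A_i`` with
``W_i`` the normalised generation/inhibition weight and ``A_i`` the HRU
area in hectares.  Indices add across pollutants for a combined value and
sum over the HRUs of a sub-basin for a sub-basin score; higher scores mean
greater spread of non-point source pollution.

Because the extensive index scales with area, the interpretation "above 1
promotes, below 1 inhibits" is carried by a separate per-unit-area column:
the raw multiplicative weight, which is exactly the HRU's export relative
to the standard-farmland baseline (baseline classes all have coefficient
1).

Also here: the source/sink classification of the six land-use classes,
land-use change tabulation between two dates, and overall accuracy / kappa
from a classification confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .factors import CoefficientTable, hru_weight, normalize_weights
from .grids import CategoricalGrid
from .hydro import HRU

__all__ = [
    "HRULCIRecord",
    "SOURCE_CLASSES",
    "SINK_CLASSES",
    "hrulci",
    "hrulci_table",
    "combine_pollutants",
    "subbasin_index",
    "classify_source_sink",
    "landuse_change",
    "accuracy_from_confusion",
]

SOURCE_CLASSES = frozenset({"cultivated", "residential", "orchard"})
SINK_CLASSES = frozenset({"forest", "water", "unused"})


@dataclass(frozen=True)
class HRULCIRecord:
    """Per-HRU, per-pollutant index record.

    ``weight`` is the basin-max-normalised weight in [0, 1]; ``per_area_index``
    is the raw weight relative to the standard-farmland baseline, whose
    threshold of 1 separates promoting from inhibiting units.
    """

    hru_id: int
    pollutant: str
    weight: float
    area_ha: float
    value: float
    per_area_index: float


def hrulci(hru: HRU, normalized_weight: float, pollutant: str,
           per_area_index: float | None = None) -> HRULCIRecord:
    """Index of one HRU: value = normalised weight x area (ha)."""
    if normalized_weight < 0:
        raise ValueError("weight must be non-negative")
    area = hru.area_ha
    if not area > 0:
        raise ValueError("HRU area must be positive")
    return HRULCIRecord(hru.id, pollutant, float(normalized_weight), area,
                        float(normalized_weight) * area,
                        float(per_area_index if per_area_index is not None else normalized_weight))


def hrulci_table(hrus: list[HRU], stack: pd.DataFrame, table: CoefficientTable,
                 pollutants: tuple[str, ...] = ("TN", "TP", "COD")) -> pd.DataFrame:
    """Full index table: raw weights, basin-max normalisation, index values.

    One row per (HRU, pollutant) with columns ``hru_id, subbasin_id,
    landuse_class, pollutant, raw_weight, weight, area_ha, value,
    per_area_index``; normalisation is per pollutant across all HRUs.
    """
    by_id = {h.id: h for h in hrus}
    frames = []
    for pol in pollutants:
        raw = np.array([hru_weight(row, table, pol) for _, row in stack.iterrows()])
        norm = normalize_weights(raw)
        df = pd.DataFrame({
            "hru_id": stack["hru_id"].to_numpy(),
            "subbasin_id": stack["subbasin_id"].to_numpy(),
            "landuse_class": stack["landuse_class"].to_numpy(),
            "pollutant": pol,
            "raw_weight": raw,
            "weight": norm,
            "area_ha": stack["area_ha"].to_numpy(),
        })
        df["value"] = df["weight"] * df["area_ha"]
        df["per_area_index"] = df["raw_weight"]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # consistency with the record-level constructor
    assert all(h in by_id for h in out["hru_id"].unique())
    return out


def combine_pollutants(records: list[HRULCIRecord] | pd.DataFrame) -> float:
    """Combined index of one HRU: the sum over its pollutant records."""
    if isinstance(records, pd.DataFrame):
        ids = records["hru_id"].unique()
        values = records["value"].to_numpy()
    else:
        ids = {r.hru_id for r in records}
        values = np.array([r.value for r in records])
    if len(ids) != 1:
        raise ValueError("combine_pollutants needs records of exactly one HRU")
    return float(values.sum())


def subbasin_index(table: pd.DataFrame, pollutant: str | None = None) -> pd.DataFrame:
    """Sub-basin scores: sum of member HRU index values, ranked descending.

    ``pollutant=None`` sums over all pollutants (combined index).
    """
    df = table if pollutant is None else table[table["pollutant"] == pollutant]
    if df["subbasin_id"].isna().any():
        raise ValueError("record with no sub-basin assignment")
    scores = (df.groupby("subbasin_id", as_index=False)["value"].sum()
                .rename(columns={"value": "score"}))
    scores["rank"] = scores["score"].rank(ascending=False, method="min").astype(int)
    return scores.sort_values("rank", ignore_index=True)


def classify_source_sink(landuse: int | str, legend: dict[int, str] | None = None) -> str:
    """'source' (cultivated, residential, orchard) or 'sink' (forest, water,
    unused) for a land-use class name or coded value."""
    if isinstance(landuse, str):
        name = landuse
    else:
        if legend is None or int(landuse) not in legend:
            raise KeyError(f"land-use code {landuse!r} not in legend")
        name = legend[int(landuse)]
    if name in SOURCE_CLASSES:
        return "source"
    if name in SINK_CLASSES:
        return "sink"
    raise KeyError(f"land-use class {name!r} is not one of the six classes")


def landuse_change(grid_a: CategoricalGrid, grid_b: CategoricalGrid) -> pd.DataFrame:
    """Cross-tabulated transition areas (ha) between two dates.

    Cells nodata on either date are excluded.  The returned matrix has one
    row per date-A class and one column per date-B class; attributes
    ``share_a`` / ``share_b`` on ``df.attrs`` give the class percentage
    composition of each date (summing to 100).
    """
    if set(grid_a.legend.items()) != set(grid_b.legend.items()):
        raise KeyError("legend mismatch between the two dates")
    if grid_a.shape != grid_b.shape or grid_a.cell_size != grid_b.cell_size:
        raise ValueError("grids not aligned")
    both = ~(grid_a.nodata_mask | grid_b.nodata_mask)
    codes = sorted(grid_a.legend)
    names = [grid_a.legend[c] for c in codes]
    k = len(codes)
    pos = {c: i for i, c in enumerate(codes)}
    mat = np.zeros((k, k), dtype=float)
    a = grid_a.codes[both]
    b = grid_b.codes[both]
    for ca, cb in zip(a.tolist(), b.tolist()):
        mat[pos[ca], pos[cb]] += 1
    mat *= grid_a.cell_size ** 2 / 1e4  # ha
    df = pd.DataFrame(mat, index=names, columns=names)
    total = mat.sum()
    df.attrs["share_a"] = pd.Series(mat.sum(axis=1) / total * 100.0, index=names)
    df.attrs["share_b"] = pd.Series(mat.sum(axis=0) / total * 100.0, index=names)
    return df


def accuracy_from_confusion(matrix: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Overall accuracy (%) and Cohen's kappa of a reference x mapped
    confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginals;
    returns NaN kappa when chance agreement p_e = 1 (degenerate marginals).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(m < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    total = m.sum()
    if not total > 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=0) * m.sum(axis=1)).sum()) / total ** 2
    overall = 100.0 * p_o
    if p_e == 1.0:
        return overall, float("nan")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return overall, float(kappa)
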