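"""Cross-realm covariate engineering.

This module implements the step that lets a single SDM see both sides of
the land–sea boundary:

* nearest-other-realm maps (which marine cell is a terrestrial cell's
  "nearest coast cell", and vice versa), with the coastal-zero convention:
  a cell valid in both realms is its own nearest other-realm cell at
  distance zero;
* the two distance-to-coast layers, ``distance_from_sea`` (terrestrial)
  and ``distance_from_land`` (marine);
* "terrestrial with marine" tables: each terrestrial cell carries its
  local values plus the mean and sample standard deviation (suffix
  ``_variation``) of every marine variable over all marine cells within
  the species' mean maximum foraging distance (MMFD) of its nearest coast
  cell;
* "marine with terrestrial" tables: each marine cell inherits the local
  values of its nearest terrestrial cell (prefix ``nearest_``);
* landmass labelling with spherical areas and isolation (distance to the
  nearest strictly larger landmass).

All nearest-cell searches minimise great-circle center-to-center distance
with deterministic (row, col)-lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import MultiRealmConfig
from .errors import ConfigurationError, RealmDomainError
from .grid import (
    EARTH_RADIUS_M,
    MARINE,
    TERRESTRIAL,
    GridCell,
    RealmGrid,
    haversine_m,
    other_realm,
)

#: Model types, named after the four study designs.
TERR_ONLY = "TerrOnly"
MAR_ONLY = "MarOnly"
TERR_WITH_MAR = "TerrWithMar"
MAR_WITH_TERR = "MarWithTerr"
MODEL_TYPES = (TERR_ONLY, MAR_ONLY, TERR_WITH_MAR, MAR_WITH_TERR)

FOCAL_REALM = {
    TERR_ONLY: TERRESTRIAL,
    TERR_WITH_MAR: TERRESTRIAL,
    MAR_ONLY: MARINE,
    MAR_WITH_TERR: MARINE,
}

DISTANCE_FROM_SEA = "distance_from_sea"
DISTANCE_FROM_LAND = "distance_from_land"

# Distance-to-coast layers are local covariates and background filters;
# they are not aggregated/inherited across realms (the inherited copy is
# degenerate: the nearest cell of the other realm sits on the coast where
# the distance is ~0 by construction).
_NO_CROSS_REALM = {DISTANCE_FROM_SEA, DISTANCE_FROM_LAND}


@dataclass
class CrossRealmMap:
    """Per-cell nearest valid cell of the other realm, with distances.

    Arrays are full-grid; cells invalid in the source realm hold -1 /
    NaN.  ``distance_m`` is exactly 0 for cells valid in both realms,
    whose nearest cell is themselves.
    """

    source_realm: str
    nearest_row: np.ndarray  # int, -1 outside source mask
    nearest_col: np.ndarray
    distance_m: np.ndarray   # float, NaN outside source mask

    def nearest_cell(self, cell: GridCell) -> GridCell:
        r = int(self.nearest_row[cell.row, cell.col])
        c = int(self.nearest_col[cell.row, cell.col])
        if r < 0:
            raise RealmDomainError(f"{cell} is not valid in {self.source_realm}")
        return GridCell(r, c)

    def distance(self, cell: GridCell) -> float:
        return float(self.distance_m[cell.row, cell.col])


def _pairwise_min(
    grid: RealmGrid,
    src_rows: np.ndarray,
    src_cols: np.ndarray,
    dst_rows: np.ndarray,
    dst_cols: np.ndarray,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """(argmin index into dst arrays, min distance) per source cell.

    dst cells must already be in row-major order so that np.argmin's
    first-occurrence rule realises the (row, col) lexicographic
    tie-break.
    """
    lats = grid.row_lats()
    lons = grid.col_lons()
    dst_lat = np.radians(lats[dst_rows])
    dst_lon = np.radians(lons[dst_cols])
    cos_dst = np.cos(dst_lat)
    best_idx = np.empty(len(src_rows), dtype=np.int64)
    best_d = np.empty(len(src_rows), dtype=float)
    for start in range(0, len(src_rows), chunk):
        sl = slice(start, start + chunk)
        s_lat = np.radians(lats[src_rows[sl]])[:, None]
        s_lon = np.radians(lons[src_cols[sl]])[:, None]
        a = (
            np.sin((dst_lat[None, :] - s_lat) / 2.0) ** 2
            + np.cos(s_lat) * cos_dst[None, :] * np.sin((dst_lon[None, :] - s_lon) / 2.0) ** 2
        )
        d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
        idx = np.argmin(d, axis=1)
        best_idx[sl] = idx
        best_d[sl] = d[np.arange(d.shape[0]), idx]
    return best_idx, best_d


def nearest_other_realm(grid: RealmGrid, source_realm: str) -> CrossRealmMap:
    """Map every source-realm cell to the nearest valid cell of the other
    realm (great-circle center-to-center distance).

    Cells valid in both realms map to themselves at distance 0.  Raises
    :class:`RealmDomainError` when either realm mask is empty.
    """
    target_realm = other_realm(source_realm)
    src_mask = grid.realm_valid(source_realm)
    dst_mask = grid.realm_valid(target_realm)
    if not src_mask.any():
        raise RealmDomainError(f"{source_realm} realm has no valid cells")
    if not dst_mask.any():
        raise RealmDomainError(f"{target_realm} realm has no valid cells")

    shape = (grid.n_rows, grid.n_cols)
    nearest_row = np.full(shape, -1, dtype=np.int64)
    nearest_col = np.full(shape, -1, dtype=np.int64)
    distance = np.full(shape, np.nan)

    both = src_mask & dst_mask
    br, bc = np.nonzero(both)
    nearest_row[br, bc] = br
    nearest_col[br, bc] = bc
    distance[br, bc] = 0.0

    remaining = src_mask & ~both
    sr, sc = np.nonzero(remaining)
    if len(sr):
        dr, dc = np.nonzero(dst_mask)  # row-major: lexicographic tie-break
        idx, d = _pairwise_min(grid, sr, sc, dr, dc)
        nearest_row[sr, sc] = dr[idx]
        nearest_col[sr, sc] = dc[idx]
        distance[sr, sc] = d
    return CrossRealmMap(source_realm, nearest_row, nearest_col, distance)


def distance_variables(grid: RealmGrid) -> dict[str, CrossRealmMap]:
    """Compute and register ``distance_from_sea`` / ``distance_from_land``.

    Returns the two cross-realm maps (keyed by source realm) so callers
    can reuse the nearest-cell assignments.
    """
    maps = {
        TERRESTRIAL: nearest_other_realm(grid, TERRESTRIAL),
        MARINE: nearest_other_realm(grid, MARINE),
    }
    grid.add_layer(
        DISTANCE_FROM_SEA, TERRESTRIAL, maps[TERRESTRIAL].distance_m,
        valid=grid.terrestrial_valid,
    )
    grid.add_layer(
        DISTANCE_FROM_LAND, MARINE, maps[MARINE].distance_m,
        valid=grid.marine_valid,
    )
    return maps


def ensure_distance_layers(grid: RealmGrid) -> None:
    if DISTANCE_FROM_SEA not in grid.layers or DISTANCE_FROM_LAND not in grid.layers:
        distance_variables(grid)


# -- model-ready covariate tables ---------------------------------------


@dataclass
class AugmentedCovariates:
    """Model-ready per-cell covariate table for one of the four designs.

    ``table`` is indexed by (row, col); ``n_sampled`` records, for
    TerrWithMar, how many marine cells fell inside each row's foraging
    buffer.
    """

    model_type: str
    table: pd.DataFrame
    mmfd_m: float | None = None
    n_sampled: pd.Series | None = None

    @property
    def focal_realm(self) -> str:
        return FOCAL_REALM[self.model_type]

    @property
    def variables(self) -> list[str]:
        return list(self.table.columns)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model_type={self.model_type}\n")
            if self.mmfd_m is not None:
                fh.write(f"# mmfd_m={self.mmfd_m!r}\n")
            self.table.to_csv(fh)


def _cell_index(mask: np.ndarray) -> pd.MultiIndex:
    rows, cols = np.nonzero(mask)
    return pd.MultiIndex.from_arrays([rows, cols], names=["row", "col"])


def local_table(grid: RealmGrid, realm: str) -> pd.DataFrame:
    """Local covariates of one realm at that realm's valid cells."""
    mask = grid.realm_valid(realm)
    if not mask.any():
        raise RealmDomainError(f"{realm} realm has no valid cells")
    idx = _cell_index(mask)
    rows, cols = np.nonzero(mask)
    data = {
        name: layer.values[rows, cols]
        for name, layer in sorted(grid.realm_layers(realm).items())
    }
    return pd.DataFrame(data, index=idx)


def terrestrial_with_marine(
    grid: RealmGrid, config: MultiRealmConfig
) -> AugmentedCovariates:
    """Approach 1: terrestrial cells augmented with foraging-buffer
    statistics of the marine variables.

    For each terrestrial cell, the nearest marine-valid cell is its
    "nearest coast cell"; all marine cells within ``config.mmfd_m`` of
    that coast cell are sampled and each marine variable contributes a
    ``mean_<X>`` and ``<X>_variation`` (sample SD, n-1 denominator; a
    single-cell buffer yields 0) column.  The buffer always contains the
    coast cell itself, so it is never empty.
    """
    mar_layers = {
        n: l for n, l in sorted(grid.realm_layers(MARINE).items()) if n not in _NO_CROSS_REALM
    }
    if not mar_layers:
        raise ConfigurationError("no marine layers to aggregate")
    if config.mmfd_m <= 0:
        raise ConfigurationError("mmfd_m must be positive")
    table = local_table(grid, TERRESTRIAL)
    coast_map = nearest_other_realm(grid, TERRESTRIAL)

    t_rows = table.index.get_level_values("row").to_numpy()
    t_cols = table.index.get_level_values("col").to_numpy()
    coast_r = coast_map.nearest_row[t_rows, t_cols]
    coast_c = coast_map.nearest_col[t_rows, t_cols]

    m_rows, m_cols = np.nonzero(grid.marine_valid)
    lats = grid.row_lats()
    lons = grid.col_lons()
    mar_values = {n: l.values[m_rows, m_cols] for n, l in mar_layers.items()}

    # Many inland cells share a coast cell; compute buffer stats once per
    # unique coast cell.
    coast_keys = coast_r * grid.n_cols + coast_c
    uniq, inverse = np.unique(coast_keys, return_inverse=True)
    n_uniq = len(uniq)
    stats = {
        n: {"mean": np.empty(n_uniq), "sd": np.empty(n_uniq)} for n in mar_layers
    }
    counts = np.empty(n_uniq, dtype=np.int64)
    for k, key in enumerate(uniq):
        cr, cc = divmod(int(key), grid.n_cols)
        d = haversine_m(lons[cc], lats[cr], lons[m_cols], lats[m_rows])
        in_buf = d <= config.mmfd_m
        assert in_buf.any(), "buffer must contain its own coast cell"
        counts[k] = int(in_buf.sum())
        for name in mar_layers:
            vals = mar_values[name][in_buf]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                stats[name]["mean"][k] = np.nan
                stats[name]["sd"][k] = np.nan
            else:
                stats[name]["mean"][k] = vals.mean()
                stats[name]["sd"][k] = vals.std(ddof=1) if len(vals) > 1 else 0.0

    for name in mar_layers:
        table[f"mean_{name}"] = stats[name]["mean"][inverse]
        table[f"{name}_variation"] = stats[name]["sd"][inverse]
    n_sampled = pd.Series(counts[inverse], index=table.index, name="n_sampled")
    return AugmentedCovariates(TERR_WITH_MAR, table, mmfd_m=config.mmfd_m, n_sampled=n_sampled)


def marine_with_terrestrial(
    grid: RealmGrid, config: MultiRealmConfig | None = None
) -> AugmentedCovariates:
    """Approach 2: marine cells inherit their nearest terrestrial cell's
    local values (columns prefixed ``nearest_``).

    Uses the same nearest-cell map as ``distance_from_land``; a cell valid
    in both realms inherits its own terrestrial values.
    """
    terr_layers = {
        n: l for n, l in sorted(grid.realm_layers(TERRESTRIAL).items()) if n not in _NO_CROSS_REALM
    }
    if not terr_layers:
        raise RealmDomainError("no terrestrial layers to inherit")
    table = local_table(grid, MARINE)
    near = nearest_other_realm(grid, MARINE)
    m_rows = table.index.get_level_values("row").to_numpy()
    m_cols = table.index.get_level_values("col").to_numpy()
    nr = near.nearest_row[m_rows, m_cols]
    nc = near.nearest_col[m_rows, m_cols]
    for name, layer in terr_layers.items():
        table[f"nearest_{name}"] = layer.values[nr, nc]
    return AugmentedCovariates(MAR_WITH_TERR, table)


def build_covariates(
    grid: RealmGrid, model_type: str, config: MultiRealmConfig
) -> AugmentedCovariates:
    """Build the model-ready table for any of the four study designs."""
    ensure_distance_layers(grid)
    if model_type == TERR_ONLY:
        return AugmentedCovariates(TERR_ONLY, local_table(grid, TERRESTRIAL))
    if model_type == MAR_ONLY:
        return AugmentedCovariates(MAR_ONLY, local_table(grid, MARINE))
    if model_type == TERR_WITH_MAR:
        return terrestrial_with_marine(grid, config)
    if model_type == MAR_WITH_TERR:
        return marine_with_terrestrial(grid, config)
    raise ConfigurationError(f"unknown model type {model_type!r}")


# -- landmasses ----------------------------------------------------------


@dataclass
class LandmassTable:
    """Connected terrestrial components with areas and isolation.

    ``isolation_m`` is the minimum great-circle distance from a landmass
    to any cell of a strictly larger (by km²) landmass; it is missing for
    the largest landmass (and for exact area ties at the top).
    """

    table: pd.DataFrame  # index: label; columns n_cells, area_km2, isolation_m
    labels: np.ndarray   # per-cell landmass label, 0 = not terrestrial


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_landmasses(grid: RealmGrid, connectivity: int = 8) -> LandmassTable:
    """Label connected components of the terrestrial mask and compute each
    landmass's cell count, spherical area (km²) and isolation."""
    if connectivity not in _STRUCTURES:
        raise ConfigurationError("connectivity must be 4 or 8")
    mask = grid.terrestrial_valid
    if not mask.any():
        raise RealmDomainError("terrestrial mask is empty")
    labels, n_labels = ndimage.label(mask, structure=_STRUCTURES[connectivity])

    lats = grid.row_lats()
    lons = grid.col_lons()
    records = []
    cells_by_label: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for lab in range(1, n_labels + 1):
        r, c = np.nonzero(labels == lab)
        cells_by_label[lab] = (r, c)
        area = float(np.sum(grid.cell_area_km2(r)))
        records.append({"label": lab, "n_cells": len(r), "area_km2": area})
    df = pd.DataFrame(records).set_index("label")

    isolation = np.full(n_labels, np.nan)
    areas = df["area_km2"].to_numpy()
    for i, lab in enumerate(df.index):
        larger = [l for j, l in enumerate(df.index) if areas[j] > areas[i]]
        if not larger:
            continue
        r1, c1 = cells_by_label[lab]
        best = np.inf
        for lab2 in larger:
            r2, c2 = cells_by_label[lab2]
            d = haversine_m(
                lons[c1][:, None], lats[r1][:, None], lons[c2][None, :], lats[r2][None, :]
            )
            best = min(best, float(d.min()))
        isolation[i] = best
    df["isolation_m"] = isolation
    return LandmassTable(table=df, labels=labels)
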