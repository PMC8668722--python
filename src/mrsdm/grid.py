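"""Two-realm gridded data model, coordinate conventions and distance kernel.

A :class:`RealmGrid` is a regular lon/lat grid (row 0 is the northernmost
row, column 0 the westernmost; coordinates refer to cell *centers*) holding
named environmental layers, each tagged as ``terrestrial`` or ``marine``
and carrying its own validity mask.  A cell that is valid in both realms is
a *coastal* cell and belongs to both realms simultaneously — this is what
makes the distance-to-the-other-realm variables well defined (they are zero
exactly on the coast).

Distances between cell centers are great-circle (haversine) distances on a
sphere of mean radius 6,371,008.8 m.  At the 5-arc-minute resolutions this
package targets, the spherical approximation is within half a percent of an
ellipsoidal geodesic, which is accurate enough for foraging-radius buffers
while avoiding any dependence on a particular map projection.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, RealmDomainError

TERRESTRIAL = "terrestrial"
MARINE = "marine"
REALMS = (TERRESTRIAL, MARINE)

#: Mean Earth radius in meters (IUGG mean radius R1).
EARTH_RADIUS_M = 6_371_008.8

#: Geographic coordinates are compared to this tolerance (degrees).
COORD_TOL = 1e-9


def other_realm(realm: str) -> str:
    if realm == TERRESTRIAL:
        return MARINE
    if realm == MARINE:
        return TERRESTRIAL
    raise ConfigurationError(f"unknown realm tag: {realm!r}")


@dataclass(frozen=True, order=True)
class GridCell:
    """A 0-based (row, col) cell index; row 0 is the northernmost row."""

    row: int
    col: int


@dataclass
class Layer:
    """One named environmental variable on the grid."""

    realm: str
    values: np.ndarray  # float64, NaN where invalid
    valid: np.ndarray   # bool


class RealmGrid:
    """A two-realm stack of gridded covariates with validity masks.

    Parameters
    ----------
    n_rows, n_cols:
        Grid shape.
    origin_lon, origin_lat:
        Longitude/latitude (degrees) of the *center* of the north-west
        cell, i.e. cell (0, 0).
    cell_size:
        Cell edge in degrees (both axes); the study resolution of
        5 arc-min is ``1/12``.
    terrestrial_valid, marine_valid:
        Optional initial realm masks.  Adding a layer unions its validity
        mask into its realm's mask, so grids built purely from layers need
        not pass masks explicitly.
    """

    def __init__(
        self,
        n_rows: int,
        n_cols: int,
        origin_lon: float,
        origin_lat: float,
        cell_size: float,
        terrestrial_valid: np.ndarray | None = None,
        marine_valid: np.ndarray | None = None,
    ) -> None:
        if n_rows < 1 or n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.origin_lon = float(origin_lon)
        self.origin_lat = float(origin_lat)
        self.cell_size = float(cell_size)
        self.layers: dict[str, Layer] = {}
        self._realm_valid = {
            TERRESTRIAL: self._as_mask(terrestrial_valid),
            MARINE: self._as_mask(marine_valid),
        }

    # -- masks -----------------------------------------------------------

    def _as_mask(self, mask: np.ndarray | None) -> np.ndarray:
        if mask is None:
            return np.zeros((self.n_rows, self.n_cols), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise AlignmentError(
                f"mask shape {mask.shape} != grid shape {(self.n_rows, self.n_cols)}"
            )
        return mask.copy()

    @property
    def terrestrial_valid(self) -> np.ndarray:
        return self._realm_valid[TERRESTRIAL]

    @property
    def marine_valid(self) -> np.ndarray:
        return self._realm_valid[MARINE]

    def realm_valid(self, realm: str) -> np.ndarray:
        other_realm(realm)  # validates the tag
        return self._realm_valid[realm]

    @property
    def coastal(self) -> np.ndarray:
        """Cells valid in both realms."""
        return self.terrestrial_valid & self.marine_valid

    # -- layers ----------------------------------------------------------

    def add_layer(
        self,
        name: str,
        realm: str,
        values: np.ndarray,
        valid: np.ndarray | None = None,
    ) -> None:
        """Register a layer; its validity mask is unioned into the realm mask.

        Validity defaults to the finite entries of ``values``; invalid
        entries are stored as NaN regardless of the input values.
        """
        other_realm(realm)  # validates tag
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows, self.n_cols):
            raise AlignmentError(
                f"layer {name!r} shape {values.shape} != {(self.n_rows, self.n_cols)}"
            )
        if valid is None:
            valid = np.isfinite(values)
        else:
            valid = self._as_mask(valid)
        stored = np.where(valid, values, np.nan)
        self.layers[name] = Layer(realm=realm, values=stored, valid=valid)
        self._realm_valid[realm] |= valid

    def realm_layers(self, realm: str) -> dict[str, Layer]:
        other_realm(realm)
        return {n: l for n, l in self.layers.items() if l.realm == realm}

    # -- coordinates -----------------------------------------------------

    def in_bounds(self, cell: GridCell) -> bool:
        return 0 <= cell.row < self.n_rows and 0 <= cell.col < self.n_cols

    def cell_center(self, cell: GridCell) -> tuple[float, float]:
        """(lon, lat) of a cell's center in degrees."""
        if not self.in_bounds(cell):
            raise IndexError(f"cell {cell} outside {self.n_rows}x{self.n_cols} grid")
        lon = self.origin_lon + cell.col * self.cell_size
        lat = self.origin_lat - cell.row * self.cell_size
        return lon, lat

    def row_lats(self) -> np.ndarray:
        return self.origin_lat - np.arange(self.n_rows) * self.cell_size

    def col_lons(self) -> np.ndarray:
        return self.origin_lon + np.arange(self.n_cols) * self.cell_size

    def cell_from_lonlat(self, lon: float, lat: float) -> GridCell:
        """Snap a lon/lat point to its containing cell."""
        col = int(round((lon - self.origin_lon) / self.cell_size))
        row = int(round((self.origin_lat - lat) / self.cell_size))
        cell = GridCell(row, col)
        if not self.in_bounds(cell):
            raise IndexError(f"point ({lon}, {lat}) falls outside the grid")
        return cell

    def cell_area_km2(self, row: int | np.ndarray) -> np.ndarray | float:
        """Area of cells in a given row, from the spherical quadrilateral
        bounded by the cell's meridians and parallels."""
        lat = self.origin_lat - np.asarray(row, dtype=float) * self.cell_size
        half = self.cell_size / 2.0
        top = np.radians(np.clip(lat + half, -90.0, 90.0))
        bot = np.radians(np.clip(lat - half, -90.0, 90.0))
        dlon = math.radians(self.cell_size)
        r_km = EARTH_RADIUS_M / 1000.0
        return r_km**2 * dlon * (np.sin(top) - np.sin(bot))

    def geo_meta(self) -> dict[str, float]:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin_lon": self.origin_lon,
            "origin_lat": self.origin_lat,
            "cell_size": self.cell_size,
        }

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RealmGrid({self.n_rows}x{self.n_cols}, cell_size={self.cell_size:g}, "
            f"layers={list(self.layers)})"
        )


# -- distance kernel -----------------------------------------------------


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Vectorised great-circle distance in meters (broadcasting inputs).

    Spherical Earth, mean radius ``EARTH_RADIUS_M``.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dphi = lat2 - lat1
    dlmb = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lon, lat) points."""
    for _, lat in (a, b):
        if not -90.0 <= lat <= 90.0:
            raise RealmDomainError(f"latitude {lat} outside [-90, 90]")
    return float(haversine_m(a[0], a[1], b[0], b[1]))


# -- gridded CSV I/O -----------------------------------------------------
#
# One CSV per layer.  Metadata lives in '#' comment headers so a file is
# self-describing; only valid cells are listed and values are written with
# repr() so a write -> load round trip is bit-stable.

_FORMAT_TAG = "mrsdm-grid v1"
_MASK_VARIABLE = "__realm_mask__"


def _format_header(meta: Mapping[str, float], variable: str, realm: str) -> str:
    geo = " ".join(
        f"{k}={meta[k]!r}" for k in ("n_rows", "n_cols", "origin_lon", "origin_lat", "cell_size")
    )
    return (
        f"# {_FORMAT_TAG}\n# {geo}\n# variable={variable} realm={realm}\n"
    )


def _parse_header(path: Path) -> dict[str, str]:
    fields: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if _FORMAT_TAG not in first:
            raise ConfigurationError(f"{path}: not a {_FORMAT_TAG} file")
        for line in fh:
            if not line.startswith("#"):
                break
            for key, val in re.findall(r"(\w+)=(\S+)", line):
                fields[key] = val
    return fields


def save_layer_csv(grid: RealmGrid, name: str, path: str | Path) -> None:
    layer = grid.layers[name]
    _write_cells_csv(grid, name, layer.realm, layer.values, layer.valid, path)


def _write_cells_csv(
    grid: RealmGrid,
    variable: str,
    realm: str,
    values: np.ndarray,
    valid: np.ndarray,
    path: str | Path,
) -> None:
    rows, cols = np.nonzero(valid)
    with open(path, "w") as fh:
        fh.write(_format_header(grid.geo_meta(), variable, realm))
        fh.write("row,col,value\n")
        vals = values[rows, cols]
        for r, c, v in zip(rows.tolist(), cols.tolist(), vals.tolist()):
            fh.write(f"{r},{c},{v!r}\n")


def save_grid(grid: RealmGrid, directory: str | Path) -> list[Path]:
    """Write every layer (plus the two realm-mask files) to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for realm in REALMS:
        mask = grid.realm_valid(realm)
        path = directory / f"_{realm}_mask.csv"
        _write_cells_csv(grid, _MASK_VARIABLE, realm, mask.astype(float), mask, path)
        written.append(path)
    for name in sorted(grid.layers):
        path = directory / f"{name}.csv"
        save_layer_csv(grid, name, path)
        written.append(path)
    return written


def _check_aligned(ref: Mapping[str, float], meta: Mapping[str, str], path: Path) -> None:
    if int(meta["n_rows"]) != ref["n_rows"] or int(meta["n_cols"]) != ref["n_cols"]:
        raise AlignmentError(f"{path}: grid shape differs from first input")
    for key in ("origin_lon", "origin_lat", "cell_size"):
        if abs(float(meta[key]) - ref[key]) > COORD_TOL:
            raise AlignmentError(
                f"{path}: {key}={meta[key]} differs from {ref[key]} by more than {COORD_TOL} deg"
            )


def load_grid(
    paths: Sequence[str | Path],
    realm_tags: Mapping[str, str] | None = None,
) -> RealmGrid:
    """Load aligned gridded-CSV layers into one :class:`RealmGrid`.

    All files must agree on shape, origin and cell size to within 1e-9
    degrees, otherwise an :class:`AlignmentError` is raised.  ``realm_tags``
    may override the realm recorded in a file's header; an unknown tag is a
    :class:`ConfigurationError`.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ConfigurationError("no input files")
    grid: RealmGrid | None = None
    ref: dict[str, float] = {}
    for path in paths:
        meta = _parse_header(path)
        if grid is None:
            ref = {
                "n_rows": int(meta["n_rows"]),
                "n_cols": int(meta["n_cols"]),
                "origin_lon": float(meta["origin_lon"]),
                "origin_lat": float(meta["origin_lat"]),
                "cell_size": float(meta["cell_size"]),
            }
            grid = RealmGrid(**ref)  # type: ignore[arg-type]
        else:
            _check_aligned(ref, meta, path)
        variable = meta["variable"]
        realm = meta["realm"]
        if realm_tags and variable in realm_tags:
            realm = realm_tags[variable]
        if realm not in REALMS:
            raise ConfigurationError(f"{path}: unknown realm tag {realm!r}")
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        values = np.full((grid.n_rows, grid.n_cols), np.nan)
        r = df["row"].to_numpy(dtype=int)
        c = df["col"].to_numpy(dtype=int)
        if len(r) and (r.min() < 0 or r.max() >= grid.n_rows or c.min() < 0 or c.max() >= grid.n_cols):
            raise AlignmentError(f"{path}: cell indices outside declared grid shape")
        values[r, c] = df["value"].to_numpy(dtype=float)
        if variable == _MASK_VARIABLE:
            mask = np.zeros((grid.n_rows, grid.n_cols), dtype=bool)
            mask[r, c] = True
            grid._realm_valid[realm] |= mask
        else:
            grid.add_layer(variable, realm, values)
    assert grid is not None
    return grid


def load_grid_dir(directory: str | Path, realm_tags: Mapping[str, str] | None = None) -> RealmGrid:
    """Load every ``*.csv`` layer file found in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise ConfigurationError(f"no .csv layer files in {directory}")
    return load_grid(paths, realm_tags=realm_tags)


def valid_cells(mask: np.ndarray) -> list[GridCell]:
    """Cells of a boolean mask in row-major (lexicographic) order."""
    rows, cols = np.nonzero(mask)
    return [GridCell(int(r), int(c)) for r, c in zip(rows, cols)]
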