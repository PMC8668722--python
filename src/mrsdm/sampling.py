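"""Presence handling and constrained pseudo-absence generation.

Background eligibility follows the study design for coastal species:

* terrestrial background = terrestrial-valid cells within the coastal
  band (default 20 km) of the sea;
* marine background = marine-valid cells within ``mmfd_m *
  exclusion_factor`` of land — the mean maximum foraging distance is
  treated as a 90th-percentile distance and the exclusion radius as the
  nominal 100th percentile.

Pseudo-absences are uniform draws *without replacement* from the eligible
background excluding occupied (presence) cells; replicate sets are drawn
with independent child seeds, plus one balanced diagnostic set sized to
the presences (prevalence 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import STAGE_PSEUDO_ABSENCE, MultiRealmConfig, stage_seed
from .cross_realm import DISTANCE_FROM_LAND, DISTANCE_FROM_SEA, ensure_distance_layers
from .errors import ConfigurationError, SamplingError
from .grid import MARINE, TERRESTRIAL, GridCell, RealmGrid


@dataclass
class OccurrenceData:
    """Presences plus replicate pseudo-absence sets for one realm."""

    realm: str
    presences: frozenset[GridCell]
    pa_sets: list[frozenset[GridCell]] = field(default_factory=list)
    pa_seeds: list[int] = field(default_factory=list)
    balanced_set: frozenset[GridCell] = frozenset()
    balanced_seed: int | None = None

    def __post_init__(self) -> None:
        for s in [*self.pa_sets, self.balanced_set]:
            overlap = s & self.presences
            if overlap:
                raise SamplingError(
                    f"pseudo-absences coincide with presences: {sorted(overlap)[:5]}"
                )


def terrestrial_background(grid: RealmGrid, config: MultiRealmConfig) -> set[GridCell]:
    """Terrestrial-valid cells within ``coastal_band_m`` of the sea."""
    ensure_distance_layers(grid)
    layer = grid.layers[DISTANCE_FROM_SEA]
    ok = layer.valid & (layer.values <= config.coastal_band_m)
    cells = {GridCell(int(r), int(c)) for r, c in zip(*np.nonzero(ok))}
    if not cells:
        warnings.warn("terrestrial background is empty", stacklevel=2)
    return cells


def marine_background(grid: RealmGrid, config: MultiRealmConfig) -> set[GridCell]:
    """Marine-valid cells within the exclusion radius of land.

    The radius is ``mmfd_m * exclusion_factor`` (default 10/9, mapping the
    90th-percentile MMFD to a nominal 100th-percentile distance).
    """
    ensure_distance_layers(grid)
    radius = config.mmfd_m * config.exclusion_factor
    layer = grid.layers[DISTANCE_FROM_LAND]
    ok = layer.valid & (layer.values <= radius)
    cells = {GridCell(int(r), int(c)) for r, c in zip(*np.nonzero(ok))}
    if not cells:
        warnings.warn("marine background is empty", stacklevel=2)
    return cells


def background_for_realm(grid: RealmGrid, realm: str, config: MultiRealmConfig) -> set[GridCell]:
    if realm == TERRESTRIAL:
        return terrestrial_background(grid, config)
    if realm == MARINE:
        return marine_background(grid, config)
    raise ConfigurationError(f"unknown realm {realm!r}")


def _draw(eligible: list[GridCell], n: int, seed: int) -> frozenset[GridCell]:
    if n > len(eligible):
        raise SamplingError(
            f"requested {n} pseudo-absences but only {len(eligible)} eligible "
            f"background cells remain (shortfall {n - len(eligible)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return frozenset(eligible[i] for i in idx)


def draw_pseudo_absences(
    background: set[GridCell],
    presences: set[GridCell],
    realm: str,
    config: MultiRealmConfig,
) -> OccurrenceData:
    """Draw ``config.n_sets`` replicate pseudo-absence sets of size
    ``config.n_pseudo`` plus the balanced diagnostic set.

    Each set is a uniform sample without replacement from the eligible
    cells (background minus presences); set *i* is reproducible from the
    child seed ``stage_seed(config.seed, STAGE_PSEUDO_ABSENCE, i)``.
    """
    eligible = sorted(background - set(presences))
    if not eligible:
        raise SamplingError("no eligible background cells outside presences")
    pa_sets: list[frozenset[GridCell]] = []
    pa_seeds: list[int] = []
    for i in range(config.n_sets):
        s = stage_seed(config.seed, STAGE_PSEUDO_ABSENCE, i)
        pa_sets.append(_draw(eligible, config.n_pseudo, s))
        pa_seeds.append(s)
    bseed = stage_seed(config.seed, STAGE_PSEUDO_ABSENCE, config.n_sets)
    balanced = _draw(eligible, len(presences), bseed)
    return OccurrenceData(
        realm=realm,
        presences=frozenset(presences),
        pa_sets=pa_sets,
        pa_seeds=pa_seeds,
        balanced_set=balanced,
        balanced_seed=bseed,
    )


# -- presence I/O --------------------------------------------------------


def read_presences_csv(path: str | Path, grid: RealmGrid) -> set[GridCell]:
    """Read presence cells from CSV: either (row, col) or (lon, lat),
    the latter snapped to the containing cell."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "row" in cols and "col" in cols:
        cells = {
            GridCell(int(r), int(c))
            for r, c in zip(df[cols["row"]], df[cols["col"]])
        }
    elif "lon" in cols and "lat" in cols:
        cells = {
            grid.cell_from_lonlat(float(lon), float(lat))
            for lon, lat in zip(df[cols["lon"]], df[cols["lat"]])
        }
    else:
        raise ConfigurationError(f"{path}: need row/col or lon/lat columns")
    for cell in cells:
        if not grid.in_bounds(cell):
            raise ConfigurationError(f"{path}: presence {cell} out of bounds")
    return cells


def write_occurrences_csv(occ: OccurrenceData, path: str | Path) -> None:
    """Serialise presences and pseudo-absence sets with seed metadata."""
    with open(path, "w") as fh:
        fh.write(f"# realm={occ.realm}\n")
        fh.write(f"# pa_seeds={','.join(map(str, occ.pa_seeds))}\n")
        fh.write(f"# balanced_seed={occ.balanced_seed}\n")
        fh.write("kind,set_index,row,col\n")
        for cell in sorted(occ.presences):
            fh.write(f"presence,,{cell.row},{cell.col}\n")
        for i, s in enumerate(occ.pa_sets):
            for cell in sorted(s):
                fh.write(f"pseudo_absence,{i},{cell.row},{cell.col}\n")
        for cell in sorted(occ.balanced_set):
            fh.write(f"balanced,,{cell.row},{cell.col}\n")
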