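"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive nearest-cell maps, buffer statistics,
background filters and landmass isolation by exhaustive scans with their
own tie-break logic, so they share nothing with the package's search
algorithms except the distance kernel (which is itself checked against
closed forms and an external geodesic library).
"""

from __future__ import annotations

import numpy as np

from mrsdm.grid import GridCell, RealmGrid, haversine_m


def random_realm_grid(seed: int, max_side: int = 40, with_layers: bool = True) -> RealmGrid:
    """A random two-realm grid with overlapping (coastal) cells."""
    rng = np.random.default_rng(seed)
    n_rows = int(rng.integers(8, max_side + 1))
    n_cols = int(rng.integers(8, max_side + 1))
    terr = rng.random((n_rows, n_cols)) < 0.45
    mar = rng.random((n_rows, n_cols)) < 0.5
    # guarantee both realms non-empty and at least one coastal cell
    terr[0, 0] = True
    mar[0, 0] = True
    mar[n_rows - 1, n_cols - 1] = True
    grid = RealmGrid(
        n_rows, n_cols,
        origin_lon=float(rng.uniform(-30, 30)),
        origin_lat=float(rng.uniform(40, 70)),
        cell_size=1.0 / 12.0,
        terrestrial_valid=terr,
        marine_valid=mar,
    )
    if with_layers:
        grid.add_layer("t_var", "terrestrial", np.where(terr, rng.normal(size=terr.shape), np.nan))
        grid.add_layer("m_var", "marine", np.where(mar, rng.normal(size=mar.shape), np.nan))
    return grid


def brute_nearest(grid: RealmGrid, source_realm: str):
    """Exhaustive nearest-other-realm scan with explicit lexicographic
    tie-breaking, one source cell at a time."""
    from mrsdm.grid import other_realm

    src = grid.realm_valid(source_realm)
    dst = grid.realm_valid(other_realm(source_realm))
    lats, lons = grid.row_lats(), grid.col_lons()
    # scan targets in an order unrelated to the implementation's
    dr, dc = np.nonzero(dst.T)
    dr, dc = dc.copy(), dr.copy()  # column-major order
    out = {}
    for r, c in zip(*np.nonzero(src)):
        if src[r, c] and dst[r, c]:
            out[GridCell(int(r), int(c))] = (GridCell(int(r), int(c)), 0.0)
            continue
        d = haversine_m(lons[c], lats[r], lons[dc], lats[dr])
        dmin = d.min()
        ties = np.nonzero(d == dmin)[0]
        cands = sorted((int(dr[i]), int(dc[i])) for i in ties)
        out[GridCell(int(r), int(c))] = (GridCell(*cands[0]), float(dmin))
    return out


def brute_buffer_stats(grid: RealmGrid, mmfd_m: float, layer_name: str):
    """Per terrestrial cell: nearest coast cell by exhaustive scan, then
    mean/sample-SD of one marine layer over all marine cells within
    ``mmfd_m`` of that coast cell."""
    nearest = brute_nearest(grid, "terrestrial")
    lats, lons = grid.row_lats(), grid.col_lons()
    mr, mc = np.nonzero(grid.marine_valid)
    vals = grid.layers[layer_name].values[mr, mc]
    out = {}
    for cell, (coast, _) in nearest.items():
        d = haversine_m(lons[coast.col], lats[coast.row], lons[mc], lats[mr])
        sel = vals[d <= mmfd_m]
        sel = sel[np.isfinite(sel)]
        mean = sel.mean() if len(sel) else np.nan
        sd = sel.std(ddof=1) if len(sel) > 1 else (0.0 if len(sel) == 1 else np.nan)
        out[cell] = (int((d <= mmfd_m).sum()), float(mean), float(sd))
    return out


def brute_background(grid: RealmGrid, realm: str, radius_m: float) -> set[GridCell]:
    """Realm cells whose exhaustively-computed distance to the other
    realm is within ``radius_m``."""
    nearest = brute_nearest(grid, realm)
    return {cell for cell, (_, d) in nearest.items() if d <= radius_m}


def brute_isolation(grid: RealmGrid, labels: np.ndarray) -> dict[int, float]:
    """Per landmass: min center-to-center distance to any strictly larger
    (by spherical area) landmass; NaN when none is larger."""
    lats, lons = grid.row_lats(), grid.col_lons()
    ids = [int(l) for l in np.unique(labels) if l != 0]
    cells = {l: np.nonzero(labels == l) for l in ids}
    areas = {l: float(np.sum(grid.cell_area_km2(cells[l][0]))) for l in ids}
    out = {}
    for l in ids:
        larger = [k for k in ids if areas[k] > areas[l]]
        if not larger:
            out[l] = float("nan")
            continue
        r1, c1 = cells[l]
        best = np.inf
        for k in larger:
            r2, c2 = cells[k]
            for i in range(len(r1)):
                d = haversine_m(lons[c1[i]], lats[r1[i]], lons[c2], lats[r2])
                best = min(best, float(d.min()))
        out[l] = best
    return out


def pairwise_auc(predictions, labels) -> float:
    """AUC by exhaustive presence/absence pair comparison (ties = 1/2)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = p[y == 1]
    neg = p[y == 0]
    wins = 0.0
    for a in pos:
        wins += np.sum(a > neg) + 0.5 * np.sum(a == neg)
    return wins / (len(pos) * len(neg))


def make_straight_coast_grid(n_land_rows: int, n_sea_rows: int, n_cols: int = 6,
                             origin_lat: float = 50.0, cell_size: float = 1.0 / 12.0):
    """Land occupies the top rows, sea the bottom rows, and the last land
    row is coastal (valid in both realms)."""
    n_rows = n_land_rows + n_sea_rows
    terr = np.zeros((n_rows, n_cols), dtype=bool)
    mar = np.zeros((n_rows, n_cols), dtype=bool)
    terr[:n_land_rows] = True
    mar[n_land_rows:] = True
    mar[n_land_rows - 1] = True  # coastal fringe
    return RealmGrid(
        n_rows, n_cols, origin_lon=0.0, origin_lat=origin_lat,
        cell_size=cell_size, terrestrial_valid=terr, marine_valid=mar,
    )
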