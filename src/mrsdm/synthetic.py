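"""Synthetic seascapes and virtual species.

Every stage of the pipeline is testable without external data by
generating (i) a random coastline partitioning a grid into terrestrial
and marine realms with a one-cell both-realm coastal fringe, (ii) smooth
Gaussian-random-field environmental layers in each realm, and (iii) a
*virtual species* whose true habitat suitability is an inverse-logit of a
known linear combination of covariates — which may include cross-realm
features such as a marine variable's foraging-buffer mean, so the four
model designs are separable by construction.

Fields are seeded white noise smoothed with a fixed Gaussian kernel and
standardized within their realm, so coefficients of a virtual species are
on a z-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .config import STAGE_SYNTH, stage_seed
from .cross_realm import AugmentedCovariates
from .errors import ConfigurationError, SchemaError
from .grid import MARINE, TERRESTRIAL, GridCell, RealmGrid


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized Gaussian random field: white noise smoothed at
    length-scale ``sigma`` (cells)."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_seascape(
    n_rows: int = 60,
    n_cols: int = 60,
    coastline_complexity: float = 0.5,
    n_terr_vars: int = 2,
    n_mar_vars: int = 2,
    seed: int = 0,
    field_sigma: float = 4.0,
    origin_lon: float = -10.0,
    origin_lat: float = 58.0,
    cell_size: float = 1.0 / 12.0,
) -> RealmGrid:
    """Generate a two-realm world with smooth environmental fields.

    A smooth "elevation" field thresholded at its median splits the grid
    roughly in half into land and sea; land cells bordering the sea
    (8-neighbourhood) form the coastal fringe and are valid in *both*
    realms.  ``coastline_complexity`` in (0, 1] shortens the elevation
    length-scale (1 = most convoluted coastline);  environmental layers
    (``terr_0..``, ``mar_0..``) are independent fields at length-scale
    ``field_sigma`` cells, standardized within their realm's mask.
    Deterministic given ``seed``.
    """
    if n_rows < 8 or n_cols < 8:
        raise ConfigurationError("seascape needs at least an 8x8 grid")
    if not 0 < coastline_complexity <= 1:
        raise ConfigurationError("coastline_complexity must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_SYNTH]))
    coast_sigma = max(2.0, 0.25 * min(n_rows, n_cols) / (1.0 + 4.0 * coastline_complexity))
    elevation = _smooth_field(rng, (n_rows, n_cols), coast_sigma)
    land = elevation >= np.median(elevation)
    sea = ~land
    fringe = land & ndimage.binary_dilation(sea, structure=np.ones((3, 3), dtype=bool))
    terr_mask = land
    mar_mask = sea | fringe  # coastal fringe is valid in both realms

    grid = RealmGrid(
        n_rows, n_cols, origin_lon=origin_lon, origin_lat=origin_lat, cell_size=cell_size,
        terrestrial_valid=terr_mask, marine_valid=mar_mask,
    )
    for i in range(n_terr_vars):
        f = _smooth_field(rng, (n_rows, n_cols), field_sigma)
        vals = np.where(terr_mask, f, np.nan)
        m = np.nanmean(vals)
        s = np.nanstd(vals)
        grid.add_layer(f"terr_{i}", TERRESTRIAL, (vals - m) / s, valid=terr_mask)
    for i in range(n_mar_vars):
        f = _smooth_field(rng, (n_rows, n_cols), field_sigma)
        vals = np.where(mar_mask, f, np.nan)
        m = np.nanmean(vals)
        s = np.nanstd(vals)
        grid.add_layer(f"mar_{i}", MARINE, (vals - m) / s, valid=mar_mask)
    return grid


@dataclass
class VirtualSpecies:
    """A species with a known generative suitability function.

    ``coefficients`` maps covariate names (local layers or cross-realm
    features such as ``mean_mar_0``) to coefficients on the z-score scale
    of the referenced covariate; suitability is
    ``inverse_logit(intercept + Σ βⱼ zⱼ)``.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0
    realm: str = TERRESTRIAL

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.coefficients.values()):
            raise ConfigurationError("virtual species needs a nonzero coefficient")


def true_suitability(species: VirtualSpecies, covariates: AugmentedCovariates) -> pd.Series:
    """Per-cell true suitability over the focal-realm cells of a
    covariate table.

    Covariates are standardized over the table's complete rows before the
    linear predictor is formed, so coefficients are effect sizes per SD.
    """
    table = covariates.table
    missing = [v for v in species.coefficients if v not in table.columns]
    if missing:
        raise SchemaError(f"covariate table lacks {missing}")
    sub = table[list(species.coefficients)].dropna()
    z = (sub - sub.mean()) / sub.std(ddof=0).replace(0.0, 1.0)
    eta = species.intercept + sum(
        beta * z[name] for name, beta in species.coefficients.items()
    )
    return pd.Series(special.expit(eta), index=sub.index, name="true_suitability")


def sample_occurrences(
    suitability: pd.Series, n_presence_target: int, seed: int
) -> set[GridCell]:
    """Draw presence cells by independent Bernoulli trials.

    Per-cell probabilities are the suitabilities rescaled (and clipped at
    1) so the expected presence count is approximately
    ``n_presence_target``.
    """
    if n_presence_target > len(suitability):
        raise ConfigurationError(
            f"target {n_presence_target} exceeds {len(suitability)} candidate cells"
        )
    total = float(suitability.sum())
    if total == 0:
        return set()
    p = np.clip(suitability.to_numpy() * (n_presence_target / total), 0.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_SYNTH, 1]))
    hits = rng.random(len(p)) < p
    rows = suitability.index.get_level_values("row").to_numpy()[hits]
    cols = suitability.index.get_level_values("col").to_numpy()[hits]
    return {GridCell(int(r), int(c)) for r, c in zip(rows, cols)}
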