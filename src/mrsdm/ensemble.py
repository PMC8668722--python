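"""TSS-gated, TSS-weighted ensemble projection with variance uncertainty.

Models enter the ensemble only when their cross-validated TSS strictly
exceeds the gate (default 0.6, the conventional "substantial" skill
bound).  Member suitability maps are min–max rescaled to a common [0, 1]
scale (rank-preserving), then combined per cell as the TSS-weighted mean;
uncertainty is the unweighted across-member variance.  The
validation-vs-full Spearman check quantifies how similar an ensemble
built from internally validated (70%) models is to the full-data
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, EnsembleError, MetricError


def gate_models(tss_by_model: Mapping, gate: float) -> list:
    """Keys of models whose TSS strictly exceeds the gate.

    Raises :class:`EnsembleError` naming every TSS value when no model
    passes.
    """
    included = [k for k, t in tss_by_model.items() if t > gate]
    if not included:
        detail = ", ".join(f"{k}={t:.3f}" for k, t in tss_by_model.items())
        raise EnsembleError(f"no model exceeds the TSS gate {gate}: {detail}")
    return included


def rescale_predictions(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Min–max rescale one member map onto [0, 1] (rank preserving)."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise EnsembleError("cannot rescale a constant suitability map")
    out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


@dataclass
class EnsembleResult:
    """Weighted ensemble map with its members and uncertainty."""

    members: list[tuple[str, float]]         # (member name, TSS weight)
    mean: pd.Series                          # per-cell weighted mean in [0, 1]
    variance: pd.Series                      # per-cell unweighted variance
    spearman_rho: float | None = None        # validation-vs-full agreement


def weighted_ensemble(
    maps: Sequence[pd.Series],
    weights: Sequence[float],
    names: Sequence[str] | None = None,
) -> EnsembleResult:
    """Combine member maps as a per-cell weighted mean.

    ``mean = Σ wᵢ sᵢ / Σ wᵢ``; variance is the unweighted population
    variance of member values per cell (zero wherever members agree, and
    for a singleton ensemble).  All maps must share an identical cell
    index.
    """
    if not maps:
        raise EnsembleError("ensemble needs at least one member map")
    if len(maps) != len(weights):
        raise AlignmentError("one weight per member map required")
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise EnsembleError("ensemble weights must be positive")
    index = maps[0].index
    for m in maps[1:]:
        if not m.index.equals(index):
            raise AlignmentError("member maps cover different cells")
    stack = np.vstack([np.asarray(m, dtype=float) for m in maps])
    mean = (w[:, None] * stack).sum(axis=0) / w.sum()
    variance = stack.var(axis=0, ddof=0)
    if names is None:
        names = [f"member_{i}" for i in range(len(maps))]
    return EnsembleResult(
        members=list(zip(names, w.tolist())),
        mean=pd.Series(mean, index=index, name="mean_suitability"),
        variance=pd.Series(variance, index=index, name="variance"),
    )


def validation_full_agreement(
    ensemble_validation: pd.Series, ensemble_full: pd.Series
) -> float:
    """Spearman rank correlation between two ensemble maps over their
    (identical) cells."""
    a, b = ensemble_validation.align(ensemble_full, join="inner")
    if len(a) < 3:
        raise MetricError("need at least three common cells for Spearman rho")
    return float(stats.spearmanr(a.to_numpy(), b.to_numpy()).statistic)


def write_ensemble_csv(result: EnsembleResult, path) -> None:
    with open(path, "w") as fh:
        roster = "; ".join(f"{n}:w={w!r}" for n, w in result.members)
        fh.write(f"# members={roster}\n")
        if result.spearman_rho is not None:
            fh.write(f"# validation_full_spearman={result.spearman_rho!r}\n")
        df = pd.DataFrame({
            "mean_suitability": result.mean,
            "variance": result.variance,
        })
        df.to_csv(fh)
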