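"""End-to-end orchestration of the four model designs.

``run_approach`` executes the full chain for one design: build the
model-ready covariate table, screen collinearity and enumerate candidate
variable sets, run repeated internal validation for each candidate,
select the strongest set by mean cross-validated TSS, fit full-data
models per (learner, pseudo-absence set), gate on cross-validated TSS,
project and combine the gated members into a TSS-weighted ensemble with
across-member variance, compute the validation-vs-full Spearman
agreement, and (optionally) permutation variable importance.

``run_all`` drives several designs from one configuration and writes CSV
outputs plus a JSON manifest (config snapshot, seeds, input/output
hashes, timings) sufficient to reproduce a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .config import STAGE_FIT, MultiRealmConfig, stage_seed
from .cross_realm import (
    FOCAL_REALM,
    MODEL_TYPES,
    AugmentedCovariates,
    build_covariates,
    ensure_distance_layers,
)
from .ensemble import (
    EnsembleResult,
    gate_models,
    rescale_predictions,
    validation_full_agreement,
    weighted_ensemble,
    write_ensemble_csv,
)
from .errors import ConfigurationError, DataError
from .evaluation import (
    importance_table,
    repeated_validation,
    summarize_validation,
)
from .grid import GridCell, RealmGrid, load_grid_dir
from .modeling import VariableSet, fit_learner, pearson_screen, variable_set_permutations
from .sampling import (
    OccurrenceData,
    background_for_realm,
    draw_pseudo_absences,
    read_presences_csv,
)


@dataclass
class ApproachResult:
    """Everything one model design produces."""

    approach: str
    best_variables: VariableSet
    candidate_sets: list[VariableSet]
    records: pd.DataFrame            # validation records for the best set
    summary: pd.DataFrame            # mean ± SD TSS/ROC per learner
    ensemble: EnsembleResult
    importance: pd.DataFrame | None
    mean_tss: float
    mean_roc: float


def assemble_training_table(
    cov: AugmentedCovariates,
    presences: set[GridCell],
    pa_set: frozenset[GridCell],
    variables: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack presence rows (label 1) over pseudo-absence rows (label 0),
    pulling covariates from the model-ready table."""
    cols = list(variables) if variables is not None else list(cov.table.columns)
    idx_p = pd.MultiIndex.from_tuples(
        sorted((c.row, c.col) for c in presences), names=["row", "col"]
    )
    idx_a = pd.MultiIndex.from_tuples(
        sorted((c.row, c.col) for c in pa_set), names=["row", "col"]
    )
    missing = idx_p.difference(cov.table.index).union(idx_a.difference(cov.table.index))
    if len(missing):
        raise DataError(
            f"{len(missing)} occurrence cells are not valid focal-realm cells"
        )
    Xp = cov.table.loc[idx_p, cols]
    Xa = cov.table.loc[idx_a, cols]
    X = pd.concat([Xp, Xa])
    y = np.concatenate([np.ones(len(Xp), dtype=int), np.zeros(len(Xa), dtype=int)])
    ok = X.notna().all(axis=1).to_numpy()
    return X.loc[ok], y[ok]


def _projection_rows(cov: AugmentedCovariates, variables: Sequence[str]) -> pd.DataFrame:
    return cov.table[list(variables)].dropna()


def run_approach(
    approach: str,
    grid: RealmGrid,
    presences: set[GridCell],
    config: MultiRealmConfig,
    compute_importance: bool = True,
    importance_repeats: int = 10,
) -> ApproachResult:
    """Run one model design end to end (see module docstring)."""
    if approach not in MODEL_TYPES:
        raise ConfigurationError(f"unknown approach {approach!r}; one of {MODEL_TYPES}")
    ensure_distance_layers(grid)
    realm = FOCAL_REALM[approach]
    cov = build_covariates(grid, approach, config)

    background = background_for_realm(grid, realm, config)
    occ = draw_pseudo_absences(background, presences, realm, config)

    pairs = pearson_screen(cov.table, config.collinearity_threshold)
    candidate_sets = variable_set_permutations(cov.variables, pairs)

    # Evaluate every candidate variable set; keep the strongest by mean
    # cross-validated TSS across learners, repeats and pa-sets.
    best = None
    for vs in candidate_sets:
        tables = {
            i: assemble_training_table(cov, presences, pa, vs.variables)
            for i, pa in enumerate(occ.pa_sets)
        }
        records, models = repeated_validation(
            tables, config.learners, config, keep_models=True
        )
        ok = records[records["error"] == ""]
        mean_tss = float(ok["tss"].mean()) if len(ok) else float("-inf")
        if best is None or mean_tss > best[0]:
            best = (mean_tss, vs, records, models, tables)
    assert best is not None
    mean_tss, best_vs, records, val_models, tables = best
    summary = summarize_validation(records)

    # Cross-validated TSS per (learner, pa-set) gates and weighs the
    # full-data models (gating a full model on its own training TSS would
    # be circular).
    ok = records[records["error"] == ""]
    cv_tss = ok.groupby(["learner", "pa_set"])["tss"].mean().to_dict()
    included = gate_models(cv_tss, config.tss_gate)

    proj_rows = _projection_rows(cov, best_vs.variables)
    full_maps, val_maps, weights, names = [], [], [], []
    full_models = []
    for learner, pa_idx in sorted(included):
        X, y = tables[pa_idx]
        seed = stage_seed(config.seed, STAGE_FIT, pa_idx, 999, list(config.learners).index(learner))
        model = fit_learner(learner, X, y, config, seed)
        model.pa_set = pa_idx
        full_models.append(model)
        full_maps.append(rescale_predictions(
            pd.Series(model.predict(proj_rows), index=proj_rows.index)
        ))
        vm = val_models.get((learner, pa_idx, 0))
        if vm is not None:
            val_maps.append(rescale_predictions(
                pd.Series(vm.predict(proj_rows), index=proj_rows.index)
            ))
        weights.append(cv_tss[(learner, pa_idx)])
        names.append(f"{learner}/pa{pa_idx}")

    ens_full = weighted_ensemble(full_maps, weights, names)
    if len(val_maps) == len(full_maps):
        ens_val = weighted_ensemble(val_maps, weights, names)
        ens_full.spearman_rho = validation_full_agreement(ens_val.mean, ens_full.mean)

    importance = None
    if compute_importance:
        importance = importance_table(
            full_models, proj_rows, seed=stage_seed(config.seed, 7), n_repeats=importance_repeats
        )

    return ApproachResult(
        approach=approach,
        best_variables=best_vs,
        candidate_sets=candidate_sets,
        records=records,
        summary=summary,
        ensemble=ens_full,
        importance=importance,
        mean_tss=mean_tss,
        mean_roc=float(ok["roc_auc"].mean()) if len(ok) else float("nan"),
    )


def compare_approaches(results: Mapping[str, "ApproachResult | pd.DataFrame"]) -> pd.DataFrame:
    """Rank approaches by mean validation TSS (SD, then name break ties).

    Accepts :class:`ApproachResult` objects or raw record tables with a
    ``tss`` column.  The best approach is flagged.
    """
    if len(results) < 2:
        raise ConfigurationError("need at least two approaches to compare")
    rows = []
    for name in sorted(results):
        res = results[name]
        rec = res.records if isinstance(res, ApproachResult) else res
        ok = rec[rec["error"] == ""] if "error" in rec.columns else rec
        rows.append({
            "approach": name,
            "tss_mean": float(ok["tss"].mean()),
            "tss_sd": float(ok["tss"].std(ddof=1)),
            "roc_mean": float(ok["roc_auc"].mean()) if "roc_auc" in ok else np.nan,
            "roc_sd": float(ok["roc_auc"].std(ddof=1)) if "roc_auc" in ok else np.nan,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["tss_mean", "tss_sd", "approach"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["best"] = [i == 0 for i in range(len(df))]
    return df


def format_report(comparison: pd.DataFrame) -> str:
    """Tabular mean (SD) TSS/ROC report, one row per approach."""
    lines = [f"{'Approach':<14}{'TSS':>14}{'ROC':>14}"]
    for _, r in comparison.iterrows():
        star = " *" if r["best"] else ""
        lines.append(
            f"{r['approach']:<14}"
            f"{r['tss_mean']:.2f} ({r['tss_sd']:.2f})"
            f"   {r['roc_mean']:.2f} ({r['roc_sd']:.2f}){star}"
        )
    return "\n".join(lines)


# -- file-level driver with manifest ------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(
    grid_dir: str | Path,
    presences_path: str | Path,
    config: MultiRealmConfig,
    out_dir: str | Path,
    approaches: Sequence[str] = MODEL_TYPES,
    compute_importance: bool = True,
) -> dict:
    """Run several designs from files on disk and write outputs + manifest.

    Outputs per approach: ``<approach>_records.csv``,
    ``<approach>_ensemble.csv``, ``<approach>_importance.csv``; plus
    ``comparison.csv`` and ``manifest.json``.  The manifest records the
    config snapshot, package version, input and output SHA-256 hashes and
    per-stage timings, so a rerun can be verified hash-for-hash.
    """
    grid_dir, presences_path, out_dir = Path(grid_dir), Path(presences_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = load_grid_dir(grid_dir)
    presences_all = read_presences_csv(presences_path, grid)

    manifest: dict = {
        "mrsdm_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            str(p.name): _sha256(p) for p in sorted(grid_dir.glob("*.csv"))
        },
        "presences": _sha256(presences_path),
        "approaches": list(approaches),
        "timings_s": {},
        "outputs": {},
    }
    results: dict[str, ApproachResult] = {}
    for approach in approaches:
        t0 = time.perf_counter()
        realm = FOCAL_REALM[approach]
        presences = {
            c for c in presences_all if grid.realm_valid(realm)[c.row, c.col]
        }
        res = run_approach(
            approach, grid, presences, config, compute_importance=compute_importance
        )
        results[approach] = res
        rec_path = out_dir / f"{approach}_records.csv"
        res.records.to_csv(rec_path, index=False)
        ens_path = out_dir / f"{approach}_ensemble.csv"
        write_ensemble_csv(res.ensemble, ens_path)
        written = [rec_path, ens_path]
        if res.importance is not None:
            imp_path = out_dir / f"{approach}_importance.csv"
            res.importance.to_csv(imp_path)
            written.append(imp_path)
        manifest["timings_s"][approach] = round(time.perf_counter() - t0, 3)
        for p in written:
            manifest["outputs"][p.name] = _sha256(p)

    if len(results) >= 2:
        comparison = compare_approaches(results)
        cmp_path = out_dir / "comparison.csv"
        comparison.to_csv(cmp_path, index=False)
        manifest["outputs"][cmp_path.name] = _sha256(cmp_path)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
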