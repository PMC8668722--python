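"""Repeated internal validation and accuracy metrics.

Validation follows the repeated-split design: per pseudo-absence set, the
presence/absence rows are split 70/30 stratified by class, models are
calibrated on the training split and scored on the validation split with
the true skill statistic (TSS = sensitivity + specificity − 1) at the
TSS-maximising threshold, ROC AUC, sensitivity and specificity; the
process repeats ``n_repeats`` times with fresh splits.

Variable importance is permutation-based: a covariate's column is
shuffled, the *fitted* model re-predicts, and importance is 1 − Pearson r
between the reference and permuted predictions, clipped to [0, 1] — so 0
means the model is insensitive to the variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .config import STAGE_FIT, STAGE_PERMUTATION, STAGE_SPLIT, MultiRealmConfig, stage_seed
from .errors import MetricError, SplitError
from .modeling import FittedSDM, fit_learner

#: Threshold grid for TSS optimisation (step 0.001).
THRESHOLD_GRID = np.linspace(0.0, 1.0, 1001)


def split_data(
    labels: np.ndarray | Sequence[int], train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split of row indices.

    Per class, ``round(train_frac * n_class)`` rows go to training; the
    split is a disjoint, exhaustive partition, reproducible from ``seed``.
    """
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_parts, val_parts = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < 2:
            raise SplitError(f"class {cls} has {len(idx)} row(s); need at least 2")
        perm = rng.permutation(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides non-empty
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))
    return train, val


class ThresholdMetrics(NamedTuple):
    threshold: float
    sensitivity: float
    specificity: float
    tss: float


def tss_at_best_threshold(
    predictions: np.ndarray | Sequence[float], labels: np.ndarray | Sequence[int]
) -> ThresholdMetrics:
    """Sensitivity, specificity and TSS at the TSS-maximising threshold.

    Thresholds are scanned on a 0.001 grid over [0, 1]; a row is predicted
    present when its score is >= the threshold.  Ties in TSS resolve to
    the smallest threshold.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise MetricError("TSS undefined: labels contain a single class")
    pos = np.sort(p[y == 1])
    neg = np.sort(p[y == 0])
    # count of scores >= t via searchsorted on the sorted score vectors
    sens = 1.0 - np.searchsorted(pos, THRESHOLD_GRID, side="left") / len(pos)
    spec = np.searchsorted(neg, THRESHOLD_GRID, side="left") / len(neg)
    tss = sens + spec - 1.0
    k = int(np.argmax(tss))  # first occurrence -> smallest threshold
    return ThresholdMetrics(float(THRESHOLD_GRID[k]), float(sens[k]), float(spec[k]), float(tss[k]))


def roc_auc(
    predictions: np.ndarray | Sequence[float], labels: np.ndarray | Sequence[int]
) -> float:
    """Area under the ROC curve (probability a random presence outranks a
    random absence, ties counting one half)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise MetricError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, np.asarray(predictions, dtype=float)))


RECORD_COLUMNS = [
    "learner", "pa_set", "repeat", "threshold",
    "sensitivity", "specificity", "tss", "roc_auc",
    "converged", "error",
]


def repeated_validation(
    tables: Mapping[int, tuple[pd.DataFrame, np.ndarray]],
    learners: Sequence[str],
    config: MultiRealmConfig,
    keep_models: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, int, int], FittedSDM]]:
    """Run the repeated split/calibrate/validate design.

    Parameters
    ----------
    tables:
        Mapping pa-set index -> (covariate rows, binary labels).
    learners:
        Registry names to fit.
    keep_models:
        When true, fitted models are returned keyed by
        (learner, pa_set, repeat) — used to build validation-data
        ensembles without refitting.

    Returns the record table (one row per learner × pa-set × repeat; fit
    or metric failures are recorded in the ``error`` column rather than
    aborting the table) and the optional model dict.
    """
    records: list[dict] = []
    models: dict[tuple[str, int, int], FittedSDM] = {}
    for pa_idx, (X, y) in sorted(tables.items()):
        y = np.asarray(y, dtype=int)
        for rep in range(config.n_repeats):
            split_seed = stage_seed(config.seed, STAGE_SPLIT, pa_idx, rep)
            train, val = split_data(y, config.train_frac, split_seed)
            for li, name in enumerate(learners):
                rec: dict = {"learner": name, "pa_set": pa_idx, "repeat": rep,
                             "threshold": np.nan, "sensitivity": np.nan,
                             "specificity": np.nan, "tss": np.nan,
                             "roc_auc": np.nan, "converged": np.nan, "error": ""}
                try:
                    fit_seed = stage_seed(config.seed, STAGE_FIT, pa_idx, rep, li)
                    model = fit_learner(name, X.iloc[train], y[train], config, fit_seed)
                    model.pa_set, model.repeat = pa_idx, rep
                    pred = model.predict(X.iloc[val])
                    tm = tss_at_best_threshold(pred, y[val])
                    rec.update(
                        threshold=tm.threshold, sensitivity=tm.sensitivity,
                        specificity=tm.specificity, tss=tm.tss,
                        roc_auc=roc_auc(pred, y[val]), converged=model.converged,
                    )
                    if keep_models:
                        models[(name, pa_idx, rep)] = model
                except Exception as exc:  # recorded, not fatal to the table
                    rec["error"] = f"{type(exc).__name__}: {exc}"
                records.append(rec)
    return pd.DataFrame.from_records(records, columns=RECORD_COLUMNS), models


def summarize_validation(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of TSS and ROC per learner, plus an overall row."""
    ok = records[records["error"] == ""]
    rows = []
    for name, grp in ok.groupby("learner"):
        rows.append({
            "learner": name,
            "tss_mean": grp["tss"].mean(), "tss_sd": grp["tss"].std(ddof=1),
            "roc_mean": grp["roc_auc"].mean(), "roc_sd": grp["roc_auc"].std(ddof=1),
            "n_records": len(grp),
        })
    rows.append({
        "learner": "ALL",
        "tss_mean": ok["tss"].mean(), "tss_sd": ok["tss"].std(ddof=1),
        "roc_mean": ok["roc_auc"].mean(), "roc_sd": ok["roc_auc"].std(ddof=1),
        "n_records": len(ok),
    })
    return pd.DataFrame(rows)


@dataclass
class ImportanceResult:
    variable: str
    mean: float
    sd: float
    values: np.ndarray
    defined: bool = True


def permutation_importance(
    model: FittedSDM,
    rows: pd.DataFrame,
    variable: str,
    seed: int,
    n_repeats: int = 10,
) -> ImportanceResult:
    """Permutation importance of one covariate for one fitted model.

    Per repeat, the variable's column is shuffled (seeded), the fitted
    model re-predicts, and importance is ``1 − r`` (Pearson, reference vs
    permuted predictions) clipped to [0, 1].  A model whose reference
    predictions are constant has undefined importance (flagged).
    """
    if variable not in model.variables:
        raise MetricError(f"{variable!r} is not in the model's variable set")
    ref = model.predict(rows)
    if np.ptp(ref) == 0:
        return ImportanceResult(variable, np.nan, np.nan, np.full(n_repeats, np.nan), False)
    vals = np.empty(n_repeats)
    for rep in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), STAGE_PERMUTATION, rep]))
        shuffled = rows.copy()
        shuffled[variable] = rng.permutation(shuffled[variable].to_numpy())
        perm_pred = model.predict(shuffled)
        if np.array_equal(perm_pred, ref):
            # the model provably ignores the variable: r = 1 by definition
            vals[rep] = 0.0
            continue
        if np.ptp(perm_pred) == 0:
            # permutation left predictions constant => no dependence detected
            r = 1.0 if np.allclose(perm_pred, ref) else 0.0
        else:
            r = float(stats.pearsonr(ref, perm_pred).statistic)
        vals[rep] = np.clip(1.0 - r, 0.0, 1.0)
    return ImportanceResult(variable, float(vals.mean()), float(vals.std(ddof=1)), vals)


def importance_table(
    models: Sequence[FittedSDM],
    rows: pd.DataFrame,
    seed: int,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Per-variable importance mean and SD across a set of fitted models."""
    if not models:
        raise MetricError("no models to evaluate importance for")
    variables = models[0].variables
    per_model: dict[str, list[float]] = {v: [] for v in variables}
    for mi, model in enumerate(models):
        for v in model.variables:
            res = permutation_importance(model, rows, v, stage_seed(seed, mi), n_repeats)
            if res.defined:
                per_model[v].append(res.mean)
    out = []
    for v in variables:
        vals = np.array(per_model[v])
        out.append({
            "variable": v,
            "importance_mean": vals.mean() if len(vals) else np.nan,
            "importance_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n_models": len(vals),
        })
    return pd.DataFrame(out).set_index("variable")
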