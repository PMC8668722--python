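"""Collinearity screening, variable-set permutations and base learners.

The learner layer is a small registry keyed by name.  Three learners ship
by default, mirroring common SDM practice:

* ``GLM`` — logistic regression on standardized covariates with linear
  plus quadratic terms (no interactions), unpenalised;
* ``RF`` — random forest, 500 trees;
* ``ANN`` — single-hidden-layer perceptron, hidden size ⌈√p⌉.

Iterative learners attempt ``max_iter`` iterations (default 100) and
escalate once to ``max_iter_escalated`` (default 1000) on
non-convergence; the convergence flag and iteration count are recorded on
the fitted model.  Given identical data and seed, refitting reproduces
identical predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .config import MultiRealmConfig
from .errors import ConfigurationError, DataError, FitError, SchemaError


# -- collinearity --------------------------------------------------------


def pearson_screen(
    table: pd.DataFrame, threshold: float = 0.7
) -> list[tuple[str, str]]:
    """All unordered covariate pairs with |Pearson r| > ``threshold``.

    Computed on complete cases (rows with no missing covariate).
    Constant columns have undefined correlations and are excluded with a
    warning.  Requires at least two numeric covariates and three complete
    rows.
    """
    numeric = table.select_dtypes(include=[np.number])
    complete = numeric.dropna()
    if numeric.shape[1] < 2:
        raise DataError("need at least two numeric covariates to screen")
    if len(complete) < 3:
        raise DataError("need at least three complete rows to screen")
    keep = []
    for col in complete.columns:
        if complete[col].nunique() <= 1:
            warnings.warn(
                f"column {col!r} is constant; excluded from collinearity screening",
                stacklevel=2,
            )
        else:
            keep.append(col)
    corr = complete[keep].corr(method="pearson")
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                pairs.append((a, b))
    return pairs


@dataclass(frozen=True)
class VariableSet:
    """An ordered covariate selection with the members dropped to get it."""

    variables: tuple[str, ...]
    dropped: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.variables)


def _maximal_independent_sets(nodes: list[str], edges: set[frozenset[str]]) -> list[tuple[str, ...]]:
    """Maximal subsets of ``nodes`` containing no edge, by brute force."""
    if len(nodes) > 20:
        raise ConfigurationError(
            f"covarying component of {len(nodes)} variables is too large to enumerate"
        )
    independent: list[frozenset[str]] = []
    for bits in range(1 << len(nodes)):
        subset = frozenset(n for i, n in enumerate(nodes) if bits >> i & 1)
        if all(not e <= subset for e in edges):
            independent.append(subset)
    maximal = [
        s for s in independent
        if not any(s < t for t in independent)
    ]
    node_pos = {n: i for i, n in enumerate(nodes)}
    out = [tuple(sorted(s, key=node_pos.get)) for s in maximal]
    out.sort()
    return out


def variable_set_permutations(
    all_vars: Sequence[str], pairs: Sequence[tuple[str, str]]
) -> list[VariableSet]:
    """Enumerate candidate variable sets given covarying pairs.

    Each disjoint covarying pair doubles the candidate count (one member
    retained per pair, 2^k sets for k disjoint pairs).  Overlapping pairs
    form chains/components; a component contributes its maximal valid
    member-selections (subsets containing no covarying pair).  With no
    pairs, the single full set is returned.
    """
    all_vars = list(all_vars)
    edges = set()
    for a, b in pairs:
        if a not in all_vars or b not in all_vars:
            raise ConfigurationError(f"pair ({a}, {b}) references unknown variables")
        edges.add(frozenset((a, b)))
    if not edges:
        return [VariableSet(tuple(all_vars))]

    # Connected components over the covariance graph.
    involved = sorted({v for e in edges for v in e}, key=all_vars.index)
    adj: dict[str, set[str]] = {v: set() for v in involved}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    components: list[list[str]] = []
    for v in involved:
        if v in seen:
            continue
        comp, stack = [], [v]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(adj[u] - seen)
        components.append(sorted(comp, key=all_vars.index))

    per_component = [
        _maximal_independent_sets(comp, {e for e in edges if e <= set(comp)})
        for comp in components
    ]
    free = [v for v in all_vars if v not in adj]
    sets: list[VariableSet] = []
    for choice in product(*per_component):
        chosen = set(free).union(*choice)
        ordered = tuple(v for v in all_vars if v in chosen)
        dropped = tuple(v for v in all_vars if v not in chosen)
        sets.append(VariableSet(ordered, dropped))
    return sets


# -- learners ------------------------------------------------------------


@dataclass
class FittedSDM:
    """A fitted base learner with its preprocessing state and metadata."""

    learner: str
    variables: tuple[str, ...]
    estimator: Any
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    quadratic: bool
    converged: bool
    n_iter_used: int | None
    seed: int
    pa_set: int | None = None
    repeat: int | None = None

    def _design(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in rows.columns]
        if missing:
            raise SchemaError(f"rows lack model variables: {missing}")
        X = rows[list(self.variables)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise DataError("non-finite covariate values in prediction rows")
        Z = (X - self.scaler_mean) / self.scaler_scale
        if self.quadratic:
            Z = np.hstack([Z, Z**2])
        return Z

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Habitat suitability in [0, 1] per row (deterministic)."""
        Z = self._design(rows)
        p = self.estimator.predict_proba(Z)[:, 1]
        return np.clip(p, 0.0, 1.0)


LearnerBuilder = Callable[[pd.DataFrame, np.ndarray, MultiRealmConfig, int], FittedSDM]

LEARNERS: dict[str, LearnerBuilder] = {}


def register_learner(name: str):
    def deco(fn: LearnerBuilder) -> LearnerBuilder:
        LEARNERS[name] = fn
        return fn
    return deco


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant column: centered to 0, left unscaled
    return (X - mean) / scale, mean, scale


def _check_training(X: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(X).all():
        raise DataError("non-finite covariate values in training rows")
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError("training labels contain a single class")


def _fit_with_escalation(make_estimator, Z, y, config: MultiRealmConfig):
    """Fit at max_iter; on non-convergence refit once at the escalated
    budget.  Returns (estimator, converged, n_iter_used)."""
    for budget in (config.max_iter, config.max_iter_escalated):
        est = make_estimator(budget)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Z, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        n_iter = est.n_iter_
        if isinstance(n_iter, np.ndarray):
            n_iter = int(n_iter.max())
        if converged:
            return est, True, int(n_iter)
    return est, False, int(n_iter)


@register_learner("GLM")
def _fit_glm(X_df: pd.DataFrame, y: np.ndarray, config: MultiRealmConfig, seed: int) -> FittedSDM:
    X = X_df.to_numpy(dtype=float)
    _check_training(X, y)
    Z, mean, scale = _standardize(X)
    Z = np.hstack([Z, Z**2])
    est, converged, n_iter = _fit_with_escalation(
        lambda it: LogisticRegression(penalty=None, solver="lbfgs", max_iter=it),
        Z, y, config,
    )
    return FittedSDM("GLM", tuple(X_df.columns), est, mean, scale, True, converged, n_iter, seed)


@register_learner("RF")
def _fit_rf(X_df: pd.DataFrame, y: np.ndarray, config: MultiRealmConfig, seed: int) -> FittedSDM:
    X = X_df.to_numpy(dtype=float)
    _check_training(X, y)
    Z, mean, scale = _standardize(X)
    est = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    est.fit(Z, y)
    return FittedSDM("RF", tuple(X_df.columns), est, mean, scale, False, True, None, seed)


@register_learner("ANN")
def _fit_ann(X_df: pd.DataFrame, y: np.ndarray, config: MultiRealmConfig, seed: int) -> FittedSDM:
    X = X_df.to_numpy(dtype=float)
    _check_training(X, y)
    Z, mean, scale = _standardize(X)
    hidden = max(1, math.ceil(math.sqrt(X.shape[1])))
    est, converged, n_iter = _fit_with_escalation(
        lambda it: MLPClassifier(
            hidden_layer_sizes=(hidden,), max_iter=it, random_state=seed
        ),
        Z, y, config,
    )
    return FittedSDM("ANN", tuple(X_df.columns), est, mean, scale, False, converged, n_iter, seed)


def fit_learner(
    name: str,
    X: pd.DataFrame,
    y: np.ndarray | Sequence[int],
    config: MultiRealmConfig,
    seed: int,
) -> FittedSDM:
    """Fit a registered learner on covariate rows ``X`` and binary labels
    ``y`` (1 = presence, 0 = pseudo-absence)."""
    if name not in LEARNERS:
        raise ConfigurationError(
            f"unknown learner {name!r}; registered: {sorted(LEARNERS)}"
        )
    y = np.asarray(y, dtype=int)
    if len(y) != len(X):
        raise DataError("labels and rows disagree in length")
    return LEARNERS[name](X, y, config, int(seed))
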