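"""Study configuration and the seed-splitting scheme.

Every stage of the pipeline draws its randomness from a child seed derived
from the single study seed via :func:`stage_seed`, so a configuration plus
one integer reproduces a run bit-identically.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

# Stage identifiers for seed derivation (see stage_seed).
STAGE_PSEUDO_ABSENCE = 1
STAGE_SPLIT = 2
STAGE_FIT = 3
STAGE_PERMUTATION = 4
STAGE_SYNTH = 5


def stage_seed(root_seed: int, *ids: int) -> int:
    """Derive a deterministic 31-bit child seed for a pipeline stage.

    ``ids`` identifies the stage and its indices (e.g. pa-set, repeat,
    learner).  Uses numpy's SeedSequence so nearby roots give independent
    streams.
    """
    ss = np.random.SeedSequence([int(root_seed), *[int(i) for i in ids]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class MultiRealmConfig:
    """Per-species study configuration.

    Parameters
    ----------
    mmfd_m:
        Mean maximum foraging distance in meters — the radius of the
        marine buffer sampled around each terrestrial cell's nearest coast
        cell, and the basis of the marine background band.  Published
        values used as defaults elsewhere: 40 km (Atlantic puffin),
        200 km (northern gannet), 16.6 km (roseate tern).
    coastal_band_m:
        Terrestrial background is restricted to cells within this distance
        of the sea (default 20 km).
    exclusion_factor:
        The MMFD is treated as a 90th-percentile foraging distance; marine
        background extends to ``mmfd_m * exclusion_factor`` (a nominal
        100th percentile).  Default 10/9 (linear percentile scaling).
    n_pseudo, n_sets:
        Pseudo-absences per replicate set and number of replicate sets.
    collinearity_threshold:
        |Pearson r| above which two covariates count as highly covarying.
    train_frac, n_repeats:
        Internal-validation split fraction and number of repeats.
    tss_gate:
        Strict lower bound on cross-validated TSS for ensemble membership.
    max_iter, max_iter_escalated:
        Iteration budget for iterative learners; escalated once on
        non-convergence.
    learners:
        Names in the model registry to fit (default GLM, RF, ANN).
    seed:
        Root seed for the whole study.
    """

    mmfd_m: float = 40_000.0
    coastal_band_m: float = 20_000.0
    exclusion_factor: float = 10.0 / 9.0
    n_pseudo: int = 10_000
    n_sets: int = 5
    collinearity_threshold: float = 0.7
    train_frac: float = 0.7
    n_repeats: int = 5
    tss_gate: float = 0.6
    max_iter: int = 100
    max_iter_escalated: int = 1_000
    learners: tuple[str, ...] = ("GLM", "RF", "ANN")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mmfd_m <= 0 or self.coastal_band_m <= 0:
            raise ConfigurationError("distances must be positive")
        if self.exclusion_factor < 1:
            raise ConfigurationError("exclusion_factor must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ConfigurationError("train_frac must lie in (0, 1)")
        if not 0 <= self.tss_gate <= 1:
            raise ConfigurationError("tss_gate must lie in [0, 1]")
        if self.n_pseudo < 1 or self.n_sets < 1 or self.n_repeats < 1:
            raise ConfigurationError("counts must be positive")
        if isinstance(self.learners, list):
            self.learners = tuple(self.learners)

    def replace(self, **kw) -> "MultiRealmConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["learners"] = list(self.learners)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MultiRealmConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path, table: str = "config") -> "MultiRealmConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc.get(table, doc) if table in doc else doc)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise ConfigurationError(f"cannot serialise {type(v)} to TOML")


def write_toml(doc: dict, path: str | Path) -> None:
    """Write a flat {table: {key: value}} document as TOML."""
    lines: list[str] = []
    scalars = {k: v for k, v in doc.items() if not isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for table, body in doc.items():
        if isinstance(body, dict):
            lines.append(f"\n[{table}]")
            for k, v in body.items():
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
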