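"""Configuration and tabular I/O for the command-line workflow."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .regions import MixtureDataset

__all__ = ["RunConfig", "load_config", "load_dataset", "write_dataset", "DataValidationError"]


class DataValidationError(ValueError):
    """The CSV violates the dataset contract (names the offending cell)."""


@dataclass
class RunConfig:
    """Column roles and tuning parameters for a discovery run."""

    input: str | None = None
    outcome: str = "Y"
    exposures: list[str] = field(default_factory=list)
    covariates: list[str] | None = None
    folds: int = 10
    max_depth: int = 3
    min_node: int = 10
    epsilon: float = 0.01
    alpha: float = 0.05
    objective: str = "max"
    exhaustive: bool = False
    threshold_strategy: str = "rounded"
    threshold_param: int = 1
    learner_menu: list | None = None
    ensemble_cv: int = 5
    g_min: float = 0.025
    seed: int | None = None
    output_dir: str = "aretree-output"

    def __post_init__(self) -> None:
        roles = [self.outcome, *self.exposures, *(self.covariates or [])]
        if len(set(roles)) != len(roles):
            raise ValueError("outcome, exposure and covariate roles must be disjoint")

    def estimator_params(self) -> dict:
        menu = None
        if self.learner_menu is not None:
            menu = [(item["name"], item.get("params", {})) for item in self.learner_menu]
        return dict(
            n_folds=self.folds,
            max_depth=self.max_depth,
            min_node=self.min_node,
            epsilon=self.epsilon,
            alpha=self.alpha,
            objective=self.objective,
            exhaustive=self.exhaustive,
            threshold_strategy=self.threshold_strategy,
            threshold_param=self.threshold_param,
            learner_menu=menu,
            ensemble_cv=self.ensemble_cv,
            g_min=self.g_min,
            random_state=self.seed,
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML (or JSON) config file; keyword overrides win."""
    raw = Path(path).read_text()
    payload = yaml.safe_load(raw) or {}
    if not isinstance(payload, dict):
        raise DataValidationError(f"config file {path} must contain a mapping")
    payload.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**payload)


def load_dataset(path: str | Path, config: RunConfig) -> MixtureDataset:
    """Load and validate a CSV into a :class:`MixtureDataset`.

    Errors name the offending column (and row, for non-numeric cells).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise DataValidationError(f"{path}: file contains no data rows")
    needed = [config.outcome, *config.exposures, *(config.covariates or [])]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")
    use = needed if config.covariates is not None else list(frame.columns)
    for col in use:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataValidationError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise DataValidationError(f"{path}: missing value in column {col!r}, row {row}")
        frame[col] = coerced
    return MixtureDataset.from_frame(frame, config.outcome, config.exposures, config.covariates)


def write_dataset(data: MixtureDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
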