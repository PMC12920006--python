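"""Observations and axis-aligned exposure subregions.

A *region* is a conjunction of threshold rules on exposure coordinates —
an axis-aligned hyper-rectangle such as ``{A1 > 0.5, A2 <= -0.2}``.  The
binary indicator ``T = 1{A in region}`` turns a multivariate restriction
into a two-arm problem amenable to standard causal-effect machinery.

Boundary convention: ``LE`` is inclusive (A <= tau) and ``GT`` strictly
exclusive (A > tau), so the two children of a split at ``s`` partition a
node exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Operator",
    "ThresholdRule",
    "Region",
    "MixtureDataset",
    "membership",
    "normalize_region",
    "UnknownExposureError",
    "EmptyRegionError",
]


class UnknownExposureError(KeyError):
    """A rule references an exposure column absent from the data."""


class EmptyRegionError(ValueError):
    """A conjunction of rules implies an empty interval for some exposure."""


class Operator(str, Enum):
    LE = "<="
    GT = ">"


@dataclass(frozen=True)
class ThresholdRule:
    """One axis-aligned threshold, e.g. ``A1 <= 0.5``."""

    exposure: str
    operator: Operator
    cutpoint: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutpoint):
            raise ValueError(f"cutpoint for {self.exposure!r} must be finite")
        object.__setattr__(self, "operator", Operator(self.operator))
        object.__setattr__(self, "cutpoint", float(self.cutpoint))

    def evaluate(self, values: np.ndarray) -> np.ndarray:
        if self.operator is Operator.LE:
            return values <= self.cutpoint
        return values > self.cutpoint

    def __str__(self) -> str:
        op = "≤" if self.operator is Operator.LE else ">"
        return f"{self.exposure} {op} {self.cutpoint:g}"


@dataclass(frozen=True)
class Region:
    """Conjunction of threshold rules; an empty rule set is the full space."""

    rules: tuple[ThresholdRule, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        seen: dict[tuple[str, Operator], ThresholdRule] = {}
        bounds: dict[str, dict[Operator, float]] = {}
        for r in self.rules:
            key = (r.exposure, r.operator)
            if key in seen:
                raise ValueError(
                    f"duplicate {r.operator.value!r} rule for {r.exposure!r}; "
                    "use normalize_region() first"
                )
            seen[key] = r
            bounds.setdefault(r.exposure, {})[r.operator] = r.cutpoint
        for name, b in bounds.items():
            if Operator.LE in b and Operator.GT in b and b[Operator.GT] >= b[Operator.LE]:
                raise EmptyRegionError(
                    f"empty interval for {name!r}: "
                    f"> {b[Operator.GT]:g} and <= {b[Operator.LE]:g}"
                )

    @property
    def is_full_space(self) -> bool:
        return len(self.rules) == 0

    @property
    def exposures(self) -> tuple[str, ...]:
        """Sorted, deduplicated exposure names — the variable signature."""
        return tuple(sorted({r.exposure for r in self.rules}))

    def signature(self) -> tuple[str, ...]:
        return self.exposures

    def __str__(self) -> str:
        if self.is_full_space:
            return "(full exposure space)"
        return " & ".join(str(r) for r in self.rules)

    def to_records(self) -> list[dict]:
        """Lossless structured form for round-tripping."""
        return [
            {"exposure": r.exposure, "operator": r.operator.value, "cutpoint": r.cutpoint}
            for r in self.rules
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "Region":
        return cls(
            tuple(
                ThresholdRule(rec["exposure"], Operator(rec["operator"]), rec["cutpoint"])
                for rec in records
            )
        )


def normalize_region(rules: Iterable[ThresholdRule]) -> Region:
    """Collapse same-exposure/same-operator rules to the tightest bound.

    ``{A1<=5, A1<=3}`` becomes ``{A1<=3}``; ``{A1>1, A1>2}`` becomes
    ``{A1>2}``.  Raises :class:`EmptyRegionError` when the implied interval
    for some exposure is empty.
    """
    tight: dict[tuple[str, Operator], float] = {}
    order: list[tuple[str, Operator]] = []
    for r in rules:
        key = (r.exposure, r.operator)
        if key not in tight:
            tight[key] = r.cutpoint
            order.append(key)
        elif r.operator is Operator.LE:
            tight[key] = min(tight[key], r.cutpoint)
        else:
            tight[key] = max(tight[key], r.cutpoint)
    return Region(tuple(ThresholdRule(name, op, tight[(name, op)]) for name, op in order))


def membership(region: Region, A: pd.DataFrame | np.ndarray, columns: Sequence[str] | None = None) -> np.ndarray:
    """Binary indicator ``T_i = 1`` iff row ``i`` satisfies every rule.

    ``A`` may be a DataFrame (column names resolved directly) or an ndarray
    with an accompanying ``columns`` list.
    """
    if isinstance(A, pd.DataFrame):
        frame = A
    else:
        if columns is None:
            raise ValueError("columns required when A is an ndarray")
        frame = pd.DataFrame(np.asarray(A), columns=list(columns))
    out = np.ones(len(frame), dtype=bool)
    for rule in region.rules:
        if rule.exposure not in frame.columns:
            raise UnknownExposureError(rule.exposure)
        out &= rule.evaluate(frame[rule.exposure].to_numpy())
    return out.astype(np.int8)


@dataclass
class MixtureDataset:
    """Observed (W, A, Y): covariates, exposures, outcome.

    All blocks share n; values must be finite; column names unique across
    blocks.  ``W`` may have zero columns (no measured covariates).
    """

    W: pd.DataFrame
    A: pd.DataFrame
    Y: np.ndarray
    outcome_name: str = "Y"

    def __post_init__(self) -> None:
        self.W = pd.DataFrame(self.W).reset_index(drop=True)
        self.A = pd.DataFrame(self.A).reset_index(drop=True)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = len(self.Y)
        if n < 1:
            raise ValueError("dataset must contain at least one observation")
        if len(self.W) != n or len(self.A) != n:
            raise ValueError("W, A and Y must share the same number of rows")
        if self.A.shape[1] < 1:
            raise ValueError("at least one exposure column is required")
        names = list(self.W.columns) + list(self.A.columns) + [self.outcome_name]
        if len(set(names)) != len(names):
            raise ValueError("column names must be unique across W, A and Y")
        for label, block in (("W", self.W), ("A", self.A)):
            arr = block.to_numpy(dtype=float) if block.shape[1] else np.empty((n, 0))
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite or missing values in {label}")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("non-finite or missing values in Y")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def m(self) -> int:
        return self.A.shape[1]

    @property
    def p(self) -> int:
        return self.W.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return list(self.A.columns)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.W.columns)

    def membership(self, region: Region) -> np.ndarray:
        return membership(region, self.A)

    def subset(self, index: np.ndarray) -> "MixtureDataset":
        index = np.asarray(index)
        return MixtureDataset(
            self.W.iloc[index].reset_index(drop=True),
            self.A.iloc[index].reset_index(drop=True),
            self.Y[index],
            self.outcome_name,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([self.W, self.A], axis=1)
        out[self.outcome_name] = self.Y
        return out

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        outcome: str,
        exposures: Sequence[str],
        covariates: Sequence[str] | None = None,
    ) -> "MixtureDataset":
        covariates = list(covariates) if covariates is not None else [
            c for c in frame.columns if c != outcome and c not in exposures
        ]
        missing = [c for c in [outcome, *exposures, *covariates] if c not in frame.columns]
        if missing:
            raise KeyError(f"columns not found in data: {missing}")
        return cls(
            frame[covariates].astype(float),
            frame[list(exposures)].astype(float),
            frame[outcome].to_numpy(dtype=float),
            outcome_name=outcome,
        )
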