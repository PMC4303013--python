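"""Observed time-series container and the heteroscedastic error model.

Measurements are long-format records ``(time, variable, value)``; missing
combinations are simply absent, which covers asynchronous or partially
observed sampling without any special casing.  Measurement uncertainty
follows the proportional-plus-floor law σ_y = a·y + b.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ErrorModel", "Dataset"]


@dataclass(frozen=True)
class ErrorModel:
    """σ_y = a·y + b: proportional coefficient *a* (–) and additive floor *b* (mM).

    Both coefficients are non-negative and at least one must be positive,
    otherwise every weight would be infinite.
    """

    a: float
    b: float

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("error-model coefficients must be non-negative")
        if self.a == 0 and self.b == 0:
            raise ValueError("error model a = b = 0 would give zero variance")

    def sigma(self, y):
        """Standard deviation(s) for measurement value(s) *y*."""
        return self.a * np.asarray(y, dtype=float) + self.b


class Dataset:
    """Long-format experimental records with optional error model.

    Wraps a DataFrame with columns ``time`` (s), ``variable`` (state
    identifier) and ``value`` (mM).  Records are kept in a canonical sort
    (time, then variable) so row order — and hence sensitivity-matrix row
    order — is reproducible.
    """

    COLUMNS = ("time", "variable", "value")

    def __init__(self, records: pd.DataFrame, error_model: ErrorModel | None = None):
        df = pd.DataFrame(records)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        if len(df) == 0:
            raise ValueError("dataset is empty")
        if not np.all(np.isfinite(df["time"])) or np.any(df["time"] < 0):
            raise ValueError("observation times must be finite and non-negative")
        if not np.all(np.isfinite(df["value"])):
            raise ValueError("observed values must be finite")
        df = df.sort_values(["time", "variable"], kind="stable").reset_index(drop=True)
        self.records = df
        self.error_model = error_model
        if error_model is not None:
            sig = error_model.sigma(df["value"].to_numpy())
            if np.any(sig <= 0):
                raise ValueError(
                    "error model yields non-positive sigma for some records "
                    "(negative values with b = 0?)"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        error_model: ErrorModel | None = None,
    ) -> "Dataset":
        """Build from an iterable of (time, variable, value) tuples."""
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df, error_model)

    @classmethod
    def from_csv(cls, path, error_model: ErrorModel | None = None) -> "Dataset":
        return cls(pd.read_csv(path), error_model)

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(path, index=False)

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return self.records["time"].to_numpy()

    @property
    def variables(self) -> Sequence[str]:
        return self.records["variable"].tolist()

    @property
    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy()

    def unique_times(self) -> np.ndarray:
        return np.unique(self.times)

    def observed_variables(self) -> list:
        return sorted(self.records["variable"].unique())

    def sigmas(self, error_model: ErrorModel | None = None) -> np.ndarray:
        """Per-record σ_y from σ = a·y + b, evaluated on the *measured*
        values so the weight matrix stays fixed during optimization."""
        em = error_model or self.error_model
        if em is None:
            raise ValueError("no error model attached or supplied")
        sig = em.sigma(self.values)
        if np.any(sig <= 0):
            raise ValueError("non-positive sigma encountered")
        return sig

    def validate_against(self, model) -> None:
        """Check every record's variable is a measurable state of *model*."""
        bad = set(self.records["variable"]) - set(model.output_map)
        if bad:
            raise ValueError(
                f"dataset contains variables outside the model's output map: {sorted(bad)}"
            )

    def subset(self, variables: Iterable[str]) -> "Dataset":
        keep = self.records[self.records["variable"].isin(set(variables))]
        return Dataset(keep, self.error_model)

    def __repr__(self) -> str:
        nv = len(self.records["variable"].unique())
        return (
            f"Dataset({len(self)} records, {nv} variables, "
            f"t ∈ [{self.times.min():g}, {self.times.max():g}] s)"
        )
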