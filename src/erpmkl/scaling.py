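"""Feature standardization followed by a logistic squash into (0, 1).

Each column is z-scored with statistics fitted on training rows only, then
mapped through ``s = 1 / (1 + exp(-z))``; constant columns map to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScalerState", "fit_scaler", "transform", "fit_transform"]


@dataclass(frozen=True)
class ScalerState:
    """Per-column mean/sd (ddof=1) plus the row count they were fitted on."""

    mean: pd.Series
    sd: pd.Series
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sd": {k: float(v) for k, v in self.sd.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(
            mean=pd.Series(d["mean"], dtype=float),
            sd=pd.Series(d["sd"], dtype=float),
            n_rows=int(d["n_rows"]),
        )


def fit_scaler(train: pd.DataFrame) -> ScalerState:
    """Columnwise mean and sample standard deviation (denominator n-1)."""
    if train.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit the scaler")
    return ScalerState(
        mean=train.mean(axis=0), sd=train.std(axis=0, ddof=1), n_rows=train.shape[0]
    )


def transform(table: pd.DataFrame, state: ScalerState) -> pd.DataFrame:
    """Sigmoid of the z-score; strictly inside (0, 1), 0.5 where sd = 0."""
    if list(table.columns) != list(state.mean.index):
        raise ValueError("table columns do not match the fitted scaler state")
    z = table.subtract(state.mean, axis=1)
    sd = state.sd.replace(0.0, np.inf)  # constant columns: z -> 0 -> 0.5
    z = z.divide(sd, axis=1)
    with np.errstate(over="ignore"):  # exp overflow saturates to the 0 limit
        return 1.0 / (1.0 + np.exp(-z))


def fit_transform(train: pd.DataFrame) -> tuple[pd.DataFrame, ScalerState]:
    state = fit_scaler(train)
    return transform(train, state), state
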