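"""Core container for continuous glucose monitoring (CGM) traces.

A :class:`GlucoseSeries` is an ordered, strictly-increasing sequence of
timestamped glucose readings in mmol/L — the universal input to windowing,
model training, evaluation and streaming replay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GlucoseSeries", "SeriesValidationError"]


class SeriesValidationError(ValueError):
    """Raised when timestamps/values violate the series invariants."""


@dataclass(frozen=True)
class GlucoseSeries:
    """Univariate glucose time series in mmol/L.

    Parameters
    ----------
    timestamps
        Strictly increasing datetimes, one per reading.
    values
        Glucose readings in mmol/L; finite and positive.
    """

    timestamps: np.ndarray  # datetime64[ns]
    values: np.ndarray  # float64, mmol/L
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(np.asarray(self.timestamps)).values.astype(
            "datetime64[ns]"
        )
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if ts.shape != vals.shape or ts.ndim != 1:
            raise SeriesValidationError(
                "timestamps and values must be 1-D arrays of equal length"
            )
        if len(ts) < 1:
            raise SeriesValidationError("series must contain at least one reading")
        if not np.all(np.isfinite(vals)):
            raise SeriesValidationError("glucose values must be finite")
        if np.any(vals <= 0):
            raise SeriesValidationError("glucose values must be positive (mmol/L)")
        dt = np.diff(ts.astype("int64"))
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise SeriesValidationError(
                f"timestamps must be strictly increasing (violation at index {bad})"
            )
        object.__setattr__(self, "_validated", True)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Two-column DataFrame with ``Time`` and ``BGL`` columns."""
        return pd.DataFrame(
            {"Time": pd.DatetimeIndex(self.timestamps), "BGL": self.values}
        )

    def slice(self, start: int, stop: int) -> "GlucoseSeries":
        return GlucoseSeries(self.timestamps[start:stop], self.values[start:stop])

    def equals(self, other: "GlucoseSeries") -> bool:
        return bool(
            len(self) == len(other)
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
        )
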