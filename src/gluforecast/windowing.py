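"""Series-to-supervised transformation, chronological splitting and scaling.

A forecasting sample pairs a window of ``lag`` consecutive readings with the
reading ``horizon`` steps beyond the window's last element (the *direct*
multi-step strategy: one model per horizon).  From a series of length N this
yields exactly ``N - lag - horizon + 1`` samples.

Lags and horizons are counts of samples, not literal minutes: at ~15-minute
CGM sampling a "3-minute" window cannot exist, so the canonical scenario grid
keeps its minute names purely as report labels.

Scaling is min-max to [0, 1], fitted on the training partition only (pooled
over windows and targets) so that no statistic of the test region can leak
into preprocessing; test values outside the training range simply map outside
[0, 1] and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .series import GlucoseSeries

__all__ = [
    "SupervisedDataset",
    "ScalerParams",
    "ScenarioGrid",
    "InsufficientHistoryError",
    "DegenerateScaleError",
    "to_supervised",
    "chronological_split",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]


class InsufficientHistoryError(ValueError):
    """Series shorter than lag + horizon."""


class DegenerateScaleError(ValueError):
    """Constant training data cannot define a min-max scale."""


@dataclass(frozen=True)
class ScalerParams:
    """Min-max scale fitted on training values only (mmol/L)."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if not (self.max_value > self.min_value):
            raise DegenerateScaleError(
                f"max_value ({self.max_value}) must exceed min_value "
                f"({self.min_value})"
            )

    @property
    def span(self) -> float:
        return self.max_value - self.min_value

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.min_value) / self.span

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.span + self.min_value


@dataclass(frozen=True)
class SupervisedDataset:
    """Lagged windows ``X`` (n_samples x lag) and horizon-ahead targets ``y``."""

    X: np.ndarray
    y: np.ndarray
    lag: int
    horizon: int
    scaled: bool = False
    scaler: ScalerParams | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, lag) with matching y")
        if X.shape[1] != self.lag:
            raise ValueError(f"X has width {X.shape[1]}, expected lag={self.lag}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def __len__(self) -> int:
        return self.n_samples


@dataclass(frozen=True)
class ScenarioGrid:
    """Ordered (lag, horizon) pairs with report labels.

    The default grid is the six canonical forecasting scenarios, labelled by
    their minutes-ahead names: windows of 3, 10, 13, 18, 20 and 30 samples
    forecasting 5, 15, 20, 25, 30 and 60 steps ahead respectively.
    """

    pairs: tuple[tuple[int, int], ...] = (
        (3, 5),
        (10, 15),
        (13, 20),
        (18, 25),
        (20, 30),
        (30, 60),
    )
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        pairs = tuple((int(l), int(h)) for l, h in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for lag, horizon in pairs:
            if lag < 1 or horizon < 1:
                raise ValueError("all lags and horizons must be positive")
        if self.labels is None:
            if pairs == ScenarioGrid.__dataclass_fields__["pairs"].default:
                labels = ("5 min", "15 min", "20 min", "25 min", "30 min", "60 min")
            else:
                labels = tuple(f"lag {l} → +{h} steps" for l, h in pairs)
            object.__setattr__(self, "labels", labels)
        elif len(self.labels) != len(pairs):
            raise ValueError("labels must match pairs one-to-one")

    def __iter__(self):
        return iter(zip(self.labels, self.pairs))


def to_supervised(
    series: GlucoseSeries | np.ndarray,
    lag: int,
    horizon: int,
    *,
    max_gap: np.timedelta64 | None = None,
) -> SupervisedDataset:
    """Build (window, target) samples from a series.

    ``X[i] = values[i : i+lag]`` and ``y[i] = values[i + lag + horizon - 1]``,
    i.e. the target lies ``horizon`` steps beyond the window's last element.

    By default timestamp gaps are ignored (the series is treated as
    index-regular).  With ``max_gap`` set, any sample whose window+target
    span contains a timestamp step larger than ``max_gap`` is dropped.
    """
    if isinstance(series, GlucoseSeries):
        values = series.values
        timestamps = series.timestamps
    else:
        values = np.asarray(series, dtype=float)
        timestamps = None
    lag, horizon = int(lag), int(horizon)
    if lag < 1 or horizon < 1:
        raise ValueError("lag and horizon must be positive integers")
    n = len(values)
    n_samples = n - lag - horizon + 1
    if n_samples < 1:
        raise InsufficientHistoryError(
            f"series of length {n} is too short for lag={lag}, "
            f"horizon={horizon}; need at least {lag + horizon} readings"
        )
    idx = np.arange(n_samples)
    X = values[idx[:, None] + np.arange(lag)[None, :]]
    y = values[idx + lag + horizon - 1]
    if max_gap is not None and timestamps is not None:
        steps = np.diff(timestamps.astype("int64"))
        limit = np.int64(np.timedelta64(max_gap, "ns").astype("int64"))
        # sample i spans timestamp steps i .. i+lag+horizon-2
        span = np.arange(lag + horizon - 1)
        bad = (steps[idx[:, None] + span[None, :]] > limit).any(axis=1)
        X, y = X[~bad], y[~bad]
        if len(y) == 0:
            raise InsufficientHistoryError(
                "no gap-free samples remain after applying max_gap"
            )
    return SupervisedDataset(X=X, y=y, lag=lag, horizon=horizon)


def chronological_split(
    ds: SupervisedDataset, train_fraction: float = 0.75
) -> tuple[SupervisedDataset, SupervisedDataset]:
    """Split into a leading train part and trailing test part (no shuffling).

    The train part receives ``floor(train_fraction * n)`` samples; every
    training sample precedes every test sample in time.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = ds.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(train_fraction * n))
    n_train = max(1, min(n - 1, n_train))
    train = replace(ds, X=ds.X[:n_train], y=ds.y[:n_train])
    test = replace(ds, X=ds.X[n_train:], y=ds.y[n_train:])
    return train, test


def fit_scaler(train: SupervisedDataset) -> ScalerParams:
    """Min/max over the training windows and targets pooled."""
    lo = min(float(train.X.min()), float(train.y.min()))
    hi = max(float(train.X.max()), float(train.y.max()))
    if not (hi > lo):
        raise DegenerateScaleError(
            f"training data are constant ({lo}); cannot fit a min-max scale"
        )
    return ScalerParams(min_value=lo, max_value=hi)


def apply_scaler(ds: SupervisedDataset, scaler: ScalerParams) -> SupervisedDataset:
    """Map values through (x - min)/(max - min); out-of-range values are not
    clipped (test data may legitimately fall outside [0, 1])."""
    return replace(
        ds,
        X=scaler.transform(ds.X),
        y=scaler.transform(ds.y),
        scaled=True,
        scaler=scaler,
    )


def invert_scaler(values: np.ndarray, scaler: ScalerParams) -> np.ndarray:
    """Inverse of :func:`apply_scaler` on a vector of scaled values."""
    return scaler.inverse(values)


def supervised_sets(
    series: GlucoseSeries | np.ndarray,
    lag: int,
    horizon: int,
    train_fraction: float = 0.75,
) -> tuple[SupervisedDataset, SupervisedDataset, ScalerParams]:
    """Convenience: window, split chronologically, fit scaler on train only,
    return (scaled train, scaled test, scaler)."""
    ds = to_supervised(series, lag, horizon)
    train, test = chronological_split(ds, train_fraction)
    scaler = fit_scaler(train)
    return apply_scaler(train, scaler), apply_scaler(test, scaler), scaler
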