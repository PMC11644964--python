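"""The five forecasting architectures and their training loop.

Architectures (single scalar output per window — the direct multi-step
strategy trains one model per forecast horizon):

* ``gru`` / ``lstm``: recurrent layer (ReLU activation, dropout, L2) → dense
  output.
* ``cnn``: Conv1D (ReLU) → max-pool → flatten → dense (ReLU, dropout) →
  dense output.
* ``cnn_gru`` / ``cnn_lstm``: Conv1D (ReLU) → max-pool → recurrent →
  flatten → dense (ReLU) → dense output; the convolution extracts local
  shape features, the recurrent layer models the temporal dependence of the
  pooled feature sequence.

Training minimizes mean squared error with Adam, by default one sample per
update (batch size 1) for 20 epochs.  Dropout sits after the recurrent (or
hidden dense) layer and L2 weight decay applies to recurrent and dense
kernels; both are regularizers whose strengths come from the hyperparameter
search space.  Prediction always returns forecasts in original units
(mmol/L) via the stored min-max scaler.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GRULayer,
    LSTMLayer,
    MaxPool1D,
    Sequential,
)
from .windowing import ScalerParams, SupervisedDataset

__all__ = [
    "MODEL_KINDS",
    "HyperParams",
    "Forecaster",
    "TrainedForecaster",
    "TrainingDivergenceError",
    "build_model",
    "train",
    "predict",
    "save_forecaster",
    "load_forecaster",
]

MODEL_KINDS = ("lstm", "gru", "cnn", "cnn_lstm", "cnn_gru")
_CONV_KINDS = ("cnn", "cnn_lstm", "cnn_gru")


class TrainingDivergenceError(RuntimeError):
    """Loss became NaN during training; message names the epoch."""


@dataclass(frozen=True)
class HyperParams:
    """One model configuration.

    ``units`` is ``[recurrent_units]`` for single models, ``[recurrent_units,
    dense_units]`` for hybrids, and ``[dense_units]`` for the plain CNN.
    ``filters``/``kernel`` are present exactly when the architecture
    convolves; ``kernel`` must not exceed ``lag``.
    """

    model_kind: str
    units: tuple[int, ...]
    lag: int
    dropout: float = 0.2
    reg_rate: float = 0.001
    filters: int | None = None
    kernel: int | None = None
    activation: str = "relu"  # recurrent-layer activation; tanh also valid

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(int(u) for u in self.units))
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.lag < 1:
            raise ValueError("lag must be a positive integer")
        if not self.units or any(u < 1 for u in self.units):
            raise ValueError("units must be positive integers")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.reg_rate < 0:
            raise ValueError("reg_rate must be nonnegative")
        is_conv = self.model_kind in _CONV_KINDS
        if is_conv:
            if self.filters is None or self.kernel is None:
                raise ValueError(
                    f"{self.model_kind} requires filters and kernel"
                )
            if self.kernel > self.lag:
                raise ValueError(
                    f"kernel ({self.kernel}) must not exceed lag ({self.lag})"
                )
            if self.model_kind != "cnn" and len(self.units) != 2:
                raise ValueError(
                    "hybrid models take units=[recurrent_units, dense_units]"
                )
        else:
            if self.filters is not None or self.kernel is not None:
                raise ValueError(
                    f"{self.model_kind} takes no convolution parameters"
                )
            if len(self.units) != 1:
                raise ValueError("single models take units=[recurrent_units]")


class Forecaster:
    """An (initially untrained) architecture built from HyperParams."""

    def __init__(self, hp: HyperParams, net: Sequential) -> None:
        self.hp = hp
        self.net = net

    @property
    def stages(self) -> list[str]:
        """Functional stage sequence (dropout, a regularizer, is elided)."""
        return [s for s in self.net.stages if s != "dropout"]

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def forward_window(self, window: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> float:
        x = np.asarray(window, dtype=float).reshape(self.hp.lag, 1)
        return float(self.net.forward(x, training=training, rng=rng)[0])

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.hp.lag:
            raise ValueError(
                f"window width {X.shape[1]} does not match lag {self.hp.lag}"
            )
        return np.array([self.forward_window(row) for row in X])


def build_model(hp: HyperParams, seed: int = 0) -> Forecaster:
    """Construct the architecture for ``hp`` with seeded weight init."""
    kind, l2 = hp.model_kind, hp.reg_rate
    layers: list = []
    if kind in ("gru", "lstm"):
        rec = GRULayer if kind == "gru" else LSTMLayer
        layers += [
            rec(1, hp.units[0], activation=hp.activation, l2=l2),
            Dropout(hp.dropout),
            Dense(hp.units[0], 1, stage="output", l2=l2),
        ]
    elif kind == "cnn":
        conv_out = hp.lag - hp.kernel + 1
        pooled = max(1, conv_out // min(2, conv_out))
        layers += [
            Conv1D(1, hp.filters, hp.kernel, l2=l2),
            MaxPool1D(2),
            Flatten(),
            Dense(pooled * hp.filters, hp.units[0], activation="relu", l2=l2),
            Dropout(hp.dropout),
            Dense(hp.units[0], 1, stage="output", l2=l2),
        ]
    else:  # cnn_gru / cnn_lstm
        rec = GRULayer if kind == "cnn_gru" else LSTMLayer
        layers += [
            Conv1D(1, hp.filters, hp.kernel, l2=l2),
            MaxPool1D(2),
            rec(hp.filters, hp.units[0], activation=hp.activation, l2=l2),
            Dropout(hp.dropout),
            Flatten(),
            Dense(hp.units[0], hp.units[1], activation="relu", l2=l2),
            Dense(hp.units[1], 1, stage="output", l2=l2),
        ]
    net = Sequential(layers)
    net.init(np.random.default_rng(seed))
    return Forecaster(hp, net)


@dataclass
class TrainedForecaster:
    """A fitted architecture plus the scaler that defines its input space."""

    forecaster: Forecaster
    scaler: ScalerParams
    history: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def hp(self) -> HyperParams:
        return self.forecaster.hp

    @property
    def lag(self) -> int:
        return self.forecaster.hp.lag

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        """Forecasts in original units for scaled windows of width ``lag``."""
        yhat = self.forecaster.predict_scaled(X_scaled)
        return self.scaler.inverse(yhat)

    def predict_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.forecaster.predict_scaled(X_scaled)


def train(
    model: Forecaster,
    train_ds: SupervisedDataset,
    epochs: int = 20,
    batch_size: int = 1,
    seed: int = 0,
    lr: float = 1e-3,
    shuffle: bool = True,
) -> TrainedForecaster:
    """Fit with MSE loss and Adam; returns the forecaster with its per-epoch
    mean training loss history.  Deterministic for a fixed seed."""
    if not train_ds.scaled or train_ds.scaler is None:
        raise ValueError("train() expects a scaled dataset with its scaler")
    if train_ds.X.shape[1] != model.hp.lag:
        raise ValueError(
            f"dataset lag {train_ds.X.shape[1]} != model lag {model.hp.lag}"
        )
    rng = np.random.default_rng(seed)
    opt = Adam(model.net, lr=lr)
    X, y = train_ds.X, train_ds.y
    n = len(y)
    history: list[float] = []
    for epoch in range(int(epochs)):
        order = rng.permutation(n) if shuffle else np.arange(n)
        losses = np.empty(n)
        model.net.zero_grads()
        in_batch = 0
        for j, i in enumerate(order):
            out = model.net.forward(
                X[i].reshape(model.hp.lag, 1), training=True, rng=rng
            )
            err = float(out[0]) - y[i]
            losses[j] = err * err
            model.net.backward(np.array([2.0 * err]))
            in_batch += 1
            if in_batch >= batch_size or j == n - 1:
                model.net.add_l2_grads()
                if in_batch > 1:
                    for layer in model.net.layers:
                        for k in layer.grads:
                            layer.grads[k] /= in_batch
                opt.step()
                model.net.zero_grads()
                in_batch = 0
        epoch_loss = float(losses.mean())
        if not np.isfinite(epoch_loss):
            raise TrainingDivergenceError(
                f"training loss diverged (NaN/inf) at epoch {epoch + 1}"
            )
        history.append(epoch_loss)
    return TrainedForecaster(
        forecaster=model, scaler=train_ds.scaler, history=history, seed=seed
    )


def predict(model: TrainedForecaster, X_scaled: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TrainedForecaster.predict`."""
    return model.predict(X_scaled)


def persistence_forecast(X_raw: np.ndarray) -> np.ndarray:
    """Naive last-value baseline: predict the window's final reading."""
    return np.atleast_2d(np.asarray(X_raw, dtype=float))[:, -1]


def save_forecaster(model: TrainedForecaster, directory: str | Path) -> Path:
    """Persist weights (npz) plus a JSON sidecar with hyperparameters,
    scaler, seed and loss history."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.forecaster.net.get_weights())
    meta = {
        "hyperparams": asdict(model.hp),
        "scaler": {"min_value": model.scaler.min_value,
                   "max_value": model.scaler.max_value},
        "seed": model.seed,
        "history": model.history,
    }
    (directory / "forecaster.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_forecaster(directory: str | Path) -> TrainedForecaster:
    directory = Path(directory)
    meta = json.loads((directory / "forecaster.json").read_text())
    hp_dict = dict(meta["hyperparams"])
    hp_dict["units"] = tuple(hp_dict["units"])
    hp = HyperParams(**hp_dict)
    model = build_model(hp, seed=meta["seed"])
    with np.load(directory / "weights.npz") as npz:
        model.net.set_weights({k: npz[k] for k in npz.files})
    return TrainedForecaster(
        forecaster=model,
        scaler=ScalerParams(**meta["scaler"]),
        history=list(meta["history"]),
        seed=meta["seed"],
    )
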