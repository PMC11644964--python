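"""RMSE/MAE metrics and the six-scenario model-comparison runner.

RMSE = sqrt(mean((y_obs - y_pred)^2)); MAE = mean(|y_obs - y_pred|).
Both are reported in original units (mmol/L) after inverse scaling, and
RMSE >= MAE always (Jensen).  The scenario runner mirrors the canonical
experiment: for each (lag, horizon) pair and each architecture — window,
split 75/25 chronologically, min-max scale on train, optionally tune, train
(epochs 20, batch 1), predict the test windows and score.  A persistence
(last observed value) baseline row anchors every report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .models import (
    HyperParams,
    TrainedForecaster,
    build_model,
    persistence_forecast,
    train,
)
from .series import GlucoseSeries
from .windowing import (
    InsufficientHistoryError,
    ScenarioGrid,
    chronological_split,
    supervised_sets,
    to_supervised,
)

__all__ = [
    "EvalMetrics",
    "ScenarioReport",
    "rmse",
    "mae",
    "evaluate_forecaster",
    "run_scenario",
    "default_hyperparams",
    "report_to_json",
    "report_to_csv",
]

logger = logging.getLogger(__name__)


def _check_pair(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0:
        raise ValueError("empty input")
    if y_obs.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_obs.size} observed vs {y_pred.size} predicted"
        )
    if not (np.all(np.isfinite(y_obs)) and np.all(np.isfinite(y_pred))):
        raise ValueError("inputs must be finite")
    return y_obs, y_pred


def rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def mae(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error."""
    y_obs, y_pred = _check_pair(y_obs, y_pred)
    return float(np.mean(np.abs(y_obs - y_pred)))


@dataclass(frozen=True)
class EvalMetrics:
    """RMSE and MAE (mmol/L) for one (model, lag, horizon) cell."""

    rmse: float
    mae: float
    n: int

    @classmethod
    def from_predictions(cls, y_obs: np.ndarray, y_pred: np.ndarray) -> "EvalMetrics":
        y_obs, y_pred = _check_pair(y_obs, y_pred)
        return cls(rmse=rmse(y_obs, y_pred), mae=mae(y_obs, y_pred), n=y_obs.size)


@dataclass
class ScenarioReport:
    """One forecasting scenario: per-model metrics plus winning configs."""

    label: str
    lag: int
    horizon: int
    metrics: dict[str, EvalMetrics] = field(default_factory=dict)
    hyperparams: dict[str, HyperParams] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "lag": self.lag,
            "horizon": self.horizon,
            "models": {
                kind: {
                    "rmse": m.rmse,
                    "mae": m.mae,
                    "n": m.n,
                    "hyperparams": (
                        asdict(self.hyperparams[kind])
                        if kind in self.hyperparams
                        else None
                    ),
                }
                for kind, m in self.metrics.items()
            },
        }


def evaluate_forecaster(
    model: TrainedForecaster, test_scaled, y_obs_original: np.ndarray
) -> EvalMetrics:
    """Score a trained model on scaled test windows; metrics in mmol/L."""
    y_pred = model.predict(test_scaled.X)
    return EvalMetrics.from_predictions(y_obs_original, y_pred)


def default_hyperparams(kind: str, lag: int) -> HyperParams:
    """Reasonable per-architecture defaults (no tuning).

    Sizes are deliberately modest so an untuned comparison run completes in
    seconds on one CPU core; the hyperparameter search space is where large
    configurations live.
    """
    if kind == "gru":
        return HyperParams("gru", (50,), lag)
    if kind == "lstm":
        return HyperParams("lstm", (70,), lag)
    if kind == "cnn":
        return HyperParams("cnn", (32,), lag, filters=32,
                           kernel=min(3, lag))
    if kind in ("cnn_gru", "cnn_lstm"):
        return HyperParams(kind, (32, 16), lag, filters=32,
                           kernel=min(3, lag))
    raise ValueError(f"unknown model kind {kind!r}")


def run_scenario(
    series: GlucoseSeries,
    grid: ScenarioGrid | None = None,
    model_kinds: Sequence[str] = ("gru", "lstm", "cnn", "cnn_lstm", "cnn_gru"),
    hyperparams: Mapping[str, HyperParams] | None = None,
    hpo_config: Mapping | None = None,
    epochs: int = 20,
    batch_size: int = 1,
    seed: int = 0,
    train_fraction: float = 0.75,
    include_persistence: bool = True,
) -> list[ScenarioReport]:
    """Run the model comparison over every (lag, horizon) scenario.

    ``hyperparams`` maps model kind to a fixed configuration; otherwise, if
    ``hpo_config`` is given (keys ``n_trials``, ``n_initial``, optional
    ``epochs``), each architecture is tuned per scenario with Bayesian
    optimization; otherwise per-kind defaults are used.  Scenarios the
    series is too short for are skipped with a warning.
    """
    grid = grid or ScenarioGrid()
    reports: list[ScenarioReport] = []
    for scenario_idx, (label, (lag, horizon)) in enumerate(grid):
        try:
            full = to_supervised(series, lag, horizon)
        except InsufficientHistoryError as exc:
            logger.warning("skipping scenario %s: %s", label, exc)
            continue
        train_raw, test_raw = chronological_split(full, train_fraction)
        train_scaled, test_scaled, scaler = supervised_sets(
            series, lag, horizon, train_fraction
        )
        report = ScenarioReport(label=label, lag=lag, horizon=horizon)
        for kind_idx, kind in enumerate(model_kinds):
            # distinct, stable per-(scenario, kind) seed stream
            kind_seed = (seed * 1009 + scenario_idx * 101 + kind_idx) % (2**31)
            if hyperparams is not None and kind in hyperparams:
                from dataclasses import replace

                hp = hyperparams[kind]
                if hp.lag != lag:  # re-target a fixed config to this scenario
                    kw = {"lag": lag}
                    if hp.kernel is not None and hp.kernel > lag:
                        kw["kernel"] = lag
                    hp = replace(hp, **kw)
            elif hpo_config is not None:
                from .hpo import SearchSpace, select_architecture

                result = select_architecture(
                    train_scaled,
                    scaler,
                    kind,
                    SearchSpace.for_kind(kind, lag),
                    n_trials=int(hpo_config.get("n_trials", 20)),
                    n_initial=int(hpo_config.get("n_initial", 5)),
                    epochs=int(hpo_config.get("epochs", epochs)),
                    batch_size=batch_size,
                    seed=kind_seed,
                )
                hp = result.best.hyperparams
            else:
                hp = default_hyperparams(kind, lag)
            model = build_model(hp, seed=kind_seed)
            fitted = train(
                model, train_scaled, epochs=epochs, batch_size=batch_size,
                seed=kind_seed,
            )
            report.metrics[kind] = evaluate_forecaster(
                fitted, test_scaled, test_raw.y
            )
            report.hyperparams[kind] = hp
        if include_persistence:
            y_naive = persistence_forecast(test_raw.X)
            report.metrics["persistence"] = EvalMetrics.from_predictions(
                test_raw.y, y_naive
            )
        reports.append(report)
    return reports


def report_to_json(reports: Sequence[ScenarioReport], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps([r.as_dict() for r in reports], indent=2) + "\n"
    )
    return path


def report_to_csv(reports: Sequence[ScenarioReport], path: str | Path) -> Path:
    """Flat CSV: one row per (scenario, model)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("scenario,lag,horizon,model,rmse,mae,n\n")
        for r in reports:
            for kind, m in r.metrics.items():
                fh.write(
                    f"{r.label},{r.lag},{r.horizon},{kind},"
                    f"{m.rmse:.6f},{m.mae:.6f},{m.n}\n"
                )
    return path


def format_report_table(report: ScenarioReport) -> str:
    """Human-readable fixed-width table for one scenario."""
    lines = [
        f"Scenario {report.label} (lag={report.lag}, horizon={report.horizon})",
        f"{'Model':<12} {'RMSE':>8} {'MAE':>8} {'n':>6}",
    ]
    for kind, m in report.metrics.items():
        lines.append(f"{kind:<12} {m.rmse:>8.4f} {m.mae:>8.4f} {m.n:>6d}")
    return "\n".join(lines)
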