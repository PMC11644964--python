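"""Hyperparameter search: Gaussian-process Bayesian optimization + random
search baseline.

The search space per architecture:

=========  =======================  ==========  ==========================  ==============  ========
model      units                    dropout     reg_rate                    filters         kernel
=========  =======================  ==========  ==========================  ==============  ========
gru/lstm   50…500 step 10           0.1…0.9     {0.01, 0.05, 0.005, 0.001}  —               —
cnn        50…500 step 10           0.1…0.9     {0.01, 0.05, 0.005, 0.001}  {200, 128, 250}  {3, 4}
hybrids    (50…500 step 10) × 2     0.1…0.9     {0.01, 0.05, 0.005, 0.001}  {200, 128, 250}  {3, 4}
=========  =======================  ==========  ==========================  ==============  ========

Bayesian optimization fits a Gaussian-process surrogate (Matern 5/2) to the
trials evaluated so far — integer dimensions scaled to [0, 1], categoricals
one-hot — and proposes the next configuration by maximizing expected
improvement over a random candidate pool.  The objective for architecture
selection is validation RMSE (original units) on the chronologically last
quarter of the training partition, so the test set never leaks into tuning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .models import HyperParams, build_model, train
from .windowing import ScalerParams, SupervisedDataset, chronological_split

__all__ = [
    "SearchSpace",
    "TrialRecord",
    "HpoResult",
    "sample_space",
    "random_search",
    "bayes_optimize",
    "select_architecture",
]

_REG_RATES = (0.01, 0.05, 0.005, 0.001)
_FILTERS = (200, 128, 250)
_KERNELS = (3, 4)


@dataclass(frozen=True)
class SearchSpace:
    """Declarative mixed search space for one architecture.

    ``units_ranges`` holds one ``(lo, hi, step)`` inclusive integer range per
    units dimension (two for hybrids).  ``dropout_range`` is a continuous
    interval; the remaining dimensions are categorical choices.
    """

    model_kind: str
    lag: int
    units_ranges: tuple[tuple[int, int, int], ...] = ((50, 500, 10),)
    dropout_range: tuple[float, float] = (0.1, 0.9)
    reg_rate_choices: tuple[float, ...] = _REG_RATES
    filters_choices: tuple[int, ...] | None = None
    kernel_choices: tuple[int, ...] | None = None

    @classmethod
    def for_kind(cls, kind: str, lag: int) -> "SearchSpace":
        conv = kind in ("cnn", "cnn_lstm", "cnn_gru")
        n_units = 2 if kind in ("cnn_lstm", "cnn_gru") else 1
        kernels = tuple(k for k in _KERNELS if k <= lag) if conv else None
        if conv and not kernels:
            raise ValueError(f"no valid kernel fits lag={lag}")
        return cls(
            model_kind=kind,
            lag=lag,
            units_ranges=((50, 500, 10),) * n_units,
            filters_choices=_FILTERS if conv else None,
            kernel_choices=kernels,
        )

    def sample(self, rng: np.random.Generator) -> HyperParams:
        units = tuple(
            int(lo + rng.integers((hi - lo) // st + 1) * st)
            for lo, hi, st in self.units_ranges
        )
        kw: dict = {}
        if self.filters_choices:
            kw["filters"] = int(rng.choice(self.filters_choices))
            kw["kernel"] = int(rng.choice(self.kernel_choices))
        return HyperParams(
            model_kind=self.model_kind,
            units=units,
            lag=self.lag,
            dropout=float(rng.uniform(*self.dropout_range)),
            reg_rate=float(self.reg_rate_choices[
                rng.integers(len(self.reg_rate_choices))
            ]),
            **kw,
        )

    def contains(self, hp: HyperParams) -> bool:
        if hp.model_kind != self.model_kind or hp.lag != self.lag:
            return False
        if len(hp.units) != len(self.units_ranges):
            return False
        for u, (lo, hi, st) in zip(hp.units, self.units_ranges):
            if not (lo <= u <= hi and (u - lo) % st == 0):
                return False
        if not (self.dropout_range[0] <= hp.dropout <= self.dropout_range[1]):
            return False
        if hp.reg_rate not in self.reg_rate_choices:
            return False
        if self.filters_choices:
            if hp.filters not in self.filters_choices:
                return False
            if hp.kernel not in self.kernel_choices:
                return False
        return True

    # --- numeric encoding for the GP surrogate -------------------------
    def encode(self, hp: HyperParams) -> np.ndarray:
        feats: list[float] = []
        for u, (lo, hi, _st) in zip(hp.units, self.units_ranges):
            feats.append((u - lo) / max(hi - lo, 1))
        lo, hi = self.dropout_range
        feats.append((hp.dropout - lo) / (hi - lo) if hi > lo else 0.0)
        feats.extend(
            1.0 if hp.reg_rate == c else 0.0 for c in self.reg_rate_choices
        )
        if self.filters_choices:
            feats.extend(
                1.0 if hp.filters == c else 0.0 for c in self.filters_choices
            )
            feats.extend(
                1.0 if hp.kernel == c else 0.0 for c in self.kernel_choices
            )
        return np.array(feats)


@dataclass(frozen=True)
class TrialRecord:
    hyperparams: HyperParams
    objective: float  # validation RMSE, original units; NaN = failed trial
    seed: int = 0
    epoch_count: int = 0

    @property
    def failed(self) -> bool:
        return not math.isfinite(self.objective)


@dataclass
class HpoResult:
    best: TrialRecord
    trials: list[TrialRecord]
    space: SearchSpace

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "model_kind": self.space.model_kind,
            "best": _trial_dict(self.best),
            "trials": [_trial_dict(t) for t in self.trials],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _trial_dict(t: TrialRecord) -> dict:
    from dataclasses import asdict

    return {
        "hyperparams": asdict(t.hyperparams),
        "objective": None if t.failed else t.objective,
        "seed": t.seed,
        "epoch_count": t.epoch_count,
    }


def sample_space(space: SearchSpace, seed: int) -> HyperParams:
    """One uniform draw per dimension; deterministic under ``seed``."""
    return space.sample(np.random.default_rng(seed))


def _finish(trials: list[TrialRecord], space: SearchSpace) -> HpoResult:
    ok = [t for t in trials if not t.failed]
    if not ok:
        raise RuntimeError("all hyperparameter trials failed")
    best = min(ok, key=lambda t: t.objective)
    return HpoResult(best=best, trials=trials, space=space)


def random_search(
    objective: Callable[[HyperParams], float],
    space: SearchSpace,
    n_trials: int,
    seed: int = 0,
) -> HpoResult:
    """Uniform-random baseline at the same trial budget."""
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(int(n_trials)):
        hp = space.sample(rng)
        trials.append(TrialRecord(hp, _safe_eval(objective, hp), seed=seed))
    return _finish(trials, space)


def _safe_eval(objective, hp) -> float:
    try:
        val = float(objective(hp))
    except (ArithmeticError, RuntimeError):
        return float("nan")
    return val


def bayes_optimize(
    objective: Callable[[HyperParams], float],
    space: SearchSpace,
    n_trials: int = 20,
    n_initial: int = 5,
    seed: int = 0,
    n_candidates: int = 256,
    xi: float = 0.01,
) -> HpoResult:
    """Sequential model-based optimization with a GP surrogate and expected
    improvement.

    ``n_initial`` random trials seed the surrogate; each subsequent trial
    maximizes EI over ``n_candidates`` random draws from the space (already
    evaluated configurations are skipped).  Failed (NaN) trials are recorded
    but excluded from the surrogate.
    """
    if n_initial < 2:
        raise ValueError("n_initial must be at least 2")
    if n_trials < n_initial:
        raise ValueError("n_trials must be >= n_initial")
    import warnings

    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    seen: set = set()

    def record(hp: HyperParams) -> None:
        trials.append(TrialRecord(hp, _safe_eval(objective, hp), seed=seed))
        seen.add(hp)

    def draw_fresh() -> HyperParams:
        # avoid re-evaluating configurations; give up after enough attempts
        # (the space may simply be exhausted at small discrete sizes)
        for _ in range(200):
            hp = space.sample(rng)
            if hp not in seen:
                return hp
        return space.sample(rng)

    for _ in range(int(n_initial)):
        record(draw_fresh())

    kernel = ConstantKernel(1.0) * Matern(nu=2.5) + WhiteKernel(
        noise_level=1e-6, noise_level_bounds=(1e-10, 1e1)
    )
    while len(trials) < n_trials:
        ok = [t for t in trials if not t.failed]
        if len(ok) < 2:
            record(draw_fresh())
            continue
        X = np.array([space.encode(t.hyperparams) for t in ok])
        y = np.array([t.objective for t in ok])
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(X, y)
        candidates = [space.sample(rng) for _ in range(n_candidates)]
        fresh: list[HyperParams] = []
        local: set = set()
        for c in candidates:  # order-stable dedup keeps runs reproducible
            if c not in seen and c not in local:
                fresh.append(c)
                local.add(c)
        if not fresh:
            record(draw_fresh())
            continue
        Xc = np.array([space.encode(c) for c in fresh])
        mu, sd = gp.predict(Xc, return_std=True)
        best_y = y.min()
        with np.errstate(divide="ignore", invalid="ignore"):
            imp = best_y - mu - xi
            zscore = imp / sd
            ei = imp * norm.cdf(zscore) + sd * norm.pdf(zscore)
            ei[sd <= 0] = 0.0
        record(fresh[int(np.argmax(ei))])
    return _finish(trials, space)


def select_architecture(
    train_scaled: SupervisedDataset,
    scaler: ScalerParams,
    model_kind: str,
    space: SearchSpace | None = None,
    n_trials: int = 20,
    n_initial: int = 5,
    epochs: int = 20,
    batch_size: int = 1,
    seed: int = 0,
    val_fraction: float = 0.25,
) -> HpoResult:
    """Tune one architecture; objective = validation RMSE in mmol/L.

    The validation set is the chronologically final ``val_fraction`` of the
    training partition, so tuning never touches test data.
    """
    from .evaluation import rmse as _rmse

    space = space or SearchSpace.for_kind(model_kind, train_scaled.lag)
    fit_part, val_part = chronological_split(train_scaled, 1.0 - val_fraction)
    y_val_orig = scaler.inverse(val_part.y)

    def objective(hp: HyperParams) -> float:
        model = build_model(hp, seed=seed)
        fitted = train(
            model, fit_part, epochs=epochs, batch_size=batch_size, seed=seed
        )
        return _rmse(y_val_orig, fitted.predict(val_part.X))

    return bayes_optimize(
        objective, space, n_trials=n_trials, n_initial=n_initial, seed=seed
    )
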