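"""Synthetic CGM trace generator.

Emulates the structure of a single-patient type-1-diabetes CGM export:
~15-minute sampling, values in a physiological 2–25 mmol/L band, a circadian
drift, meal excursions that rise instantly and decay exponentially, and
autocorrelated (AR(1)) sensor noise.  The generator makes every other module
testable without any external dataset.

The signal model, per reading at clock time t:

    value(t) = clamp( baseline
                      + circadian_amplitude * sin(2*pi*(t - 6h)/24h)
                      + sum_meals A_m * exp(-(t - t_m)/tau)   for t >= t_m
                      + e(t),
                      floor, ceiling )

with e(t) = ar_coefficient * e(t-1) + N(0, noise_sd^2) innovations, and meal
amplitudes A_m drawn log-normally with the configured mean/sd (in mmol/L).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import GlucoseSeries

__all__ = ["CgmSimParams", "SimParamsError", "generate_cgm", "inject_gaps"]

_DEFAULT_MEALS = ("07:30", "12:30", "19:00")
_DEFAULT_START = "2020-11-02T00:00"


class SimParamsError(ValueError):
    """A simulation parameter violates its constraint; names the field."""


@dataclass(frozen=True)
class CgmSimParams:
    """Parameters of the synthetic CGM signal model (units: mmol/L, minutes)."""

    n_points: int = 2000
    interval_minutes: float = 15.0
    baseline: float = 7.0
    circadian_amplitude: float = 0.8
    meal_times: Sequence[str] = _DEFAULT_MEALS
    meal_amplitude_mean: float = 4.0
    meal_amplitude_sd: float = 1.0
    meal_decay_minutes: float = 90.0
    noise_sd: float = 0.25
    ar_coefficient: float = 0.7
    floor: float = 2.0
    ceiling: float = 25.0
    seed: int = 0
    start_time: str = field(default=_DEFAULT_START)

    def validate(self) -> None:
        if self.n_points < 1:
            raise SimParamsError("n_points must be a positive integer")
        if self.interval_minutes <= 0:
            raise SimParamsError("interval_minutes must be positive")
        if not (self.floor < self.baseline < self.ceiling):
            raise SimParamsError(
                "baseline must lie strictly between floor and ceiling"
            )
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise SimParamsError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0:
            raise SimParamsError("noise_sd must be nonnegative")
        if self.meal_decay_minutes <= 0:
            raise SimParamsError("meal_decay_minutes must be positive")
        if self.meal_amplitude_mean < 0 or self.meal_amplitude_sd < 0:
            raise SimParamsError(
                "meal_amplitude_mean and meal_amplitude_sd must be nonnegative"
            )
        if self.floor <= 0:
            raise SimParamsError("floor must be positive (glucose in mmol/L)")
        for t in self.meal_times:
            _parse_clock(t)


def _parse_clock(text: str) -> float:
    """Clock time 'HH:MM' -> minutes past midnight."""
    try:
        h, m = text.split(":")
        h_i, m_i = int(h), int(m)
    except (ValueError, AttributeError) as exc:
        raise SimParamsError(f"meal_times entry {text!r} is not 'HH:MM'") from exc
    if not (0 <= h_i < 24 and 0 <= m_i < 60):
        raise SimParamsError(f"meal_times entry {text!r} is not a valid clock time")
    return 60.0 * h_i + m_i


def generate_cgm(params: CgmSimParams) -> GlucoseSeries:
    """Generate a deterministic (seeded) synthetic CGM series.

    Identical ``params`` (including ``seed``) give an element-wise identical
    series.  All emitted values are clamped to ``[floor, ceiling]``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_points
    step = np.timedelta64(int(round(params.interval_minutes * 60)), "s")
    start = np.datetime64(params.start_time, "ns")
    timestamps = start + np.arange(n) * step

    # minutes since the series start, and minutes-past-midnight of each sample
    t_min = np.arange(n) * params.interval_minutes
    start_dt = timestamps[0].astype("datetime64[m]").astype(_dt.datetime)
    start_mpm = start_dt.hour * 60.0 + start_dt.minute
    clock = (start_mpm + t_min) % 1440.0

    # circadian term: sinusoid with a 24 h period, trough near 03:00
    circ = params.circadian_amplitude * np.sin(
        2.0 * np.pi * (clock - 6.0 * 60.0) / 1440.0
    )

    # meal excursions: instantaneous rise at each scheduled meal, exp decay
    meals = np.zeros(n)
    day_span = int(np.ceil((start_mpm + t_min[-1]) / 1440.0)) + 1
    for clock_txt in params.meal_times:
        mpm = _parse_clock(clock_txt)
        for day in range(day_span):
            onset = day * 1440.0 + mpm - start_mpm  # minutes from series start
            if onset > t_min[-1]:
                break
            if params.meal_amplitude_sd > 0:
                mu = np.log(
                    params.meal_amplitude_mean**2
                    / np.sqrt(params.meal_amplitude_mean**2 + params.meal_amplitude_sd**2)
                ) if params.meal_amplitude_mean > 0 else -np.inf
                sig = np.sqrt(
                    np.log(1.0 + params.meal_amplitude_sd**2 / params.meal_amplitude_mean**2)
                ) if params.meal_amplitude_mean > 0 else 0.0
                amp = float(rng.lognormal(mu, sig)) if np.isfinite(mu) else 0.0
            else:
                amp = params.meal_amplitude_mean
            mask = t_min >= onset
            meals[mask] += amp * np.exp(
                -(t_min[mask] - onset) / params.meal_decay_minutes
            )

    # AR(1) sensor noise
    noise = np.zeros(n)
    if params.noise_sd > 0:
        innov = rng.normal(0.0, params.noise_sd, size=n)
        e = 0.0
        for i in range(n):
            e = params.ar_coefficient * e + innov[i]
            noise[i] = e

    values = np.clip(
        params.baseline + circ + meals + noise, params.floor, params.ceiling
    )
    return GlucoseSeries(timestamps, values)


def inject_gaps(
    series: GlucoseSeries, gap_spans: Sequence[tuple[int, int]]
) -> GlucoseSeries:
    """Remove the readings in the given inclusive index ranges.

    Remaining timestamps are unchanged (and therefore still strictly
    increasing); this is how irregular sampling and sensor dropouts are
    emulated.  Ranges are inclusive ``(start, stop)`` index pairs.
    """
    n = len(series)
    drop = np.zeros(n, dtype=bool)
    for span in gap_spans:
        lo, hi = int(span[0]), int(span[1])
        if lo < 0 or hi >= n or lo > hi:
            raise IndexError(
                f"gap span ({lo}, {hi}) out of range for series of length {n}"
            )
        drop[lo : hi + 1] = True
    if drop.all():
        raise IndexError("gap spans would remove every reading")
    keep = ~drop
    return GlucoseSeries(series.timestamps[keep], series.values[keep])
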