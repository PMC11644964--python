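"""CSV input/output for CGM series plus the packaged 12-row sample trace.

The on-disk dialect is a two-column CSV, header ``Time,BGL``, with
month/day/year timestamps on a 24-hour clock without zero padding
(``11/2/2020 20:23``) and glucose in mmol/L.  Reading validates the series
invariants (strictly increasing timestamps, positive finite values); rows
that arrive out of order are re-sorted with a counted warning, while
duplicate timestamps are an error — silent aggregation would hide sensor
faults.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .series import GlucoseSeries, SeriesValidationError

__all__ = [
    "CsvParseError",
    "read_cgm_csv",
    "write_cgm_csv",
    "write_jsonl",
    "read_jsonl",
    "table1_fixture",
    "DEFAULT_TIMESTAMP_FORMAT",
]

DEFAULT_TIMESTAMP_FORMAT = "%m/%d/%Y %H:%M"

# 12-row single-patient sample used as the canonical tiny fixture; mmol/L.
_SAMPLE_ROWS = [
    ("11/2/2020 20:23", 8.9),
    ("11/3/2020 19:53", 6.5),
    ("11/3/2020 20:08", 7.4),
    ("11/3/2020 20:23", 7.8),
    ("11/3/2020 20:39", 8.2),
    ("11/3/2020 20:54", 8.7),
    ("11/3/2020 21:08", 9.4),
    ("11/3/2020 21:23", 8.3),
    ("11/3/2020 21:38", 7.4),
    ("11/3/2020 21:55", 7.1),
    ("11/3/2020 22:10", 8.3),
    ("11/3/2020 22:25", 9.5),
]


class CsvParseError(ValueError):
    """Unparseable row (reported with its 1-based data row number)."""


def table1_fixture() -> GlucoseSeries:
    """The packaged 12-reading sample CGM trace (values 8.9 … 9.5 mmol/L).

    Note the day-long gap between the first two readings — real CGM exports
    are irregular, and downstream code must tolerate that.
    """
    ts = pd.to_datetime(
        [t for t, _ in _SAMPLE_ROWS], format=DEFAULT_TIMESTAMP_FORMAT
    )
    vals = np.array([v for _, v in _SAMPLE_ROWS])
    return GlucoseSeries(ts.values, vals)


def read_cgm_csv(
    path: str | Path,
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT,
) -> GlucoseSeries:
    """Read a two-column (Time, BGL) CSV into a validated series.

    A header row is optional.  Out-of-order rows are re-sorted; one
    ``UserWarning`` reports how many rows were out of order.  Duplicate
    timestamps raise :class:`~gluforecast.series.SeriesValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, header=None, names=["Time", "BGL"], dtype=str,
                     skip_blank_lines=True)
    if len(df) and str(df.iloc[0, 0]).strip().lower() == "time":
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) == 0:
        raise CsvParseError(f"no records in {path}")

    timestamps = np.empty(len(df), dtype="datetime64[ns]")
    values = np.empty(len(df))
    for i, (t_raw, v_raw) in enumerate(zip(df["Time"], df["BGL"])):
        row = i + 1
        t_txt = "" if t_raw is None else str(t_raw).strip()
        try:
            ts = pd.to_datetime(t_txt, format=timestamp_format)
        except (ValueError, TypeError):
            try:  # tolerate an explicit seconds field
                ts = pd.to_datetime(t_txt, format=timestamp_format + ":%S")
            except (ValueError, TypeError) as exc:
                raise CsvParseError(
                    f"row {row}: unparseable timestamp {t_txt!r}"
                ) from exc
        try:
            values[i] = float(v_raw)
        except (ValueError, TypeError) as exc:
            raise CsvParseError(
                f"row {row}: non-numeric glucose value {v_raw!r}"
            ) from exc
        timestamps[i] = ts.to_datetime64()

    order = np.argsort(timestamps, kind="stable")
    n_out_of_order = int(np.sum(order != np.arange(len(order))))
    if n_out_of_order:
        warnings.warn(
            f"{n_out_of_order} rows out of chronological order; re-sorted",
            UserWarning,
            stacklevel=2,
        )
        timestamps, values = timestamps[order], values[order]
    if len(timestamps) > 1 and np.any(np.diff(timestamps.astype("int64")) == 0):
        raise SeriesValidationError(f"duplicate timestamps in {path}")
    return GlucoseSeries(timestamps, values)


def _format_timestamp(ts: np.datetime64) -> str:
    t = pd.Timestamp(ts)
    base = f"{t.month}/{t.day}/{t.year} {t.hour}:{t.minute:02d}"
    return base + (f":{t.second:02d}" if t.second else "")


def write_cgm_csv(series: GlucoseSeries, path: str | Path) -> Path:
    """Write the series in the Time,BGL dialect; round-trips exactly through
    :func:`read_cgm_csv` for minute- or second-aligned series."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Time,BGL\n")
        for ts, v in zip(series.timestamps, series.values):
            fh.write(f"{_format_timestamp(ts)},{float(v)!r}\n")
    return path


def write_jsonl(series: GlucoseSeries, path: str | Path) -> Path:
    """JSON-lines export (one ``{"time": iso8601, "bgl": value}`` per line)
    for streaming sinks and replay."""
    path = Path(path)
    with open(path, "w") as fh:
        for ts, v in zip(series.timestamps, series.values):
            fh.write(
                json.dumps({"time": pd.Timestamp(ts).isoformat(), "bgl": v}) + "\n"
            )
    return path


def read_jsonl(path: str | Path) -> GlucoseSeries:
    times, vals = [], []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                times.append(pd.Timestamp(rec["time"]))
                vals.append(float(rec["bgl"]))
    if not times:
        raise CsvParseError(f"no records in {path}")
    return GlucoseSeries(pd.DatetimeIndex(times).values, np.array(vals))
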