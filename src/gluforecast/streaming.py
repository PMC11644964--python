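"""Online forecasting pipeline: sensor source → broker → sliding window →
model → JSONL sink.

The pipeline is broker-agnostic: any object satisfying the
:class:`InProcessBroker` publish/subscribe contract (per-topic FIFO,
at-least-once delivery to every subscriber) can carry events.  The bundled
in-process broker is loss-free and FIFO, which makes the core invariant
checkable: events in = forecasts out + (lag − 1) warm-up + rejected +
duplicate + out-of-order counts.

Streamed forecasts are element-wise identical (to float tolerance) to batch
predictions over the same windows — the stream consumer maintains a
fixed-capacity :class:`WindowBuffer` of the most recent ``lag`` readings,
scales them with the model's training scaler, and emits one forecast per
event once the buffer is full.
"""

from __future__ import annotations

import json
import time
from collections import deque
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .models import TrainedForecaster
from .series import GlucoseSeries
from .synthetic import CgmSimParams, generate_cgm

__all__ = [
    "StreamEvent",
    "ForecastRecord",
    "InProcessBroker",
    "BrokerClosedError",
    "WindowBuffer",
    "StreamForecaster",
    "sensor_source",
    "stream_forecast",
    "sink_writer",
    "read_sink",
]


@dataclass(frozen=True)
class StreamEvent:
    """One sensor reading in flight."""

    timestamp: pd.Timestamp
    value: float  # mmol/L
    source_id: str = "cgm-sensor"
    sequence_number: int = 0


@dataclass(frozen=True)
class ForecastRecord:
    """One emitted forecast with its provenance and latency."""

    event_timestamp: str  # ISO-8601 of the triggering event
    forecast: float  # mmol/L, clamped at 0 on output
    horizon: int
    model_id: str
    sequence_number: int
    latency_ms: float


class BrokerClosedError(RuntimeError):
    pass


class _Subscription:
    def __init__(self) -> None:
        self._queue: deque = deque()

    def poll(self):
        return self._queue.popleft() if self._queue else None

    def drain(self) -> list:
        out = list(self._queue)
        self._queue.clear()
        return out

    def __iter__(self):
        while self._queue:
            yield self._queue.popleft()


class InProcessBroker:
    """Loss-free, per-topic FIFO publish/subscribe in one process.

    Every subscriber to a topic receives every event published after it
    subscribed, in publication order (fan-out).  Publishing or subscribing
    after :meth:`close` raises :class:`BrokerClosedError`.
    """

    def __init__(self) -> None:
        self._topics: dict[str, list[_Subscription]] = {}
        self._closed = False
        self.published: dict[str, int] = {}

    def _check_open(self) -> None:
        if self._closed:
            raise BrokerClosedError("broker is closed")

    def subscribe(self, topic: str) -> _Subscription:
        self._check_open()
        if not topic:
            raise ValueError("topic name must be nonempty")
        sub = _Subscription()
        self._topics.setdefault(topic, []).append(sub)
        return sub

    def publish(self, topic: str, event) -> None:
        self._check_open()
        if not topic:
            raise ValueError("topic name must be nonempty")
        self.published[topic] = self.published.get(topic, 0) + 1
        for sub in self._topics.get(topic, []):
            sub._queue.append(event)

    def close(self) -> None:
        self._closed = True


def sensor_source(
    source: GlucoseSeries | CgmSimParams,
    rate: float | None = None,
    seed: int = 0,
    source_id: str = "cgm-sensor",
) -> Iterator[StreamEvent]:
    """Yield StreamEvents in timestamp order.

    Replay mode (a :class:`GlucoseSeries`) emits exactly the series' points
    once; generator mode synthesizes a series from :class:`CgmSimParams`
    first (seeded, so two runs emit identical values).  ``rate`` throttles
    emission to that many events per second; ``None`` is unthrottled.
    """
    if isinstance(source, CgmSimParams):
        from dataclasses import replace

        source = generate_cgm(replace(source, seed=seed))
    for i, (ts, v) in enumerate(zip(source.timestamps, source.values)):
        if rate is not None and i:
            time.sleep(1.0 / rate)
        yield StreamEvent(
            timestamp=pd.Timestamp(ts),
            value=float(v),
            source_id=source_id,
            sequence_number=i,
        )


class WindowBuffer:
    """Fixed-capacity buffer of the most recent readings (capacity = lag).

    Emits a full window only once exactly ``capacity`` values are buffered;
    appending beyond capacity evicts the oldest reading.
    """

    def __init__(self, capacity: int) -> None:
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = int(capacity)
        self._values: deque = deque(maxlen=self.capacity)
        self.last_timestamp: pd.Timestamp | None = None

    def append(self, value: float, timestamp: pd.Timestamp) -> None:
        self._values.append(float(value))
        self.last_timestamp = timestamp

    @property
    def full(self) -> bool:
        return len(self._values) == self.capacity

    def window(self) -> np.ndarray:
        if not self.full:
            raise ValueError("buffer not yet full")
        return np.array(self._values)


class StreamForecaster:
    """Stateful stream consumer: dedupe, order-check, window, forecast.

    Policy: duplicate sequence numbers are dropped (counted); events older
    than the newest seen, beyond ``order_tolerance`` positions, are dropped
    (counted); nonpositive glucose values are quarantined to ``rejects``.
    Forecasts are clamped at 0 mmol/L on output.
    """

    def __init__(
        self,
        model: TrainedForecaster,
        horizon: int = 1,
        model_id: str | None = None,
        order_tolerance: int = 0,
    ) -> None:
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        self.model = model
        self.horizon = int(horizon)
        self.model_id = model_id or f"{model.hp.model_kind}-lag{model.lag}"
        self.order_tolerance = int(order_tolerance)
        self.buffer = WindowBuffer(model.lag)
        self.seen_sequences: set[int] = set()
        self.max_sequence = -1
        self.n_events = 0
        self.n_forecasts = 0
        self.n_duplicates = 0
        self.n_out_of_order = 0
        self.rejects: list[StreamEvent] = []

    def process(self, event: StreamEvent) -> ForecastRecord | None:
        t0 = time.perf_counter()
        self.n_events += 1
        if event.sequence_number in self.seen_sequences:
            self.n_duplicates += 1
            return None
        if event.sequence_number < self.max_sequence - self.order_tolerance:
            self.n_out_of_order += 1
            return None
        self.seen_sequences.add(event.sequence_number)
        self.max_sequence = max(self.max_sequence, event.sequence_number)
        if not (np.isfinite(event.value) and event.value > 0):
            self.rejects.append(event)
            return None
        self.buffer.append(event.value, event.timestamp)
        if not self.buffer.full:
            return None
        window_scaled = self.model.scaler.transform(self.buffer.window())
        forecast = float(self.model.predict(window_scaled[None, :])[0])
        self.n_forecasts += 1
        return ForecastRecord(
            event_timestamp=event.timestamp.isoformat(),
            forecast=max(0.0, forecast),
            horizon=self.horizon,
            model_id=self.model_id,
            sequence_number=event.sequence_number,
            latency_ms=(time.perf_counter() - t0) * 1e3,
        )

    def run(self, events: Iterable[StreamEvent]) -> Iterator[ForecastRecord]:
        for event in events:
            record = self.process(event)
            if record is not None:
                yield record


def stream_forecast(
    events: Iterable[StreamEvent],
    model: TrainedForecaster,
    horizon: int = 1,
    **kwargs,
) -> Iterator[ForecastRecord]:
    """Functional wrapper over :class:`StreamForecaster`."""
    yield from StreamForecaster(model, horizon=horizon, **kwargs).run(events)


def sink_writer(
    records: Iterable[ForecastRecord],
    path: str | Path,
    append: bool = False,
) -> Path:
    """Append-or-write ForecastRecords as JSON lines; an empty stream still
    creates the file."""
    path = Path(path)
    with open(path, "a" if append else "w") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec)) + "\n")
    return path


def read_sink(path: str | Path) -> list[ForecastRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                records.append(ForecastRecord(**json.loads(line)))
    return records
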