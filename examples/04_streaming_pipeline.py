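"""Online forecasting: replay a CGM trace through the streaming pipeline.

sensor source -> in-process broker topic -> sliding-window stream consumer
(window = the model's lag) -> one forecast per event once warmed up ->
JSONL sink.  Streamed forecasts are identical to batch predictions over
the same windows.
"""

from gluforecast import (
    CgmSimParams,
    HyperParams,
    InProcessBroker,
    StreamForecaster,
    build_model,
    generate_cgm,
    sensor_source,
    sink_writer,
    supervised_sets,
    train,
)

series = generate_cgm(CgmSimParams(n_points=400, seed=9))
lag = 5

train_scaled, _test, _scaler = supervised_sets(series.slice(0, 200), lag, 1)
hp = HyperParams("cnn_gru", (12, 8), lag, filters=8, kernel=3)
model = train(build_model(hp, seed=0), train_scaled, epochs=5, seed=0)

broker = InProcessBroker()
subscription = broker.subscribe("bgl-stream")
for event in sensor_source(series.slice(200, 400)):
    broker.publish("bgl-stream", event)

consumer = StreamForecaster(model, horizon=1)
records = list(consumer.run(subscription))
sink_writer(records, "forecasts.jsonl")

print(f"{consumer.n_events} events consumed -> {consumer.n_forecasts} "
      f"forecasts ({lag - 1} warm-up events before the window filled)")
print(f"first forecast: {records[0].forecast:.2f} mmol/L at "
      f"{records[0].event_timestamp} "
      f"(latency {records[0].latency_ms:.2f} ms)")
print("forecast log written to forecasts.jsonl (one JSON record per line)")
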