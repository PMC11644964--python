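"""Compare all five architectures across forecasting scenarios.

Each scenario pairs a window length (lag, in samples) with a forecast
distance (horizon, in steps); the canonical grid is labelled by its
minutes-ahead names.  For speed this demo uses two short scenarios, two
epochs and small fixed configurations; the full experiment uses the
default grid, 20 epochs, and per-scenario Bayesian tuning
(hpo_config={"n_trials": 20, "n_initial": 5}).
"""

from gluforecast import CgmSimParams, HyperParams, generate_cgm, run_scenario
from gluforecast.evaluation import format_report_table, report_to_csv
from gluforecast.windowing import ScenarioGrid

series = generate_cgm(CgmSimParams(n_points=500, seed=1))

fast_configs = {
    "gru": HyperParams("gru", (12,), 10),
    "lstm": HyperParams("lstm", (12,), 10),
    "cnn": HyperParams("cnn", (12,), 10, filters=8, kernel=3),
    "cnn_lstm": HyperParams("cnn_lstm", (12, 8), 10, filters=8, kernel=3),
    "cnn_gru": HyperParams("cnn_gru", (12, 8), 10, filters=8, kernel=3),
}

reports = run_scenario(
    series,
    grid=ScenarioGrid(((10, 1), (10, 4))),
    model_kinds=list(fast_configs),
    hyperparams=fast_configs,
    epochs=2,
    seed=0,
)

for report in reports:
    print(format_report_table(report))
    print()
# each table row is one model's test RMSE/MAE in mmol/L for that scenario
# (lower is better); "persistence" is the naive last-value anchor every
# learned model should undercut

report_to_csv(reports, "scenario_reports.csv")
print("flat results written to scenario_reports.csv")
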