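"""Bayesian hyperparameter search for a CNN-GRU on synthetic data.

A Gaussian-process surrogate with expected improvement proposes each trial;
the objective is validation RMSE (mmol/L) on the chronologically last
quarter of the training partition.  A small custom space keeps this demo
fast — SearchSpace.for_kind() gives the full canonical space (units
50-500 step 10, dropout 0.1-0.9, reg rates {0.01, 0.05, 0.005, 0.001},
filters {200, 128, 250}, kernels {3, 4}).
"""

from gluforecast import CgmSimParams, generate_cgm, supervised_sets
from gluforecast.hpo import SearchSpace, select_architecture

series = generate_cgm(CgmSimParams(n_points=300, seed=3))
train_scaled, _test, scaler = supervised_sets(series, lag := 5, horizon := 1)

space = SearchSpace(
    model_kind="cnn_gru", lag=lag,
    units_ranges=((8, 32, 8), (4, 16, 4)),
    dropout_range=(0.1, 0.4),
    filters_choices=(4, 8), kernel_choices=(3,),
)
result = select_architecture(
    train_scaled, scaler, "cnn_gru", space,
    n_trials=8, n_initial=3, epochs=5, seed=0,
)

print(f"{len(result.trials)} trials; validation RMSE per trial (mmol/L):")
for t in result.trials:
    marker = " <- best" if t is result.best else ""
    print(f"  units={t.hyperparams.units} dropout={t.hyperparams.dropout:.2f}"
          f" filters={t.hyperparams.filters}: {t.objective:.3f}{marker}")
print(f"best configuration: {result.best.hyperparams}")
# the best trial's RMSE is the minimum of the column above; after the 3
# random warm-up trials the surrogate steers sampling toward that region
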