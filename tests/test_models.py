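"""Architecture contracts, training behaviour, persistence of fitted models."""

import numpy as np
import pytest

import gluforecast as gf
from gluforecast.models import MODEL_KINDS, TrainingDivergenceError
from gluforecast.nn.recurrent import GRULayer, LSTMLayer
from gluforecast.windowing import ScalerParams, SupervisedDataset


def make_hp(kind, lag=10, units=None):
    if kind in ("cnn_gru", "cnn_lstm"):
        return gf.HyperParams(kind, units or (12, 8), lag, filters=8, kernel=3)
    if kind == "cnn":
        return gf.HyperParams(kind, units or (12,), lag, filters=8, kernel=3)
    return gf.HyperParams(kind, units or (12,), lag)


def scaled_dataset(values, lag=10, horizon=1):
    ds = gf.to_supervised(np.asarray(values, dtype=float), lag, horizon)
    scaler = ScalerParams(float(np.min(values)) - 1e-9,
                          float(np.max(values)) + 1e-9)
    return gf.apply_scaler(ds, scaler)


class TestHyperParamsValidation:
    def test_kernel_exceeding_lag_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            gf.HyperParams("cnn_gru", (12, 8), lag=2, filters=8, kernel=3)

    def test_single_models_take_no_conv_params(self):
        with pytest.raises(ValueError):
            gf.HyperParams("gru", (50,), 10, filters=128, kernel=3)

    def test_hybrids_require_two_unit_dims(self):
        with pytest.raises(ValueError):
            gf.HyperParams("cnn_gru", (150,), 10, filters=128, kernel=3)

    def test_gru_config_has_no_conv_fields(self):
        hp = gf.HyperParams("gru", (50,), 10)
        assert hp.filters is None and hp.kernel is None


class TestArchitectureContract:
    @pytest.mark.parametrize("kind,expected", [
        ("gru", ["gru", "output"]),
        ("lstm", ["lstm", "output"]),
        ("cnn", ["conv1d", "maxpool", "flatten", "dense", "output"]),
        ("cnn_lstm", ["conv1d", "maxpool", "lstm", "flatten", "dense",
                      "output"]),
        ("cnn_gru", ["conv1d", "maxpool", "gru", "flatten", "dense",
                     "output"]),
    ])
    def test_stage_sequences(self, kind, expected):
        model = gf.build_model(make_hp(kind), seed=0)
        assert model.stages == expected

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_window_in_scalar_out(self, kind):
        model = gf.build_model(make_hp(kind), seed=0)
        out = model.predict_scaled(np.random.default_rng(0).random((4, 10)))
        assert out.shape == (4,)
        assert np.all(np.isfinite(out))

    def test_width_mismatch_rejected(self):
        model = gf.build_model(make_hp("cnn_gru"), seed=0)
        with pytest.raises(ValueError, match="lag"):
            model.predict_scaled(np.zeros((2, 7)))

    def test_parameter_count_monotone_in_units_and_filters(self):
        base = gf.build_model(make_hp("cnn_gru", units=(12, 8)), seed=0)
        wider = gf.build_model(make_hp("cnn_gru", units=(24, 8)), seed=0)
        assert wider.n_params > base.n_params
        more_filters = gf.build_model(
            gf.HyperParams("cnn_gru", (12, 8), 10, filters=16, kernel=3),
            seed=0,
        )
        assert more_filters.n_params > base.n_params

    def test_shortest_lag_survives_conv_stack(self):
        hp = gf.HyperParams("cnn_gru", (8, 4), lag=3, filters=4, kernel=3)
        model = gf.build_model(hp, seed=0)
        assert model.predict_scaled(np.array([[0.1, 0.5, 0.2]])).shape == (1,)


class TestGateRanges:
    @pytest.mark.parametrize("cell_cls,gates", [
        (GRULayer, ("z", "r")),
        (LSTMLayer, ("f", "i", "o")),
    ])
    def test_sigmoid_gates_in_unit_interval(self, cell_cls, gates):
        rng = np.random.default_rng(1)
        layer = cell_cls(3, 8)
        layer.init(rng)
        layer.forward(rng.normal(scale=3.0, size=(20, 3)))
        for cache in layer.caches:
            for g in gates:
                assert np.all(cache[g] > 0.0) and np.all(cache[g] < 1.0)

    def test_tanh_candidate_bounded(self):
        rng = np.random.default_rng(2)
        layer = GRULayer(2, 6, activation="tanh")
        layer.init(rng)
        layer.forward(rng.normal(scale=3.0, size=(15, 2)))
        for cache in layer.caches:
            assert np.all(np.abs(cache["h_cand"]) < 1.0)

    def test_relu_candidate_nonnegative(self):
        rng = np.random.default_rng(3)
        layer = GRULayer(2, 6, activation="relu")
        layer.init(rng)
        layer.forward(rng.normal(scale=3.0, size=(15, 2)))
        for cache in layer.caches:
            assert np.all(cache["h_cand"] >= 0.0)


class TestTraining:
    def test_zero_epochs_is_untrained_noop(self):
        ds = scaled_dataset(np.linspace(4, 10, 30))
        model = gf.build_model(make_hp("gru"), seed=0)
        before = {k: v.copy() for k, v in model.net.get_weights().items()}
        fitted = gf.train(model, ds, epochs=0, seed=0)
        assert fitted.history == []
        after = model.net.get_weights()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_constant_target_loss_decreases(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 10))
        ds = SupervisedDataset(X, np.full(40, 0.5), 10, 1, scaled=True,
                               scaler=ScalerParams(0.0, 1.0))
        model = gf.build_model(make_hp("cnn_gru"), seed=0)
        fitted = gf.train(model, ds, epochs=5, seed=0)
        assert fitted.history[-1] <= fitted.history[0]

    def test_unscaled_dataset_rejected(self):
        ds = gf.to_supervised(np.linspace(4, 10, 30), 10, 1)
        model = gf.build_model(make_hp("gru"), seed=0)
        with pytest.raises(ValueError, match="scaled"):
            gf.train(model, ds, epochs=1)

    def test_training_determinism(self):
        ds = scaled_dataset(np.sin(np.arange(60) / 5.0) + 2.0)
        runs = []
        for _ in range(2):
            model = gf.build_model(make_hp("cnn_lstm"), seed=3)
            fitted = gf.train(model, ds, epochs=3, seed=3)
            runs.append((fitted.history, fitted.predict(ds.X[:5])))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_divergence_raises_with_epoch(self):
        ds = scaled_dataset(np.linspace(4, 10, 30))
        model = gf.build_model(make_hp("gru"), seed=0)
        # absurd learning rate drives ReLU-recurrent training to overflow
        with pytest.raises(TrainingDivergenceError, match="epoch"):
            with np.errstate(all="ignore"):
                gf.train(model, ds, epochs=5, seed=0, lr=1e160)


class TestPrediction:
    def test_inference_repeatable_despite_dropout_config(self):
        ds = scaled_dataset(np.linspace(4, 10, 40))
        hp = gf.HyperParams("cnn_gru", (12, 8), 10, dropout=0.5, filters=8,
                            kernel=3)
        fitted = gf.train(gf.build_model(hp, seed=0), ds, epochs=2, seed=0)
        a = fitted.predict(ds.X)
        b = fitted.predict(ds.X)
        np.testing.assert_array_equal(a, b)

    def test_single_window_single_forecast(self):
        ds = scaled_dataset(np.linspace(4, 10, 40))
        fitted = gf.train(gf.build_model(make_hp("gru"), seed=0), ds,
                          epochs=1, seed=0)
        assert fitted.predict(ds.X[0]).shape == (1,)

    def test_predictions_in_original_units(self):
        values = np.linspace(4, 10, 40)
        ds = scaled_dataset(values)
        fitted = gf.train(gf.build_model(make_hp("gru"), seed=0), ds,
                          epochs=10, seed=0)
        preds = fitted.predict(ds.X)
        # a fitted model's outputs live near the data's mmol/L range
        assert preds.mean() > 2.0


def test_save_load_round_trip(tmp_path):
    values = np.sin(np.arange(80) / 6.0) * 2 + 7
    ds = gf.to_supervised(values, 10, 1)
    scaler = gf.fit_scaler(ds)
    scaled = gf.apply_scaler(ds, scaler)
    hp = gf.HyperParams("cnn_gru", (12, 8), 10, filters=8, kernel=3)
    fitted = gf.train(gf.build_model(hp, seed=5), scaled, epochs=2, seed=5)
    gf.save_forecaster(fitted, tmp_path / "bundle")
    loaded = gf.load_forecaster(tmp_path / "bundle")
    assert loaded.hp == hp
    assert loaded.history == fitted.history
    np.testing.assert_array_equal(loaded.predict(scaled.X),
                                  fitted.predict(scaled.X))
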