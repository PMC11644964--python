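"""Hyperparameter search: space membership, GP/EI optimizer, baselines."""

import numpy as np
import pytest

import gluforecast as gf
from gluforecast.hpo import SearchSpace, bayes_optimize, random_search, \
    sample_space


@pytest.fixture(scope="module")
def hybrid_space():
    return SearchSpace.for_kind("cnn_gru", lag=10)


def toy_space():
    """Tiny discrete space: 3 units values x 2 kernels, everything else
    pinned (6 configurations total)."""
    return SearchSpace(
        model_kind="cnn_gru",
        lag=10,
        units_ranges=((100, 300, 100), (50, 50, 10)),
        dropout_range=(0.2, 0.2),
        reg_rate_choices=(0.01,),
        filters_choices=(128,),
        kernel_choices=(3, 4),
    )


def toy_objective(hp):
    return (hp.units[0] - 200) ** 2 + 10 * abs(hp.kernel - 3)


class TestSampling:
    def test_degenerate_space_yields_single_config(self):
        space = SearchSpace(
            model_kind="gru", lag=5, units_ranges=((70, 70, 10),),
            dropout_range=(0.3, 0.3), reg_rate_choices=(0.005,),
        )
        hp = sample_space(space, seed=0)
        assert hp.units == (70,) and hp.dropout == 0.3
        assert hp.reg_rate == 0.005

    def test_seed_determinism(self, hybrid_space):
        assert sample_space(hybrid_space, 5) == sample_space(hybrid_space, 5)

    def test_categorical_supports(self, hybrid_space):
        rng = np.random.default_rng(0)
        draws = [hybrid_space.sample(rng) for _ in range(1000)]
        assert {hp.kernel for hp in draws} == {3, 4}
        assert {hp.reg_rate for hp in draws} == {0.01, 0.05, 0.005, 0.001}
        assert {hp.filters for hp in draws} == {200, 128, 250}

    def test_units_grid_and_dropout_range(self, hybrid_space):
        rng = np.random.default_rng(1)
        for hp in (hybrid_space.sample(rng) for _ in range(500)):
            for u in hp.units:
                assert 50 <= u <= 500 and (u - 50) % 10 == 0
            assert 0.1 <= hp.dropout <= 0.9
            assert hybrid_space.contains(hp)

    def test_kernel_capped_by_lag(self):
        space = SearchSpace.for_kind("cnn", lag=3)
        rng = np.random.default_rng(2)
        assert {space.sample(rng).kernel for _ in range(50)} == {3}


class TestBayesOptimize:
    def test_constant_objective(self):
        res = bayes_optimize(lambda hp: 4.2, toy_space(), n_trials=6,
                             n_initial=2, seed=0)
        assert res.best.objective == 4.2
        assert len(res.trials) == 6

    def test_exhaustive_budget_finds_global_minimum(self):
        """With budget = grid size the optimizer must match brute force."""
        space = toy_space()
        rng = np.random.default_rng(0)
        grid = {space.sample(rng) for _ in range(2000)}
        assert len(grid) == 6
        brute_best = min(toy_objective(hp) for hp in grid)
        res = bayes_optimize(toy_objective, space, n_trials=6, n_initial=3,
                             seed=1)
        assert res.best.objective == brute_best
        assert res.best.hyperparams.units[0] == 200
        assert res.best.hyperparams.kernel == 3

    def test_best_is_min_over_trials(self):
        res = bayes_optimize(toy_objective, toy_space(), n_trials=5,
                             n_initial=2, seed=3)
        assert res.best.objective == min(t.objective for t in res.trials)

    def test_monotone_best_so_far_under_shared_seed(self, hybrid_space):
        def cheap(hp):
            return (hp.units[0] - 270) ** 2 / 1e4 + hp.dropout

        objs = {}
        for n in (5, 10, 15):
            objs[n] = bayes_optimize(cheap, hybrid_space, n_trials=n,
                                     n_initial=5, seed=9).best.objective
        assert objs[10] <= objs[5]
        assert objs[15] <= objs[10]

    def test_all_proposals_inside_space(self, hybrid_space):
        def cheap(hp):
            return hp.dropout + hp.units[0] / 500

        res = bayes_optimize(cheap, hybrid_space, n_trials=12, n_initial=4,
                             seed=2)
        assert all(hybrid_space.contains(t.hyperparams) for t in res.trials)

    def test_nan_trials_excluded_from_best(self):
        calls = []

        def flaky(hp):
            calls.append(hp)
            return float("nan") if len(calls) % 2 else float(hp.units[0])

        res = bayes_optimize(flaky, toy_space(), n_trials=6, n_initial=2,
                             seed=0)
        assert np.isfinite(res.best.objective)
        assert sum(t.failed for t in res.trials) >= 1

    def test_all_failed_raises(self):
        with pytest.raises(RuntimeError, match="failed"):
            bayes_optimize(lambda hp: float("nan"), toy_space(), n_trials=4,
                           n_initial=2, seed=0)

    def test_budget_validation(self, hybrid_space):
        with pytest.raises(ValueError):
            bayes_optimize(lambda hp: 0.0, hybrid_space, n_trials=3,
                           n_initial=1)
        with pytest.raises(ValueError):
            bayes_optimize(lambda hp: 0.0, hybrid_space, n_trials=2,
                           n_initial=5)


def test_bayes_beats_random_in_median(hybrid_space):
    """Paired comparison at budget 20 over repeated seeds on a smooth toy
    objective; the GP should at least match random search's median."""
    def objective(hp):
        return ((hp.units[0] - 270) ** 2 + (hp.units[1] - 120) ** 2) / 1e4 \
            + 2.0 * abs(hp.dropout - 0.35)

    bayes, rand = [], []
    for seed in range(10):
        bayes.append(bayes_optimize(objective, hybrid_space, n_trials=20,
                                    n_initial=5, seed=seed).best.objective)
        rand.append(random_search(objective, hybrid_space, n_trials=20,
                                  seed=seed).best.objective)
    assert np.median(bayes) <= np.median(rand)


@pytest.fixture(scope="module")
def prepared(ar1_series):
    train_scaled, _test, scaler = gf.supervised_sets(
        ar1_series.slice(0, 120), 5, 1
    )
    return train_scaled, scaler


class TestSelectArchitecture:
    def test_bookkeeping_and_determinism(self, prepared):
        train_scaled, scaler = prepared
        space = SearchSpace(
            model_kind="cnn_gru", lag=5, units_ranges=((8, 16, 8), (4, 8, 4)),
            dropout_range=(0.1, 0.3), filters_choices=(4,),
            kernel_choices=(3,),
        )
        kw = dict(n_trials=4, n_initial=2, epochs=2, seed=0)
        res1 = gf.select_architecture(train_scaled, scaler, "cnn_gru", space,
                                      **kw)
        assert len(res1.trials) == 4
        assert res1.best.objective == min(t.objective for t in res1.trials)
        assert res1.best.objective >= 0
        res2 = gf.select_architecture(train_scaled, scaler, "cnn_gru", space,
                                      **kw)
        assert [t.hyperparams for t in res1.trials] == \
            [t.hyperparams for t in res2.trials]
        assert [t.objective for t in res1.trials] == \
            [t.objective for t in res2.trials]

    def test_single_trial(self, prepared):
        train_scaled, scaler = prepared
        space = SearchSpace(
            model_kind="gru", lag=5, units_ranges=((8, 16, 8),),
            dropout_range=(0.1, 0.3),
        )
        res = gf.select_architecture(train_scaled, scaler, "gru", space,
                                     n_trials=2, n_initial=2, epochs=1,
                                     seed=1)
        assert res.best in res.trials


def test_result_serialization(tmp_path):
    res = bayes_optimize(toy_objective, toy_space(), n_trials=4, n_initial=2,
                         seed=0)
    path = res.to_json(tmp_path / "hpo.json")
    import json

    payload = json.loads(path.read_text())
    assert payload["model_kind"] == "cnn_gru"
    assert len(payload["trials"]) == 4
    assert payload["best"]["objective"] == res.best.objective
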