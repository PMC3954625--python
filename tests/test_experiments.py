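import numpy as np
import pytest

from stdpforage import RunConfig
from stdpforage._rng import make_state
from stdpforage.env import FoodDistribution
from stdpforage.experiments import (
    PerformanceTracker,
    Simulation,
    perturb_weights,
    reversed_reward_run,
    run_ablation,
    run_training,
    switch_environment,
    update_performance,
    write_run_outputs,
)
from stdpforage.strategies import run_strategy

from conftest import make_config


class TestPerformanceMetric:
    def test_single_success_from_zero(self):
        t = update_performance(PerformanceTracker(a=1e-5), True)
        assert t.x == pytest.approx(1e-5)

    def test_constant_success_converges_to_one(self):
        t = PerformanceTracker(a=0.01, x=1.0)
        t.update(True)
        assert t.x == 1.0  # fixed point

    def test_two_step_hand_evaluation(self):
        t = PerformanceTracker(a=0.5)
        t.update(True)
        t.update(False)
        assert t.x == pytest.approx(0.25)

    def test_ema_converges_to_bernoulli_rate(self):
        """EMA of a Bernoulli(p) stream settles within 3*sqrt(A/2) of p."""
        a, p = 1e-3, 0.3
        draws = np.random.default_rng(5).random(20_000) < p
        t = PerformanceTracker(a=a)
        for s in draws:
            t.update(bool(s))
        assert abs(t.x - p) < 3 * np.sqrt(a / 2)


class TestTrainingLoop:
    def test_logs_have_run_length(self):
        logs = run_training(RunConfig(seed=4), n_epochs=300)
        assert logs.epochs_run == 300
        assert logs.performance.shape == (300,)
        assert logs.W.shape == (49, 9)
        assert not logs.halted

    def test_learning_disabled_keeps_weights_fixed(self):
        cfg = make_config(4, **{"experiment.learning_on": False})
        logs = run_training(cfg, n_epochs=500)
        np.testing.assert_array_equal(logs.W, 2.0)
        np.testing.assert_array_equal(logs.w_j0, 98.0)

    def test_learning_off_performance_close_to_blind_strategy(self):
        """An untrained frozen network forages like the blind reference."""
        cfg = make_config(8, **{"experiment.learning_on": False})
        logs = run_training(cfg, n_epochs=20_000)
        blind = run_strategy(1, 200_000, seed=8)["rate"]
        assert abs(logs.food_rate - blind) < 0.012

    def test_freeze_window_holds_weights_constant(self):
        cfg = make_config(5, **{"plasticity.stdp_strength": 4.0})
        sim = Simulation(cfg, freeze_windows=[(200, 400)])
        sim.run(200)
        w_at_freeze = sim.net.W.copy()
        sim.run(200)
        np.testing.assert_array_equal(sim.net.W, w_at_freeze)
        sim.run(600)
        assert not np.array_equal(sim.net.W, w_at_freeze)

    def test_overlapping_freeze_windows_rejected(self):
        with pytest.raises(ValueError):
            Simulation(RunConfig(seed=1), freeze_windows=[(0, 100), (50, 150)])

    def test_snapshots_collected(self):
        logs = run_training(RunConfig(seed=6), n_epochs=300, snapshot_every=100)
        assert [e for e, _ in logs.snapshots] == [100, 200, 300]


class TestAblations:
    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            run_ablation(RunConfig(seed=1), "synapses", n_epochs=10)

    def test_punishment_off_still_learns_smoke(self):
        logs = run_ablation(make_config(3, **{"plasticity.stdp_strength": 4.0}),
                            "punishment", n_epochs=2000)
        assert logs.epochs_run == 2000
        assert not logs.halted

    def test_reversed_switch_off_is_identity(self):
        l1 = run_training(RunConfig(seed=21), n_epochs=300)
        l2 = run_training(make_config(21, **{"experiment.reward_reversed": False}),
                          n_epochs=300)
        np.testing.assert_array_equal(l1.performance, l2.performance)

    def test_reversed_run_differs_from_default(self):
        cfg = make_config(22, **{"plasticity.stdp_strength": 4.0})
        l1 = run_training(cfg, n_epochs=3000)
        l2 = reversed_reward_run(cfg, n_epochs=3000)
        assert not np.array_equal(l1.W, l2.W)


class TestPerturbation:
    def test_zero_level_is_identity(self):
        W = np.random.default_rng(0).uniform(0.5, 3.0, (49, 9))
        out = perturb_weights(W, 0.0, make_state(1))
        np.testing.assert_allclose(out, W, rtol=1e-12)

    def test_column_sums_restored_and_factors_bounded(self):
        W = np.random.default_rng(1).uniform(0.5, 3.0, (49, 9))
        out = perturb_weights(W, 0.2, make_state(2))
        np.testing.assert_allclose(out.sum(axis=0), W.sum(axis=0), rtol=1e-9)
        assert not np.allclose(out, W)

    @pytest.mark.parametrize("level", [-0.1, 1.0, 1.5])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            perturb_weights(np.ones((49, 9)), level, make_state(0))

    def test_trained_network_survives_perturbation(self):
        """Randomising trained weights leaves totals intact and the run healthy."""
        cfg = make_config(9, **{"plasticity.stdp_strength": 4.0,
                                "experiment.ema_a": 1e-3})
        sim = Simulation(cfg)
        sim.run(5000)
        col_sums = sim.net.W.sum(axis=0).copy()
        sim.perturb(0.5)
        np.testing.assert_allclose(sim.net.W.sum(axis=0), col_sums, rtol=1e-9)
        sim.run(2000)
        assert not sim.halted


class TestEnvironmentSwitch:
    def test_null_switch_keeps_behaviour_statistics(self):
        """Switching to an identical distribution does not change performance."""
        cfg = make_config(13, **{"experiment.learning_on": False})
        logs = switch_environment(cfg, at_epoch=6000, new_dist=FoodDistribution(),
                                  n_epochs=12_000)
        before = logs.ate[:6000].mean()
        after = logs.ate[6000:].mean()
        assert abs(before - after) < 0.02

    def test_vertical_switch_changes_relocation_bias(self):
        cfg = RunConfig(seed=14)
        sim = Simulation(cfg)
        sim.run(10)
        sim.switch_environment(FoodDistribution(vertical_bias=0.9))
        assert sim.world.food.sum() == 250
        sim.run(10)
        from stdpforage.config import P_VBIAS

        assert sim.net.params[P_VBIAS] == 0.9

    def test_trained_network_transfers_to_vertical_environment(self):
        """A net trained on random food stays successful (with frozen weights)
        after the food distribution switches to vertically biased columns."""
        cfg = make_config(88, **{"plasticity.stdp_strength": 4.0,
                                 "experiment.ema_a": 1e-3})
        sim = Simulation(cfg, freeze_windows=[(150_000, 200_000)])
        sim.run(150_000)
        pre = sim.collect().ate[-30_000:].mean()
        sim.switch_environment(FoodDistribution(density=0.10, vertical_bias=0.9))
        sim.run(50_000)
        post = sim.collect().ate[150_000:].mean()
        assert pre > 0.12          # learned well above the blind baseline
        assert post > 0.8 * pre    # no collapse in the new environment

    def test_bad_switch_epoch_rejected(self):
        with pytest.raises(ValueError):
            switch_environment(RunConfig(seed=1), at_epoch=0,
                               new_dist=FoodDistribution(), n_epochs=100)


class TestOutputs:
    def test_run_outputs_written(self, tmp_path):
        logs = run_training(RunConfig(seed=2), n_epochs=200, snapshot_every=100)
        write_run_outputs(logs, tmp_path, every=10)
        for name in ("performance.csv", "trajectory.csv", "weights.npz", "manifest.yaml"):
            assert (tmp_path / name).exists()
        import pandas as pd

        perf = pd.read_csv(tmp_path / "performance.csv")
        assert len(perf) == 20

    def test_config_yaml_roundtrip(self):
        cfg = make_config(3, **{"plasticity.stdp_strength": 2.5})
        back = RunConfig.from_yaml(cfg.to_yaml())
        assert back == cfg

    def test_cli_strategies_smoke(self, tmp_path):
        from click.testing import CliRunner
        from stdpforage.cli import main

        res = CliRunner().invoke(
            main, ["strategies", "--moves", "2000", "--which", "1", "--seed", "1",
                   "--out", str(tmp_path)]
        )
        assert res.exit_code == 0, res.output
        assert "strategy 1" in res.output
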