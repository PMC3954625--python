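import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdpforage.config import PlasticityConfig
from stdpforage.plasticity import (
    HomeostasisState,
    TraceKind,
    apply_reward_or_punish,
    balance_inhibition,
    detect_stdp_events,
    homeostatic_update,
    output_balancing_scale,
    rebalance_inputs,
)

from oracles import naive_stdp_pairs


@pytest.fixture
def params():
    return PlasticityConfig()


class TestTraceDetection:
    def test_simultaneous_pair_gives_maximal_potentiation(self, params):
        (tr,) = detect_stdp_events([10], [10], weight=1.0, params=params)
        assert tr.kind is TraceKind.PRE_BEFORE_POST
        assert tr.value == pytest.approx(0.025)

    def test_only_first_following_post_creates_event(self, params):
        traces = detect_stdp_events([10], [12, 14], weight=1.0, params=params)
        assert len(traces) == 1
        assert traces[0].value == pytest.approx(0.025 * np.exp(-2 / 20))
        assert traces[0].created_at == 12

    def test_post_before_pre_depresses(self, params):
        (tr,) = detect_stdp_events([20], [14], weight=1.0, params=params)
        assert tr.kind is TraceKind.POST_BEFORE_PRE
        assert tr.value == pytest.approx(-0.025 * np.exp(-6 / 20))

    def test_zero_weight_gives_zero_trace(self, params):
        traces = detect_stdp_events([10], [12], weight=0.0, params=params)
        assert traces[0].value == 0.0

    @pytest.mark.parametrize("weight", [0.5, 1.0, 2.0, 7.5])
    def test_trace_value_scales_linearly_with_weight(self, params, weight):
        (tr,) = detect_stdp_events([10], [15], weight=weight, params=params)
        assert tr.value == pytest.approx(weight * 0.025 * np.exp(-5 / 20))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pre=st.lists(st.integers(0, 60), max_size=8, unique=True),
        post=st.lists(st.integers(0, 60), max_size=8, unique=True),
    )
    def test_matches_naive_event_scanner(self, pre, post):
        """Nearest-pairing-with-suppression equals an independent per-event scan."""
        params = PlasticityConfig()
        traces = detect_stdp_events(pre, post, weight=1.0, params=params)
        got = sorted(
            (tr.kind.value, float(tr.created_at), round(tr.value, 12)) for tr in traces
        )
        expected = []
        for kind, t1, t2 in naive_stdp_pairs(pre, post):
            k = params.k_plus if kind == "pre_before_post" else params.k_minus
            expected.append((kind, float(t2), round(k * np.exp(-(t2 - t1) / params.tc_steps), 12)))
        assert got == sorted(expected)


class TestRewardApplication:
    def make_setup(self, w=1.0):
        W = np.full((49, 9), w)
        homeo = HomeostasisState(w_j0=np.full(9, 49.0 * w))
        w_io = W.sum(axis=1)
        return W, homeo, w_io

    def test_no_traces_leaves_weights_unchanged(self, params):
        W, homeo, w_io = self.make_setup()
        out = apply_reward_or_punish([], W, True, 300.0, params, homeo, w_io)
        np.testing.assert_array_equal(out, W)

    def test_fresh_trace_full_reward_increment(self, params):
        """Age-0 trace with unit scales adds exactly vE (before rebalancing)."""
        from stdpforage.plasticity import StdpTrace

        W, homeo, w_io = self.make_setup()
        tr = StdpTrace(3, 2, 0.025, created_at=300.0, kind=TraceKind.PRE_BEFORE_POST)
        out = apply_reward_or_punish([tr], W, True, 300.0, params, homeo, w_io,
                                     input_balancing=False)
        assert out[3, 2] == pytest.approx(W[3, 2] + 0.025)

    def test_decay_at_five_epoch_horizon(self, params):
        from stdpforage.plasticity import StdpTrace

        W, homeo, w_io = self.make_setup()
        tr = StdpTrace(3, 2, 0.025, created_at=0.0, kind=TraceKind.PRE_BEFORE_POST)
        out = apply_reward_or_punish([tr], W, True, 5 * 600.0, params, homeo, w_io,
                                     input_balancing=False)
        assert out[3, 2] - W[3, 2] == pytest.approx(0.025 * np.exp(-5), rel=1e-9)

    def test_punishment_flips_sign_at_reduced_constant_scale(self, params):
        from stdpforage.plasticity import StdpTrace

        for w in (1.0, 2.0):  # punishment scale must not depend on outgoing totals
            W, homeo, w_io = self.make_setup(w)
            tr = StdpTrace(3, 2, 0.025, created_at=300.0, kind=TraceKind.PRE_BEFORE_POST)
            out = apply_reward_or_punish([tr], W, False, 300.0, params, homeo, w_io,
                                         input_balancing=False)
            assert out[3, 2] - W[3, 2] == pytest.approx(-params.punish_fraction * 0.025)

    def test_weights_floored_at_zero(self, params):
        from stdpforage.plasticity import StdpTrace

        W, homeo, w_io = self.make_setup(0.001)
        tr = StdpTrace(3, 2, -1.0, created_at=300.0, kind=TraceKind.POST_BEFORE_PRE)
        out = apply_reward_or_punish([tr], W, True, 300.0, params, homeo, w_io,
                                     input_balancing=False)
        assert out[3, 2] == 0.0

    def test_rebalancing_restores_column_sum(self, params):
        from stdpforage.plasticity import StdpTrace

        W, homeo, w_io = self.make_setup()
        tr = StdpTrace(3, 2, 0.025, created_at=300.0, kind=TraceKind.PRE_BEFORE_POST)
        out = apply_reward_or_punish([tr], W, True, 300.0, params, homeo, w_io)
        assert out[:, 2].sum() == pytest.approx(homeo.w_j0[2], rel=1e-12)


class TestOutputBalancing:
    def test_scale_is_unity_at_initial_total(self, params):
        assert output_balancing_scale(9.0, 9.0, params) == pytest.approx(1.0)

    def test_scale_halves_when_total_doubles(self, params):
        assert output_balancing_scale(18.0, 9.0, params) == pytest.approx(0.5)

    def test_nonpositive_total_rejected(self, params):
        with pytest.raises(ValueError):
            output_balancing_scale(0.0, 9.0, params)


class TestHomeostasis:
    def test_on_target_rate_leaves_target_unchanged(self, params):
        h = HomeostasisState(w_j0=np.full(9, 98.0), f_est=np.full(9, params.f_target))
        out = homeostatic_update(h, np.full(9, params.f_target), params, 98.0)
        np.testing.assert_allclose(out.w_j0, 98.0)

    def test_silent_cell_target_strictly_increases(self, params):
        h = HomeostasisState(w_j0=np.full(9, 98.0))
        for _ in range(20):
            prev = h.w_j0.copy()
            h = homeostatic_update(h, np.zeros(9), params, 98.0)
            assert np.all(h.w_j0 > prev)

    def test_overactive_cell_target_strictly_decreases(self, params):
        h = HomeostasisState(w_j0=np.full(9, 98.0), f_est=np.full(9, 5.0))
        for _ in range(20):
            prev = h.w_j0.copy()
            h = homeostatic_update(h, np.full(9, 5.0), params, 98.0)
            assert np.all(h.w_j0 < prev)

    def test_target_floored(self, params):
        h = HomeostasisState(w_j0=np.full(9, 98.0), f_est=np.full(9, 50.0))
        for _ in range(5000):
            h = homeostatic_update(h, np.full(9, 50.0), params, 98.0)
        np.testing.assert_allclose(h.w_j0, params.w_j0_min_fraction * 98.0)


class TestBalancingPrimitives:
    def test_rebalance_identity_when_sum_matches(self):
        col = np.random.default_rng(0).uniform(0.1, 2.0, 49)
        out = rebalance_inputs(col, col.sum())
        np.testing.assert_allclose(out, col, rtol=1e-15)

    def test_rebalance_restores_sum_and_preserves_ratios(self):
        rng = np.random.default_rng(1)
        col = rng.uniform(0.1, 2.0, 49)
        target = col.sum()
        bumped = col.copy()
        bumped[7] += 0.5
        out = rebalance_inputs(bumped, target)
        assert out.sum() == pytest.approx(target, rel=1e-12)
        ratios = out[np.arange(49) != 7] / bumped[np.arange(49) != 7]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)

    def test_doubling_target_doubles_every_weight(self):
        col = np.random.default_rng(2).uniform(0.1, 2.0, 49)
        out = rebalance_inputs(col, 2 * col.sum())
        np.testing.assert_allclose(out, 2 * col, rtol=1e-12)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            rebalance_inputs(np.zeros(49), 1.0)

    def test_inhibition_uniform_and_sum_matched(self):
        col = np.random.default_rng(3).uniform(0.1, 2.0, 49)
        wi = balance_inhibition(np.zeros(49), col)
        assert np.unique(wi).size == 1
        assert wi.sum() == pytest.approx(col.sum(), rel=1e-12)

    def test_zero_excitation_gives_zero_inhibition(self):
        wi = balance_inhibition(np.ones(49), np.zeros(49))
        np.testing.assert_array_equal(wi, 0.0)

    def test_excitatory_sum_49_gives_unit_inhibition(self):
        wi = balance_inhibition(np.zeros(49), np.full(49, 1.0))
        np.testing.assert_allclose(wi, 1.0)


class TestEngineConservation:
    def test_conservation_invariants_hold_every_epoch(self):
        """Excitatory column sums track W_j0 and inhibition tracks excitation."""
        from conftest import scaled_config
        from stdpforage.experiments import run_training

        cfg = scaled_config(77, **{"experiment.validate": True})
        logs = run_training(cfg, n_epochs=4000)
        assert logs.counters[1] == 0  # no violations at 1e-9 relative
        assert logs.fmetrics[0] < 1e-9
        assert logs.fmetrics[1] < 1e-9

    def test_traces_have_no_influence_beyond_five_epochs(self):
        """A trace applied 6 epochs after creation changes nothing; at 5 it does."""
        from stdpforage import RunConfig
        from stdpforage import _engine as eng
        from stdpforage.circuit import NetworkState

        for age, expect_change in ((5, True), (6, False)):
            net = NetworkState(RunConfig(seed=1))
            net.tr_pre[0, 0] = 3
            net.tr_post[0, 0] = 2
            net.tr_val[0, 0] = 0.025
            net.tr_time[0, 0] = 100.0
            net.tr_count[0] = 1
            net.slot_epoch[0] = 0
            before = net.W.copy()
            eng.apply_reward_kernel(
                net.params, net.W, net.WI, net.w_j0, net.w_io, net.row_sum,
                net.tr_pre, net.tr_post, net.tr_val, net.tr_time, net.tr_count,
                net.slot_epoch, age, True, net.dW, net.touched, net.counters,
            )
            changed = not np.array_equal(net.W, before)
            assert changed is expect_change

    def test_disabling_input_balancing_causes_runaway(self):
        """Forced rewards without input balancing trip the runaway detector."""
        from conftest import make_config
        from stdpforage.experiments import run_training

        cfg = make_config(
            66,
            **{
                "experiment.input_balancing_on": False,
                "experiment.force_reward": True,
                "plasticity.stdp_strength": 4.0,
            },
        )
        logs = run_training(cfg, n_epochs=10_000)
        assert logs.halted
        assert logs.epochs_run < 10_000
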