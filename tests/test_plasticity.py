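"""The STDP rule: closed-form updates, pairing logic, boundedness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placesim.plasticity import (PlasticityState, STDPParams,
                                 depression_update, depression_window,
                                 dendritic_spike_times, on_spike_event,
                                 potentiation_update)

G0 = 0.004
GMAX = 0.0072


@pytest.fixture
def params():
    return STDPParams(g_peak_max=GMAX)


class TestDepression:
    def test_zero_increment_stays_zero(self, params):
        for dt in (-1.0, -24.0, -80.0):
            assert depression_update(0.0, dt, params) == 0.0

    def test_maximal_at_window_center(self, params):
        # independent scalar evaluation of the multiplier at Δ = M
        expected = 1.0 - params.d / (params.V * math.sqrt(2 * math.pi))
        A = 1e-3
        assert depression_update(A, params.M, params) == \
            pytest.approx(A * expected, rel=1e-12)
        # Δ = M minimizes the multiplier over a grid
        grid = np.arange(-100.0, -0.01, 0.05)
        mult = np.array([depression_update(1.0, d, params) for d in grid])
        assert grid[np.argmin(mult)] == pytest.approx(params.M, abs=0.1)

    def test_far_tail_leaves_weight_unchanged(self, params):
        assert depression_update(1.0, -200.0, params) == \
            pytest.approx(1.0, abs=1e-9)

    def test_wrong_branch_rejected(self, params):
        with pytest.raises(ValueError):
            depression_update(1e-3, 0.0, params)
        with pytest.raises(ValueError):
            depression_update(1e-3, 5.0, params)


class TestPotentiation:
    def test_saturation_is_fixed_point(self, params):
        A_sat = params.g_peak_max - G0
        assert potentiation_update(A_sat, 1.0, G0, params) == \
            pytest.approx(A_sat)

    def test_vanishes_at_large_delay(self, params):
        assert potentiation_update(1e-3, 1e4, G0, params) == \
            pytest.approx(1e-3)

    def test_e_folding_at_tau(self, params):
        # A = 0, Δ = τ: increment is the headroom times e^{-1}
        expected = (params.g_peak_max - G0) * params.p * math.exp(-1.0)
        assert potentiation_update(0.0, params.tau, G0, params) == \
            pytest.approx(expected, rel=1e-12)

    def test_wrong_branch_rejected(self, params):
        with pytest.raises(ValueError):
            potentiation_update(0.0, -1.0, G0, params)


class TestPairing:
    def test_first_pre_only_updates_history(self, params):
        s = PlasticityState()
        on_spike_event(s, "pre", 10.0, params, G0)
        assert s.A == 0.0 and s.last_pre == 10.0 and s.last_post is None

    def test_pre_then_post_potentiates(self, params):
        s = PlasticityState()
        on_spike_event(s, "pre", 10.0, params, G0)
        on_spike_event(s, "post", 12.0, params, G0)
        expected = potentiation_update(0.0, 2.0, G0, params)
        assert s.A == pytest.approx(expected)

    def test_post_then_pre_depresses_at_window_center(self, params):
        s = PlasticityState(A=1e-3)
        on_spike_event(s, "post", 10.0, params, G0)
        on_spike_event(s, "pre", 34.0, params, G0)   # Δ = 10 − 34 = M
        expected = depression_update(1e-3, -24.0, params)
        assert s.A == pytest.approx(expected)

    def test_out_of_order_events_rejected(self, params):
        s = PlasticityState()
        on_spike_event(s, "pre", 10.0, params, G0)
        with pytest.raises(ValueError):
            on_spike_event(s, "post", 5.0, params, G0)

    def test_unknown_event_rejected(self, params):
        with pytest.raises(ValueError):
            on_spike_event(PlasticityState(), "spike", 1.0, params, G0)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["pre", "post"]),
                              st.floats(0.1, 50.0)),
                    min_size=1, max_size=60))
    def test_weight_stays_bounded(self, events, ):
        """g_peak ∈ [g0, g_max] for any event stream (soft bounds)."""
        params = STDPParams(g_peak_max=GMAX)
        s = PlasticityState()
        t = 0.0
        for kind, gap in events:
            t += gap
            on_spike_event(s, kind, t, params, G0)
            assert 0.0 <= s.A <= GMAX - G0 + 1e-15
            assert G0 <= G0 + s.A <= GMAX + 1e-15

    def test_depression_only_monotone_nonincreasing(self, params):
        s = PlasticityState(A=2e-3)
        on_spike_event(s, "post", 0.0, params, G0)
        prev = s.A
        t = 0.0
        rng = np.random.default_rng(5)
        for _ in range(50):
            t += rng.uniform(1.0, 40.0)
            on_spike_event(s, "pre", t, params, G0)
            assert s.A <= prev + 1e-18
            prev = s.A

    def test_potentiation_only_converges_to_ceiling(self, params):
        s = PlasticityState()
        t = 0.0
        prev = -1.0
        for _ in range(200):
            t += 1.0
            on_spike_event(s, "pre", t, params, G0)
            t += 1.0
            on_spike_event(s, "post", t, params, G0)
            assert s.A >= prev
            prev = s.A
        # converges to the ceiling up to the residual depression exerted
        # by each pre pairing with the immediately preceding post
        assert s.A == pytest.approx(GMAX - G0, rel=1e-3)


class TestDendriticSpikeTimes:
    def test_subthreshold_trace_gives_no_posts(self, params):
        trace = np.full(2000, -30.0)
        assert dendritic_spike_times(trace, params, 0.05).size == 0

    def test_plateau_excursion_gives_one_post(self, params):
        trace = np.concatenate([np.full(100, -65.0), np.full(400, 0.0),
                                np.full(100, -65.0)])
        assert dendritic_spike_times(trace, params, 0.05).size == 1

    def test_two_excursions_give_two_posts(self, params):
        bump = np.concatenate([np.full(100, -65.0), np.full(100, 0.0)])
        trace = np.concatenate([bump, bump, np.full(100, -65.0)])
        assert dendritic_spike_times(trace, params, 0.05).size == 2


class TestKernelAgreement:
    def test_engine_updates_match_scalar_rule(self, cfg, prepared):
        """Force a dendritic spike in the integrated model and check the
        kernel's weight update against the scalar pairing rule applied to
        the recorded pre/post times."""
        from placesim import engine

        model, _, weights, _ = prepared
        model.reset_to_rest()
        g0 = weights["oblique0"]
        ci = model.index_of("oblique0")
        syn = engine.SynapseArrays([ci], [g0], [1.8 * g0],
                                   engine.syn_param_pack(cfg.synapse))
        ev_t = np.array([40.0, 52.0, 64.0])
        # strong local injection forces a crossing shortly after the pres
        inj = (np.array([ci]), np.array([60.0]), np.array([80.0]),
               np.array([1.5]))
        out = engine.run_segment(model, 200.0, syn=syn,
                                 events=(ev_t, np.zeros(3, np.int64)),
                                 stdp=cfg.stdp, plasticity_on=True,
                                 injections=inj, rec_stride_ms=0.0)
        model.reset_to_rest()
        posts = out["dend_spike_t"]
        assert posts.size >= 1
        params = STDPParams.from_config(cfg.stdp, 1.8 * g0)
        s = PlasticityState()
        stream = sorted([("pre", t) for t in ev_t] +
                        [("post", t) for t in posts], key=lambda e: e[1])
        for kind, t in stream:
            on_spike_event(s, kind, t, params, g0)
        assert syn.A[0] == pytest.approx(s.A, rel=1e-9)
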