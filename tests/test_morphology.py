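"""Reduced morphology, channel gradients, integration and spike detection."""

import numpy as np
import pytest

from placesim import canonical_scenario
from placesim.morphology import (ChannelDistribution, build_morphology,
                                 channel_density_at,
                                 detect_threshold_crossings, advance_state)
from placesim import engine


def small_cfg(**kwargs):
    cfg = canonical_scenario()
    for k, v in kwargs.items():
        setattr(cfg.morphology, k, v)
    return cfg


class TestBuildMorphology:
    def test_counts_echo_config(self):
        model = build_morphology(small_cfg(n_oblique=14))
        obliques = model.ids_in_region("oblique")
        assert len(obliques) == 14
        assert len(model.ids_in_region("trunk")) == 8
        assert len(model.ids_in_region("soma")) == 1

    def test_obliques_have_distinct_path_distances(self):
        model = build_morphology(small_cfg(n_oblique=30))
        dists = [c.path_distance_to_soma for c in model.compartments
                 if c.region == "oblique"]
        assert len(dists) == 30
        assert len(set(np.round(dists, 6))) == 30

    def test_trunk_distance_is_cumulative_length(self):
        cfg = small_cfg()
        model = build_morphology(cfg)
        m = cfg.morphology
        last = model.compartments[model.index_of(
            f"trunk{m.trunk_sections - 1}")]
        # midpoint of the most distal section
        expected = m.soma_length_um / 2 + \
            (m.trunk_sections - 0.5) * m.trunk_length_um
        assert last.path_distance_to_soma == pytest.approx(expected)
        assert model.compartments[0].path_distance_to_soma == 0.0

    def test_rejects_too_few_obliques_for_cue_config(self):
        with pytest.raises(ValueError, match="cue synapses"):
            build_morphology(small_cfg(n_oblique=10))

    def test_rejects_non_positive_geometry(self):
        with pytest.raises(ValueError, match="geometry"):
            build_morphology(small_cfg(trunk_diameter_um=-1.0))

    def test_tree_rooted_at_soma(self):
        model = build_morphology(small_cfg())
        assert model.parent_idx[0] == -1
        assert np.all(model.parent_idx[1:] >= 0)
        # parents precede children: no cycles possible
        assert np.all(model.parent_idx[1:] < np.arange(1, model.n))


class TestChannelDensity:
    def test_intercept_at_soma(self):
        d = ChannelDistribution("I_h", 2e-4, 1e-6,
                                frozenset({"soma", "trunk", "oblique",
                                           "basal"}), -30.0)
        assert channel_density_at(d, 0.0) == pytest.approx(2e-4)

    def test_linear_growth(self):
        d = ChannelDistribution("K_A_distal", 1e-3, 5e-6,
                                frozenset({"trunk", "oblique"}), -90.0)
        assert channel_density_at(d, 100.0) == pytest.approx(1e-3 + 100 * 5e-6)

    def test_region_mask_zeroes_km_outside_soma_axon(self):
        d = ChannelDistribution("K_M", 1e-3, 0.0,
                                frozenset({"soma", "axon"}), -90.0)
        assert channel_density_at(d, 50.0, region="trunk") == 0.0
        assert channel_density_at(d, 0.0, region="soma") > 0.0

    def test_negative_distance_rejected(self):
        d = ChannelDistribution("Na", 0.1, 0.0, frozenset({"soma"}), 55.0)
        with pytest.raises(ValueError):
            channel_density_at(d, -1.0)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            ChannelDistribution("K_M", 1e-3, 0.0, frozenset({"trunk"}), -90.0)
        with pytest.raises(ValueError):
            ChannelDistribution("Na", 0.1, 1e-6, frozenset({"soma"}), 55.0)
        with pytest.raises(ValueError):
            ChannelDistribution("I_h", 1e-4, 0.0, frozenset({"soma"}), -30.0)

    def test_distance_gradient_across_obliques(self, prepared):
        model = _first(prepared)
        obl = [model.index_of(c) for c in model.ids_in_region("oblique")]
        dists = np.array([model.compartments[i].path_distance_to_soma
                          for i in obl])
        order = np.argsort(dists)
        for name in ("I_h", "K_A_distal"):
            dens = model.gbar_uS[name][obl] / np.array(
                [model.compartments[i].area_cm2 for i in obl]) / 1e6
            assert np.all(np.diff(dens[order]) >= -1e-12)


def _first(prepared):
    return prepared[0]


class TestIntegration:
    def test_resting_stability_two_seconds(self, prepared):
        model = _first(prepared)
        model.reset_to_rest()
        v0 = model.v.copy()
        engine.run_segment(model, 2000.0, rec_stride_ms=0.0)
        assert np.abs(model.v - v0).max() < 2.0
        assert np.all(np.isfinite(model.v))
        model.reset_to_rest()

    def test_gating_variables_bounded(self, prepared):
        model = _first(prepared)
        model.reset_to_rest()
        inj = np.zeros(model.n)
        inj[0] = 0.6
        engine.integrate_passive_segment(model, 300.0, inj)
        assert model.gates.min() >= 0.0 and model.gates.max() <= 1.0
        model.reset_to_rest()

    def test_suprathreshold_current_spikes_repetitively(self, prepared):
        model = _first(prepared)
        model.reset_to_rest()
        inj = np.zeros(model.n)
        inj[0] = 0.8
        out = engine.integrate_passive_segment(model, 500.0, inj)
        assert out["soma_spikes"].size > 3
        model.reset_to_rest()

    def test_zero_input_is_fixed_point(self, prepared):
        model = _first(prepared)
        model.reset_to_rest()
        v0 = model.v.copy()
        advance_state(model, np.zeros(model.n), np.zeros(model.n), 0.05)
        assert np.abs(model.v - v0).max() < 1e-4
        model.reset_to_rest()

    def test_advance_state_rejects_bad_dt(self, prepared):
        model = _first(prepared)
        zero = np.zeros(model.n)
        with pytest.raises(ValueError):
            advance_state(model, zero, zero, 0.0)
        with pytest.raises(ValueError):
            advance_state(model, zero, zero, 1.0)

    def test_dt_convergence(self):
        """Halving dt changes the voltage trace by < 0.5 mV RMS."""
        traces = {}
        for dt in (0.05, 0.025):
            cfg = canonical_scenario(dt_ms=dt)
            model = build_morphology(cfg)
            inj = np.zeros(model.n)
            inj[model.index_of("trunk4")] = 0.3
            comp = np.array([model.index_of("trunk4")])
            out = engine.run_segment(
                model, 1000.0,
                injections=(comp, np.array([100.0]), np.array([600.0]),
                            np.array([0.3])),
                injection_ramp_ms=25.0,
                probes=[0, model.index_of("trunk4")], rec_stride_ms=1.0)
            traces[dt] = out["probe_v"]
        rms = np.sqrt(np.mean((traces[0.05] - traces[0.025]) ** 2))
        assert rms < 0.5


class TestThresholdCrossings:
    def test_flat_trace_has_no_events(self):
        trace = np.full(1000, -65.0)
        assert detect_threshold_crossings(trace, -10.0, 0.05).size == 0

    def test_single_triangular_excursion_counts_once(self):
        trace = np.concatenate([np.full(50, -65.0),
                                np.linspace(-65, 0, 100),
                                np.linspace(0, -65, 100),
                                np.full(50, -65.0)])
        events = detect_threshold_crossings(trace, -10.0, 0.05)
        assert events.size == 1

    def test_sine_crossing_count_matches_period(self):
        t = np.arange(0, 100, 0.05)
        k = 7
        trace = -30.0 + 40.0 * np.sin(2 * np.pi * k * t / 100.0)
        events = detect_threshold_crossings(trace, -10.0, 0.05)
        assert events.size == k

    def test_no_double_count_within_excursion(self):
        # noisy plateau above threshold: still one event
        rng = np.random.default_rng(0)
        trace = np.concatenate([np.full(100, -65.0),
                                np.full(200, 5.0) + rng.normal(0, 1, 200),
                                np.full(100, -65.0)])
        events = detect_threshold_crossings(trace, -10.0, 0.05)
        assert events.size == 1

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_threshold_crossings(np.array([]), -10.0, 0.05)
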