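"""Shared fixtures.

The expensive pieces — building and calibrating the neuron, and the
canonical control/learning/recall sessions — are computed once per test
run (session scope) and shared by the unit and acceptance tests.
"""

import numpy as np
import pytest

from placesim import canonical_scenario, prepare_simulation, rotate_arena
from placesim.simulation import SessionConfig, run_session


@pytest.fixture(scope="session")
def cfg():
    return canonical_scenario()


@pytest.fixture(scope="session")
def prepared(cfg):
    """(model, arena, weights, plateau amplitudes), fully calibrated."""
    return prepare_simulation(cfg)


@pytest.fixture(scope="session")
def control_result(cfg, prepared):
    model, arena, weights, _ = prepared
    session = SessionConfig(mode="control_no_plateau",
                            seed_trajectory=1, seed_synaptic=2)
    return run_session(model, arena, cfg, session, weights)


@pytest.fixture(scope="session")
def learning_result(cfg, prepared):
    model, arena, weights, amps = prepared
    session = SessionConfig(mode="learning_with_plateau",
                            rewarded_object="red",
                            seed_trajectory=1, seed_synaptic=2)
    return run_session(model, arena, cfg, session, weights,
                       plateau_amplitude_nA=amps)


@pytest.fixture(scope="session")
def recall_result(cfg, prepared, learning_result):
    model, arena, weights, _ = prepared
    session = SessionConfig(mode="recall",
                            seed_trajectory=11, seed_synaptic=12)
    return run_session(model, arena, cfg, session, weights,
                       initial_A=learning_result.A_final)


@pytest.fixture(scope="session")
def rotated_recall_result(cfg, prepared, learning_result):
    model, arena, weights, _ = prepared
    session = SessionConfig(mode="recall",
                            seed_trajectory=13, seed_synaptic=14)
    return run_session(model, rotate_arena(arena, 90.0), cfg, session,
                       weights, initial_A=learning_result.A_final)


@pytest.fixture(scope="session")
def blue_recall_result(cfg, prepared):
    """Recall after training on the blue object instead (remapping)."""
    model, arena, weights, amps = prepared
    learn = run_session(
        model, arena, cfg,
        SessionConfig(mode="learning_with_plateau", rewarded_object="blue",
                      seed_trajectory=1, seed_synaptic=2),
        weights, plateau_amplitude_nA=amps)
    return run_session(
        model, arena, cfg,
        SessionConfig(mode="recall", seed_trajectory=11, seed_synaptic=12),
        weights, initial_A=learn.A_final)


def red_blue_indices(result):
    red = [i for i, f in enumerate(result.feature_ids) if f.startswith("red:")]
    blue = [i for i, f in enumerate(result.feature_ids) if f.startswith("blue:")]
    return red, blue
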