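"""Event-driven STDP rule for the cue synapses.

The effective peak conductance of a synapse is g_peak = g0 + A, with the
plastic increment A updated at every pre- or post-synaptic spike using
nearest-neighbor pairing.  Post events are local dendritic spikes (upward
−10 mV crossings in the synapse's oblique), not somatic spikes.

With Δ = t_post − t_pre:

* Δ < 0 (pre after post) — depression, a Gaussian window centered at
  M = −24 ms with width V = 6.32 ms:
      A ← A · (1 − d · exp(−(Δ−M)²/(2V²)) / (V·√(2π)))
* Δ > 0 (post after pre) — soft-bounded potentiation with e-folding
  τ = 2 ms:
      A ← A + (g_max − g0 − A) · p · exp(−Δ/τ)

A is clipped to [0, g_max − g0] after every update, so g_peak stays inside
[g0, g_max] for any event stream.  Pairings at exactly Δ = 0 are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STDPConfig
from .morphology import detect_threshold_crossings

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class STDPParams:
    M: float = -24.0          # ms, depression-window center
    V: float = 6.32           # ms, depression-window width
    tau: float = 2.0          # ms, potentiation e-folding
    d: float = 0.3            # depression strength
    p: float = 1.0            # potentiation strength
    g_peak_max: float = 1.0   # µS
    dendritic_spike_threshold: float = -10.0  # mV

    def __post_init__(self):
        if self.V <= 0 or self.tau <= 0 or self.d <= 0:
            raise ValueError("V, tau and d must be positive")

    @classmethod
    def from_config(cls, c: STDPConfig, g_peak_max: float) -> "STDPParams":
        return cls(M=c.M_ms, V=c.V_ms, tau=c.tau_ms, d=c.d, p=c.p,
                   g_peak_max=g_peak_max,
                   dendritic_spike_threshold=c.dendritic_threshold_mV)


@dataclass
class PlasticityState:
    A: float = 0.0
    last_pre: float | None = None
    last_post: float | None = None
    _last_t: float = -math.inf


def depression_window(delta_t: float, params: STDPParams) -> float:
    """Gaussian pairing window G(Δ), maximal at Δ = M."""
    return math.exp(-((delta_t - params.M) ** 2) / (2.0 * params.V ** 2)) / \
        (params.V * SQRT_2PI)


def depression_update(A: float, delta_t: float, params: STDPParams) -> float:
    """Depression branch (Δ = t_post − t_pre < 0): multiplicative shrink."""
    if delta_t >= 0:
        raise ValueError("depression branch requires delta_t < 0")
    return max(0.0, A * (1.0 - params.d * depression_window(delta_t, params)))


def potentiation_update(A: float, delta_t: float, g0: float,
                        params: STDPParams) -> float:
    """Potentiation branch (Δ > 0): headroom-limited additive increment."""
    if delta_t <= 0:
        raise ValueError("potentiation branch requires delta_t > 0")
    head = params.g_peak_max - g0 - A
    A_new = A + head * params.p * math.exp(-delta_t / params.tau)
    return min(max(A_new, 0.0), params.g_peak_max - g0)


def on_spike_event(state: PlasticityState, event: str, t: float,
                   params: STDPParams, g0: float) -> PlasticityState:
    """Process one pre or post event (nearest-neighbor pairing, in place).

    Events must arrive in nondecreasing time order; an event with no
    partner in history only updates the history.
    """
    if t < state._last_t:
        raise ValueError("events must be delivered in nondecreasing time order")
    state._last_t = t
    if event == "pre":
        if state.last_post is not None:
            delta = state.last_post - t
            if delta < 0:
                state.A = depression_update(state.A, delta, params)
        state.last_pre = t
    elif event == "post":
        if state.last_pre is not None:
            delta = t - state.last_pre
            if delta > 0:
                state.A = potentiation_update(state.A, delta, g0, params)
        state.last_post = t
    else:
        raise ValueError(f"unknown event type {event!r}")
    return state


def dendritic_spike_times(local_trace: np.ndarray, params: STDPParams,
                          dt_ms: float, t0_ms: float = 0.0) -> np.ndarray:
    """Post-event times: upward crossings of the dendritic threshold."""
    return detect_threshold_crossings(local_trace,
                                      params.dendritic_spike_threshold,
                                      dt_ms, t0_ms)


def weight_trace_frame(times_ms, g_peak, synapse_ids) -> pd.DataFrame:
    """Long-format weight trajectory log (time_ms, synapse_id, g_peak_uS)."""
    g = np.asarray(g_peak)
    rows = {
        "time_ms": np.repeat(np.asarray(times_ms), g.shape[1]),
        "synapse_id": np.tile(np.asarray(synapse_ids), g.shape[0]),
        "g_peak_uS": g.ravel(),
    }
    return pd.DataFrame(rows)
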