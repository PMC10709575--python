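"""AMPA+NMDA cue synapses on oblique dendrites.

Each oblique dendrite hosts exactly one synapse that stands for the
synchronous activation of a group of co-located inputs.  The AMPA
component is a peak-normalized double exponential (0.5 ms rise, 1 ms
decay, 0 mV reversal); the NMDA component is a slower double exponential
scaled by a sigmoidal voltage-dependent Mg-block factor (1 mM external
Mg²⁺).  The effective peak conductance is g0 + A, where g0 is the
calibrated baseline and A the plastic increment.

Baseline weights are calibrated per dendrite: the largest value on a
geometric grid for which a seeded background-rate (3 Hz) probe of that
synapse alone produces no local crossing of the dendritic spike threshold
("just below the spiking threshold at background frequency").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .config import SimulatorConfig, SynapseConfig
from .environment import poisson_spike_train
from .morphology import NeuronModel, detect_threshold_crossings


@dataclass
class SynapseParams:
    ampa_rise: float = 0.5       # ms
    ampa_decay: float = 1.0      # ms
    reversal: float = 0.0        # mV
    mg_concentration: float = 1.0  # mM
    nmda_rise: float = 5.0       # ms
    nmda_decay: float = 50.0     # ms
    nmda_to_ampa_ratio: float = 0.25
    mg_eta: float = 0.28         # per mM
    mg_gamma: float = 0.062      # per mV

    def __post_init__(self):
        if not (0 < self.ampa_rise < self.ampa_decay):
            raise ValueError("need 0 < ampa_rise < ampa_decay")
        if self.nmda_rise <= 0 or self.nmda_decay <= 0:
            raise ValueError("NMDA time constants must be positive")
        if self.mg_concentration <= 0:
            raise ValueError("Mg concentration must be positive")

    @classmethod
    def from_config(cls, c: SynapseConfig) -> "SynapseParams":
        return cls(ampa_rise=c.ampa_rise_ms, ampa_decay=c.ampa_decay_ms,
                   reversal=c.reversal_mV, mg_concentration=c.mg_mM,
                   nmda_rise=c.nmda_rise_ms, nmda_decay=c.nmda_decay_ms,
                   nmda_to_ampa_ratio=c.nmda_to_ampa_ratio,
                   mg_eta=c.mg_eta_per_mM, mg_gamma=c.mg_gamma_per_mV)


@dataclass
class SynapseState:
    """One cue synapse: identity, weight and presynaptic history."""

    synapse_id: str
    dendrite: str                    # oblique compartment id
    g0_peak: float                   # µS, calibrated baseline
    A: float = 0.0                   # µS, plastic increment
    feature_id: str = "background-only"
    presyn_spike_times: list = field(default_factory=list)

    @property
    def g_peak(self) -> float:
        return self.g0_peak + self.A


def _dual_exp(t, rise, decay):
    return np.exp(-t / decay) - np.exp(-t / rise)


def ampa_conductance(t_since_spike, params: SynapseParams, g_peak: float):
    """Peak-normalized double-exponential AMPA conductance (µS) at ``t``."""
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    norm = engine.dual_exp_norm(params.ampa_rise, params.ampa_decay)
    return g_peak * norm * _dual_exp(t, params.ampa_rise, params.ampa_decay)


def nmda_conductance(t_since_spike, params: SynapseParams, g_peak: float):
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be non-negative")
    norm = engine.dual_exp_norm(params.nmda_rise, params.nmda_decay)
    return g_peak * params.nmda_to_ampa_ratio * norm * \
        _dual_exp(t, params.nmda_rise, params.nmda_decay)


def mg_block(V, mg: float = 1.0, eta: float = 0.28, gamma: float = 0.062):
    """Voltage-dependent Mg²⁺ unblock factor in (0, 1].

    Sigmoid 1/(1 + η·[Mg]·exp(−γV)); → 0 for strongly hyperpolarized V,
    → 1 at depolarized V or vanishing [Mg].
    """
    if mg < 0:
        raise ValueError("Mg concentration cannot be negative")
    return 1.0 / (1.0 + eta * mg * np.exp(-gamma * np.asarray(V, dtype=float)))


def synaptic_current(syn: SynapseState, V_local: float, t: float,
                     params: SynapseParams) -> float:
    """Total synaptic current (nA, inward-negative) at time ``t`` ms.

    I = g·(V − E): negative (inward, depolarizing) below the 0 mV
    reversal.  Sums AMPA and Mg-blocked NMDA conductances over the recent
    presynaptic history (spikes older than 10 NMDA decay times are
    dropped).
    """
    horizon = 10.0 * params.nmda_decay
    g_a = 0.0
    g_n = 0.0
    for ts in syn.presyn_spike_times:
        dt = t - ts
        if dt < 0 or dt > horizon:
            continue
        g_a += float(ampa_conductance(dt, params, syn.g_peak))
        g_n += float(nmda_conductance(dt, params, syn.g_peak))
    g_n *= float(mg_block(V_local, params.mg_concentration,
                          params.mg_eta, params.mg_gamma))
    return (g_a + g_n) * (V_local - params.reversal)


# ----------------------------------------------------------------------
def place_cue_synapses(model: NeuronModel, feature_ids: list[str],
                       g0: np.ndarray | float = 0.0,
                       gmax_ratio: float = 1.8,
                       syn_cfg: SynapseConfig | None = None):
    """One synapse per oblique, feature i on oblique i.

    Returns (list of SynapseState, engine.SynapseArrays sharing the same
    weight arrays).
    """
    syn_cfg = syn_cfg or SynapseConfig()
    obliques = model.ids_in_region("oblique")
    if len(feature_ids) > len(obliques):
        raise ValueError("more features than oblique dendrites")
    g0_arr = np.broadcast_to(np.asarray(g0, dtype=float),
                             (len(feature_ids),)).copy()
    states = []
    comp_idx = []
    for i, fid in enumerate(feature_ids):
        dend = obliques[i]
        states.append(SynapseState(
            synapse_id=f"syn{i}", dendrite=dend, g0_peak=g0_arr[i],
            feature_id=fid))
        comp_idx.append(model.index_of(dend))
    arrays = engine.SynapseArrays(comp_idx, g0_arr, gmax_ratio * g0_arr,
                                  engine.syn_param_pack(syn_cfg))
    return states, arrays


def _probe_crossings(model, comp_idx, g0, rate_hz, duration_ms, seed,
                     syn_cfg, stdp_cfg):
    """Count threshold crossings in a single-synapse seeded probe run."""
    rng = np.random.default_rng(seed)
    ev_t = poisson_spike_train(lambda t: rate_hz, 0.0, duration_ms, rng)
    ev_syn = np.zeros(ev_t.size, dtype=np.int64)
    state = model.copy_state()
    arrays = engine.SynapseArrays([comp_idx], np.array([g0]),
                                  np.array([10.0 * g0 + 1.0]),
                                  engine.syn_param_pack(syn_cfg))
    out = engine.run_segment(model, duration_ms, syn=arrays,
                             events=(ev_t, ev_syn), stdp=stdp_cfg,
                             plasticity_on=False,
                             rec_stride_ms=0.0, soma_threshold=0.0)
    model.restore_state(state)
    return out["dend_spike_t"].size, out["soma_spikes"].size


def calibrate_baseline_weights(model: NeuronModel, cfg: SimulatorConfig,
                               seed: int | None = None) -> dict[str, float]:
    """Per-dendrite baseline peak conductances, "just below threshold".

    For each oblique in turn, walk a geometric grid of g0 values upward and
    keep the largest one whose seeded 3 Hz single-synapse probe produces no
    −10 mV crossing in that dendrite.  Reproducible given the calibration
    seed.  Returns mapping oblique compartment id → g0 (µS).
    """
    sc = cfg.synapse
    seed = sc.calibration_seed if seed is None else seed
    duration_ms = sc.calibration_duration_s * 1000.0
    obliques = model.ids_in_region("oblique")
    out: dict[str, float] = {}
    for k, dend in enumerate(obliques):
        ci = model.index_of(dend)
        g = sc.calibration_grid_start_uS
        best = None
        for _ in range(sc.calibration_grid_steps):
            n_dend, _ = _probe_crossings(
                model, ci, g, sc.background_rate_hz, duration_ms,
                seed + k, sc, cfg.stdp)
            if n_dend > 0:
                break
            best = g
            g *= sc.calibration_grid_factor
        if best is None:
            raise RuntimeError(
                f"{dend}: even the smallest grid conductance "
                f"({sc.calibration_grid_start_uS} µS) triggers a dendritic spike")
        # back off from the last silent grid point: the probe samples the
        # threshold with finite resolution, and "just below threshold" must
        # stay below it for any admissible background realization
        out[dend] = best / sc.calibration_grid_factor ** sc.calibration_backoff_steps
    return out


def export_weights(weights: dict[str, float], path) -> None:
    rows = [{"synapse_id": f"syn{i}", "dendrite_id": d, "g0_peak_uS": g}
            for i, (d, g) in enumerate(weights.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def import_weights(path) -> dict[str, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    return dict(zip(df["dendrite_id"], df["g0_peak_uS"]))
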