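"""Environment-coupled simulation sessions.

A session co-simulates the virtual animal (environment step, default
100 ms) and the compartmental neuron (sub-millisecond membrane step).  At
every environment step the visible feature set is re-evaluated, presynaptic
Poisson trains are regenerated at the corresponding rates, and — in
learning mode — the plateau protocol is triggered the first time the
rewarded object is fully in view.  STDP runs event-driven inside the
membrane integration (pre delivery → voltage step → dendritic spike
detection → weight update, pre before post within one step).

Modes: ``control_no_plateau`` (no trigger), ``learning_with_plateau``
(plateau gated by the rewarded object), ``recall`` (no plateau; weights
imported from a learning session, plasticity left free by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .config import SimulatorConfig
from .environment import (Arena, initial_trajectory_state, poisson_spike_train,
                          presynaptic_rates, step_trajectory, visible_features,
                          VisualField)
from .morphology import NeuronModel
from .plateau import PlateauProtocol
from .synapses import place_cue_synapses

MODES = ("control_no_plateau", "learning_with_plateau", "recall")


def prepare_simulation(cfg: SimulatorConfig):
    """Build and calibrate everything a session needs.

    Returns ``(model, arena, weights, amplitudes)``: the compartmental
    neuron at rest, the arena, per-dendrite baseline weights ("just below
    threshold" at background rate) and per-electrode plateau amplitudes.
    The two calibrations are deterministic (fixed calibration seed) and
    dominate the preparation cost (a few minutes of simulated probing).
    """
    from .morphology import build_morphology
    from .plateau import calibrate_amplitude
    from .synapses import calibrate_baseline_weights

    model = build_morphology(cfg)
    arena = Arena.from_config(cfg.arena)
    weights = calibrate_baseline_weights(model, cfg)
    protocol = PlateauProtocol.from_config(model, cfg.plateau,
                                           cfg.morphology.trunk_sections)
    if cfg.plateau.amplitude_nA is not None:
        amplitudes = np.broadcast_to(
            np.asarray(cfg.plateau.amplitude_nA, dtype=float),
            (len(protocol.electrode_compartments),)).copy()
    else:
        amplitudes = calibrate_amplitude(model, protocol, cfg, weights)
    return model, arena, weights, amplitudes


@dataclass
class SessionConfig:
    mode: str = "control_no_plateau"
    rewarded_object: str | None = None
    duration_s: float | None = None          # None → mode default
    seed_trajectory: int = 1
    seed_synaptic: int = 2
    plasticity_enabled: bool = True
    trigger_min_features: int | None = None  # None → all rewarded features
    record_stride_ms: float = 5.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "learning_with_plateau" and not self.rewarded_object:
            raise ValueError("learning mode requires a rewarded object")


@dataclass
class SimulationResult:
    somatic_spikes_ms: np.ndarray
    dend_spike_t_ms: np.ndarray
    dend_spike_syn: np.ndarray
    weight_t_ms: np.ndarray
    weight_g_peak: np.ndarray                # (n_samples, n_syn)
    traj_t_s: np.ndarray
    traj_xy: np.ndarray
    traj_heading: np.ndarray
    visible_sets: list
    probe_t_ms: np.ndarray
    probe_v: np.ndarray
    probe_ids: list
    plateau_onsets_ms: list
    synapse_ids: list
    dendrite_ids: list
    feature_ids: list
    g0: np.ndarray
    A_final: np.ndarray
    config_hash: str = ""
    dt_env_s: float = 0.1

    @property
    def g_peak_final(self) -> np.ndarray:
        return self.g0 + self.A_final

    def spike_positions(self) -> np.ndarray:
        """Arena position of the agent at each somatic spike (nearest sample)."""
        if self.somatic_spikes_ms.size == 0:
            return np.empty((0, 2))
        idx = np.clip(np.round(self.somatic_spikes_ms / 1000.0 /
                               self.dt_env_s).astype(int),
                      0, len(self.traj_t_s) - 1)
        return self.traj_xy[idx]

    def spikes_during_visibility(self, object_id: str) -> np.ndarray:
        """Boolean mask: somatic spike fell while a feature of the object
        was in the visual field (at environment-step resolution)."""
        prefix = object_id + ":"
        vis = np.array([any(f.startswith(prefix) for f in s)
                        for s in self.visible_sets])
        if self.somatic_spikes_ms.size == 0:
            return np.empty(0, dtype=bool)
        idx = np.clip((self.somatic_spikes_ms / 1000.0 /
                       self.dt_env_s).astype(int), 0, len(vis) - 1)
        return vis[idx]


def interleaved_feature_ids(arena: Arena) -> list[str]:
    """Feature → oblique assignment order: objects interleaved.

    Feature k of object j goes to oblique j + k·n_objects, so each
    object's features spread over the whole trunk rather than clustering
    on one branch region.
    """
    lists = [o.feature_ids() for o in arena.objects]
    out = []
    for k in range(max(len(l) for l in lists)):
        for l in lists:
            if k < len(l):
                out.append(l[k])
    return out


def reward_trigger(visible: set[str], rewarded_object: str,
                   already_fired: bool, n_features: int,
                   min_features: int | None = None) -> bool:
    """Decide whether to start the plateau at this environment step.

    Fires on the first step where at least ``min_features`` (default: all)
    of the rewarded object's features are in view; a lockout (handled by
    the caller through ``already_fired``) limits it to once per session.
    """
    if already_fired:
        return False
    need = n_features if min_features is None else min_features
    count = sum(1 for f in visible if f.startswith(rewarded_object + ":"))
    return count >= need


def run_session(model: NeuronModel, arena: Arena, cfg: SimulatorConfig,
                session: SessionConfig, weights: dict[str, float],
                plateau_amplitude_nA: float | None = None,
                initial_A: np.ndarray | None = None) -> SimulationResult:
    """Run one environment-coupled session; deterministic given the seeds.

    ``weights`` maps oblique compartment id → calibrated g0 (µS).
    Learning mode needs a calibrated ``plateau_amplitude_nA``.
    """
    durations = {"control_no_plateau": cfg.durations.control_s,
                 "learning_with_plateau": cfg.durations.learning_s,
                 "recall": cfg.durations.recall_s}
    duration_s = session.duration_s or durations[session.mode]
    dt_env = cfg.trajectory.dt_env_s
    n_env = int(round(duration_s / dt_env))
    model.reset_to_rest()

    feature_ids = interleaved_feature_ids(arena)
    states, syn = place_cue_synapses(
        model, feature_ids,
        g0=np.array([weights[f"oblique{i}"] for i in range(len(feature_ids))]),
        gmax_ratio=cfg.synapse.g_peak_max_ratio, syn_cfg=cfg.synapse)
    if initial_A is not None:
        syn.A[:] = initial_A
    synapse_map = {s.feature_id: s.synapse_id for s in states}
    syn_order = {s.synapse_id: i for i, s in enumerate(states)}

    vf = VisualField.from_config(cfg.visual)
    rng_traj = np.random.default_rng(session.seed_trajectory)
    rng_syn = np.random.default_rng(session.seed_synaptic)
    traj = initial_trajectory_state(cfg.trajectory, rng_traj, arena)

    use_plateau = session.mode == "learning_with_plateau"
    protocol = None
    injections = None
    if use_plateau:
        if plateau_amplitude_nA is None and cfg.plateau.amplitude_nA is None:
            raise ValueError("learning mode requires a calibrated amplitude")
        protocol = PlateauProtocol.from_config(
            model, cfg.plateau, cfg.morphology.trunk_sections)
        if plateau_amplitude_nA is not None:
            protocol.amplitude = plateau_amplitude_nA
        else:
            protocol.amplitude = cfg.plateau.amplitude_nA

    n_feat_rewarded = 0
    if session.rewarded_object:
        n_feat_rewarded = next(o.n_features for o in arena.objects
                               if o.object_id == session.rewarded_object)

    probe_ids = ["soma"]
    for region_pick in (0, 1):
        probe_ids.append(states[region_pick].dendrite)
    probes = [model.index_of(p) for p in probe_ids]
    soma_above = np.zeros(1, dtype=np.int64)

    traj_t, traj_xy, traj_h, vis_sets = [], [], [], []
    soma_sp, dend_t, dend_s = [], [], []
    w_t, w_g, pv_t, pv_v = [], [], [], []
    plateau_onsets: list[float] = []
    triggered = False

    for step in range(n_env):
        t_ms = step * dt_env * 1000.0
        traj_t.append(traj.time)
        traj_xy.append(traj.position.copy())
        traj_h.append(traj.heading)
        visible = visible_features(traj, arena, vf)
        vis_sets.append(frozenset(visible))

        if use_plateau and reward_trigger(
                visible, session.rewarded_object, triggered,
                n_feat_rewarded, session.trigger_min_features):
            triggered = True
            protocol.t_start = t_ms
            plateau_onsets.append(t_ms)
            injections = protocol.injection_arrays(model)

        rates = presynaptic_rates(visible, synapse_map,
                                  cfg.synapse.cue_rate_hz,
                                  cfg.synapse.background_rate_hz)
        ev_t_all, ev_syn_all = [], []
        for sid, rate in rates.items():
            times = poisson_spike_train(lambda _t: rate, t_ms,
                                        t_ms + dt_env * 1000.0, rng_syn)
            ev_t_all.append(times)
            ev_syn_all.append(np.full(times.size, syn_order[sid],
                                      dtype=np.int64))
        ev_t = np.concatenate(ev_t_all)
        ev_syn = np.concatenate(ev_syn_all)
        order = np.argsort(ev_t, kind="stable")

        out = engine.run_segment(
            model, dt_env * 1000.0, t0=t_ms, syn=syn,
            events=(ev_t[order], ev_syn[order]), stdp=cfg.stdp,
            plasticity_on=session.plasticity_enabled,
            injections=injections,
            injection_ramp_ms=(protocol.onset_ramp if protocol else 0.0),
            probes=probes,
            rec_stride_ms=session.record_stride_ms,
            soma_threshold=cfg.integration.somatic_threshold_mV,
            soma_above=soma_above)

        soma_sp.append(out["soma_spikes"])
        dend_t.append(out["dend_spike_t"])
        dend_s.append(out["dend_spike_syn"])
        w_t.append(out["probe_t"])
        w_g.append(out["weights"])
        pv_t.append(out["probe_t"])
        pv_v.append(out["probe_v"])

        traj = step_trajectory(traj, dt_env, rng_traj, arena,
                               cfg.trajectory.heading_std_deg)

    return SimulationResult(
        somatic_spikes_ms=np.concatenate(soma_sp),
        dend_spike_t_ms=np.concatenate(dend_t),
        dend_spike_syn=np.concatenate(dend_s),
        weight_t_ms=np.concatenate(w_t),
        weight_g_peak=np.vstack(w_g),
        traj_t_s=np.array(traj_t),
        traj_xy=np.array(traj_xy),
        traj_heading=np.array(traj_h),
        visible_sets=vis_sets,
        probe_t_ms=np.concatenate(pv_t),
        probe_v=np.vstack(pv_v),
        probe_ids=probe_ids,
        plateau_onsets_ms=plateau_onsets,
        synapse_ids=[s.synapse_id for s in states],
        dendrite_ids=[s.dendrite for s in states],
        feature_ids=feature_ids,
        g0=syn.g0.copy(),
        A_final=syn.A.copy(),
        config_hash=cfg.config_hash(),
        dt_env_s=dt_env,
    )


# ----------------------------------------------------------------------
def freeze_and_export_weights(result: SimulationResult, path) -> None:
    """Serialize final per-synapse weights with the config hash."""
    pd.DataFrame({
        "synapse_id": result.synapse_ids,
        "dendrite_id": result.dendrite_ids,
        "feature_id": result.feature_ids,
        "g0_peak_uS": result.g0,
        "A_uS": result.A_final,
        "g_peak_uS": result.g_peak_final,
        "config_hash": result.config_hash,
    }).to_csv(path, index=False)


def import_session_weights(path):
    """Load (g0 mapping, A array, config_hash) exported by a session."""
    df = pd.read_csv(path, float_precision="round_trip")
    g0 = dict(zip(df["dendrite_id"], df["g0_peak_uS"]))
    return g0, df["A_uS"].to_numpy(), str(df["config_hash"].iloc[0])


def export_session(result: SimulationResult, out_dir, cfg=None) -> None:
    """Write spikes.csv, weights.csv, trajectory.csv and session_meta.json."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_ms": result.somatic_spikes_ms}).to_csv(
        out / "spikes.csv", index=False)
    freeze_and_export_weights(result, out / "weights.csv")
    pd.DataFrame({
        "time_s": result.traj_t_s,
        "x": result.traj_xy[:, 0],
        "y": result.traj_xy[:, 1],
        "heading_deg": result.traj_heading,
        "visible_feature_ids": [";".join(sorted(s))
                                for s in result.visible_sets],
    }).to_csv(out / "trajectory.csv", index=False)
    meta = {"config_hash": result.config_hash,
            "plateau_onsets_ms": result.plateau_onsets_ms,
            "n_somatic_spikes": int(result.somatic_spikes_ms.size)}
    if cfg is not None:
        meta["config"] = cfg.to_dict()
    (out / "session_meta.json").write_text(json.dumps(meta, indent=2))
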