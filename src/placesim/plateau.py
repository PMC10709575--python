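"""Forward-propagating dendritic plateau emulation.

The plateau potential triggered by the distal (entorhinal) input is
emulated, as an empirical surrogate for a calcium wave, by four 200 ms
current steps injected at four apical-trunk locations, activated
sequentially every 500 ms starting from the most distal electrode and
moving proximally.  The injection amplitude is calibrated (it is a free
parameter of the emulation): the smallest grid value that drives each
electrode's trunk section over the dendritic spike threshold during its
step while depolarizing the oblique branches by a configured margin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .config import PlateauConfig, SimulatorConfig
from .morphology import NeuronModel, electrode_sections


@dataclass
class PlateauProtocol:
    """Schedule of four trunk current-injection epochs (distal first)."""

    electrode_compartments: list[str]
    step_duration: float = 200.0          # ms
    inter_onset_interval: float = 500.0   # ms
    amplitude: float | list = 1.0         # nA, scalar or one value per electrode
    t_start: float = 0.0                  # ms
    onset_ramp: float = 25.0              # ms, exponential rise of each step

    def validate(self, model: NeuronModel) -> None:
        dists = [model.compartments[model.index_of(c)].path_distance_to_soma
                 for c in self.electrode_compartments]
        if not all(a > b for a, b in zip(dists, dists[1:])):
            raise ValueError("electrodes must be ordered distal → proximal")

    def onsets(self) -> np.ndarray:
        k = np.arange(len(self.electrode_compartments))
        return self.t_start + k * self.inter_onset_interval

    @property
    def total_span(self) -> float:
        return (len(self.electrode_compartments) - 1) * \
            self.inter_onset_interval + self.step_duration

    def injection_arrays(self, model: NeuronModel):
        """(comp_idx, on, off, amp) arrays for the integration kernel."""
        comp = np.array([model.index_of(c)
                         for c in self.electrode_compartments], dtype=np.int64)
        on = self.onsets()
        off = on + self.step_duration
        amp = np.broadcast_to(np.asarray(self.amplitude, dtype=float),
                              comp.shape).copy()
        return comp, on, off, amp

    @classmethod
    def from_config(cls, model: NeuronModel, cfg: PlateauConfig,
                    trunk_sections: int, t_start: float = 0.0
                    ) -> "PlateauProtocol":
        secs = electrode_sections(trunk_sections, cfg.n_electrodes)
        proto = cls([f"trunk{s}" for s in secs],
                    step_duration=cfg.step_duration_ms,
                    inter_onset_interval=cfg.inter_onset_interval_ms,
                    amplitude=cfg.amplitude_nA or 1.0,
                    t_start=t_start, onset_ramp=cfg.onset_ramp_ms)
        proto.validate(model)
        return proto


def injected_current(protocol: PlateauProtocol, compartment: str,
                     t: float) -> float:
    """Injected current (nA) into ``compartment`` at time ``t`` ms.

    Reports the step plateau level (the exponential onset ramp is an
    integration detail applied by the engine).
    """
    amps = np.broadcast_to(np.asarray(protocol.amplitude, dtype=float),
                           (len(protocol.electrode_compartments),))
    for k, comp in enumerate(protocol.electrode_compartments):
        if comp != compartment:
            continue
        onset = protocol.t_start + k * protocol.inter_onset_interval
        if onset <= t < onset + protocol.step_duration:
            return float(amps[k])
    return 0.0


def adjacent_obliques(model, electrode_comp: str) -> list[str]:
    """Obliques on the trunk section just distal to an electrode."""
    sec = int(electrode_comp.removeprefix("trunk"))
    host = f"trunk{sec + 1}"
    return [c.id for c in model.compartments
            if c.region == "oblique" and c.parent == host]


def _protocol_trial(model, protocol, cfg, probe_obls, g0s, seed):
    """Full ramped protocol with 80 Hz probes on selected obliques.

    Returns per-epoch electrode peak V, per-probe depolarization above
    rest within its nearest epoch, and per-probe crossing counts.
    """
    state = model.copy_state()
    rest = model.v.copy()
    protocol = dataclasses.replace(protocol, t_start=100.0)
    span = protocol.total_span + 200.0
    rng = np.random.default_rng(seed)
    ev_t, ev_s = [np.empty(0)], [np.empty(0, dtype=np.int64)]
    for j in range(len(probe_obls)):
        n = rng.poisson(cfg.synapse.cue_rate_hz * span / 1000.0)
        ev_t.append(np.sort(rng.random(n) * span))
        ev_s.append(np.full(n, j, dtype=np.int64))
    ev_t = np.concatenate(ev_t)
    ev_s = np.concatenate(ev_s)
    order = np.argsort(ev_t, kind="stable")
    obl_idx = [model.index_of(o) for o in probe_obls]
    if probe_obls:
        arrays = engine.SynapseArrays(obl_idx, np.asarray(g0s, dtype=float),
                                      10.0 * np.asarray(g0s) + 1.0,
                                      engine.syn_param_pack(cfg.synapse))
    else:
        arrays = None
    out = engine.run_segment(
        model, span, syn=arrays, events=(ev_t[order], ev_s[order]),
        stdp=cfg.stdp, injections=protocol.injection_arrays(model),
        injection_ramp_ms=protocol.onset_ramp,
        probes=[model.index_of(c) for c in protocol.electrode_compartments]
        + obl_idx, rec_stride_ms=1.0)
    model.restore_state(state)
    t = out["probe_t"]
    n_el = len(protocol.electrode_compartments)
    # sustained suprathreshold fraction of the electrode during its step
    # (a plateau, not a passing action potential)
    thr = cfg.stdp.dendritic_threshold_mV
    frac_elec = np.empty(n_el)
    epoch_sel = []
    for k in range(n_el):
        onset = protocol.t_start + k * protocol.inter_onset_interval
        sel = (t >= onset) & (t < onset + protocol.step_duration)
        epoch_sel.append((onset, onset + protocol.step_duration))
        frac_elec[k] = (out["probe_v"][sel, k] >= thr).mean()
    depol = np.empty(len(probe_obls))
    for j, oi in enumerate(obl_idx):
        depol[j] = out["probe_v"][:, n_el + j].max() - rest[oi]
    return frac_elec, depol, out, epoch_sel


def calibrate_amplitude(model: NeuronModel, protocol: PlateauProtocol,
                        cfg: SimulatorConfig,
                        weights: dict[str, float]) -> np.ndarray:
    """Per-electrode injection amplitudes (nA), distal first.

    Electrodes are calibrated sequentially in the context of the full
    four-epoch protocol: for each electrode, the smallest amplitude on a
    geometric grid such that during its epoch (i) the electrode's trunk
    compartment stays above the dendritic spike threshold for at least
    half the step (a sustained plateau, not a passing spike), (ii) the
    obliques on the adjacent trunk section are depolarized by at least
    ``target_oblique_depol_mV`` above rest, and (iii) an 80 Hz cue probe
    on each of those obliques (at its calibrated baseline weight, fixed
    seed) elicits at least one local dendritic spike within that epoch.
    Deterministic given the calibration seed.
    """
    pc = cfg.plateau
    n_el = len(protocol.electrode_compartments)
    amps = np.full(n_el, pc.calibration_grid_start_nA)
    for k, elec in enumerate(protocol.electrode_compartments):
        # probe an interleaved half of the host's obliques: during learning
        # only one object's features (every other oblique) fire at the cue
        # rate, so this is the co-activation pattern the step must serve
        obls = adjacent_obliques(model, elec)[::2]
        g0s = [weights[o] for o in obls]
        found = None
        amp = pc.calibration_grid_start_nA
        for _ in range(pc.calibration_grid_steps):
            amps[k] = amp
            trial = dataclasses.replace(protocol)
            trial.amplitude = amps.copy()
            frac_elec, depol, out, epochs = _protocol_trial(
                model, trial, cfg, obls, g0s,
                cfg.synapse.calibration_seed + 101 + k)
            lo, hi = epochs[k]
            in_epoch = (out["dend_spike_t"] >= lo) & (out["dend_spike_t"] < hi)
            crossings = np.bincount(out["dend_spike_syn"][in_epoch],
                                    minlength=max(len(obls), 1))
            obl_ok = (len(obls) == 0
                      or (depol.min() >= pc.target_oblique_depol_mV
                          and crossings[:len(obls)].min() >= 1))
            if frac_elec[k] >= 0.5 and obl_ok:
                found = amp
                break
            amp *= pc.calibration_grid_factor
        if found is None:
            raise RuntimeError(
                f"amplitude grid exhausted for electrode {elec}")
        amps[k] = found
    return amps


def propagation_profile(probe_t: np.ndarray, probe_v: np.ndarray,
                        distances_um: np.ndarray,
                        bin_width_um: float = 50.0):
    """Mean voltage as a function of path distance at each time sample.

    Returns (bin_centers_um, profile) with profile shaped
    (n_times, n_bins); bins with no compartments are NaN.
    """
    distances_um = np.asarray(distances_um, dtype=float)
    edges = np.arange(0.0, distances_um.max() + bin_width_um, bin_width_um)
    if edges.size < 2:
        edges = np.array([0.0, bin_width_um])
    which = np.clip(np.digitize(distances_um, edges) - 1, 0, edges.size - 2)
    n_bins = edges.size - 1
    prof = np.full((probe_v.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            prof[:, b] = probe_v[:, sel].mean(axis=1)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, prof


def peak_distance_per_epoch(protocol: PlateauProtocol, probe_t: np.ndarray,
                            centers_um: np.ndarray, profile: np.ndarray
                            ) -> np.ndarray:
    """Distance of the profile's voltage peak, averaged within each epoch."""
    filled = np.isfinite(profile).any(axis=0)
    out = []
    for k in range(len(protocol.electrode_compartments)):
        onset = protocol.t_start + k * protocol.inter_onset_interval
        sel = (probe_t >= onset + 20.0) & \
            (probe_t < onset + protocol.step_duration)
        mean_v = np.nanmean(profile[np.ix_(sel, filled)], axis=0)
        out.append(centers_um[filled][int(np.nanargmax(mean_v))])
    return np.array(out)
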