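"""Configuration objects and the canonical two-object scenario.

All simulator parameters live in plain dataclasses that serialize to/from
YAML.  Units follow one convention throughout the package: mV, ms, nA, µS,
nF, S/cm², µm for the neuron; arena lengths are dimensionless "arena units"
(the square arena has side 1 by default) and environment time is seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class MorphologyConfig:
    """Geometry of the reduced CA1 pyramidal cell.

    The cell is a soma, a short axon chain, a single apical trunk chain,
    ``n_oblique`` oblique side branches attached at distinct trunk
    positions, and one lumped basal dendrite.
    """

    n_oblique: int = 14
    trunk_sections: int = 8
    soma_length_um: float = 20.0
    soma_diameter_um: float = 20.0
    axon_sections: int = 2
    axon_length_um: float = 50.0
    axon_diameter_um: float = 1.0
    trunk_length_um: float = 50.0          # per section
    trunk_diameter_um: float = 2.0
    oblique_length_um: float = 80.0
    oblique_length_step_um: float = 2.0    # makes oblique path distances distinct
    oblique_diameter_um: float = 0.8
    basal_length_um: float = 150.0
    basal_diameter_um: float = 4.0
    axial_resistivity_ohm_cm: float = 150.0
    specific_capacitance_uF_cm2: float = 1.0
    leak_conductance_S_cm2: float = 5e-5
    leak_reversal_mV: float = -66.0


@dataclass
class ChannelConfig:
    """Peak conductance densities (S/cm²) and linear distance gradients.

    K_A and I_h densities grow linearly with path distance from the soma;
    Na and K_DR are uniform; K_M is restricted to soma and axon.
    """

    na_soma: float = 0.8
    na_axon: float = 1.6
    na_dend: float = 0.15
    kdr_soma: float = 0.1
    kdr_axon: float = 0.2
    kdr_dend: float = 0.002
    kdr_trunk: float | None = None   # None → kdr_dend
    na_trunk: float = 0.15           # apical trunk Na (spike relay)
    ka_prox_base: float = 0.005
    ka_prox_slope: float = 1e-5
    ka_dist_base: float = 0.03
    ka_dist_slope: float = 5e-6
    ih_base: float = 0.004
    ih_soma: float = 0.004           # soma/basal I_h density
    ih_slope: float = 1e-6
    km_soma_axon: float = 0.004
    e_na: float = 55.0
    e_k: float = -90.0
    e_h: float = -30.0
    # gate-kinetics overrides: gate name → [v_half mV, slope mV, tau ms]
    kinetics: dict = field(default_factory=dict)


@dataclass
class SynapseConfig:
    """AMPA+NMDA cue synapse parameters (one synapse per oblique)."""

    ampa_rise_ms: float = 0.5
    ampa_decay_ms: float = 1.0
    nmda_rise_ms: float = 5.0
    nmda_decay_ms: float = 30.0
    reversal_mV: float = 0.0
    nmda_to_ampa_ratio: float = 6.0
    nmda_saturation_volleys: int = 3   # volleys to reach the NMDA ceiling
    mg_mM: float = 1.0
    mg_eta_per_mM: float = 0.0214936      # unblock half-voltage −32 mV
    mg_gamma_per_mV: float = 0.12
    # baseline-weight calibration
    background_rate_hz: float = 3.0
    cue_rate_hz: float = 80.0
    calibration_duration_s: float = 10.0
    calibration_seed: int = 20260101
    calibration_grid_start_uS: float = 5e-4
    calibration_grid_factor: float = 1.1
    calibration_grid_steps: int = 60
    calibration_backoff_steps: int = 7   # grid steps below the last silent point
    g_peak_max_ratio: float = 1.8        # g_peak_max = ratio * calibrated g0


@dataclass
class STDPConfig:
    """Spike-timing-dependent plasticity rule parameters."""

    M_ms: float = -24.0
    V_ms: float = 6.32
    tau_ms: float = 2.0
    d: float = 0.3
    p: float = 1.0
    dendritic_threshold_mV: float = -10.0


@dataclass
class PlateauConfig:
    """Forward-propagating plateau emulation: four trunk current steps."""

    step_duration_ms: float = 200.0
    inter_onset_interval_ms: float = 500.0
    onset_ramp_ms: float = 25.0          # exponential rise of each step
    amplitude_nA: float | None = None    # None → calibrate ("auto")
    n_electrodes: int = 4
    target_oblique_depol_mV: float = 25.0
    calibration_grid_start_nA: float = 1.0
    calibration_grid_factor: float = 1.1
    calibration_grid_steps: int = 60


@dataclass
class ObjectConfig:
    object_id: str = "red"
    x: float = 0.85
    y: float = 0.5
    width: float = 0.06
    height: float = 0.5
    n_features: int = 7


@dataclass
class ArenaConfig:
    side_length: float = 1.0
    rotation_deg: float = 0.0
    objects: list[ObjectConfig] = field(default_factory=list)


@dataclass
class VisualConfig:
    fov_deg: float = 90.0
    max_range: float = 0.8
    full_resolution_fraction: float = 0.45   # of max_range; 0 → pure linear decay


@dataclass
class TrajectoryConfig:
    speed: float = 0.15                  # arena units / s
    heading_std_deg: float = 12.0        # per environment step
    dt_env_s: float = 0.1
    x0: float = 0.5
    y0: float = 0.5
    heading0_deg: float = 0.0


@dataclass
class IntegrationConfig:
    dt_ms: float = 0.025
    max_dt_ms: float = 0.05
    somatic_threshold_mV: float = 0.0
    probe_stride_ms: float = 1.0


@dataclass
class SessionDurations:
    control_s: float = 60.0
    learning_s: float = 120.0
    recall_s: float = 300.0


@dataclass
class SimulatorConfig:
    """Top-level configuration bundle."""

    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    arena: ArenaConfig = field(default_factory=ArenaConfig)
    visual: VisualConfig = field(default_factory=VisualConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    durations: SessionDurations = field(default_factory=SessionDurations)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (provenance stamps)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def canonical_scenario(dt_ms: float = 0.05) -> SimulatorConfig:
    """The canonical two-object study configuration.

    A unit square arena with two vertical bars on opposite sides ("red" on
    the right, "blue" on the left), 7 features per object, each feature
    wired to its own oblique dendrite (14 cue synapses total).
    """
    cfg = SimulatorConfig()
    cfg.integration.dt_ms = dt_ms
    cfg.arena.objects = [
        ObjectConfig(object_id="red", x=0.85, y=0.5, width=0.06, height=0.5,
                     n_features=7),
        ObjectConfig(object_id="blue", x=0.15, y=0.5, width=0.06, height=0.5,
                     n_features=7),
    ]
    return cfg


def _from_dict(cls, data):
    if data is None:
        return cls()
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "objects":
            v = [_from_dict(ObjectConfig, o) for o in v]
        elif dataclasses.is_dataclass(f.type) or f.name in _SECTION_TYPES:
            v = _from_dict(_SECTION_TYPES[f.name], v)
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTION_TYPES = {
    "morphology": MorphologyConfig,
    "channels": ChannelConfig,
    "synapse": SynapseConfig,
    "stdp": STDPConfig,
    "plateau": PlateauConfig,
    "arena": ArenaConfig,
    "visual": VisualConfig,
    "trajectory": TrajectoryConfig,
    "integration": IntegrationConfig,
    "durations": SessionDurations,
}


def load_config(path) -> SimulatorConfig:
    """Read a YAML configuration file; missing sections fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = SimulatorConfig()
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            setattr(cfg, name, _from_dict(cls, data[name]))
    return cfg


def save_config(cfg: SimulatorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
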