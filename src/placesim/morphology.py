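"""Reduced compartmental CA1 pyramidal neuron.

The cell is a tree of cylindrical compartments rooted at the soma: a short
axon chain, an apical trunk chain, oblique side branches (one cue synapse
each), and a lumped basal dendrite.  Six voltage-gated conductances are
distributed over the tree — transient Na, delayed-rectifier K, proximal and
distal A-type K, the hyperpolarization-activated mixed-cation current I_h,
and the muscarinic K_M (soma and axon only).  K_A and I_h peak densities
increase linearly with path distance from the soma.

Voltage is integrated with a fully implicit (backward-Euler) cable step on
the tree (Hines elimination) and exponential-Euler gating updates; see
:mod:`placesim.engine` for the inner loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ChannelConfig, MorphologyConfig, SimulatorConfig
from . import engine

REGIONS = ("soma", "axon", "trunk", "oblique", "basal")

MAX_DT_MS = 0.05   # largest step the implicit integrator is validated for

CHANNELS = ("Na", "K_DR", "K_A_proximal", "K_A_distal", "I_h", "K_M")


@dataclass
class Compartment:
    """One cylindrical section of membrane."""

    id: str
    region: str
    length: float                  # µm
    diameter: float                # µm
    path_distance_to_soma: float   # µm, measured at the compartment midpoint
    parent: str | None
    axial_resistivity: float       # Ω·cm
    specific_capacitance: float    # µF/cm²
    leak_conductance: float        # S/cm²
    leak_reversal: float           # mV

    @property
    def area_cm2(self) -> float:
        return math.pi * self.diameter * self.length * 1e-8


@dataclass
class ChannelDistribution:
    """Linear-in-distance conductance density profile for one channel type."""

    channel: str
    gbar_at_soma: float            # S/cm²
    linear_slope: float            # S/cm² per µm
    region_mask: frozenset
    reversal: float                # mV

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.channel == "K_M" and self.region_mask != frozenset({"soma", "axon"}):
            raise ValueError("K_M is restricted to soma and axon")
        if self.channel in ("Na", "K_DR") and self.linear_slope != 0:
            raise ValueError(f"{self.channel} density must be uniform (slope 0)")
        if self.channel in ("K_A_proximal", "K_A_distal", "I_h") and self.linear_slope <= 0:
            raise ValueError(f"{self.channel} requires a positive distance gradient")


def channel_density_at(dist: ChannelDistribution, x: float, region: str | None = None) -> float:
    """Conductance density (S/cm²) at path distance ``x`` µm from the soma.

    Zero if ``region`` is given and outside the distribution's region mask.
    """
    if x < 0:
        raise ValueError("path distance must be non-negative")
    if region is not None and region not in dist.region_mask:
        return 0.0
    return max(0.0, dist.gbar_at_soma + dist.linear_slope * x)


@dataclass
class NeuronModel:
    """Compartment tree plus flattened numeric state used by the integrator."""

    compartments: list[Compartment]
    channels: list[ChannelDistribution]
    integration_dt: float
    # flattened arrays (filled by build_morphology)
    parent_idx: np.ndarray = field(default=None, repr=False)
    cap_nF: np.ndarray = field(default=None, repr=False)
    g_leak_uS: np.ndarray = field(default=None, repr=False)
    e_leak: np.ndarray = field(default=None, repr=False)
    g_axial_uS: np.ndarray = field(default=None, repr=False)
    gbar_uS: dict = field(default=None, repr=False)   # channel name → per-comp µS
    v: np.ndarray = field(default=None, repr=False)
    gates: np.ndarray = field(default=None, repr=False)  # (engine.N_GATES, n)
    e_rev: dict = field(default=None, repr=False)
    kin: np.ndarray = field(default=None, repr=False)    # gate kinetics table
    s_mask: np.ndarray = field(default=None, repr=False)  # slow-Na-inact regions

    def __post_init__(self):
        self._index = {c.id: i for i, c in enumerate(self.compartments)}

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    def index_of(self, comp_id: str) -> int:
        return self._index[comp_id]

    def ids_in_region(self, region: str) -> list[str]:
        return [c.id for c in self.compartments if c.region == region]

    @property
    def membrane_potential(self) -> np.ndarray:
        return self.v

    def initialize_rest(self, settle_ms: float = 500.0, v0: float = -65.0) -> None:
        """Set V and gating to steady state, then settle the full model.

        The settled state is kept as the model's rest snapshot so that
        every session can start from an identical, reproducible state.
        """
        self.v = np.full(self.n, v0)
        self.gates = engine.gates_at_steady_state(self.v, self.kin)
        if settle_ms > 0:
            zero = np.zeros(self.n)
            engine.integrate_passive_segment(self, settle_ms, zero)
        self._rest_snapshot = self.copy_state()

    def reset_to_rest(self) -> None:
        """Restore membrane potential and gating to the rest snapshot."""
        self.restore_state(self._rest_snapshot)

    def copy_state(self):
        return self.v.copy(), self.gates.copy()

    def restore_state(self, state) -> None:
        self.v, self.gates = state[0].copy(), state[1].copy()


# ----------------------------------------------------------------------
def default_channels(ch: ChannelConfig) -> list[ChannelDistribution]:
    """The default channel complement for the reduced cell.

    Na and K_DR are present in every excitable region (with region-specific
    density handled in :func:`build_morphology` via per-region overrides);
    A-type K splits into a proximal variant (soma, basal) and a distal
    variant (trunk, obliques) whose density grows with distance; I_h grows
    with distance over the apical tree; K_M is somato-axonal only.
    """
    return [
        ChannelDistribution("Na", ch.na_dend, 0.0,
                            frozenset({"soma", "axon", "trunk", "oblique"}), ch.e_na),
        ChannelDistribution("K_DR", ch.kdr_dend, 0.0,
                            frozenset({"soma", "axon", "trunk", "oblique"}), ch.e_k),
        ChannelDistribution("K_A_proximal", ch.ka_prox_base, ch.ka_prox_slope,
                            frozenset({"soma", "basal"}), ch.e_k),
        ChannelDistribution("K_A_distal", ch.ka_dist_base, ch.ka_dist_slope,
                            frozenset({"trunk", "oblique"}), ch.e_k),
        ChannelDistribution("I_h", ch.ih_base, ch.ih_slope,
                            frozenset({"soma", "trunk", "oblique", "basal"}), ch.e_h),
        ChannelDistribution("K_M", ch.km_soma_axon, 0.0,
                            frozenset({"soma", "axon"}), ch.e_k),
    ]


def oblique_attachment_sections(n_oblique: int, trunk_sections: int) -> list[int]:
    """Trunk section index (0 = most proximal) hosting each oblique.

    Obliques attach to the non-electrode trunk sections (every other
    section, starting from the second-most-distal) so that the plateau
    injection sites are separated from the synaptic branch points by one
    axial segment.  Consecutive oblique pairs walk distal → proximal, which
    spreads each object's feature set (even/odd interleaved) over the whole
    trunk.
    """
    hosts = [s for s in range(trunk_sections - 1, 2, -2)]
    if not hosts:
        hosts = list(range(trunk_sections))
    return [hosts[(i // 2) % len(hosts)] for i in range(n_oblique)]


def electrode_sections(trunk_sections: int, n_electrodes: int = 4) -> list[int]:
    """Trunk sections carrying the plateau electrodes, distal first."""
    secs = [s for s in range(trunk_sections - 2, -1, -2)][:n_electrodes]
    if len(secs) < n_electrodes:
        raise ValueError("not enough trunk sections for the electrodes")
    return secs


def build_morphology(cfg: SimulatorConfig, min_oblique: int | None = None) -> NeuronModel:
    """Construct the reduced compartment tree and its flattened arrays.

    Raises ``ValueError`` if the configured oblique count cannot host the
    cue synapses of the default scenario, or on non-positive geometry.
    """
    m = cfg.morphology
    required = min_oblique if min_oblique is not None else sum(
        o.n_features for o in cfg.arena.objects) or 14
    if m.n_oblique < required:
        raise ValueError(
            f"n_oblique={m.n_oblique} cannot host {required} cue synapses")
    if m.trunk_sections < 4:
        raise ValueError("trunk needs at least 4 sections")
    for name in ("soma_length_um", "soma_diameter_um", "trunk_length_um",
                 "trunk_diameter_um", "oblique_length_um", "oblique_diameter_um",
                 "axon_length_um", "axon_diameter_um", "basal_length_um",
                 "basal_diameter_um", "axial_resistivity_ohm_cm"):
        if getattr(m, name) <= 0:
            raise ValueError(f"non-positive geometry: {name}")

    comps: list[Compartment] = []

    def add(cid, region, length, diam, parent):
        if parent is None:
            dist = 0.0
        else:
            p = comps[idx[parent]]
            dist = p.path_distance_to_soma + p.length / 2 + length / 2
        comps.append(Compartment(
            id=cid, region=region, length=length, diameter=diam,
            path_distance_to_soma=dist, parent=parent,
            axial_resistivity=m.axial_resistivity_ohm_cm,
            specific_capacitance=m.specific_capacitance_uF_cm2,
            leak_conductance=m.leak_conductance_S_cm2,
            leak_reversal=m.leak_reversal_mV))
        idx[cid] = len(comps) - 1

    idx: dict[str, int] = {}
    add("soma", "soma", m.soma_length_um, m.soma_diameter_um, None)
    prev = "soma"
    for i in range(m.axon_sections):
        add(f"axon{i}", "axon", m.axon_length_um, m.axon_diameter_um, prev)
        prev = f"axon{i}"
    add("basal", "basal", m.basal_length_um, m.basal_diameter_um, "soma")
    prev = "soma"
    for i in range(m.trunk_sections):
        add(f"trunk{i}", "trunk", m.trunk_length_um, m.trunk_diameter_um, prev)
        prev = f"trunk{i}"
    hosts = oblique_attachment_sections(m.n_oblique, m.trunk_sections)
    for i in range(m.n_oblique):
        length = m.oblique_length_um + m.oblique_length_step_um * i
        add(f"oblique{i}", "oblique", length, m.oblique_diameter_um,
            f"trunk{hosts[i]}")

    model = NeuronModel(
        compartments=comps,
        channels=default_channels(cfg.channels),
        integration_dt=cfg.integration.dt_ms,
    )
    _flatten(model, cfg)
    model.initialize_rest()
    return model


def _flatten(model: NeuronModel, cfg: SimulatorConfig) -> None:
    """Fill the numeric arrays consumed by the integration kernel."""
    n = model.n
    comps = model.compartments
    parent_idx = np.full(n, -1, dtype=np.int64)
    cap = np.empty(n)
    gl = np.empty(n)
    el = np.empty(n)
    gax = np.zeros(n)
    for i, c in enumerate(comps):
        area = c.area_cm2
        cap[i] = c.specific_capacitance * area * 1e3        # µF/cm²·cm² → nF
        gl[i] = c.leak_conductance * area * 1e6             # S → µS
        el[i] = c.leak_reversal
        if c.parent is not None:
            p = comps[model.index_of(c.parent)]
            parent_idx[i] = model.index_of(c.parent)
            # half-cylinder axial resistances in Ω, child center to parent center
            r_child = c.axial_resistivity * (c.length / 2 * 1e-4) / \
                (math.pi * (c.diameter / 2 * 1e-4) ** 2)
            r_par = p.axial_resistivity * (p.length / 2 * 1e-4) / \
                (math.pi * (p.diameter / 2 * 1e-4) ** 2)
            gax[i] = 1.0 / (r_child + r_par) * 1e6          # S → µS
    # tree ordering sanity: parents precede children (true by construction)
    assert all(parent_idx[i] < i for i in range(1, n))

    ch_cfg = cfg.channels
    region_override = {
        ("Na", "soma"): ch_cfg.na_soma,
        ("Na", "axon"): ch_cfg.na_axon,
        ("K_DR", "soma"): ch_cfg.kdr_soma,
        ("K_DR", "axon"): ch_cfg.kdr_axon,
    }
    if ch_cfg.kdr_trunk is not None:
        region_override[("K_DR", "trunk")] = ch_cfg.kdr_trunk
    if ch_cfg.na_trunk is not None:
        region_override[("Na", "trunk")] = ch_cfg.na_trunk
    region_override[("I_h", "soma")] = ch_cfg.ih_soma
    region_override[("I_h", "basal")] = ch_cfg.ih_soma
    gbar = {name: np.zeros(n) for name in CHANNELS}
    for dist in model.channels:
        for i, c in enumerate(comps):
            if c.region not in dist.region_mask:
                continue
            base = region_override.get((dist.channel, c.region))
            if base is not None:
                dens = max(0.0, base + dist.linear_slope * c.path_distance_to_soma)
            else:
                dens = channel_density_at(dist, c.path_distance_to_soma, c.region)
            gbar[dist.channel][i] = dens * c.area_cm2 * 1e6  # → µS

    model.kin = engine.kin_array(ch_cfg.kinetics)
    model.s_mask = np.array([1.0 if c.region in ("oblique", "basal")
                             else 0.0 for c in comps])
    model.parent_idx = parent_idx
    model.cap_nF = cap
    model.g_leak_uS = gl
    model.e_leak = el
    model.g_axial_uS = gax
    model.gbar_uS = gbar
    model.e_rev = {"Na": ch_cfg.e_na, "K": ch_cfg.e_k, "H": ch_cfg.e_h}


# ----------------------------------------------------------------------
def detect_threshold_crossings(trace: np.ndarray, threshold: float,
                               dt_ms: float, t0_ms: float = 0.0) -> np.ndarray:
    """Upward threshold-crossing times of a uniformly sampled voltage trace.

    A new event requires the trace to fall back below threshold first, so a
    single suprathreshold excursion counts once.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    above = trace >= threshold
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return t0_ms + ups * dt_ms


def advance_state(model: NeuronModel, synaptic_currents: np.ndarray,
                  injected_currents: np.ndarray, dt: float) -> NeuronModel:
    """Advance the cable + channel state by one step of ``dt`` ms (in place).

    ``synaptic_currents`` and ``injected_currents`` are per-compartment
    currents in nA (positive = depolarizing).  Raises ``FloatingPointError``
    with the offending compartment on divergence.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > MAX_DT_MS:
        raise ValueError(f"dt exceeds the configured maximum {MAX_DT_MS} ms")
    engine.single_step(model, synaptic_currents, injected_currents, dt)
    if not np.all(np.isfinite(model.v)):
        bad = int(np.flatnonzero(~np.isfinite(model.v))[0])
        raise FloatingPointError(
            f"voltage diverged in compartment {model.compartments[bad].id}")
    return model
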