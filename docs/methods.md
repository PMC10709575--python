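# Methods

This note documents the model behind `placesim`: what is simulated, the
choices made where the design was open, the parameters that matter, and
what the synthetic environment does and does not capture.

## The neuron

The cell is a reduced CA1 pyramidal neuron: one somatic compartment, a
two-section axon, a single lumped basal dendrite, an apical trunk of 8
sections (50 µm each), and 14 unbranched oblique dendrites attached at
distinct trunk positions. Compartments are cylinders; membrane voltage is
integrated with a fully implicit backward-Euler cable step on the tree
(Hines elimination, unconditionally stable) and exponential-Euler gating
updates, at a default step of 0.05 ms (0.025 ms available; halving the
step changes a standard stimulus trace by well under 0.5 mV RMS). The
inner loop is a single numba-compiled kernel that also handles synaptic
events, spike detection and plasticity, which keeps multi-minute sessions
at desk scale.

Six conductances are distributed over the tree: transient Na (m³h plus a
slow inactivation gate, see below), delayed-rectifier K (n²), proximal and
distal A-type K (a·b), the hyperpolarization-activated cation current I_h,
and muscarinic K_M confined to soma and axon. K_A and I_h densities grow
linearly with path distance from the soma. Gating kinetics are fixed
first-order Boltzmann forms (half-voltage, slope, constant time constant
per gate) with every parameter exposed in the configuration; densities are
configuration values chosen to satisfy the behavioral contract of the
model (see "Design choices"), not measurements.

Two region-specific choices are load-bearing:

* **Trunk spike relay.** The apical trunk carries enough Na to regenerate
  a propagating spike when an oblique fires a local dendritic spike. This
  is how dendritic events reach the soma: the subthreshold EPSP barrage of
  a fully visible object depolarizes the soma by only a few millivolts,
  while each oblique spike launches a trunk action potential that fires
  the cell. Without the relay there is no voltage margin separating
  "object in view, weights at baseline" (which must stay silent) from
  "object in view, weights potentiated" (which must fire).
* **Slow Na inactivation in the thin dendrites only.** Obliques (and the
  basal lump) carry a slow inactivation gate (τ = 80 ms) on Na. Sustained
  gamma-rate drive therefore *lowers* a dendrite's excitability slightly
  below its fresh value, which protects calibrated synapses against the
  accumulated depolarization of long cue-viewing bouts. The soma, axon
  and trunk are exempt so the relay stays responsive.

## Synapses and their calibration

Each oblique hosts one AMPA+NMDA synapse representing a synchronously
active group of inputs. AMPA is a peak-normalized double exponential
(rise 0.5 ms, decay 1 ms, reversal 0 mV). NMDA is a slower double
exponential (5/30 ms) scaled by a sigmoidal Mg-block factor
1/(1 + η[Mg]e^(−γV)) at 1 mM Mg²⁺. Two deliberately non-standard features
implement the "synchronous group" reading:

* **Per-volley saturation.** The conductance applied to the membrane is
  clamped at the single-volley peak (g_peak for AMPA, ratio·g_peak for
  NMDA). Without the clamp, chance Poisson near-coincidences at 80 Hz
  stack to ~1.8× the single-volley peak and cross the dendritic threshold
  at calibrated weights, destroying the control condition.
* **Fractional NMDA charging.** One volley contributes a third of the
  full NMDA weight (`nmda_saturation_volleys = 3`), so the slow component
  reaches its ceiling only after ~3 volleys inside its decay time. This
  makes the dendritic spike a *rate* detector: under the plateau, a
  gamma-driven synapse reaches full NMDA charge and crosses, while an
  isolated background volley (one third of the charge) does not. The
  NMDA:AMPA peak ratio is high (6) and the Mg unblock curve steep
  (γ = 0.12/mV, half-unblock −32 mV) for the same reason: the NMDA
  component only becomes a player at plateau-level depolarization.

Baseline weights are calibrated per dendrite: walk a geometric grid
(factor 1.1) of g₀ upward until a fixed-seed 10 s probe of that synapse
alone at 3 Hz produces a local −10 mV crossing, then back off 7 grid steps
(≈ ×0.51). The back-off width was chosen so that no admissible background
or cue-rate realization crosses at baseline — the last silent grid point
itself is within sampling noise of threshold, and a synapse calibrated
there ignites a runaway loop (spike → trunk relay → somatic spike →
backpropagation → more spikes) on the first unlucky bout. The fine grid
keeps the margin *uniform* across dendrites, which is what lets a single
plateau amplitude discriminate rewarded (80 Hz, full NMDA) from
non-rewarded (3 Hz, fractional NMDA) synapses on the same trunk section.

## The plateau protocol

Four electrodes on trunk sections 6, 4, 2, 0 (distal first) inject 200 ms
current steps every 500 ms, each rising with a 25 ms exponential ramp.
The ramp matters: an instantaneous step fires a transient trunk Na spike
at every epoch onset that registers as a dendritic spike in every oblique.
Obliques attach to the odd sections, i.e. just *distal* to their
electrode, because injections depolarize the sealed distal side of the
trunk far more cheaply than the soma-loaded proximal side.

Amplitudes are calibrated per electrode (they differ several-fold along
the trunk), sequentially and in the context of the full protocol: the
smallest grid value for which, during that electrode's epoch, (i) the
electrode compartment stays above −10 mV for at least half the step — a
plateau, not a passing spike, (ii) the adjacent obliques are depolarized
≥ 25 mV above rest, and (iii) an 80 Hz probe on an interleaved half of
those obliques (the single-object viewing pattern) fires at least one
local dendritic spike in the epoch. In environment-coupled learning the
protocol triggers once per session, when all features of the rewarded
object are first resolvable — the moment the animal is near the object
and facing it, which is when the co-activation the mechanism needs
actually exists.

## Plasticity

The update rule, its parameters (M = −24, V = 6.32 ms, τ = 2 ms, d = 0.3,
p = 1) and the −10 mV local threshold are as stated in the README. Three
operational decisions: pairing is nearest-neighbor (each event pairs with
the most recent opposite event only); "post" means a local dendritic
spike in the synapse's own oblique, never a somatic spike; and within one
integration step presynaptic delivery precedes spike detection, so a
coincident pre/post pair resolves as pre-before-post. The potentiation
branch is additive in the headroom (g_max − g₀ − A): a literally
multiplicative recurrence pins A at zero forever from the initial
condition A = 0, so the soft-bounded additive form is the only reading
with non-trivial dynamics. The ceiling is g_max = 1.8 g₀: at 2 g₀ or
above, a potentiated synapse crosses threshold on *single* background
volleys, which makes the cell fire everywhere and leaks potentiation onto
the other object's synapses whenever both are in view.

## The environment

A unit square arena contains two vertical bars on opposite sides, each
decomposed into 7 features wired one-to-one to oblique dendrites
(features of the two objects interleave along the trunk). The virtual
animal moves at 0.15 arena units/s with Gaussian heading increments
(σ = 12° per 100 ms step) and reflective walls; speed and turning were
set so that cue-viewing bouts last one to two seconds, the span of the
plateau protocol. Vision: 90° field of view, 0.8 range, full feature
resolution out to 0.36 and a linear fall-off beyond (an object is fully
resolved only from nearby, which also keeps the two objects from being
fully co-visible — a 14-synapse gamma barrage exceeds what any single-
object condition produces and would fire the soma). The environment steps
at 100 ms; presynaptic trains are regenerated each step as piecewise-
homogeneous Poisson processes, which is exact for piecewise-constant
rates. Everything is reproducible from a (trajectory, synaptic) seed
pair; calibrations use their own fixed seed.

Session defaults: 60 s control, 120 s learning, 300 s recall — scaled-down
versions of the study conditions, long enough for several viewing bouts
of each object.

## What the synthetic environment does not capture

No inhibition (deliberately, matching the modeled circuit), no
head-direction/grid/border inputs, no multi-room contexts, no depth or
occlusion in vision, and cues are static. Passing tests therefore show
that the *mechanism* — conjunctive gating of STDP by a propagating
plateau — works and is selective under these conditions; they do not
show robustness to inhibitory sculpting or richer sensory statistics.

## Known limitations

* The behavior is an emergent property of many coupled margins; the
  shipped densities are one working point, not a fitted optimum, and
  moderate parameter changes (e.g. a different oblique diameter) require
  recalibration and possibly retuning.
* Somatic EPSPs are not equalized across dendrites (they span roughly an
  order of magnitude): the K_A/I_h gradients were flattened to keep
  dendritic-spike margins uniform, which sacrifices the distance-
  compensation effect a detailed morphology shows.
* The isolated single-synapse "2× baseline crosses at 80 Hz" contrast
  holds cooperatively (for an object's co-activated feature set) but not
  for every dendrite in isolation.
* In learning sessions with unlucky trajectories the animal leaves the
  rewarded object mid-protocol; some of its features then miss their
  epoch and end unpotentiated (6 rather than 7), and occasionally a
  non-rewarded synapse caught by a backpropagating spike during an epoch
  potentiates. The default-seed canonical run shows the clean 7/0
  outcome; across seeds the potentiated count varies by about one.
* Dendritic spike rates during recall are high (the cell can fire near
  100 Hz in-field); somatic adaptation (K_M) moderates but does not
  enforce experimental in-field rates.
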