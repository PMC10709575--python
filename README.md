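# placesim

A compartmental-model simulator of **place-cell formation in a CA1
pyramidal neuron**. It tests, at the level of a single cell, the
hypothesis that a hippocampal neuron becomes a place cell when two
independent excitatory pathways coincide: cue-driven Schaffer-collateral
(CA3) input onto its oblique dendrites, and a forward-propagating
dendritic plateau potential standing in for the entorhinal/reward signal.
When — and only when — the two meet, spike-timing-dependent plasticity
potentiates exactly the synapses that encode the cue being viewed, and the
neuron subsequently fires whenever the animal looks at that cue from
nearby: a place field.

The package is aimed at computational neuroscientists who want a
desk-scale, fully scriptable version of this mechanism: a reduced
CA1 neuron (soma, axon, 8-section apical trunk, 14 oblique dendrites,
basal lump; ~26 compartments) with Hodgkin–Huxley-style channels, coupled
to a virtual animal exploring a square arena.

## The model in brief

* **Cue coding.** Each of two bar-shaped objects ("red", "blue") is split
  into 7 features; each feature drives one AMPA+NMDA synapse on its own
  oblique dendrite. A feature inside the animal's 90° field of view fires
  its synapse at the gamma rate (80 Hz); all other synapses idle at the
  theta rate (3 Hz). Baseline weights g₀ are calibrated per dendrite to be
  just below the local dendritic-spike threshold at background rate.
* **Plateau.** The entorhinal input is emulated by four 200 ms current
  steps at four apical-trunk locations, activated every 500 ms from the
  tuft toward the soma. In learning sessions it triggers once, when the
  rewarded object first comes fully into view.
* **Plasticity.** The peak conductance is g_peak = g₀ + A, updated at
  every pre- or postsynaptic (local dendritic, −10 mV crossing) spike:

  depression (Δt = t_post − t_pre < 0):
      A ← A · (1 − d · exp(−(Δt − M)² / 2V²) / (V√(2π)))
  potentiation (Δt > 0):
      A ← A + (g_max − g₀ − A) · p · exp(−Δt/τ)

  with M = −24 ms, V = 6.32 ms, τ = 2 ms, d = 0.3, p = 1.

## Worked example

`python examples/03_place_cell_formation.py` calibrates the neuron and
runs the three canonical sessions. With the default seeds it prints:

```
control : 0 somatic spikes, max weight change 0.00 %
learning: plateau at t = 2.1 s, potentiated 7/7 red and 0/7 blue synapses
recall  : 170 somatic spikes, 100 % while the red bar was in view
place field centroid at (0.83, 0.24) — the red bar is at (0.85, 0.50)
```

Reading: gamma-rate cue viewing alone neither fires the cell nor moves a
weight (control); adding the plateau while the red bar is viewed
potentiates exactly the seven red-feature synapses (learning); afterwards
the cell fires only while the red bar is in its visual field, giving a
compact firing field on the approach side of the red bar (recall — the
field sits where the *animal stands while viewing* the bar, hence the
offset from the bar itself). `examples/04_rotation_and_remapping.py` shows
that the field follows a 90° arena rotation and moves to the blue bar when
the neuron is re-trained on it.

Other entry points: `examples/01_stdp_rule.py` (the plasticity rule in
isolation), `examples/02_plateau_propagation.py` (the distal→proximal
voltage wave), and a thin CLI (`placesim run ... / placesim analyze ...`)
that writes spikes/weights/trajectory CSVs and rate-map summaries.

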