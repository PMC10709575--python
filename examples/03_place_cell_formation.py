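"""The central experiment: control vs learning vs recall.

Runs three environment-coupled sessions with the same calibrated neuron:

* control (60 s): cue viewing at the gamma rate, no plateau — the neuron
  must stay silent and the weights must not move;
* learning (120 s): the plateau protocol fires when the red bar is fully
  in view — exactly the 7 red-feature synapses should potentiate;
* recall (300 s): plasticity left free, no plateau — the neuron should now
  fire as a place cell, spiking where the red bar is visible.

Takes several minutes; the calibration dominates.
"""

import numpy as np

from placesim import canonical_scenario
from placesim.analysis import field_centroid_and_size, rate_map
from placesim.simulation import (SessionConfig, prepare_simulation,
                                 run_session)

cfg = canonical_scenario()
model, arena, weights, amps = prepare_simulation(cfg)

ctrl = run_session(model, arena, cfg,
                   SessionConfig(mode="control_no_plateau",
                                 seed_trajectory=1, seed_synaptic=2),
                   weights)
print(f"control : {ctrl.somatic_spikes_ms.size} somatic spikes, "
      f"max weight change "
      f"{100 * np.abs(ctrl.g_peak_final / ctrl.g0 - 1).max():.2f} %")

learn = run_session(model, arena, cfg,
                    SessionConfig(mode="learning_with_plateau",
                                  rewarded_object="red",
                                  seed_trajectory=1, seed_synaptic=2),
                    weights, plateau_amplitude_nA=amps)
pot = learn.g_peak_final > 1.01 * learn.g0
red = [i for i, f in enumerate(learn.feature_ids) if f.startswith("red:")]
blue = [i for i, f in enumerate(learn.feature_ids) if f.startswith("blue:")]
print(f"learning: plateau at t = {learn.plateau_onsets_ms[0] / 1000:.1f} s, "
      f"potentiated {pot[red].sum()}/7 red and {pot[blue].sum()}/7 blue "
      f"synapses")

rec = run_session(model, arena, cfg,
                  SessionConfig(mode="recall",
                                seed_trajectory=11, seed_synaptic=12),
                  weights, initial_A=learn.A_final)
frac = rec.spikes_during_visibility("red").mean()
rm = rate_map(rec, smooth_sigma_bins=1.5, min_occupancy_s=0.1)
centroid, area = field_centroid_and_size(rm)
print(f"recall  : {rec.somatic_spikes_ms.size} somatic spikes, "
      f"{100 * frac:.0f} % while the red bar was in view")
print(f"place field centroid at ({centroid[0]:.2f}, {centroid[1]:.2f}) "
      f"— the red bar is at ({arena.objects[0].position[0]:.2f}, "
      f"{arena.objects[0].position[1]:.2f})")
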