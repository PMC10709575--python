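"""Robustness experiments: arena rotation and cue remapping.

After learning on the red bar, (a) rigidly rotating the arena by 90°
should carry the place field with it (the field is cue-locked, not
room-locked), and (b) re-training the same neuron on the blue bar should
move the field to the blue side of the arena.
Takes several minutes.
"""

import numpy as np

from placesim import canonical_scenario, rotate_arena
from placesim.analysis import (field_centroid_and_size, rate_map,
                               remap_test, rotation_test)
from placesim.simulation import (SessionConfig, prepare_simulation,
                                 run_session)

cfg = canonical_scenario()
model, arena, weights, amps = prepare_simulation(cfg)

learn = run_session(model, arena, cfg,
                    SessionConfig(mode="learning_with_plateau",
                                  rewarded_object="red",
                                  seed_trajectory=1, seed_synaptic=2),
                    weights, plateau_amplitude_nA=amps)
rec = run_session(model, arena, cfg,
                  SessionConfig(mode="recall", seed_trajectory=11,
                                seed_synaptic=12),
                  weights, initial_A=learn.A_final)
rm = rate_map(rec, smooth_sigma_bins=1.5, min_occupancy_s=0.1)

rec90 = run_session(model, rotate_arena(arena, 90.0), cfg,
                    SessionConfig(mode="recall", seed_trajectory=13,
                                  seed_synaptic=14),
                    weights, initial_A=learn.A_final)
rm90 = rate_map(rec90, smooth_sigma_bins=1.5, min_occupancy_s=0.1)
print(f"rotation: map correlation at 90° = "
      f"{rotation_test(rm, rm90, 90.0):+.2f}, at 0° = "
      f"{rotation_test(rm, rm90, 0.0):+.2f} "
      f"(the field follows the arena if the first is larger)")

learn_b = run_session(model, arena, cfg,
                      SessionConfig(mode="learning_with_plateau",
                                    rewarded_object="blue",
                                    seed_trajectory=1, seed_synaptic=2),
                      weights, plateau_amplitude_nA=amps)
rec_b = run_session(model, arena, cfg,
                    SessionConfig(mode="recall", seed_trajectory=11,
                                  seed_synaptic=12),
                    weights, initial_A=learn_b.A_final)
rm_b = rate_map(rec_b, smooth_sigma_bins=1.5, min_occupancy_s=0.1)
c_red, _ = field_centroid_and_size(rm)
c_blue, _ = field_centroid_and_size(rm_b)
print(f"remap   : red-trained field at ({c_red[0]:.2f}, {c_red[1]:.2f}), "
      f"blue-trained field at ({c_blue[0]:.2f}, {c_blue[1]:.2f}), "
      f"centroid separation {remap_test(rm, rm_b):.2f} arena units")
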