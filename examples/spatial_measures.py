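"""Spatial kinematics from synthetic marker trajectories.

Generates matching toe/hip/shoulder trajectories for a synthetic trial
and computes stride length, toe-to-girdle distances at contact/liftoff,
and homolateral (fore toe to hind toe) interference distances.
"""

import quadgait as qg

config = qg.SyntheticGaitConfig(n_hind_cycles=15, frame_rate=60.0, seed=5)
table = qg.generate_event_schedule(config)
markers = qg.generate_marker_trajectories(table, config)
cycles = qg.segment_all(table)

summary = qg.spatial_summary(cycles, markers, config.belt_speed)
print(summary.groupby("limb")[["stride_length_m", "dist_at_contact_m",
                               "dist_at_liftoff_m"]]
      .mean().round(3).to_string())

hi = qg.homolateral_interference(cycles["RF"], markers)
print()
print("right-side interference (m):",
      hi.groupby("event")["distance_m"].mean().round(3).to_dict())
print()
print("Stride length = stance displacement + swing x belt speed; distances")
print("are signed toe-minus-girdle positions (positive rostral) at stance")
print("onset/offset; interference is the fore-to-hind toe gap on one side.")
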