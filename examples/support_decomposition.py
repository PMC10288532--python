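"""Decompose normalized hindlimb cycles into the nine support periods.

Simulates an intact lateral-sequence-like walk and expresses the time
spent in each canonical support configuration (triple, diagonal,
homolateral double, quadrupedal) as a percentage of the right hindlimb
cycle.
"""

import quadgait as qg

config = qg.SyntheticGaitConfig(n_hind_cycles=30, seed=3)
table = qg.generate_event_schedule(config)
cycles = qg.segment_cycles(table, "RH")

decomps = qg.decompose_trial(table, cycles)
frame = qg.decompositions_to_frame(decomps, table.meta)
agg = qg.aggregate_support(frame)

print(agg[["category", "mean_percent", "sd_percent"]]
      .sort_values("mean_percent", ascending=False)
      .round(2).to_string(index=False))
print()
print("Percentages over all complete cycles sum to 100; 'other' holds any")
print("configuration outside the nine canonical ones (aerial, single-limb,")
print("girdle-only doubles). Mirror categories (e.g. the two diagonals)")
print("are symmetric for this left-right symmetric gait.")
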