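"""Classify fore-hind coordination and summarize phases circularly.

Simulates a 'hemisection-like' trial in which 60% of hindlimb cycles
carry 2:1 fore-hind coordination (the forelimb steps twice per hindlimb
cycle) with dispersed phase coupling, then reports the 2:1 proportion and
the circular statistics (mean resultant length r, Rayleigh z = n r^2) per
coordination label.
"""

import quadgait as qg

config = qg.SyntheticGaitConfig(
    n_hind_cycles=50, phase_kappa=2.0,
    ratio_mix={"1:1": 0.4, "2:1": 0.6, "1:2": 0.0}, seed=11)
table = qg.generate_event_schedule(config)

labels = qg.classify_fore_hind(table, fore="RF", hind="RH")
prop = qg.proportion_2to1(labels)
print(f"2:1 coordination: {prop.percent}% "
      f"({prop.count_2to1}/{prop.total_classified} hindlimb cycles)")

samples = qg.phase_intervals(table, classification=labels)
for label, s in qg.circular_summaries_by_label(samples).items():
    star = "*" if s.significant else ""
    print(f"  {label:10s} n={s.n:3d}  mean={s.mean_deg:6.1f} deg  "
          f"r={s.r:.2f}{star}  z={s.z:.2f}  p={s.p:.3g}")
print()
print("r near 1 means the forelimb lands at a consistent phase of the")
print("hindlimb cycle; the asterisk marks Rayleigh-significant (p < 0.05)")
print("concentration. 2:1 cycles contribute two phases (first/second")
print("forelimb contact).")
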