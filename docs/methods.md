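# Methods

## Scope and data model

The package analyzes one treadmill trial at a time. A trial is (a) a
per-limb event table — strictly alternating contact/liftoff timestamps in
seconds, starting with a contact, for LF/RF/LH/RH — plus belt speed,
frame rate and subject/state labels, and (b) optionally a marker table:
horizontal (fore-aft, positive rostral) toe, hip and shoulder positions
in meters on a uniform time grid. Events are taken as given (in real
recordings they come from frame-by-frame visual scoring or tracking
post-processing); detecting events from trajectories is explicitly out of
scope.

Cycles are half-open `[contact_i, contact_{i+1})`: an event exactly at
the next contact belongs to the next cycle. This makes the cycle
partition unambiguous and makes a forelimb contact belong to exactly one
hindlimb cycle. Stance is liftoff − contact; swing is the remainder, so
stance + swing = cycle holds exactly for every emitted cycle. Trailing
contacts without a successor are dropped; a contact pair without exactly
one interior liftoff is excluded with a logged warning (unreachable on a
validated table, defensive on raw data).

## Coordination classification

Per hindlimb cycle, count k forelimb contacts in the window: k = 1 → 1:1,
k = 2 → 2:1, otherwise unclassified — except that 1:2 coordination is
keyed on the forelimb: a hindlimb cycle with k = 0 whose window is fully
covered by a single forelimb cycle is labelled 1:2, together with the
neighbouring hindlimb cycle that contains that forelimb cycle's contact
(if it was 1:1). k > 2 is never silently truncated. The 2:1 proportion is
reported over classified cycles only, rounded half-up to an integer
percent (the convention the reference tables use, e.g. 1/8 → 13%), with
the raw fraction retained.

Phase intervals are (t_F − t_H,start)/T_H ∈ [0, 1), ×360 for degrees.
The quotient is non-negative by construction, so no absolute value is
needed; phases live naturally on [0°, 360°). In 2:1 cycles the two
contacts yield separate samples labelled first/second in time order; a
1:2 pair yields one sample.

## Circular statistics

r is the magnitude of the mean unit vector; the mean direction its
argument. Rayleigh's statistic is z = n r² (exact identity, enforced in
tests), with the standard closed-form approximation

p = exp( sqrt(1 + 4n + 4(n² − n z)) − (1 + 2n) ),

clipped to [0, 1], significant at p < 0.05. The approximation replaces a
critical-value table lookup; it agrees with an independent implementation
(pingouin's Rayleigh test) to ~1e-12 over n = 5–80 in the tests, and its
empirical type-I error on uniform samples is 5.0% over 1,000 replicates
at n = 30.

## Support decomposition

A sweep over the merged event sequence yields maximal segments with a
constant stance set; the configuration after the last event persists
open-endedly. Before a limb's first event its state is treated as
unknown (even though it is inferable from the first event's kind) and
those segments are flagged; decompositions whose window touches a flagged
or uncovered span are marked partial and excluded from aggregation.

Categories are identified by stance *set*, not order of occurrence —
configuration uniquely identifies each of the nine canonical diagrams,
and order can change after a lesion; recurrences within a cycle are
summed. Everything outside the nine (aerial, single-limb, both-forelimbs,
both-hindlimbs) goes to `other`, never folded into a neighbour, so the
ten percentages sum to exactly 100. Segments straddling the cycle
boundary are clipped. Correctness is checked against a brute-force 1 ms
grid oracle (agreement within 0.2% per category) and an exact left-right
mirror property: relabelling L↔R and decomposing over the *same* time
window swaps mirror categories exactly (using each side's own reference
cycle instead would shift the window and is not expected to match
exactly).

## Spatial measures

Marker positions at event times are linearly interpolated between the
two bracketing frames — events are frame-quantized in real data, so
interpolation is the least-assumption lookup; times outside the sampled
span by more than one frame are missing (logged) rather than
extrapolated. Signs are kept (positive rostral); interference distances
are reported as magnitudes. Pixel-to-meter calibration for
DeepLabCut-style input is a required parameter with no default.

## Synthetic gait generator

The generator emulates the statistical structure the analysis assumes —
not locomotor dynamics. Per right-hindlimb cycle: duration mean × (1 +
cv·ε), ε standard normal, redrawn while non-positive; LH contact at
`lr_hind_phase` (default 0.5) of the cycle; a coordination mode drawn
from `ratio_mix`; RF contact(s) at a von Mises phase of the cycle (2:1
adds a second contact half a cycle later, wrapped so both stay inside
the window; 1:2 places one RF contact per two RH cycles, and when drawn
at the final cycle with no partner it falls back to 1:1); LF mirrors RF
shifted by half the forelimb cycle; liftoffs at contact + duty ×
own-cycle, plus `stance_asym` on right limbs. Concentrations κ ≥ 1e6 are
treated as a point mass (the sampling jitter is far below any measurable
phase resolution). Configs making any stance non-positive are rejected;
in abnormally short forelimb cycles (dispersed phases) the stance
saturates at 95% of the cycle — the paw must lift before its next
contact — rather than invalidating the schedule.

Defaults are the study conditions: belt 0.4 m/s, 60 frames/s camera
(event quantization to the frame grid is available but off by default so
construction identities hold exactly), hindlimb cycle mean 0.85 s and
duty factor 0.65 (typical cat treadmill walking at 0.4 m/s), homolateral
phase mean 90° (intact phase intervals cluster in the 30–120° range),
κ = 8 intact, cycle-duration CV 0.1 (no distributional data exist per
state; this is a placeholder, not an estimate). Marker trajectories move
the toe caudally at belt speed during stance and return it along a cubic
Hermite interpolant during swing; only the endpoints carry meaning, so
the swing shape is free. Contact positions are girdle + offset (default
+0.05 m rostral), making every spatial target known by construction.

What the generator does **not** emulate: musculoskeletal or CPG
dynamics, EMG, vertical kinematics, autocorrelated cycle-to-cycle drift,
tracking noise or missing samples. Passing tests therefore demonstrate
correctness of the measurement pipeline under the assumed statistical
structure, not robustness to real-data artifacts.

## Group statistics

Cycles are averaged within subject × state before any cross-subject
aggregation (studies of this design average ~8–36 cycles per animal);
whether trials should be pooled within a time point first is not
prescribed, so the package works at the subject × state level. Asymmetry
indexes are right − left (the sign convention under which a longer left
stance appears negative). Friedman tests use scipy; fully tied data
(every subject identical across states) would make the tie correction
0/0, and are reported as statistic 0, p 1. Pairwise Wilcoxon signed-rank
tests use the exact small-sample distribution for n ≤ 25, falling back
to the normal approximation when zeros force it; the Bonferroni family
is the set of pairwise comparisons actually emitted (m is logged with
the result). Note the exact two-sided Wilcoxon floor at n = 8 subjects
is 2/2⁸ ≈ 0.0078, so with 5 states (m = 10, adjusted α = 0.005) no
pairwise comparison can reach significance; forced-significance checks
in the tests use 4 states. r aggregates use the sample SD (ddof = 1);
single-value groups report SD as missing, and subjects lacking a
coordination type contribute no row.

## Problem sizes and numerical choices

Tests run synthetic trials of 100–200 hindlimb cycles (closed-form
recovery tolerances: duty ±0.02, r ±0.05 of the Bessel ratio
I₁(κ)/I₀(κ)), 1,000-replicate calibration checks for the Rayleigh and
Friedman type-I rates (±2 points around 5%), and 100 replicate pairs for
the hemisection-recovery contrast; the full suite completes in well
under a minute. Tolerances of 1e-9 mark construction identities; 1e-12
marks pure floating-point identities. Reported percentages round half-up
to integers and r values to 2 decimals, matching the reference tables'
conventions.

## Known limitations

Only fore-aft (x) kinematics are handled; no step width, joint angles or
stability margins. Coordination labels assume reasonably clean event
trains — noisy data can leave cycles unclassified (by design, with
warnings) rather than guessing. A 1:2 pair truncated at the end of a
trial cannot be distinguished from 1:1 without the closing forelimb
contact and is left as generated. The classifier's count invariant
(samples = #1:1 + 2·#2:1 + #1:2-pairs) can be violated by pathological
hand-built tables where a spanning forelimb cycle's contact falls in a
2:1 cycle; this does not arise from generated or well-formed gait data.
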