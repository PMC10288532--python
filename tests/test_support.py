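"""Support timeline sweep and nine-period cycle decomposition."""

import numpy as np
import pytest

import quadgait as qg
from conftest import make_table


def lateral_walk_table(n_cycles=10, cycle=1.0, duty=0.65,
                       phases=(0.0, 0.25, 0.5, 0.75)):
    """Lateral-sequence walk: RH 0, RF 0.25, LH 0.5, LF 0.75 phase offsets."""
    ph = dict(zip(("RH", "RF", "LH", "LF"), phases))
    contacts = {limb: [(i + p) * cycle for i in range(n_cycles + 1)]
                for limb, p in ph.items()}
    liftoffs = {limb: [c + duty * cycle for c in contacts[limb][:-1]]
                for limb in ph}
    return make_table(contacts, liftoffs)


def grid_oracle(table, t0, t1, dt=1e-3):
    """Brute-force percent per category from a fine time grid.

    A limb is in stance at t when its last event at or before t is a
    contact; grid points before a limb's first event are skipped (unknown).
    """
    times = np.arange(t0 + dt / 2, t1, dt)
    ev = {limb: (table.events[table.events["limb"] == limb]
                 .sort_values("time_s")) for limb in qg.LIMBS}
    counts = {cat: 0 for cat in qg.CATEGORIES}
    total = 0
    for t in times:
        stance = set()
        known = True
        for limb, sub in ev.items():
            before = sub[sub["time_s"] <= t]
            if before.empty:
                known = False
                break
            if before["event"].iloc[-1] == "contact":
                stance.add(limb)
        if not known:
            continue
        cat = qg.support.CATEGORY_BY_CONFIG.get(frozenset(stance), "other")
        counts[cat] += 1
        total += 1
    return {cat: 100.0 * c / total for cat, c in counts.items()}


class TestTimeline:
    def test_static_quad_stance_is_single_segment(self):
        table = make_table({limb: [0.0] for limb in qg.LIMBS}, {})
        timeline = qg.support_configuration_timeline(table)
        assert len(timeline) == 1
        assert timeline[0].limbs == frozenset(qg.LIMBS)
        assert timeline[0].known

    def test_liftoff_splits_quad_support(self):
        table = make_table({limb: [0.0] for limb in qg.LIMBS},
                           {"LF": [0.3]})
        timeline = qg.support_configuration_timeline(table)
        assert timeline[0].limbs == frozenset(qg.LIMBS)
        assert timeline[0].end == pytest.approx(0.3)
        assert timeline[1].limbs == frozenset({"RF", "LH", "RH"})

    def test_unknown_state_before_first_event_is_flagged(self):
        table = make_table({"RH": [0.0, 1.0], "LF": [0.5]}, {"RH": [0.7]})
        timeline = qg.support_configuration_timeline(table)
        assert not timeline[0].known  # LF/LH/RF still undetermined at t=0

    def test_timeline_matches_grid_oracle_on_synthetic_trial(self):
        cfg = qg.SyntheticGaitConfig(n_hind_cycles=8, seed=13)
        table = qg.generate_event_schedule(cfg)
        timeline = qg.support_configuration_timeline(table)
        rng = np.random.default_rng(0)
        t0, t1 = table.span
        for t in rng.uniform(t0, t1, 200):
            seg = next(s for s in timeline if s.start <= t < s.end)
            stance = set()
            for limb in qg.LIMBS:
                sub = table.events[(table.events["limb"] == limb)
                                   & (table.events["time_s"] <= t)]
                if not sub.empty and sub.sort_values("time_s")["event"].iloc[-1] \
                        == "contact":
                    stance.add(limb)
            if seg.known:
                assert seg.limbs == frozenset(stance)


class TestDecomposition:
    def test_static_quad_stance_decomposes_to_100_percent_quad(self):
        table = make_table({limb: [0.0] for limb in qg.LIMBS}, {})
        timeline = qg.support_configuration_timeline(table)
        cycle = qg.LimbCycle("RH", 0, 0.0, 0.8, 1.0)
        dec = qg.decompose_cycle(timeline, cycle)
        assert dec.percents["quad"] == pytest.approx(100.0)
        assert sum(dec.percents.values()) == pytest.approx(100.0, abs=1e-9)
        assert not dec.partial

    def test_alternating_diagonals_split_40_60(self):
        # within [1, 2): {LF,RH} for 0.4 s then {RF,LH} for 0.6 s; the
        # leading second establishes every limb's state
        table = make_table(
            {"LF": [0.0, 1.0], "RH": [0.0, 1.0],
             "RF": [0.4, 1.4], "LH": [0.4, 1.4]},
            {"LF": [0.4, 1.4], "RH": [0.4, 1.4],
             "RF": [1.0, 2.0], "LH": [1.0, 2.0]})
        timeline = qg.support_configuration_timeline(table)
        cycle = qg.LimbCycle("RH", 0, 1.0, 1.4, 2.0)
        dec = qg.decompose_cycle(timeline, cycle)
        assert dec.percents["diag_LF_RH"] == pytest.approx(40.0)
        assert dec.percents["diag_RF_LH"] == pytest.approx(60.0)
        assert sum(dec.percents.values()) == pytest.approx(100.0, abs=1e-9)

    def test_lateral_walk_matches_1ms_grid_oracle(self):
        table = lateral_walk_table()
        cycles = qg.segment_cycles(table, "RH")
        timeline = qg.support_configuration_timeline(table)
        target = cycles[2]  # interior cycle, full coverage
        dec = qg.decompose_cycle(timeline, target)
        assert not dec.partial
        oracle = grid_oracle(table, target.contact_start, target.contact_end)
        for cat in qg.CATEGORIES:
            assert dec.percents[cat] == pytest.approx(oracle[cat], abs=0.2)

    def test_partial_flag_when_cycle_precedes_other_limbs(self):
        table = make_table({"RH": [0.0, 1.0, 2.0], "LF": [1.2]},
                           {"RH": [0.7, 1.7]})
        timeline = qg.support_configuration_timeline(table)
        cycles = qg.segment_cycles(table, "RH")
        dec = qg.decompose_cycle(timeline, cycles[0])
        assert dec.partial

    def test_lr_relabeling_swaps_mirror_categories_exactly(self):
        table = lateral_walk_table(n_cycles=6)
        cycles = qg.segment_cycles(table, "RH")
        window = cycles[2]
        dec = qg.decompose_cycle(qg.support_configuration_timeline(table),
                                 window)
        mirrored = qg.decompose_cycle(
            qg.support_configuration_timeline(table.relabeled_lr()), window)
        for cat in qg.CATEGORIES:
            assert mirrored.percents[qg.MIRROR[cat]] == \
                pytest.approx(dec.percents[cat], abs=1e-12)


class TestAggregation:
    def test_single_decomposition_aggregates_to_itself(self):
        table = lateral_walk_table(n_cycles=4)
        cycles = qg.segment_cycles(table, "RH")
        decs = qg.decompose_trial(table, cycles[2:3])
        frame = qg.decompositions_to_frame(decs, table.meta)
        agg = qg.aggregate_support(frame)
        merged = agg.merge(frame, on="category")
        np.testing.assert_allclose(merged["mean_percent"], merged["percent"])
        assert (agg["sd_percent"] == 0.0).all()

    def test_two_identical_subjects_have_zero_sd(self):
        table = lateral_walk_table(n_cycles=4)
        cycles = qg.segment_cycles(table, "RH")
        decs = qg.decompose_trial(table, cycles[2:3])
        frames = []
        for subject in ("a", "b"):
            f = qg.decompositions_to_frame(decs, table.meta)
            f["subject"] = subject
            frames.append(f)
        import pandas as pd
        agg = qg.aggregate_support(pd.concat(frames))
        assert (agg["n_subjects"] == 2).all()
        np.testing.assert_allclose(agg["sd_percent"], 0.0, atol=1e-12)

    def test_symmetric_gait_mirror_categories_agree(self):
        table = lateral_walk_table(n_cycles=12)
        cycles = qg.segment_cycles(table, "RH")
        decs = [d for d in qg.decompose_trial(table, cycles) if not d.partial]
        mean = {cat: np.mean([d.percents[cat] for d in decs])
                for cat in qg.CATEGORIES}
        for a, b in (("triple_LH_RH_RF", "triple_LH_RH_LF"),
                     ("diag_LF_RH", "diag_RF_LH"),
                     ("homolateral_RF_RH", "homolateral_LF_LH"),
                     ("triple_LF_RF_RH", "triple_LF_RF_LH")):
            assert mean[a] == pytest.approx(mean[b], abs=1e-6)
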