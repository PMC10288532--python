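"""Stride length, paw-to-girdle distances and homolateral interference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quadgait as qg


def simple_markers(duration=2.0, fr=100.0, belt=0.4, x0=0.25):
    """Toe drifting caudally at belt speed from x0; fixed girdles."""
    t = np.arange(0, duration + 1e-9, 1 / fr)
    return pd.DataFrame({
        "time_s": t,
        "toe_RH_x": x0 - belt * t,
        "toe_RF_x": 0.45 - belt * t,
        "toe_LH_x": x0 - belt * t,
        "toe_LF_x": 0.45 - belt * t,
        "hip_x": np.full_like(t, 0.20),
        "shoulder_x": np.full_like(t, 0.55),
    })


class TestStrideLength:
    def test_stance_displacement_plus_belt_travel_during_swing(self):
        markers = simple_markers()
        cycle = qg.LimbCycle("RH", 0, 0.0, 0.5, 1.0)  # swing 0.5 s
        # stance displacement 0.2 m + 0.5 s x 0.4 m/s = 0.4 m
        assert qg.stride_length(cycle, markers, 0.4) == pytest.approx(0.40)

    def test_degenerate_zero_swing_is_stance_displacement(self):
        markers = simple_markers()
        cycle = qg.LimbCycle("RH", 0, 0.0, 1.0, 1.0)
        assert qg.stride_length(cycle, markers, 0.4) == pytest.approx(0.40)

    def test_event_outside_trajectory_span_raises(self):
        markers = simple_markers(duration=0.5)
        cycle = qg.LimbCycle("RH", 0, 0.0, 0.9, 1.2)
        with pytest.raises(ValueError, match="span"):
            qg.stride_length(cycle, markers, 0.4)

    @settings(max_examples=20, derandomize=True)
    @given(offset=st.floats(min_value=-5.0, max_value=5.0, allow_nan=False))
    def test_invariant_to_constant_position_offset(self, offset):
        markers = simple_markers()
        shifted = markers.copy()
        for col in markers.columns:
            if col != "time_s":
                shifted[col] = markers[col] + offset
        cycle = qg.LimbCycle("RH", 0, 0.1, 0.6, 1.1)
        assert qg.stride_length(cycle, shifted, 0.4) == pytest.approx(
            qg.stride_length(cycle, markers, 0.4), abs=1e-9)


class TestRelativeDistance:
    def test_toe_rostral_of_hip_is_positive(self):
        markers = simple_markers(x0=0.25)  # hip at 0.20 -> +0.05 at contact
        cycles = [qg.LimbCycle("RH", 0, 0.0, 0.5, 1.0)]
        rd = qg.relative_distance_at_events(cycles, markers)
        assert rd["dist_at_contact_m"].iloc[0] == pytest.approx(0.05)
        # at liftoff the toe has drifted 0.2 m caudally
        assert rd["dist_at_liftoff_m"].iloc[0] == pytest.approx(-0.15)

    def test_toe_at_girdle_is_zero(self):
        markers = simple_markers(x0=0.20)
        cycles = [qg.LimbCycle("LH", 0, 0.0, 0.5, 1.0)]
        rd = qg.relative_distance_at_events(cycles, markers)
        assert rd["dist_at_contact_m"].iloc[0] == pytest.approx(0.0)

    def test_forelimb_references_shoulder(self):
        markers = simple_markers()
        cycles = [qg.LimbCycle("RF", 0, 0.0, 0.5, 1.0)]
        rd = qg.relative_distance_at_events(cycles, markers)
        # toe_RF 0.45 vs shoulder 0.55 -> -0.10 at contact
        assert rd["dist_at_contact_m"].iloc[0] == pytest.approx(-0.10)

    def test_event_outside_span_yields_missing_not_error(self, caplog):
        markers = simple_markers(duration=0.5)
        cycles = [qg.LimbCycle("RH", 0, 0.0, 0.9, 1.2)]
        with caplog.at_level("WARNING"):
            rd = qg.relative_distance_at_events(cycles, markers)
        assert np.isnan(rd["dist_at_contact_m"].iloc[0])
        assert "cycle 0" in caplog.text


class TestInterference:
    def test_fore_minus_hind_toe_distance(self):
        markers = simple_markers()
        markers["toe_LF_x"] = 0.30
        markers["toe_LH_x"] = 0.05
        cycles = [qg.LimbCycle("LF", 0, 0.0, 0.5, 1.0)]
        hi = qg.homolateral_interference(cycles, markers)
        at_contact = hi[hi["event"] == "contact"]["distance_m"].iloc[0]
        assert at_contact == pytest.approx(0.25)

    def test_identical_positions_give_zero(self):
        markers = simple_markers()
        markers["toe_RF_x"] = markers["toe_RH_x"]
        cycles = [qg.LimbCycle("RF", 0, 0.0, 0.5, 1.0)]
        hi = qg.homolateral_interference(cycles, markers)
        np.testing.assert_allclose(hi["distance_m"], 0.0, atol=1e-12)

    def test_matches_direct_subtraction_on_generated_frames(self):
        cfg = qg.SyntheticGaitConfig(n_hind_cycles=10, frame_rate=60.0, seed=6)
        table = qg.generate_event_schedule(cfg)
        markers = qg.generate_marker_trajectories(table, cfg)
        cycles = qg.segment_cycles(table, "RF")
        hi = qg.homolateral_interference(cycles, markers)
        for rec in hi.itertuples(index=False):
            i = int(round(rec.time_s * 60 - markers["time_s"].iloc[0] * 60))
            direct = abs(markers["toe_RF_x"].iloc[i]
                         - markers["toe_RH_x"].iloc[i])
            assert rec.distance_m == pytest.approx(direct, abs=1e-9)


class TestConstructionExactness:
    def test_spatial_measures_exact_on_frame_aligned_events(self):
        """Frame-aligned schedule: measures match construction to 1e-9 m."""
        fr, belt, duty, cycle = 60.0, 0.4, 0.6, 1.0
        meta = qg.TrialMeta(belt_speed=belt, frame_rate=0.0)
        contacts = {l: np.arange(6) + p for l, p in
                    (("RH", 0.0), ("RF", 0.25), ("LH", 0.5), ("LF", 0.75))}
        liftoffs = {l: c[:-1] + duty for l, c in contacts.items()}
        table = qg.from_times(contacts, liftoffs, meta)
        cfg = qg.SyntheticGaitConfig(belt_speed=belt, frame_rate=fr)
        markers = qg.generate_marker_trajectories(table, cfg)
        cycles = qg.segment_all(table)
        summ = qg.spatial_summary(cycles, markers, belt)
        np.testing.assert_allclose(summ["dist_at_contact_m"], 0.05, atol=1e-9)
        np.testing.assert_allclose(summ["dist_at_liftoff_m"],
                                   0.05 - belt * duty, atol=1e-9)
        np.testing.assert_allclose(summ["stride_length_m"], belt * cycle,
                                   atol=1e-9)


class TestMarkerIO:
    def test_wide_round_trip(self, tmp_path):
        markers = simple_markers(duration=0.2)
        path = tmp_path / "m.csv"
        qg.write_marker_table(markers, path)
        back = qg.read_marker_table(path)
        np.testing.assert_allclose(back["toe_RH_x"], markers["toe_RH_x"])

    def test_dlc_dialect_round_trip_with_pixel_scale(self, tmp_path):
        markers = simple_markers(duration=0.2)
        path = tmp_path / "m_dlc.csv"
        px_to_m = 0.002
        qg.write_marker_table(markers, path, dialect="dlc", px_to_m=px_to_m)
        back = qg.read_marker_table(path, dialect="dlc", px_to_m=px_to_m)
        np.testing.assert_allclose(back["toe_RH_x"], markers["toe_RH_x"],
                                   atol=1e-9)

    def test_dlc_dialect_requires_calibration(self, tmp_path):
        markers = simple_markers(duration=0.2)
        path = tmp_path / "m_dlc.csv"
        qg.write_marker_table(markers, path, dialect="dlc", px_to_m=0.002)
        with pytest.raises(ValueError, match="px_to_m"):
            qg.read_marker_table(path, dialect="dlc")
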