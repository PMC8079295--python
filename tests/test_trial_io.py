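"""Protocol schedule, arena geometry, and file-format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shuttlebox as sb
from shuttlebox.errors import FormatError, GeometryError, ProtocolError


class TestTrialProtocol:
    def test_default_trial_lasts_200_minutes(self):
        assert sb.default_protocol().total_min == 200.0

    def test_no_step_protocol_lasts_60_minutes(self):
        p = sb.build_trial_protocol(40, [], 10, 10, 20)
        assert p.total_min == 60.0
        assert len(p.intervals()) == 3  # baseline + two reoxygenation bins

    def test_default_protocol_has_16_post_baseline_bins(self):
        ivs = sb.default_protocol().intervals()
        kinds = [iv.kind for iv in ivs[1:]]
        assert len(kinds) == 16
        assert kinds.count("ramp") == 7
        assert kinds.count("hold") == 7
        assert kinds.count("reoxygenation") == 2

    def test_non_decreasing_steps_rejected(self):
        with pytest.raises(ProtocolError):
            sb.build_trial_protocol(40, [70, 70, 50], 10, 10, 20)
        with pytest.raises(ProtocolError):
            sb.build_trial_protocol(40, [50, 70], 10, 10, 20)

    def test_hold_bins_carry_step_target_and_ramps_the_bin_mean(self):
        ivs = sb.default_protocol().intervals()
        holds = [iv.nominal_do for iv in ivs if iv.kind == "hold"]
        assert holds == [70, 50, 30, 25, 20, 15, 10]
        first_ramp = next(iv for iv in ivs if iv.kind == "ramp")
        assert first_ramp.nominal_do == pytest.approx((97.0 + 70.0) / 2, abs=0.1)

    def test_hypoxic_target_non_increasing_until_reoxygenation(self):
        p = sb.default_protocol()
        t = np.arange(int(p.baseline_min * 60), p.total_s - int(p.reox_min * 60))
        target = p.hypoxic_target(t)
        assert np.all(np.diff(target) <= 1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(baseline=st.integers(5, 60), ramp=st.integers(1, 15),
           hold=st.integers(1, 15), reox=st.integers(1, 30),
           n_steps=st.integers(0, 7))
    def test_segment_durations_always_sum_to_total(self, baseline, ramp, hold,
                                                   reox, n_steps):
        steps = [70, 50, 30, 25, 20, 15, 10][:n_steps]
        p = sb.build_trial_protocol(baseline, steps, ramp, hold, reox)
        assert sum(s.duration_s for s in p.segments()) == p.total_s
        assert p.total_min == baseline + n_steps * (ramp + hold) + reox


class TestZoneAssignment:
    geom = sb.ArenaGeometry()

    def test_compartment_centers(self):
        left = self.geom.compartment_centers["left"]
        assert sb.assign_zone(*left, self.geom).compartment == "left"
        # the shelter sits at the compartment center
        assert sb.assign_zone(*left, self.geom).in_shelter

    def test_passage_midpoint(self):
        z = sb.assign_zone(0.0, 0.0, self.geom)
        assert z.compartment == "passage" and not z.in_shelter

    def test_point_outside_arena_raises(self):
        with pytest.raises(GeometryError):
            sb.assign_zone(0.0, 30.0, self.geom)

    def test_matches_brute_force_oracle_on_random_points(self):
        rng = np.random.default_rng(123)
        g = self.geom
        r = g.compartment_radius
        pts = []
        while len(pts) < 1000:
            x, y = rng.uniform(-60, 60), rng.uniform(-26, 26)
            cl, cr = g.compartment_centers["left"], g.compartment_centers["right"]
            if (np.hypot(x - cl[0], y - cl[1]) < r - 0.1
                    or np.hypot(x - cr[0], y - cr[1]) < r - 0.1):
                pts.append((x, y))
        for x, y in pts:
            z = sb.assign_zone(x, y, g)
            # oracle: passage rectangle first, then point-in-circle
            xmin, xmax, ymin, ymax = g.passage_bounds
            if xmin <= x <= xmax and ymin <= y <= ymax:
                expect = "passage"
            elif np.hypot(x - g.compartment_centers["left"][0], y) <= r:
                expect = "left"
            else:
                expect = "right"
            assert z.compartment == expect
            shel = any(b[0] <= x <= b[1] and b[2] <= y <= b[3]
                       for b in (g.shelter_bounds("left"), g.shelter_bounds("right")))
            assert z.in_shelter == (shel and expect != "passage")

    def test_every_in_bounds_point_gets_exactly_one_zone(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(-56, 56, 4000)
        ys = rng.uniform(-25, 25, 4000)
        keep = []
        g = self.geom
        for x, y in zip(xs, ys):
            try:
                sb.assign_zone(x, y, g)
                keep.append((x, y))
            except GeometryError:
                pass
        comp, _ = sb.assign_zones(*np.array(keep).T, g)
        assert set(np.unique(comp)) <= {0, 1, 2}

    def test_shelter_zone_must_fit_in_compartment(self):
        with pytest.raises(GeometryError):
            sb.ArenaGeometry(compartment_diameter=10.0)


class TestPositionLogIO:
    def test_round_trip_is_lossless(self, tmp_path, default_cfg, cohort_logs):
        path = tmp_path / "fish.csv"
        log = cohort_logs[0]
        sb.write_position_log(log, path)
        back = sb.read_position_log(path)
        assert back.fish_id == log.fish_id
        assert back.hypoxic_side == log.hypoxic_side
        assert back.sbl == pytest.approx(log.sbl, abs=0.01)
        # written values are already on the format grid -> exact round trip
        path2 = tmp_path / "fish2.csv"
        sb.write_position_log(back, path2)
        assert path.read_text() == path2.read_text()

    def test_duplicated_timestamp_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# fish_id=f01\n# sbl_cm=9.00\n# hypoxic_side=left\n"
            "t_s,x_cm,y_cm,dist_cm,vel_cm_s,do_left,do_right,temp_c\n"
            "0,-32,0,0,0,97,97,25.6\n1,-32,0,0,0,97,97,25.6\n1,-32,0,0,0,97,97,25.6\n")
        with pytest.raises(FormatError, match="row"):
            sb.read_position_log(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# fish_id=f01\n# sbl_cm=9.00\n# hypoxic_side=left\n"
                        "t_s,x_cm,y_cm\n0,-32,0\n")
        with pytest.raises(FormatError, match="missing columns"):
            sb.read_position_log(path)

    def test_velocity_must_match_step_distance(self):
        import pandas as pd
        frame = pd.DataFrame({"t_s": [0, 1], "x_cm": [-32.0, -32.0],
                              "y_cm": [0.0, 0.0], "dist_cm": [0.0, 0.0],
                              "vel_cm_s": [0.0, 5.0], "do_left": [97.0, 97.0],
                              "do_right": [97.0, 97.0], "temp_c": [25.6, 25.6]})
        with pytest.raises(FormatError, match="velocity"):
            sb.PositionLog("f01", 9.0, "left", frame)


class TestConfigAndRecordingIO:
    def test_yaml_config_round_trip(self, tmp_path):
        geom = sb.ArenaGeometry(passage_width=9.0)
        proto = sb.build_trial_protocol(30, [50, 25, 10], 5, 10, 15)
        path = tmp_path / "cfg.yaml"
        sb.save_config(path, geom, proto)
        g2, p2 = sb.load_config(path)
        assert g2 == geom
        assert p2 == proto

    def test_wav_round_trip_preserves_metadata(self, tmp_path):
        rng = np.random.default_rng(0)
        rec = sb.EODRecording("f03", 20000, rng.normal(0, 0.1, 40000).astype(np.float32),
                              start_time=12.0, window_times=np.array([12, 40]))
        path = tmp_path / "eod.wav"
        sb.write_eod_recording(rec, path)
        back = sb.read_eod_recording(path)
        assert back.fish_id == "f03"
        assert back.sample_rate == 20000
        assert np.array_equal(back.window_times, rec.window_times)
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-7)
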