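"""Detector and feature-extraction tests, including generator-oracle checks."""

import numpy as np
import pytest
from scipy.signal import butter, freqz

from zfhunt import kinematics as kin
from zfhunt.kinematics import (
    Bout,
    HuntEvent,
    TrackingTrace,
    compute_vergence,
    detect_bouts,
    detect_hunt_events,
    extract_capture_features,
    extract_event_features,
    filter_eye_traces,
    head_speed,
    px_to_mm,
    read_trace_csv,
    write_trace_csv,
)
from zfhunt.synthetic import CaptureKinematics, simulate_trace


def make_trace(n=5000, fps=410.0, **overrides) -> TrackingTrace:
    base = dict(
        frame=np.arange(n),
        time_s=np.arange(n) / fps,
        left_eye_deg=np.full(n, 10.0),
        right_eye_deg=np.full(n, -10.0),
        head_x_mm=np.zeros(n),
        head_y_mm=np.zeros(n),
        heading_deg=np.zeros(n),
        fps=fps,
    )
    base.update(overrides)
    return TrackingTrace(**base)


class TestScale:
    def test_dish_width(self):
        assert px_to_mm(790) == pytest.approx(35.0)

    def test_zero(self):
        assert px_to_mm(0) == 0.0

    def test_single_pixel_is_44_microns(self):
        assert px_to_mm(1) == pytest.approx(0.0443, abs=5e-4)


class TestVergence:
    def test_symmetric_convergence(self):
        tr = make_trace(200, left_eye_deg=np.full(200, 30.0), right_eye_deg=np.full(200, -30.0))
        assert compute_vergence(tr)[0] == pytest.approx(60.0)

    def test_parallel_eyes(self):
        tr = make_trace(200, left_eye_deg=np.full(200, 12.0), right_eye_deg=np.full(200, 12.0))
        assert compute_vergence(tr)[0] == pytest.approx(0.0)

    def test_asymmetric_pair_passes_vergence_only(self):
        # vergence 46 > 45 but the per-eye rule governs separately
        tr = make_trace(600, left_eye_deg=np.full(600, 25.0), right_eye_deg=np.full(600, -21.0))
        assert compute_vergence(tr)[0] == pytest.approx(46.0)
        assert len(detect_hunt_events(tr, prefiltered=True)) == 1
        tr2 = make_trace(600, left_eye_deg=np.full(600, 28.0), right_eye_deg=np.full(600, -18.0))
        # vergence 46 but right eye only 18 deg inward -> no event
        assert detect_hunt_events(tr2, prefiltered=True) == []


class TestEyeFilter:
    def test_dc_gain_unity(self):
        tr = make_trace(2000, left_eye_deg=np.full(2000, 23.0))
        out = filter_eye_traces(tr)
        np.testing.assert_allclose(out.left_eye_deg, 23.0, rtol=1e-9)

    @pytest.mark.parametrize("freq,rtol", [(100.0, 0.01), (5.0, 0.02)])
    def test_sinusoid_attenuation_matches_transfer_function(self, freq, rtol):
        fps = 410.0
        n = 8200
        t = np.arange(n) / fps
        sig = np.sin(2 * np.pi * freq * t)
        tr = make_trace(n, left_eye_deg=sig)
        out = filter_eye_traces(tr).left_eye_deg
        # analytic gain of the digital filter; filtfilt applies |H|^2
        b, a = butter(4, 28.0, btype="low", fs=fps)
        _, h = freqz(b, a, worN=[freq], fs=fps)
        expected = np.abs(h[0]) ** 2
        # amplitude by projection onto the quadrature pair, mid-section only
        mid = slice(n // 4, 3 * n // 4)
        c = np.sin(2 * np.pi * freq * t[mid]), np.cos(2 * np.pi * freq * t[mid])
        amp = 2 * np.hypot(np.mean(out[mid] * c[0]), np.mean(out[mid] * c[1]))
        assert amp == pytest.approx(expected, rel=rtol, abs=1e-4)

    def test_short_trace_rejected(self):
        tr = make_trace(10)
        with pytest.raises(ValueError):
            filter_eye_traces(tr)


def square_vergence_trace(segments, n=6000, fps=410.0):
    """Trace whose eyes converge to (30, -30) during the given frame runs."""
    left = np.full(n, 10.0)
    right = np.full(n, -10.0)
    for s, e in segments:
        left[s:e] = 30.0
        right[s:e] = -30.0
    return make_trace(n, left_eye_deg=left, right_eye_deg=right)


class TestDetector:
    def test_merge_rule(self):
        # two runs 200 frames apart -> one event spanning both
        tr = square_vergence_trace([(1000, 1150), (1350, 1500)])
        ev = detect_hunt_events(tr, prefiltered=True)
        assert len(ev) == 1
        assert ev[0].start_frame == 1000 and ev[0].end_frame == 1500

    def test_minimum_duration_rule(self):
        tr = square_vergence_trace([(1000, 1080)])  # 80 frames < 100
        assert detect_hunt_events(tr, prefiltered=True) == []

    def test_merge_applied_before_duration_filter(self):
        # two 60-frame runs 100 frames apart form one valid 220-frame event
        tr = square_vergence_trace([(1000, 1060), (1160, 1220)])
        ev = detect_hunt_events(tr, prefiltered=True)
        assert len(ev) == 1

    def test_idempotent_on_detected_runs(self):
        tr = square_vergence_trace([(500, 800), (2000, 2400)])
        first = detect_hunt_events(tr, prefiltered=True)
        again = detect_hunt_events(tr, prefiltered=True)
        assert [(e.start_frame, e.end_frame) for e in first] == [
            (e.start_frame, e.end_frame) for e in again
        ]

    def test_output_respects_event_invariants(self, rng):
        # random constructed layouts never yield events violating the
        # 100-frame minimum or the 300-frame separation
        for _ in range(20):
            starts = np.cumsum(rng.integers(200, 1200, size=5))
            segs = [(int(s), int(s + rng.integers(50, 400))) for s in starts]
            segs = [(s, e) for s, e in segs if e < 12000]
            tr = square_vergence_trace(segs, n=12000)
            evs = detect_hunt_events(tr, prefiltered=True)
            for e in evs:
                assert e.n_frames >= 100
            for e1, e2 in zip(evs, evs[1:]):
                assert e2.start_frame - e1.end_frame >= 300

    def test_generator_oracle_equivalence(self):
        # constructed event count == detected event count on seeded fixtures
        rng = np.random.default_rng(77)
        for k in range(20):
            n_ev = int(rng.integers(0, 5))
            starts, t = [], 1.0
            for _ in range(n_ev):
                starts.append(t)
                t += 0.5 + float(rng.uniform(1.0, 2.0))  # gaps > 300 frames
            tr = simulate_trace([(s, 0.5) for s in starts], t + 1.0, seed=int(k))
            assert len(detect_hunt_events(tr)) == n_ev


class TestBouts:
    def test_stationary_larva_has_no_bouts(self):
        assert detect_bouts(make_trace(2000)) == []

    def test_triangular_pulse_peak_recovered(self):
        fps = 410.0
        n = 4100
        speed = np.zeros(n)
        # triangular speed pulse peaking at 30 mm/s over 0.4 s
        w = int(0.4 * fps)
        pulse = 30.0 * (1 - np.abs(np.linspace(-1, 1, w)))
        speed[2000 : 2000 + w] = pulse
        # integrate to positions along x
        x = np.cumsum(speed) / fps
        tr = make_trace(n, head_x_mm=x)
        bouts = detect_bouts(tr)
        assert len(bouts) == 1
        assert bouts[0].peak_speed == pytest.approx(30.0, rel=0.05)

    def test_two_pulses_two_bouts(self):
        fps = 410.0
        n = 6000
        speed = np.zeros(n)
        w = int(0.3 * fps)
        pulse = 20.0 * (1 - np.abs(np.linspace(-1, 1, w)))
        speed[1000 : 1000 + w] = pulse
        speed[3000 : 3000 + w] = pulse
        tr = make_trace(n, head_x_mm=np.cumsum(speed) / fps)
        assert len(detect_bouts(tr)) == 2


class TestFeatures:
    def make_kinematic_trace(self, seed=5, **kin_kwargs):
        k = CaptureKinematics(**kin_kwargs)
        tr = simulate_trace([(2.0, 0.8)], 5.0, seed=seed, kinematics=k)
        (event,) = detect_hunt_events(tr)
        return tr, event, k

    def test_lunge_recovery(self):
        tr, event, k = self.make_kinematic_trace()
        f = extract_event_features(event, tr)
        assert f.capture_speed_mm_s == pytest.approx(28.2, rel=0.1)
        assert f.capture_distance_mm == pytest.approx(0.35, rel=0.15)
        assert f.prey_azimuth_deg == pytest.approx(40.0, abs=1.0)
        assert f.first_turn_deg == pytest.approx(0.73 * 40.0, abs=1.0)
        assert f.turn_ratio == pytest.approx(0.73, abs=0.03)
        assert f.t_prey_s > 0

    def test_mirror_symmetry(self):
        tr, event, _ = self.make_kinematic_trace()
        f = extract_event_features(event, tr)
        # reflect the arena left<->right (y -> -y, angles negate)
        mirrored = TrackingTrace(
            frame=tr.frame,
            time_s=tr.time_s,
            left_eye_deg=-tr.right_eye_deg,
            right_eye_deg=-tr.left_eye_deg,
            head_x_mm=tr.head_x_mm,
            head_y_mm=-tr.head_y_mm,
            heading_deg=-tr.heading_deg,
            prey_x_mm=tr.prey_x_mm,
            prey_y_mm=-tr.prey_y_mm,
            fps=tr.fps,
        )
        (ev_m,) = detect_hunt_events(mirrored)
        fm = extract_event_features(ev_m, mirrored)
        assert fm.prey_azimuth_deg == pytest.approx(-f.prey_azimuth_deg, abs=1e-6)
        assert fm.first_turn_deg == pytest.approx(-f.first_turn_deg, abs=1e-6)
        assert fm.turn_ratio == pytest.approx(f.turn_ratio, abs=1e-9)
        assert fm.capture_speed_mm_s == pytest.approx(f.capture_speed_mm_s, abs=1e-9)
        assert fm.capture_distance_mm == pytest.approx(f.capture_distance_mm, abs=1e-9)

    def test_near_zero_azimuth_flagged(self):
        tr, event, _ = self.make_kinematic_trace(azimuth_deg=1.0, capture_distance=0.5)
        f = extract_event_features(event, tr)
        assert np.isnan(f.turn_ratio)  # |theta| below the 3-degree minimum

    def test_trailing_post_capture_bout_ignored(self):
        tr, event, _ = self.make_kinematic_trace()
        f = extract_event_features(event, tr)
        # append a post-capture bout after the closest approach
        fps = tr.fps
        n = len(tr)
        speed = np.zeros(n)
        w = int(0.1 * fps)
        start = event.end_frame - w - 2
        speed[start : start + w] = 15.0 * (1 - np.abs(np.linspace(-1, 1, w)))
        extra = np.cumsum(speed) / fps
        tr2 = TrackingTrace(
            frame=tr.frame,
            time_s=tr.time_s,
            left_eye_deg=tr.left_eye_deg,
            right_eye_deg=tr.right_eye_deg,
            head_x_mm=tr.head_x_mm + extra,
            head_y_mm=tr.head_y_mm,
            heading_deg=tr.heading_deg,
            prey_x_mm=tr.prey_x_mm,
            prey_y_mm=tr.prey_y_mm,
            fps=tr.fps,
        )
        (ev2,) = detect_hunt_events(tr2)
        f2 = extract_event_features(ev2, tr2)
        assert f2.capture_distance_mm == pytest.approx(f.capture_distance_mm, rel=0.05)
        assert f2.capture_speed_mm_s == pytest.approx(f.capture_speed_mm_s, rel=0.05)

    def test_missing_prey_flagged(self):
        tr = square_vergence_trace([(1000, 1300)])
        (event,) = detect_hunt_events(tr, prefiltered=True)
        f = extract_event_features(event, tr)
        assert np.isnan(f.prey_azimuth_deg) and np.isnan(f.capture_distance_mm)


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        tr = simulate_trace([(1.0, 0.5)], 3.0, seed=1)
        p = tmp_path / "trace.csv"
        write_trace_csv(tr, p)
        back = read_trace_csv(p)
        assert back.fps == tr.fps
        np.testing.assert_allclose(back.left_eye_deg, tr.left_eye_deg)
        np.testing.assert_allclose(back.head_x_mm, tr.head_x_mm)
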