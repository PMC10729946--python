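"""Wave-measurement pipeline tests, mostly against planted synthetic truth."""

import numpy as np
import pytest

from optospiral.analysis import (
    arrhythmia_peaks,
    core_growth,
    core_radius,
    detect_termination,
    dominant_frequency,
    space_time_plot,
    tip_trajectory,
    trajectory_diameter,
)
from optospiral.errors import InsufficientDataError, NoCoreError, NoPeakError
from optospiral.synthetic import MovieSpec, generate_movie, movie_recording
from optospiral.tissue import LightPulse, Recording


def _recording_from_frames(frames, dt_ms=1.0, dx_cm=0.025):
    times = np.arange(frames.shape[0]) * dt_ms
    probe = frames[:, frames.shape[1] // 2, frames.shape[2] // 2]
    return Recording(frames=frames, frame_times=times,
                     probes={"p0": probe}, probe_times=times,
                     light_log=[], meta={"params": {"dx": dx_cm}})


class TestSpaceTimePlot:
    def test_uniform_movie_constant(self):
        rec = _recording_from_frames(np.full((20, 10, 10), -80.0))
        st = space_time_plot(rec, row_y_mm=1.0)
        assert st.shape == (10, 20)
        assert np.all(st == -80.0)

    def test_plane_wave_stripes_slope(self):
        """A front moving at speed c appears as stripes of slope 1/c."""
        nx, nt = 50, 40
        speed = 8.0                  # nodes per ms
        dt_ms = 0.25
        frames = np.full((nt, 5, nx), -80.0)
        for k in range(nt):
            frames[k, :, :int(speed * k * dt_ms)] = 20.0
        rec = _recording_from_frames(frames, dt_ms=dt_ms)
        st = space_time_plot(rec, row_y_mm=0.5)
        x_idx = [10, 30]
        t_cross = [np.argmax(st[j] > 0) * dt_ms for j in x_idx]
        measured = (x_idx[1] - x_idx[0]) / (t_cross[1] - t_cross[0])
        assert measured == pytest.approx(speed, rel=0.15)

    def test_core_column_is_blurred_on_spiral(self, spiral_recording):
        """The rotor core shows as a low-variance band of the space-time plot."""
        tips = tip_trajectory(spiral_recording)
        cx = float(np.median([x for _, x, _ in tips]))
        cy = float(np.median([y for _, _, y in tips]))
        st = space_time_plot(spiral_recording, row_y_mm=cy)
        var = st.var(axis=1)
        core_col = int(round(cx / 0.25))
        off_col = (core_col + 20) % st.shape[0]
        assert var[core_col] < 0.5 * var[off_col]

    def test_row_outside_domain_rejected(self, spiral_recording):
        with pytest.raises(ValueError):
            space_time_plot(spiral_recording, row_y_mm=40.0)


class TestTipTrajectory:
    def test_plane_wave_has_no_singularity(self):
        frames = np.full((30, 20, 20), -80.0)
        for k in range(30):
            frames[k, :, :min(20, k)] = 20.0
        rec = _recording_from_frames(frames)
        assert tip_trajectory(rec) == []

    def test_synthetic_rotor_tip_near_planted_center(self):
        spec = MovieSpec(duration_ms=200.0, rotation_hz=20.0, seed=1)
        frames, truth = generate_movie(spec)
        rec = movie_recording(frames, truth)
        tips = tip_trajectory(rec)
        assert len(tips) > 50
        cx = 32 * spec.px_size_mm
        xs = np.median([x for _, x, _ in tips])
        ys = np.median([y for _, _, y in tips])
        assert abs(xs - cx) < spec.px_size_mm * 2
        assert abs(ys - cx) < spec.px_size_mm * 2

    def test_trajectory_diameter_requires_points(self):
        with pytest.raises(InsufficientDataError):
            trajectory_diameter([(0.0, 1.0, 1.0)])


class TestCoreRadius:
    def test_planted_disk_recovered(self):
        yy, xx = np.mgrid[0:64, 0:64]
        frame = np.where(np.hypot(xx - 30, yy - 34) <= 20, -10.0, -80.0)
        (cx, cy), r, q = core_radius(frame, px_size_mm=1.0)
        assert r == pytest.approx(20.0, abs=1.0)
        assert cx == pytest.approx(30.0, abs=1.5)
        assert cy == pytest.approx(34.0, abs=1.5)

    def test_uniform_frame_has_no_core(self):
        with pytest.raises(NoCoreError):
            core_radius(np.full((64, 64), -80.0))
        with pytest.raises(NoCoreError):
            core_radius(np.full((64, 64), 0.0))

    def test_planted_circle_oracle_with_noise(self):
        """100 random noisy disks: radius error <= 1 px in >= 95% of cases."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            r_true = rng.uniform(3.0, 30.0)
            cx0 = rng.uniform(32 - 8, 32 + 8)
            cy0 = rng.uniform(32 - 8, 32 + 8)
            yy, xx = np.mgrid[0:64, 0:64]
            frame = np.where(np.hypot(xx - cx0, yy - cy0) <= r_true, -10.0, -80.0)
            frame = frame + rng.normal(0.0, 0.10 * 100.0, frame.shape)
            try:
                _, r, _ = core_radius(frame, px_size_mm=1.0)
            except NoCoreError:
                continue
            hits += abs(r - r_true) <= 1.0
        assert hits >= 95


class TestCoreGrowth:
    def test_planted_linear_growth_recovered(self):
        spec = MovieSpec(duration_ms=700.0, rotation_hz=18.75, noise_sigma=0.02,
                         crosstalk=(150.0, 500.0, 0.1), core_radius0_mm=0.5,
                         core_growth_mm_per_ms=0.007, seed=21)
        frames, truth = generate_movie(spec)
        rec = movie_recording(frames, truth)
        track, fit = core_growth(rec, LightPulse(li=1.0, pl=500.0, t_on=150.0),
                                 v_threshold=-40.0)
        assert fit.slope == pytest.approx(0.007, rel=0.05)
        assert np.all(np.diff(track.times) >= 10.0 - 1e-9)

    def test_insufficient_radii_rejected(self):
        spec = MovieSpec(duration_ms=300.0, rotation_hz=20.0, core_radius0_mm=0.0,
                         seed=2)
        frames, truth = generate_movie(spec)
        rec = movie_recording(frames, truth)
        with pytest.raises((InsufficientDataError, ValueError)):
            core_growth(rec, LightPulse(li=1.0, pl=50.0, t_on=400.0))


class TestTermination:
    def test_unlit_spiral_not_terminated(self, spiral_recording):
        pulse = LightPulse(li=0.0, pl=100.0,
                           t_on=float(spiral_recording.frame_times[0]) - 250.0)
        res = detect_termination(spiral_recording, pulse)
        assert not res.terminated
        assert res.t_term is None

    def test_planted_last_peak_recovered(self):
        spec = MovieSpec(duration_ms=760.0, rotation_hz=20.0,
                         crosstalk=(200.0, 300.0, 0.1), terminate_at_ms=263.0,
                         noise_sigma=0.01, seed=5)
        frames, truth = generate_movie(spec)
        rec = movie_recording(frames, truth)
        res = detect_termination(rec, LightPulse(li=1.0, pl=300.0, t_on=200.0))
        assert res.terminated
        assert res.t_term + 200.0 == pytest.approx(truth["last_peak_ms"], abs=1.0)

    def test_onset_shift_leaves_t_term_unchanged(self):
        """Shifting the protocol by Δ shifts peak times but not t_term."""
        t_terms = []
        for shift in (0.0, 60.0):
            spec = MovieSpec(duration_ms=800.0, rotation_hz=20.0,
                             crosstalk=(200.0 + shift, 300.0, 0.1),
                             terminate_at_ms=263.0 + shift, t0_ms=shift, seed=9)
            frames, truth = generate_movie(spec)
            rec = movie_recording(frames, truth)
            res = detect_termination(rec, LightPulse(li=1.0, pl=300.0,
                                                     t_on=200.0 + shift))
            t_terms.append(res.t_term)
        assert t_terms[0] == pytest.approx(t_terms[1], abs=1.0)

    def test_short_recording_rejected(self, spiral_recording):
        pulse = LightPulse(li=30.0, pl=300.0,
                           t_on=float(spiral_recording.frame_times[0]))
        with pytest.raises(ValueError):
            detect_termination(spiral_recording, pulse)


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        t = np.arange(0, 1000.0, 1.0)
        trace = np.sin(2 * np.pi * 20.0 * t / 1000.0)
        f, res = dominant_frequency(trace, t)
        assert f == pytest.approx(20.0, abs=res)

    def test_constant_trace_has_no_peak(self):
        t = np.arange(0, 500.0, 1.0)
        with pytest.raises(NoPeakError):
            dominant_frequency(np.full_like(t, -80.0), t)

    def test_synthetic_movie_frequency_recovered(self):
        spec = MovieSpec(duration_ms=800.0, rotation_hz=18.75,
                         noise_sigma=0.02, seed=4)
        frames, truth = generate_movie(spec)
        rec = movie_recording(frames, truth)
        f, res = dominant_frequency(rec.probes["p0"], rec.probe_times)
        assert f == pytest.approx(18.75, abs=res)


class TestArrhythmiaPeaks:
    def test_plateau_excluded_by_downstroke_rule(self):
        t = np.arange(0, 600.0, 1.0)
        trace = np.full_like(t, -80.0)
        for peak in (50, 100, 150):
            trace[peak - 5:peak + 5] = 20.0 - 4.0 * np.abs(np.arange(-5, 5))
        trace[200:500] = -20.0          # sustained light-driven plateau
        peaks = arrhythmia_peaks(trace, t)
        assert len(peaks) == 3
        assert np.all(peaks < 200)
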