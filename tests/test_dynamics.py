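"""Tracking, kymograph lag, FRAP fitting and tip-offset profiles."""

import itertools
import math

import numpy as np
import pytest

from memtopo.dynamics import (Detection, FitError, Track, build_kymograph,
                              comet_lag, detect_movie, detect_puncta,
                              frap_fit, link_tracks, tip_offset,
                              track_velocities)
from memtopo.io import ImageStack
from memtopo.quantify import MembranePath
from memtopo.synthetic_data import (MovieSpec, StructureSpec,
                                    simulate_surface_movie)


class TestDetect:
    def test_blank_noisy_frames_rarely_fire(self):
        total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = rng.poisson(100.0, size=(64, 64)).astype(float)
            total += len(detect_puncta(frame))
        assert total / 100 < 0.05  # false positives per frame

    def test_subpixel_localization_of_injected_spot(self):
        rng = np.random.default_rng(8)
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        clean = 100.0 + 100.0 * np.exp(
            -((xx - 10.30) ** 2 + (yy - 7.60) ** 2) / 2.0)  # SNR 10
        frame = rng.poisson(clean).astype(float)
        dets = detect_puncta(frame)
        assert len(dets) == 1
        assert dets[0].x_px == pytest.approx(10.30, abs=0.15)
        assert dets[0].y_px == pytest.approx(7.60, abs=0.15)

    def test_two_well_separated_spots(self):
        rng = np.random.default_rng(2)
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        clean = 100.0 + sum(
            100.0 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / 2.0)
            for x0, y0 in [(20.0, 20.0), (41.0, 20.0)])  # 3x diameter apart
        dets = detect_puncta(rng.poisson(clean).astype(float))
        assert len(dets) == 2

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            detect_puncta(np.zeros((16, 16)), diameter_px=6)


def synth_detections(trajectories):
    """Detections from exact per-frame positions {frame: [(x, y), ...]}."""
    dets = []
    for f, pts in trajectories.items():
        for x, y in pts:
            dets.append(Detection(frame=f, x_px=x, y_px=y, amplitude=1.0))
    return dets


class TestLink:
    def test_persistent_spot_single_track(self):
        dets = synth_detections({f: [(10.0, 10.0)] for f in range(20)})
        tracks = link_tracks(dets)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_steady_motion_within_capture_radius(self):
        dets = synth_detections({f: [(2.0 * f, 5.0)] for f in range(15)})
        tracks = link_tracks(dets, max_disp_px=5.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 15

    def test_displacement_beyond_radius_starts_new_track(self):
        dets = synth_detections({f: [(10.0 * f, 5.0)] for f in range(5)})
        tracks = link_tracks(dets, max_disp_px=5.0)
        assert len(tracks) == 5

    def test_crossing_spots_linked_at_global_minimum_cost(self):
        # two particles with distinct speeds crossing mid-movie
        T = 8
        pa = [(2.0 + 3.0 * f, 10.0) for f in range(T)]  # fast
        pb = [(14.0 - 1.0 * f, 10.0) for f in range(T)]  # slow, opposite
        dets = synth_detections({f: [pa[f], pb[f]] for f in range(T)})
        tracks = link_tracks(dets, max_disp_px=4.0)
        assert len(tracks) == 2

        def chain_cost(assignment):
            # assignment: tuple of 0/1 per frame-transition, whether to swap
            cost = 0.0
            prev = [pa[0], pb[0]]
            for f in range(1, T):
                cur = [pa[f], pb[f]]
                if assignment[f - 1]:
                    cur = cur[::-1]
                for p, q in zip(prev, cur):
                    cost += (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                prev = cur
            return cost

        best = min(chain_cost(a) for a in
                   itertools.product([0, 1], repeat=T - 1))
        linked = 0.0
        for t in tracks:
            p = t.positions
            linked += float((np.diff(p, axis=0) ** 2).sum())
        assert linked == pytest.approx(best)

    def test_memory_bridges_a_missed_frame(self):
        traj = {f: [(3.0 * f, 5.0)] for f in range(8) if f != 4}
        dets = synth_detections(traj)
        assert len(link_tracks(dets, max_disp_px=7.0, memory_frames=1)) == 1
        assert len(link_tracks(dets, max_disp_px=7.0, memory_frames=0)) == 2


class TestVelocities:
    def test_stationary_spots_have_zero_speed(self):
        dets = synth_detections({f: [(10.0, 10.0), (20.0, 20.0)]
                                 for f in range(6)})
        tracks = link_tracks(dets)
        vs = track_velocities(tracks, pixel_size_um=0.155, dt=2.0)
        assert vs.v_f_mean == 0.0
        assert vs.v_f_sd == 0.0

    def test_recovers_injected_speed_end_to_end(self):
        spec = MovieSpec(seed=6, shape_px=(96, 96), n_frames=15,
                         frame_interval_s=2.0, n_channels=1, snr=8.0)
        rng = np.random.default_rng(6)
        spec.structures = [
            StructureSpec(kind="tip_punctum",
                          x0_um=float(rng.uniform(2, 6)),
                          y0_um=float(rng.uniform(1, 13)),
                          velocity_um_s=0.20,
                          heading_deg=float(rng.uniform(-30, 30)),
                          labeled=(True,))
            for _ in range(20)]
        stack, _ = simulate_surface_movie(spec)
        dets = detect_movie(stack)
        tracks = link_tracks(dets, max_disp_px=5.0)
        vs = track_velocities(tracks, stack.pixel_size_um, 2.0)
        assert vs.v_f_mean == pytest.approx(0.20, abs=0.02)

    def test_mean_of_embryo_means(self):
        t1 = Track(id=0, embryo_id="e1", detections=[
            Detection(f, 0.1 / 0.155 * 2.0 * f, 0.0, 1.0) for f in range(6)])
        t2 = Track(id=1, embryo_id="e2", detections=[
            Detection(f, 0.3 / 0.155 * 2.0 * f, 0.0, 1.0) for f in range(6)])
        vs = track_velocities([t1, t2], pixel_size_um=0.155, dt=2.0)
        assert vs.v_e == pytest.approx(0.2)

    def test_no_long_track_is_an_error(self):
        dets = synth_detections({0: [(1.0, 1.0)]})
        with pytest.raises(ValueError, match="length"):
            track_velocities(link_tracks(dets), 0.155, 2.0)

    @pytest.mark.parametrize("speed,dt", [(0.05, 4.0), (0.1, 2.0),
                                          (0.2, 2.0), (0.5, 1.0)])
    def test_speed_recovery_within_10_percent(self, speed, dt):
        # sampling matched to motion: slow structures need longer intervals
        # so the per-step displacement dominates localization noise, fast
        # ones shorter intervals to stay within the linking capture radius
        spec = MovieSpec(seed=17, shape_px=(96, 96), n_frames=12,
                         frame_interval_s=dt, n_channels=1, snr=5.0)
        rng = np.random.default_rng(17)
        spec.structures = [
            StructureSpec(kind="tip_punctum",
                          x0_um=float(rng.uniform(2, 7)),
                          y0_um=float(rng.uniform(1, 13)),
                          velocity_um_s=speed,
                          heading_deg=float(rng.uniform(-20, 20)),
                          labeled=(True,))
            for _ in range(8)]
        stack, _ = simulate_surface_movie(spec)
        tracks = link_tracks(detect_movie(stack), max_disp_px=5.0)
        vs = track_velocities(tracks, stack.pixel_size_um, dt)
        assert vs.v_f_mean == pytest.approx(speed, rel=0.10)


def comet_movie(lag_mode="delay", lag_s=8.0, seed=3, n_frames=40,
                velocity=0.0775, snr=20.0):
    spec = MovieSpec(seed=seed, shape_px=(32, 128), n_frames=n_frames,
                     snr=snr, structures=[StructureSpec(
                         kind="comet", x0_um=1.0, y0_um=2.48,
                         velocity_um_s=velocity, heading_deg=0.0,
                         lag_mode=lag_mode, lag_s=lag_s)])
    stack, gt = simulate_surface_movie(spec)
    path = MembranePath([[4.0, 16.0], [120.0, 16.0]])
    return stack, path


class TestKymographAndLag:
    def test_uniform_movie_gives_constant_kymograph(self):
        stack = ImageStack(np.full((1, 5, 32, 64), 50.0), 0.155, 2.0)
        kymo = build_kymograph(stack, MembranePath([[5.0, 16.0], [58.0, 16.0]]))
        assert np.allclose(kymo.data, 50.0)

    def test_moving_comet_ridge_slope_equals_speed(self):
        stack, path = comet_movie()
        kymo = build_kymograph(stack, path)
        a = kymo.data[0]
        peaks = [np.argmax(a[s]) for s in range(10, 36)]
        slope_px_per_frame = np.polyfit(range(10, 36), peaks, 1)[0]
        speed = kymo.step_um / (slope_px_per_frame * kymo.dt_s)
        assert speed == pytest.approx(0.0775, rel=0.1)

    def test_identical_channels_give_identical_planes(self):
        stack, path = comet_movie(lag_mode="none", lag_s=0.0)
        kymo = build_kymograph(stack, path)
        # both channels render the same structure; noise differs, means agree
        assert np.allclose(kymo.data[0].mean(), kymo.data[1].mean(), rtol=0.02)

    def test_identical_channels_have_zero_lag(self):
        stack, path = comet_movie(lag_mode="none", lag_s=0.0)
        stack.data[1] = stack.data[0]
        kymo = build_kymograph(stack, path)
        assert comet_lag(kymo).lag_s == pytest.approx(0.0, abs=1e-9)

    def test_four_frame_shift_reads_eight_seconds(self):
        stack, path = comet_movie(lag_s=8.0)
        res = comet_lag(build_kymograph(stack, path))
        assert res.lag_s == pytest.approx(8.0, abs=0.2)
        assert res.n_positions >= 10

    def test_antisymmetric_under_channel_swap(self):
        stack, path = comet_movie(lag_s=6.0)
        kymo = build_kymograph(stack, path)
        fwd = comet_lag(kymo, channels=(0, 1)).lag_s
        rev = comet_lag(kymo, channels=(1, 0)).lag_s
        assert fwd == pytest.approx(-rev, abs=0.4)

    def test_too_few_interior_positions_is_an_error(self):
        stack = ImageStack(np.random.default_rng(0).poisson(
            100, size=(2, 10, 16, 32)).astype(float), 0.155, 2.0)
        kymo = build_kymograph(stack, MembranePath([[2.0, 8.0], [29.0, 8.0]]))
        with pytest.raises(ValueError, match="positions"):
            comet_lag(kymo, min_positions=10)


class TestFrapFit:
    @staticmethod
    def curve(k=0.1, dt=0.5, n=200, prebleach=20, c=0.2, a=0.8, noise=0.0,
              seed=0):
        t = np.arange(n) * dt
        y = np.ones(n)
        tp = t[prebleach:] - t[prebleach]
        y[prebleach:] = c + a * (1 - np.exp(-k * tp))
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, n)
        return t, y

    def test_noiseless_half_time(self):
        t, y = self.curve(k=0.1)
        fit = frap_fit(t, y)
        assert fit.tau_half_s == pytest.approx(math.log(2) / 0.1, abs=0.01)
        assert fit.mobile_fraction == pytest.approx(1.0, abs=0.01)

    def test_flat_post_bleach_curve_rejected(self):
        t = np.arange(60) * 0.5
        y = np.ones(60)
        y[20:] = 0.2
        with pytest.raises(FitError, match="no recovery"):
            frap_fit(t, y)

    def test_median_recovery_over_noisy_replicates(self):
        taus = []
        for seed in range(50):
            t, y = self.curve(k=0.1, noise=0.05, seed=seed)
            taus.append(frap_fit(t, y).tau_half_s)
        assert np.median(taus) == pytest.approx(math.log(2) / 0.1, rel=0.05)

    def test_undersampled_recovery_is_flagged(self):
        t, y = self.curve(k=2.0, dt=0.5, n=60)  # tau_half = 0.35 s
        with pytest.warns(UserWarning, match="under-sampled"):
            fit = frap_fit(t, y)
        assert fit.undersampled

    def test_prebleach_normalization(self):
        t, y = self.curve()
        fit = frap_fit(t, 7.3 * y)
        assert fit.normalized[:20].mean() == pytest.approx(1.0)


class TestTipOffset:
    @staticmethod
    def tip_image(offset_px=0.0):
        yy, xx = np.mgrid[0:40, 0:80].astype(float)
        tip = (15.0, 20.0)
        img = 20.0 + 150.0 * np.exp(
            -((xx - tip[0] - offset_px) ** 2 + (yy - tip[1]) ** 2) / 8.0)
        return img, MembranePath([[tip[0], tip[1]], [tip[0] + 40.0, tip[1]]])

    def test_co_peaked_channel_has_zero_offset(self):
        img, path = self.tip_image(0.0)
        out = tip_offset(img, [path])
        assert out["peak_offset_um"] == pytest.approx(0.0, abs=0.155)

    def test_recovers_half_micron_offset(self):
        img, path = self.tip_image(0.50 / 0.155)
        out = tip_offset(img, [path])
        assert out["peak_offset_um"] == pytest.approx(0.50, abs=0.08)

    def test_profiles_are_mean_normalized(self):
        img, path = self.tip_image(1.0)
        out = tip_offset(img, [path])
        for p in out["profiles"]:
            assert p.mean() == pytest.approx(1.0)

    def test_short_path_rejected(self):
        img, _ = self.tip_image()
        with pytest.raises((ValueError, Exception)):
            tip_offset(img, [MembranePath([[5.0, 5.0], [5.5, 5.0]])])
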