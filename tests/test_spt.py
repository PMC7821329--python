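"""Spot detection, linking, MSD and diffusion estimation."""

import numpy as np
import pytest

from memclust import spt
from memclust import synthetic as syn
from memclust.images import CalibratedImage
from memclust.spt import SpotDetection, Trajectory


def _gaussian_frame(centres, total=4000.0, sigma_px=1.5, shape=(128, 128),
                    bg=100.0, ps=0.1):
    """Render Gaussian spots at (row, col) sub-pixel centres."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.full(shape, bg)
    for cy, cx in centres:
        img += total / (2 * np.pi * sigma_px**2) * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
    return CalibratedImage(img, ps)


def _track(positions, frame_interval=0.1, frames=None, intensity=1.0):
    positions = np.asarray(positions, dtype=float)
    frames = range(len(positions)) if frames is None else frames
    dets = [SpotDetection(frame=f, position=(p[0], p[1]), total_intensity=intensity)
            for f, p in zip(frames, positions)]
    return Trajectory(detections=dets, frame_interval=frame_interval)


class TestDetectSpots:
    def test_blank_frame_empty(self):
        rng = np.random.default_rng(0)
        frame = CalibratedImage(100 + rng.normal(0, 2, (64, 64)).clip(-90, None), 0.1)
        assert spt.detect_spots(frame, expected_radius=0.15) == []

    def test_subpixel_centroid_accuracy(self):
        frame = _gaussian_frame([(30.3, 40.7)])
        spots = spt.detect_spots(frame, expected_radius=0.15)
        assert len(spots) == 1
        x, y = spots[0].position
        assert abs(x / 0.1 - 40.7) < 0.1
        assert abs(y / 0.1 - 30.3) < 0.1

    def test_planted_spots_all_found_no_false_positives(self):
        rng = np.random.default_rng(5)
        centres = []
        while len(centres) < 20:
            c = rng.uniform(15, 185, 2)
            if all(np.hypot(*(c - np.array(o))) > 12 for o in centres):
                centres.append(tuple(c))
        frame = _gaussian_frame(centres, shape=(200, 200))
        spots = spt.detect_spots(frame, expected_radius=0.15)
        assert len(spots) == 20
        for s in spots:
            err = min(np.hypot(s.position[0] / 0.1 - cx, s.position[1] / 0.1 - cy)
                      for cy, cx in centres)
            assert err < 0.5


class TestClassifyIntensity:
    @pytest.mark.parametrize("au,expected", [
        (3_000, "low"), (12_000, "medium"), (20_000, "high"),
        (5_000, "medium"), (15_000, "medium"), (15_000.01, "high"),
        (4_999.99, "low"), (0, "low"),
    ])
    def test_thresholds(self, au, expected):
        assert spt.classify_intensity(float(au)) == expected

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            spt.classify_intensity(-1.0)


class TestLinking:
    def test_nearby_detections_form_one_track(self):
        d0 = [SpotDetection(0, (1.0, 1.0), 5.0)]
        d1 = [SpotDetection(1, (1.1, 1.0), 5.0)]
        tracks = spt.link_trajectories([d0, d1], max_disp=0.5)
        assert len(tracks) == 1 and len(tracks[0]) == 2

    def test_distant_detections_stay_separate(self):
        d0 = [SpotDetection(0, (1.0, 1.0), 5.0)]
        d1 = [SpotDetection(1, (2.0, 1.0), 5.0)]
        tracks = spt.link_trajectories([d0, d1], max_disp=0.5)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_single_particle_link_is_exact(self):
        spec = syn.TrajectoryFieldSpec(n_tracks=1, n_frames=30, D_free=0.05,
                                       localization_sd=0.0, seed=3)
        truth = syn.generate_trajectories(spec)
        stack = syn.render_trajectory_stack(spec, truth)
        dets = [spt.detect_spots(fr, expected_radius=0.15) for fr in stack]
        linked = spt.link_trajectories(dets, max_disp=0.5, frame_interval=0.1)
        assert len(linked) == 1 and len(linked[0]) == 30
        np.testing.assert_allclose(linked[0].positions, truth[0].positions, atol=0.01)

    def test_rendered_low_density_links_match_truth(self):
        spec = syn.TrajectoryFieldSpec(
            n_tracks=10, n_frames=20, D_free=0.05, localization_sd=0.0, seed=0,
            intensity_means={"free": 4000.0, "immobile": 20000.0})
        truth = syn.generate_trajectories(spec)
        stack = syn.render_trajectory_stack(spec, truth)
        dets = [spt.detect_spots(fr, expected_radius=0.15) for fr in stack]
        linked = spt.link_trajectories(dets, max_disp=0.5, max_gap=2,
                                       frame_interval=0.1)
        true_pos = [t.positions for t in truth]
        n_links = n_correct = 0
        for lt in linked:
            pos, frames = lt.positions, lt.frames
            for a in range(len(lt) - 1):
                n_links += 1
                for tp in true_pos:
                    if (np.hypot(*(pos[a] - tp[frames[a]])) < 0.05
                            and np.hypot(*(pos[a + 1] - tp[frames[a + 1]])) < 0.05):
                        n_correct += 1
                        break
        assert n_links >= 0.9 * 10 * 19  # nearly all links recovered
        assert n_correct / n_links >= 0.95


class TestMSD:
    def test_stationary_track_zero_msd(self):
        tr = _track(np.zeros((30, 2)))
        curve = spt.compute_msd([tr])
        assert np.all(curve.msd == 0.0)

    def test_ballistic_track_closed_form(self):
        step = 0.1
        pos = np.column_stack([np.arange(40) * step, np.zeros(40)])
        curve = spt.compute_msd([_track(pos)], max_lag=8)
        n = np.arange(1, 9)
        np.testing.assert_allclose(curve.msd, (step * n) ** 2, rtol=1e-12)

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(7)
        pos = np.cumsum(rng.normal(0, 0.1, (50, 2)), axis=0)
        fwd = spt.compute_msd([_track(pos)], max_lag=10)
        rev = spt.compute_msd([_track(pos[::-1])], max_lag=10)
        np.testing.assert_allclose(fwd.msd, rev.msd, rtol=1e-12)

    def test_brownian_ensemble_matches_4dt(self):
        spec = syn.TrajectoryFieldSpec(
            n_tracks=500, D_free=0.05, n_frames=60, localization_sd=0.0,
            field_size=1000.0, seed=0)
        curve = spt.compute_msd(syn.generate_trajectories(spec), max_lag=4)
        expected = 4 * 0.05 * curve.lags
        assert np.all(np.abs(curve.msd - expected) <= 2 * curve.se)

    def test_no_qualifying_tracks_rejected(self):
        with pytest.raises(ValueError):
            spt.compute_msd([_track(np.zeros((3, 2)))], min_length=5)


class TestFitDiffusion:
    def test_exact_line(self):
        lags = np.arange(1, 7) * 0.1
        curve = spt.MSDCurve(lags=lags, msd=4 * 0.025 * lags,
                             se=np.full(6, np.nan), n_pairs=np.full(6, 100))
        est = spt.fit_diffusion(curve)
        assert est.D == pytest.approx(0.025, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_localization_offset_model(self):
        lags = np.arange(1, 7) * 0.1
        sigma = 0.02
        curve = spt.MSDCurve(lags=lags, msd=4 * 0.025 * lags + 4 * sigma**2,
                             se=np.full(6, np.nan), n_pairs=np.full(6, 100))
        est = spt.fit_diffusion(curve)
        assert est.D == pytest.approx(0.025, abs=1e-12)
        assert est.intercept == pytest.approx(4 * sigma**2, abs=1e-12)

    def test_negative_slope_clipped(self):
        lags = np.arange(1, 5) * 0.1
        curve = spt.MSDCurve(lags=lags, msd=0.01 - 0.01 * lags,
                             se=np.full(4, np.nan), n_pairs=np.full(4, 10))
        est = spt.fit_diffusion(curve)
        assert est.D == 0.0 and est.clipped

    def test_simulated_ensemble_recovery(self):
        spec = syn.TrajectoryFieldSpec(
            n_tracks=500, D_free=0.05, n_frames=60, localization_sd=0.02, seed=0)
        curve = spt.compute_msd(syn.generate_trajectories(spec), max_lag=4)
        est = spt.fit_diffusion(curve)
        assert est.D == pytest.approx(0.05, rel=0.10)


class TestDiffusionDistribution:
    def test_single_estimate_one_bin(self):
        est = spt.DiffusionEstimate(D=0.05, intercept=0.0, fit_lags=(0.1, 0.4),
                                    r_squared=1.0)
        _, freqs = spt.diffusion_distribution([est])
        assert freqs.sum() == pytest.approx(1.0)
        assert np.count_nonzero(freqs) == 1

    def test_two_population_bimodal(self):
        """Mixture of immobile and free ROIs gives modes near 0 and D_free."""
        ests = []
        for seed in range(30):
            imm = seed % 2 == 1
            spec = syn.TrajectoryFieldSpec(
                n_tracks=60, n_frames=60, D_free=0.05,
                immobile_fraction=1.0 if imm else 0.0,
                localization_sd=0.01, seed=seed)
            curve = spt.compute_msd(syn.generate_trajectories(spec), max_lag=4)
            ests.append(spt.fit_diffusion(curve))
        edges, freqs = spt.diffusion_distribution(
            ests, bin_edges=np.linspace(0, 0.06, 13))
        assert freqs[0] == pytest.approx(0.5, abs=0.05)  # immobile mode at ~0
        centres = 0.5 * (edges[:-1] + edges[1:])
        mobile_mode = centres[np.argmax(np.where(centres > 0.01, freqs, 0))]
        assert mobile_mode == pytest.approx(0.05, abs=0.01)


def test_high_intensity_particles_less_mobile():
    """When bright spots are the immobile ones, fitted D of the high class
    sits below the low class (intensity–mobility inverse correlation)."""
    spec = syn.TrajectoryFieldSpec(
        n_tracks=100, immobile_fraction=0.5, D_free=0.05,
        localization_sd=0.01, seed=6,
        intensity_means={"free": 3_000.0, "immobile": 20_000.0})
    tracks = syn.generate_trajectories(spec)
    by_class = {"low": [], "high": []}
    for tr in tracks:
        cls = spt.classify_intensity(tr.mean_intensity)
        if cls in by_class:
            by_class[cls].append(tr)
    d = {cls: spt.fit_diffusion(spt.compute_msd(trs, max_lag=4)).D
         for cls, trs in by_class.items()}
    assert d["high"] < d["low"]
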