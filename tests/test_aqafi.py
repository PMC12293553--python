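"""Particle detection, clustering, and SDNR/CNR metric computation."""

import math

import numpy as np
import pytest

from helpers import (
    CIRCLE,
    brute_fast_brighter,
    brute_single_linkage,
    percentile_split,
)
from sfmtools import (
    AqafiConfig,
    FeaturePixel,
    RgbImage,
    assess_image,
    cluster_features,
    detect_features,
    measure_background,
    measure_particle,
    two_level_scene,
)
from sfmtools.aqafi import ParticleDetection


def gray_rgb(channel: np.ndarray) -> RgbImage:
    pix = np.zeros(channel.shape + (3,))
    pix[:, :, 1] = channel
    return RgbImage(pix)


class TestDetectFeatures:
    def test_constant_image_has_no_features(self):
        img = gray_rgb(np.full((15, 15), 55.0))
        assert detect_features(img, AqafiConfig()) == []

    def test_bright_plateau_is_detected(self):
        g = np.full((15, 15), 10.0)
        g[5:10, 5:10] = 200.0
        feats = detect_features(gray_rgb(g), AqafiConfig(fast_threshold=20))
        assert len(feats) >= 1
        assert all(f.polarity == "brighter" for f in feats)
        # features lie on the plateau, not the background
        assert all(g[f.row, f.col] == 200.0 for f in feats)

    def test_matches_brute_force_fast_oracle(self, rng):
        for arc in (9, 11, 12):
            g = np.full((20, 20), 20.0)
            for _ in range(4):  # plant a few small spots
                r, c = rng.integers(4, 16, size=2)
                g[r, c] = 220.0
            g += rng.uniform(-5, 5, g.shape)
            g = np.clip(g, 0, 255)
            cfg = AqafiConfig(fast_threshold=30, fast_arc=arc)
            got = {(f.row, f.col) for f in detect_features(gray_rgb(g), cfg)}
            exp = set(brute_fast_brighter(g, 30, arc))
            assert got == exp

    def test_contiguous_run_below_arc_not_a_feature(self):
        # exactly 10 contiguous dimmer circle pixels: feature at arc 10, not 12
        g = np.full((13, 13), 100.0)
        for dr, dc in CIRCLE[:10]:
            g[6 + dr, 6 + dc] = 0.0
        assert (6, 6) not in {
            (f.row, f.col)
            for f in detect_features(gray_rgb(g), AqafiConfig(fast_threshold=20, fast_arc=12))
        }
        assert (6, 6) in {
            (f.row, f.col)
            for f in detect_features(gray_rgb(g), AqafiConfig(fast_threshold=20, fast_arc=10))
        }

    def test_border_pixels_never_features(self):
        g = np.zeros((15, 15))
        g[:3, :] = 255.0  # bright strip on the border
        feats = detect_features(gray_rgb(g), AqafiConfig())
        assert all(3 <= f.row < 12 and 3 <= f.col < 12 for f in feats)

    def test_tiny_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert detect_features(gray_rgb(np.zeros((5, 5))), AqafiConfig()) == []

    def test_dark_polarity_excluded_by_default(self):
        g = np.full((15, 15), 200.0)
        g[7, 7] = 0.0  # dark speck: darker polarity only
        assert detect_features(gray_rgb(g), AqafiConfig()) == []
        feats = detect_features(gray_rgb(g), AqafiConfig(include_darker=True))
        assert (7, 7) in {(f.row, f.col) for f in feats}


class TestClusterFeatures:
    def test_single_feature_single_detection(self):
        dets = cluster_features([FeaturePixel(5, 7)], AqafiConfig())
        assert len(dets) == 1
        assert (dets[0].center_row, dets[0].center_col) == (5.0, 7.0)

    def test_pair_within_cutoff_merges_to_midpoint(self):
        feats = [FeaturePixel(5, 5), FeaturePixel(5, 8)]
        dets = cluster_features(feats, AqafiConfig(cluster_cutoff_px=10))
        assert len(dets) == 1
        assert (dets[0].center_row, dets[0].center_col) == (5.0, 6.5)

    def test_two_distant_groups_stay_separate(self):
        feats = [FeaturePixel(5, 5), FeaturePixel(6, 5), FeaturePixel(105, 5), FeaturePixel(106, 6)]
        dets = cluster_features(feats, AqafiConfig(cluster_cutoff_px=10))
        assert len(dets) == 2

    def test_matches_union_find_single_linkage(self, rng):
        coords = rng.uniform(0, 60, size=(40, 2)).round()
        feats = [FeaturePixel(int(r), int(c)) for r, c in coords]
        cfg = AqafiConfig(cluster_cutoff_px=7.0)
        dets = cluster_features(feats, cfg)
        expected = brute_single_linkage(
            np.array([(f.row, f.col) for f in feats], dtype=float), 7.0
        )
        got_sets = {frozenset((d.row, d.col) for d in det.member_features) for det in dets}
        exp_sets = {
            frozenset((feats[i].row, feats[i].col) for i in grp) for grp in expected
        }
        assert got_sets == exp_sets

    def test_scipy_linkage_path_agrees_on_single(self, rng):
        coords = rng.uniform(0, 40, size=(25, 2))
        feats = [FeaturePixel(int(r), int(c)) for r, c in coords]
        a = cluster_features(feats, AqafiConfig(cluster_cutoff_px=6.0, cluster_linkage="single"))
        # complete linkage never merges more aggressively than single
        b = cluster_features(feats, AqafiConfig(cluster_cutoff_px=6.0, cluster_linkage="complete"))
        assert len(b) >= len(a)

    def test_empty_input_empty_output(self):
        assert cluster_features([], AqafiConfig()) == []


class TestBackground:
    def test_no_detections_whole_image_mean(self):
        img = gray_rgb(np.full((20, 20), 33.0))
        assert measure_background(img, [], AqafiConfig()) == 33.0

    def test_two_level_square_removed(self):
        g = np.full((41, 41), 10.0)
        g[15:26, 15:26] = 200.0
        det = ParticleDetection(20.0, 20.0, [FeaturePixel(20, 20)], window_half=5)
        assert measure_background(gray_rgb(g), [det], AqafiConfig()) == 10.0

    def test_overlapping_squares_match_mask_oracle(self, rng):
        g = rng.uniform(0, 255, (30, 30))
        dets = [
            ParticleDetection(10.0, 10.0, [FeaturePixel(10, 10)], window_half=6),
            ParticleDetection(14.0, 13.0, [FeaturePixel(14, 13)], window_half=6),
        ]
        got = measure_background(gray_rgb(g), dets, AqafiConfig())
        mask = np.ones_like(g, dtype=bool)
        for d in dets:
            r, c = int(d.center_row), int(d.center_col)
            mask[max(r - 6, 0): r + 7, max(c - 6, 0): c + 7] = False
        assert got == pytest.approx(g[mask].mean(), abs=1e-12)

    def test_windows_covering_image_raise(self):
        g = np.full((9, 9), 5.0)
        det = ParticleDetection(4.0, 4.0, [FeaturePixel(4, 4)], window_half=8)
        with pytest.raises(ValueError):
            measure_background(gray_rgb(g), [det], AqafiConfig())


class TestParticleMetrics:
    def test_forced_two_level_window(self):
        # window: 1% of pixels at 200, 99% at 50; background 10
        g = np.full((40, 40), 50.0)
        g[20, 20] = 200.0  # 1 of 100 window pixels
        det = ParticleDetection(20.0, 20.0, [FeaturePixel(20, 20)], window_half=4)
        window = np.full((10, 10), 50.0)
        window[0, 0] = 200.0
        above, below = percentile_split(window, 99.0)
        assert list(above) == [200.0] and below.mean() == 50.0
        m = measure_particle(gray_rgb(g), det, background_noise=10.0,
                             config=AqafiConfig(window_half_px=4))
        assert m.bead_intensity == 200.0
        assert m.vicinity_noise == 50.0
        assert m.sdnr == pytest.approx(15.0, abs=1e-9)
        assert m.contrast == pytest.approx(3.0, abs=1e-9)
        assert m.cnr == pytest.approx(0.3, abs=1e-9)

    def test_constant_window_degenerates_to_zero_signal(self):
        g = np.full((30, 30), 42.0)
        det = ParticleDetection(15.0, 15.0, [FeaturePixel(15, 15)], window_half=5)
        m = measure_particle(gray_rgb(g), det, background_noise=42.0, config=AqafiConfig())
        assert m.bead_intensity == m.vicinity_noise == 42.0
        assert m.sdnr == 0.0 and m.contrast == 0.0
        assert "degenerate-window" in m.flags

    def test_random_window_matches_sort_split_oracle(self, rng):
        g = rng.uniform(0, 255, (50, 50))
        det = ParticleDetection(25.0, 25.0, [FeaturePixel(25, 25)], window_half=9)
        cfg = AqafiConfig(window_half_px=9)
        m = measure_particle(gray_rgb(g), det, background_noise=10.0, config=cfg)
        window = g[16:35, 16:35]
        above, below = percentile_split(window, cfg.intensity_percentile)
        assert m.bead_intensity == pytest.approx(above.mean(), abs=1e-9)
        assert m.vicinity_noise == pytest.approx(below.mean(), abs=1e-9)

    def test_zero_denominators_flagged_nan(self):
        g = np.zeros((30, 30))
        g[15, 15] = 100.0
        det = ParticleDetection(15.0, 15.0, [FeaturePixel(15, 15)], window_half=5)
        m = measure_particle(gray_rgb(g), det, background_noise=0.0, config=AqafiConfig())
        assert math.isnan(m.sdnr) and math.isnan(m.cnr)
        assert "undefined-sdnr" in m.flags and "undefined-contrast" in m.flags

    def test_border_window_flagged(self):
        g = np.zeros((30, 30))
        g[2, 2] = 100.0
        det = ParticleDetection(2.0, 2.0, [FeaturePixel(2, 2)], window_half=5)
        m = measure_particle(gray_rgb(g), det, background_noise=1.0, config=AqafiConfig())
        assert "border" in m.flags


class TestAssessImage:
    def test_blank_image_reports_zero_particles(self):
        report = assess_image(gray_rgb(np.full((30, 30), 12.0)), AqafiConfig())
        assert report.n_particles == 0
        assert math.isnan(report.mean_sdnr) and math.isnan(report.mean_cnr)
        assert report.background_noise == 12.0

    def test_planted_two_level_scene_exact_metrics(self):
        image, centers, cfg = two_level_scene(10)
        report = assess_image(image, cfg)
        assert report.n_particles == len(centers)
        for _, m in report.particles:
            assert m.sdnr == pytest.approx(15.0, abs=1e-9)
            assert m.contrast == pytest.approx(3.0, abs=1e-9)
            assert m.cnr == pytest.approx(0.3, abs=1e-9)
        assert report.mean_sdnr == pytest.approx(15.0, abs=1e-9)
        assert report.background_noise == pytest.approx(10.0, abs=1e-12)

    def test_detected_centers_match_planted(self):
        image, centers, cfg = two_level_scene(6)
        report = assess_image(image, cfg)
        got = sorted(map(tuple, report.centers()))
        assert got == sorted(map(tuple, centers))

    def test_deterministic(self, rng):
        g = np.clip(rng.normal(15, 4, (60, 60)), 0, 255)
        g[30:33, 30:33] = 220.0
        img = gray_rgb(g)
        cfg = AqafiConfig(cluster_cutoff_px=4, window_half_px=6)
        r1 = assess_image(img, cfg)
        r2 = assess_image(img, cfg)
        assert r1.n_particles == r2.n_particles
        for (d1, m1), (d2, m2) in zip(r1.particles, r2.particles):
            assert (d1.center_row, d1.center_col) == (d2.center_row, d2.center_col)
            assert m1 == m2

    def test_metric_algebra(self):
        image, _, cfg = two_level_scene(5)
        report = assess_image(image, cfg)
        bg = report.background_noise
        for _, m in report.particles:
            assert m.sdnr * bg + m.vicinity_noise == pytest.approx(m.bead_intensity, abs=1e-9)
            assert m.cnr * bg * m.vicinity_noise == pytest.approx(
                m.bead_intensity - m.vicinity_noise, abs=1e-9
            )

    def test_percentile_split_partitions_window(self, rng):
        g = rng.uniform(0, 255, (40, 40))
        det = ParticleDetection(20.0, 20.0, [FeaturePixel(20, 20)], window_half=7)
        cfg = AqafiConfig(window_half_px=7)
        m = measure_particle(gray_rgb(g), det, 1.0, cfg)
        window = g[13:28, 13:28].ravel()
        above, below = percentile_split(window, cfg.intensity_percentile)
        assert len(above) + len(below) == window.size
        total = above.sum() + below.sum()
        assert total == pytest.approx(window.sum())

    def test_scale_covariance(self):
        image, _, cfg = two_level_scene(4)
        a = 0.5
        scaled = RgbImage(image.pixels * a)
        r1 = assess_image(image, cfg)
        dets = [d for d, _ in r1.particles]
        bg1 = measure_background(image, dets, cfg)
        bg2 = measure_background(scaled, dets, cfg)
        for det, m1 in ((d, m) for d, m in r1.particles):
            m2 = measure_particle(scaled, det, bg2, cfg)
            assert m2.contrast == pytest.approx(m1.contrast, rel=1e-9)
            assert m2.sdnr == pytest.approx(m1.sdnr, rel=1e-9)
            assert m2.cnr == pytest.approx(m1.cnr / a, rel=1e-9)
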