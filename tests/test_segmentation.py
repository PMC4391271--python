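import math

import numpy as np
import pytest

from conftest import match_to_truth
from xylemtrace import synthetic_data as sd
from xylemtrace.segmentation import (ImagePair, SegmentationParams,
                                     apply_exposure_normalization, detect_lumens,
                                     measure_stain_fraction, measure_vessels,
                                     measure_wall_completeness)


def single_vessel(stain_fraction, wall_completeness=1.0, diameter=10.0,
                  noise_sd=0.0, pixel_size=0.2, seed=3):
    """One vessel on a small canvas, returning (config, truth, pair)."""
    cfg = sd.default_config("apical", seed=seed, pixel_size=pixel_size,
                            noise_sd=noise_sd, image_shape=(500, 500),
                            fiber_density=0.0)
    wall_state = ("full" if wall_completeness >= 1.0
                  else "partial" if wall_completeness > 0 else "absent")
    center = (250 * pixel_size, 250 * pixel_size)
    v = sd.GroundTruthVessel(
        id=0, bundle_id=0, center=center, true_diameter=diameter, type="MX",
        wall_state=wall_state, expanding=False,
        true_conductive=(wall_state == "full" and stain_fraction > 0.5),
        true_stain_fraction=stain_fraction, wall_completeness=wall_completeness)
    pair = sd.render_pair([v], cfg)
    return cfg, v, pair


class TestDetectLumens:
    def test_blank_noise_image_empty(self):
        rng = np.random.default_rng(0)
        bf = 0.5 + rng.normal(0, 0.01, (300, 300))
        assert detect_lumens(bf, 0.2) == []

    def test_constant_image_empty(self):
        assert detect_lumens(np.full((100, 100), 0.3), 0.2) == []

    def test_bad_pixel_size(self):
        with pytest.raises(ValueError):
            detect_lumens(np.zeros((10, 10)), 0.0)

    def test_five_disjoint_vessels_recovered(self):
        """Known geometry: counts, centroids (1 px) and areas (5%) recovered."""
        cfg = sd.default_config("apical", seed=0, image_shape=(800, 800),
                                noise_sd=0.0, fiber_density=0.0)
        centers = [(30, 30), (30, 110), (80, 70), (130, 40), (130, 120)]
        truth = [sd.GroundTruthVessel(
            id=i, bundle_id=0, center=(float(x), float(y)),
            true_diameter=8.0 + 2 * i, type="MX", wall_state="full",
            expanding=False, true_conductive=True, true_stain_fraction=0.9,
            wall_completeness=1.0) for i, (x, y) in enumerate(centers)]
        pair = sd.render_pair(truth, cfg)
        regions = detect_lumens(pair.bf, pair.pixel_size)
        assert len(regions) == 5
        for region in regions:
            v = min(truth, key=lambda v: math.hypot(v.center[0] - region.centroid[0],
                                                    v.center[1] - region.centroid[1]))
            assert math.hypot(v.center[0] - region.centroid[0],
                              v.center[1] - region.centroid[1]) < cfg.pixel_size
            true_area = math.pi * (v.true_diameter / 2) ** 2
            assert abs(region.area_um2 - true_area) / true_area < 0.05
            assert abs(region.equivalent_diameter - v.true_diameter) \
                <= 2 * cfg.pixel_size

    def test_touching_lumens_split_by_watershed(self):
        """Two unwalled lumens fused into a dumbbell are split into 2 regions."""
        bf = np.full((300, 300), 0.5)
        yy, xx = np.mgrid[:300, :300]
        for cx in (120, 178):
            bf[(xx - cx) ** 2 + (yy - 150) ** 2 <= 32 ** 2] = 0.85
        regions = detect_lumens(bf, 0.2)
        assert len(regions) == 2

    def test_region_label_order_row_major(self):
        cfg = sd.default_config("apical", seed=0, image_shape=(600, 600),
                                noise_sd=0.0, fiber_density=0.0)
        truth = [sd.GroundTruthVessel(
            id=i, bundle_id=0, center=c, true_diameter=10.0, type="MX",
            wall_state="full", expanding=False, true_conductive=True,
            true_stain_fraction=0.9, wall_completeness=1.0)
            for i, c in enumerate([(90.0, 30.0), (30.0, 30.0), (60.0, 90.0)])]
        pair = sd.render_pair(truth, cfg)
        regions = detect_lumens(pair.bf, pair.pixel_size)
        ys = [r.centroid[1] for r in regions]
        assert ys == sorted(ys)
        assert [r.label for r in regions] == [1, 2, 3]


class TestWallCompleteness:
    def test_closed_annulus_full(self):
        _, _, pair = single_vessel(0.9, wall_completeness=1.0)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        assert measure_wall_completeness(pair.bf, region, pair.pixel_size) == 1.0

    def test_partial_arc_270_degrees(self):
        _, _, pair = single_vessel(0.0, wall_completeness=0.75)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        wc = measure_wall_completeness(pair.bf, region, pair.pixel_size)
        assert wc == pytest.approx(0.75, abs=0.02)

    def test_absent_wall_near_zero(self):
        _, _, pair = single_vessel(0.0, wall_completeness=0.0, noise_sd=0.01)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        assert measure_wall_completeness(pair.bf, region, pair.pixel_size) <= 0.05


class TestExposureNormalization:
    def test_constant_image_empty_mask(self):
        assert not apply_exposure_normalization(np.full((50, 50), 0.2)).any()

    def test_floor_rejected_arcs_kept(self):
        """Autofluorescence at bg+2s stays below, stained arcs at bg+20s above."""
        rng = np.random.default_rng(1)
        sigma = 0.01
        ef = 0.02 + rng.normal(0, sigma, (400, 400))
        ef[100:300, 100:300] += 2 * sigma          # autofluorescence floor
        yy, xx = np.mgrid[:400, :400]
        ring = np.abs(np.hypot(xx - 200, yy - 200) - 50) < 5
        ef[ring] += 20 * sigma                     # stained arcs
        mask = apply_exposure_normalization(ef)
        assert mask[ring].mean() > 0.95
        assert mask[~ring].mean() < 0.001

    def test_infinite_k_gives_empty_mask(self):
        _, _, pair = single_vessel(0.9, noise_sd=0.01)
        params = SegmentationParams(k_ef=1e9)
        assert not apply_exposure_normalization(pair.ef, params).any()


class TestStainFraction:
    def test_closed_ring_fully_stained(self):
        _, _, pair = single_vessel(1.0)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        mask = apply_exposure_normalization(pair.ef)
        assert measure_stain_fraction(mask, region, pair.pixel_size) == 1.0

    @pytest.mark.parametrize("sf", [0.75, 0.4])
    def test_partial_arc_recovered(self, sf):
        _, _, pair = single_vessel(sf)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        mask = apply_exposure_normalization(pair.ef)
        assert measure_stain_fraction(mask, region, pair.pixel_size) == \
            pytest.approx(sf, abs=0.02)

    def test_blank_ef_zero(self):
        _, _, pair = single_vessel(0.0)
        region = detect_lumens(pair.bf, pair.pixel_size)[0]
        mask = apply_exposure_normalization(pair.ef)
        assert measure_stain_fraction(mask, region, pair.pixel_size) == 0.0

    def test_monotone_in_arc_angle(self):
        measured = []
        for sf in (0.2, 0.5, 0.8):
            _, _, pair = single_vessel(sf)
            region = detect_lumens(pair.bf, pair.pixel_size)[0]
            mask = apply_exposure_normalization(pair.ef)
            measured.append(measure_stain_fraction(mask, region, pair.pixel_size))
        assert measured == sorted(measured)


class TestMeasureVessels:
    def test_deterministic(self, noisy_segment):
        _, _, pair = noisy_segment
        a = measure_vessels(pair)
        b = measure_vessels(pair)
        assert [(r.area_um2, r.wall_completeness, r.stain_fraction) for r in a] \
            == [(r.area_um2, r.wall_completeness, r.stain_fraction) for r in b]

    def test_empty_image_empty_list(self):
        pair = ImagePair(bf=np.full((64, 64), 0.5), ef=np.full((64, 64), 0.02),
                         pixel_size=0.2)
        assert measure_vessels(pair) == []

    def test_matches_truth_within_tolerance(self, noisefree_segment):
        cfg, truth, pair = noisefree_segment
        records = measure_vessels(pair)
        assert len(records) == len(truth)
        for r, v in match_to_truth(records, truth):
            assert abs(r.diameter_um - v.true_diameter) < 0.2
            assert abs(r.stain_fraction - v.true_stain_fraction) < 0.05
            if v.wall_state == "full":
                assert r.wall_completeness > 0.95

    def test_intensity_scale_invariance(self):
        """Doubling all intensities leaves the measurements unchanged."""
        _, _, pair = single_vessel(0.75, noise_sd=0.005)
        scaled = ImagePair(bf=pair.bf * 2.0, ef=pair.ef * 2.0,
                           pixel_size=pair.pixel_size)
        a = measure_vessels(pair)
        b = measure_vessels(scaled)
        assert len(a) == len(b) == 1
        assert a[0].area_um2 == pytest.approx(b[0].area_um2, rel=1e-9)
        assert a[0].stain_fraction == pytest.approx(b[0].stain_fraction, abs=1e-9)
        assert a[0].wall_completeness == pytest.approx(b[0].wall_completeness,
                                                       abs=1e-9)
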