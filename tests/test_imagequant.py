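"""Cell segmentation, background subtraction, spot detection, eGFP estimate."""

import numpy as np
import pytest

from polyqtc.imagequant import (
    CalibratedImage,
    CellSegmentation,
    DetectionParams,
    detect_spots,
    estimate_egfp,
    segment_cells,
    subtract_background,
)
from polyqtc.simdata import ImageSimConfig, gen_image
from polyqtc.simdata.images import spot_scale_um
from tests.conftest import flat_image


def _disk_image(radius_um=5.0, intensity=100.0, shape=(160, 160), pixel_size=0.1):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r_px = radius_um / pixel_size
    mask = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= r_px**2
    img = np.where(mask, intensity, 0.0)
    return CalibratedImage(img, pixel_size), mask


class TestSegmentCells:
    def test_blank_image_empty_mask(self):
        seg = segment_cells(flat_image(0.0))
        assert not seg.mask.any()
        assert seg.total_cell_volume == 0.0

    def test_planted_disk_area_recovered(self):
        img, mask = _disk_image()
        seg = segment_cells(img)
        planted_volume = mask.sum() * img.pixel_size**2
        assert seg.mask.sum() > 0
        assert seg.total_cell_volume == pytest.approx(planted_volume, rel=0.05)

    def test_threshold_above_signal_gives_empty_mask(self):
        img, _ = _disk_image(intensity=100.0)
        seg = segment_cells(img, DetectionParams(t_cell=101.0))
        assert not seg.mask.any()

    def test_implausible_calibration_warns(self):
        img = flat_image(0.0, pixel_size=1.0)  # sigma_cell 0.2 um -> 0.2 px
        with pytest.warns(UserWarning, match="calibration"):
            segment_cells(img)


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        out = subtract_background(flat_image(42.0))
        assert np.all(out.intensities == 0.0)

    def test_quantile_zero_leaves_image_unchanged(self):
        img = CalibratedImage(np.array([[0.0, 0.0, 0.0], [0.0, 10.0, 0.0]]), 0.1)
        out = subtract_background(img)  # 20% quantile of mostly-zero data is 0
        assert np.array_equal(out.intensities, img.intensities)

    def test_matches_sorted_order_statistics_oracle(self):
        vals = np.arange(1.0, 101.0)
        rng = np.random.default_rng(0)
        img = CalibratedImage(rng.permutation(vals).reshape(10, 10), 0.1)
        # brute-force linear interpolation between order statistics
        q = 0.20
        h = (len(vals) - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        s = np.sort(vals)
        expected_q = s[lo] + (h - lo) * (s[hi] - s[lo])
        out = subtract_background(img)
        assert np.min(img.intensities - out.intensities) >= 0
        assert np.max(img.intensities[out.intensities > 0] - out.intensities[out.intensities > 0]) == pytest.approx(expected_q)
        assert (out.intensities == 0).mean() >= 0.20


class TestDetectSpots:
    def test_uniform_image_has_no_spots(self):
        assert len(detect_spots(flat_image(50.0))) == 0

    def test_single_planted_spot_found_at_its_center(self):
        cfg = ImageSimConfig(n_cells=1, n_aggregates=1, noise_sd=0.0, seed=4)
        img, truth = gen_image(cfg)
        spots = detect_spots(img)
        assert len(spots) == 1
        (cy, cx) = truth.aggregates[0].centroid_px
        dy, dx = spots.spots[0].centroid[0] - cy, spots.spots[0].centroid[1] - cx
        assert np.hypot(dy, dx) <= 1.0

    def test_two_spots_merge_when_coincident(self):
        pixel_size = 0.1
        shape = (128, 128)
        base = np.full(shape, 10.0)

        def render(centers):
            img = base.copy()
            s_px = spot_scale_um(np.exp(0.5)) / pixel_size
            yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
            for cy, cx in centers:
                img += 800.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s_px**2))
            return CalibratedImage(img, pixel_size)

        far = detect_spots(render([(40, 40), (90, 90)]))  # >> sigma_large apart
        merged = detect_spots(render([(64, 64), (64, 64)]))
        assert len(far) == 2
        assert len(merged) == 1

    def test_sigma_order_violation_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            DetectionParams(sigma_spot_small=0.5, sigma_spot_large=0.1)

    def test_raising_threshold_never_adds_spots(self, detection_scene):
        _, img, _ = detection_scene
        counts = [
            len(detect_spots(img, DetectionParams(t_spot=t)))
            for t in (40.0, 80.0, 160.0, 320.0, 640.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_spot_below_minimum_volume(self, detection_scene):
        _, img, _ = detection_scene
        params = DetectionParams(v_min=0.5)
        spots = detect_spots(img, params)
        assert all(s.volume >= params.v_min for s in spots.spots)


class TestEstimateEgfp:
    def _seg(self, img, n_px):
        mask = np.zeros_like(img.intensities, dtype=bool)
        mask.flat[:n_px] = True
        vol = n_px * img.pixel_size**2
        return CellSegmentation(mask=mask, outlines=[], total_cell_volume=vol,
                                pixel_size=img.pixel_size)

    def test_pure_background_gives_zero(self):
        img = flat_image(30.0)
        assert estimate_egfp(img, self._seg(img, 100)) == 0.0

    def test_closed_form_for_planted_diffuse_signal(self):
        img, mask = _disk_image(radius_um=4.0, intensity=50.0)
        seg = CellSegmentation(
            mask=mask, outlines=[],
            total_cell_volume=float(mask.sum()) * img.pixel_size**2,
            pixel_size=img.pixel_size,
        )
        # 20% quantile is 0 (disk covers < 80% of frame): numerator = 50 * n_px
        expected = 50.0 * mask.sum() / seg.total_cell_volume
        assert estimate_egfp(img, seg) == pytest.approx(expected)

    def test_linearity_in_intensity(self):
        img, mask = _disk_image(radius_um=4.0, intensity=50.0)
        img2 = CalibratedImage(img.intensities * 2, img.pixel_size)
        seg = CellSegmentation(
            mask=mask, outlines=[],
            total_cell_volume=float(mask.sum()) * img.pixel_size**2,
            pixel_size=img.pixel_size,
        )
        assert estimate_egfp(img2, seg) == pytest.approx(2 * estimate_egfp(img, seg))

    def test_zero_cell_volume_is_an_error(self):
        img = flat_image(1.0)
        seg = CellSegmentation(mask=np.zeros_like(img.intensities, dtype=bool),
                               outlines=[], total_cell_volume=0.0, pixel_size=0.1)
        with pytest.raises(ValueError, match="volume"):
            estimate_egfp(img, seg)
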