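"""Soma detection and area-depth binning."""

import numpy as np
import pytest

from cortodeconv import (
    AnnotatedRegion,
    BinSpec,
    DetectionParams,
    Spot,
    SpotSet,
    bin_spots,
    detect_spots,
    estimate_baseline,
    nissl_density,
)
from cortodeconv.imaging import region_area_by_depth
from cortodeconv.synth import make_image


def region_from(image, baseline=None):
    """Full-frame region whose depth is the normalized row coordinate."""
    h, w = image.shape
    depth = np.broadcast_to(((np.arange(h) + 0.5) / h)[:, None], (h, w))
    return AnnotatedRegion(
        image=image, mask=np.ones((h, w), bool), depth_of_pixel=depth.copy()
    )


class TestBaseline:
    def test_constant_image(self):
        reg = region_from(np.full((10, 10), 7, dtype=np.uint8))
        assert estimate_baseline(reg) == 7

    def test_bimodal_mode(self):
        img = np.full((10, 10), 10, dtype=np.uint16)
        img[:1, :] = 200  # 10% bright
        assert estimate_baseline(region_from(img)) == 10

    def test_random_discrete_matches_brute_force_histogram(self, rng):
        values = rng.choice([3, 5, 9, 14], size=(50, 50), p=[0.2, 0.45, 0.25, 0.1])
        img = values.astype(np.int32)
        brute = max(set(img.ravel().tolist()), key=img.ravel().tolist().count)
        assert estimate_baseline(region_from(img)) == brute

    def test_float_image_uses_bin_width(self):
        img = np.full((8, 8), 4.2)
        img[0, 0] = 9.9
        est = estimate_baseline(region_from(img), float_bin_width=1.0)
        assert abs(est - 4.2) <= 0.5

    def test_empty_mask_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="mask"):
            AnnotatedRegion(
                image=img, mask=np.zeros((4, 4), bool), depth_of_pixel=np.zeros((4, 4))
            )


class TestDetect:
    def test_blank_image_yields_empty_spotset(self):
        reg = region_from(np.full((50, 50), 30, dtype=np.uint16))
        spots = detect_spots(reg)
        assert len(spots) == 0

    def test_planted_disks_detected_with_accurate_areas(self):
        planted = [
            ((25.0, 30.0), 4.0, 500.0),
            ((60.0, 80.0), 6.0, 400.0),
            ((90.0, 40.0), 5.0, 600.0),
        ]
        img = make_image(planted, canvas=(120, 120), baseline=100.0)
        spots = detect_spots(region_from(img.image.astype(np.uint16)))
        assert len(spots) == 3
        got = sorted(s.area_px for s in spots.spots)
        want = sorted(s.area_px for s in img.spots)
        for g, w in zip(got, want):
            assert abs(g - w) / w <= 0.10

    def test_thin_line_excluded_by_circularity(self):
        img = np.full((60, 60), 100.0)
        img[30, 10:50] = 600.0  # 1-px dendrite-like line
        spots = detect_spots(region_from(img), baseline=100.0)
        assert len(spots) == 0

    def test_detector_recall_precision(self):
        """>=95% recall and precision on disjoint bright disks."""
        rng = np.random.default_rng(3)
        planted = []
        taken = []
        while len(planted) < 25:
            cy, cx = rng.uniform(15, 240, 2)
            if all((cy - y) ** 2 + (cx - x) ** 2 > 30**2 for y, x in taken):
                taken.append((cy, cx))
                planted.append(((cy, cx), rng.uniform(3, 7), rng.uniform(300, 800)))
        img = make_image(planted, canvas=(256, 256), baseline=100.0)
        spots = detect_spots(region_from(img.image.astype(np.uint16)))
        # disks are disjoint and bright: detection count is the confusion table
        n_true, n_det = len(planted), len(spots)
        matched = 0
        for (cy, cx), r, _ in planted:
            for s in spots.spots:
                if abs(s.centroid_depth - cy / 256) < 2 / 256 and abs(
                    s.area_px - np.pi * r**2
                ) < 0.5 * np.pi * r**2:
                    matched += 1
                    break
        assert matched / n_true >= 0.95  # recall
        assert matched / n_det >= 0.95  # precision


class TestBinning:
    def test_single_spot_lands_in_documented_bins(self):
        """A 25-px soma at depth 0.505 falls in depth bin 50, area bin 1."""
        bins = BinSpec()
        area = np.ones(100)
        ss = SpotSet(
            spots=[Spot(centroid_depth=0.505, area_px=25,
                        integrated_intensity=10.0, circularity=1.0)],
            source_id="t", region_area_by_depth=area,
        )
        density, intensity = bin_spots(ss, bins)
        assert density.values[50, 1] == 1.0
        assert intensity.values[50, 1] == 10.0
        assert density.values.sum() == 1.0

    def test_no_spots_all_zero(self):
        ss = SpotSet(spots=[], source_id="t", region_area_by_depth=np.ones(100))
        density, intensity = bin_spots(ss, BinSpec())
        assert not density.values.any() and not intensity.values.any()

    def test_matches_brute_force_binning_oracle(self, rng):
        bins = BinSpec()
        spots = [
            Spot(
                centroid_depth=float(rng.uniform(0, 1)),
                area_px=int(rng.integers(1, 1000)),
                integrated_intensity=float(rng.uniform(0, 50)),
                circularity=1.0,
            )
            for _ in range(1000)
        ]
        area = rng.uniform(0.5, 2.0, 100)
        ss = SpotSet(spots=spots, source_id="t", region_area_by_depth=area)
        density, intensity = bin_spots(ss, bins)

        brute_d = np.zeros((100, 40))
        brute_i = np.zeros((100, 40))
        for s in spots:
            j = min(int(s.centroid_depth * 100), 99)
            k = min(s.area_px // 20, 39)
            brute_d[j, k] += 1 / area[j]
            brute_i[j, k] += s.integrated_intensity / area[j]
        assert np.allclose(density.values, brute_d)
        assert np.allclose(intensity.values, brute_i)

    def test_counting_conservation_and_order_invariance(self, rng):
        bins = BinSpec()
        spots = [
            Spot(centroid_depth=float(rng.uniform(0, 1)), area_px=int(rng.integers(1, 900)),
                 integrated_intensity=1.0, circularity=1.0)
            for _ in range(300)
        ]
        area = rng.uniform(0.5, 2.0, 100)
        fwd, _ = bin_spots(SpotSet(spots, "a", area), bins)
        rev, _ = bin_spots(SpotSet(spots[::-1], "a", area), bins)
        assert np.array_equal(fwd.values, rev.values)
        recovered = (fwd.values * area[:, None]).sum()
        assert recovered == pytest.approx(len(spots))

    def test_zero_area_bin_with_spots_rejected(self):
        area = np.ones(100)
        area[50] = 0.0
        ss = SpotSet(
            spots=[Spot(0.505, 25, 1.0, 1.0)], source_id="t", region_area_by_depth=area
        )
        with pytest.raises(ValueError, match="zero annotated area"):
            bin_spots(ss, BinSpec())

    def test_oversized_spot_clamped_to_last_bin(self):
        ss = SpotSet([Spot(0.5, 5000, 1.0, 1.0)], "t", np.ones(100))
        density, _ = bin_spots(ss, BinSpec())
        assert density.values[50, 39] == 1.0


class TestNissl:
    def test_two_identical_regions_average_to_one(self):
        img = make_image(
            [((30.0, 30.0), 5.0, 400.0), ((70.0, 60.0), 4.0, 300.0)],
            canvas=(100, 100), baseline=100.0,
        )
        reg = region_from(img.image.astype(np.uint16))
        single = nissl_density([reg])
        double = nissl_density([reg, reg])
        assert np.allclose(single.values, double.values)

    def test_averaging_of_two_known_regions(self):
        imgs = [
            make_image([((20.0, 50.0), 5.0, 400.0)], canvas=(100, 100), baseline=100.0),
            make_image([((80.0, 50.0), 5.0, 400.0)], canvas=(100, 100), baseline=100.0),
        ]
        regs = [region_from(i.image.astype(np.uint16)) for i in imgs]
        d1 = nissl_density([regs[0]]).values
        d2 = nissl_density([regs[1]]).values
        both = nissl_density(regs).values
        assert np.allclose(both, (d1 + d2) / 2)

    def test_region_area_by_depth_in_mm2(self):
        reg = region_from(np.zeros((100, 50), dtype=np.uint8))
        area = region_area_by_depth(reg, BinSpec())
        # 1 row of 50 px per depth bin, 1 um^2 each -> 5e-5 mm^2
        assert np.allclose(area, 50 * 1e-6)
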