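import numpy as np
import pytest

from nerveseg.io import LabelVolume
from nerveseg.metrics import (
    SizeBins,
    effective_diameter,
    extract_instances,
    f1_curve,
    match_instances,
    missed_by_size,
    over_under_segmentation,
)

SPACING = 11.4
PX_MM2 = (SPACING / 1000.0) ** 2


def vol_from_slices(*slices):
    return LabelVolume(labels=np.stack(slices).astype(np.uint8), spacing_um=SPACING)


def disc(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(np.uint8)


class TestExtractInstances:
    def test_diagonal_pixels_are_one_component(self):
        sl = np.zeros((5, 5), np.uint8)
        sl[1, 1] = sl[2, 2] = 1
        assert len(extract_instances(vol_from_slices(sl), 0)) == 1

    def test_separated_pixels_are_two_components(self):
        sl = np.zeros((5, 5), np.uint8)
        sl[1, 1] = sl[1, 3] = 1
        assert len(extract_instances(vol_from_slices(sl), 0)) == 2

    def test_area_uses_physical_spacing(self):
        sl = np.zeros((4, 4), np.uint8)
        sl[:2, :2] = 1
        inst = extract_instances(vol_from_slices(sl), 0)[0]
        assert inst.area_mm2 == pytest.approx(4 * PX_MM2)

    def test_phantom_slice_component_count(self, default_phantom):
        # away from events, the number of components equals the live tube count
        z = 0
        k = len(extract_instances(default_phantom.labels, z))
        assert k == default_phantom.spec.n_fascicles_initial


class TestMatchInstances:
    def test_perfect_prediction_f1_one_at_all_thresholds(self):
        sl = disc((32, 32), 10, 10, 4) + 0
        vol = vol_from_slices(sl)
        gi = extract_instances(vol, 0)
        for t in (0.5, 0.7, 0.95):
            assert match_instances(gi, gi, t).f1 == 1.0

    def test_empty_prediction_counts_false_negatives(self):
        sl = np.zeros((32, 32), np.uint8)
        for cx in (5, 15, 25):
            sl |= disc((32, 32), 8, cx, 3)
        gi = extract_instances(vol_from_slices(sl), 0)
        res = match_instances(gi, [], 0.7)
        assert (res.tp, res.fp, res.fn) == (0, 0, 3)
        assert res.f1 == 0.0

    def test_partial_match_counts_tp_fp_fn(self):
        # one pair above threshold, one prediction overlapping too little
        gt = np.zeros((32, 32), np.uint8)
        gt[2:10, 2:10] = 1    # instance A: 8x8
        gt[20:28, 20:28] = 1  # instance B
        pred = np.zeros((32, 32), np.uint8)
        pred[2:10, 2:11] = 1       # IoU with A = 64/72 = 0.89
        pred[26:28, 20:28] = 1     # IoU with B = 16/64 = 0.25
        gi = extract_instances(vol_from_slices(gt), 0)
        pi = extract_instances(vol_from_slices(pred), 0)
        res = match_instances(gi, pi, 0.7)
        assert (res.tp, res.fp, res.fn) == (1, 1, 1)
        # harmonic mean of precision and recall: 2*1 / (2*1 + 1 + 1)
        assert res.f1 == pytest.approx(0.5)

    def test_matching_is_one_to_one_at_half(self, rng):
        for _ in range(20):
            gt = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            pred = (rng.random((16, 16)) < 0.3).astype(np.uint8)
            gi = extract_instances(vol_from_slices(gt), 0)
            pi = extract_instances(vol_from_slices(pred), 0)
            res = match_instances(gi, pi, 0.5)
            assert len({i for i, _, _ in res.pairs}) == len(res.pairs)
            assert len({j for _, j, _ in res.pairs}) == len(res.pairs)

    def test_threshold_below_half_rejected(self):
        with pytest.raises(ValueError):
            match_instances([], [], 0.3)


class TestF1Curve:
    def test_perfect_prediction_curve_is_one(self, default_phantom):
        curve = f1_curve(default_phantom.labels, default_phantom.labels)
        assert all(v == 1.0 for v in curve.values())

    def test_non_increasing_in_threshold(self):
        gt = np.zeros((32, 32), np.uint8)
        gt[4:14, 4:14] = 1
        pred = np.zeros((32, 32), np.uint8)
        pred[5:14, 4:14] = 1  # IoU = 90/100 = 0.9
        curve = f1_curve(vol_from_slices(gt), vol_from_slices(pred))
        vals = [curve[t] for t in sorted(curve)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert curve[0.5] == 1.0 and curve[0.95] == 0.0


class TestOverUnderSegmentation:
    def test_perfect_prediction_rates_zero(self, default_phantom):
        rates = over_under_segmentation(default_phantom.labels, default_phantom.labels)
        assert rates == {"over": 0.0, "under": 0.0}

    def test_split_disc_counts_as_over_segmentation(self):
        gt = disc((48, 48), 24, 24, 10)
        pred = gt.copy()
        pred[:, 24] = 0  # cut the disc into two halves
        rates = over_under_segmentation(vol_from_slices(gt), vol_from_slices(pred))
        assert rates["over"] == pytest.approx(1.0)  # 1 affected / 1 total
        assert rates["under"] == 0.0

    def test_merged_blob_counts_both_under_segmented(self):
        gt = np.zeros((48, 48), np.uint8)
        gt |= disc((48, 48), 24, 14, 8)
        gt |= disc((48, 48), 24, 34, 8)
        pred = np.zeros((48, 48), np.uint8)
        pred[16:33, 5:44] = 1  # one blob covering both
        rates = over_under_segmentation(vol_from_slices(gt), vol_from_slices(pred))
        assert rates["under"] == pytest.approx(1.0)  # both of 2 affected
        assert rates["over"] == 0.0


class TestMissedBySize:
    def test_perfect_prediction_all_zero(self, default_phantom):
        out = missed_by_size(default_phantom.labels, default_phantom.labels)
        for v in out.values():
            assert v == 0.0 or np.isnan(v)

    def test_one_missed_fascicle_per_bin(self):
        # radii chosen to land inside each area bin
        shape = (256, 256)
        gt = np.zeros(shape, np.uint8)
        radii_mm = [0.05, 0.12, 0.25, 0.35]  # areas 0.008, 0.045, 0.196, 0.385 mm2
        centers = [(30, 30), (30, 128), (128, 30), (150, 150)]
        for (cy, cx), r_mm in zip(centers, radii_mm):
            gt |= disc(shape, cy, cx, r_mm * 1000 / SPACING)
        pred = np.zeros(shape, np.uint8)
        out = missed_by_size(vol_from_slices(gt), vol_from_slices(pred))
        assert all(v == 1.0 for v in out.values())

    def test_bin_lookup_of_small_area(self):
        bins = SizeBins()
        assert bins.bin_of(0.05) == "small"
        assert bins.bin_of(0.01) == "tiny"
        assert bins.bin_of(0.2) == "medium"
        assert bins.bin_of(0.5) == "large"


class TestEffectiveDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(0.02, 0.16), (0.09, 0.34), (0.3, 0.62), (np.pi, 2.0)],
    )
    def test_printed_bin_boundaries(self, area, expected):
        assert effective_diameter(area) == pytest.approx(expected, abs=0.005)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(-1.0)
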