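"""Brightness split, h-maxima seeding, seeded watershed, evaluation."""

import numpy as np
import pytest

from tmagraph.preprocess import PreprocessConfig, preprocess_core
from tmagraph.segment import (SegmentationReport, evaluate_segmentation,
                              h_maxima_seeds, records_from_labels,
                              seeded_watershed, segment_nuclei,
                              split_by_brightness)
from tmagraph.synthetic import generate_core, well_separated_spec


def _two_bumps(height=100, valley=50, sep=30, sigma=5.0, size=(40, 70)):
    """Two Gaussian bumps of equal height joined by a valley of given depth."""
    yy, xx = np.mgrid[0:size[0], 0:size[1]]
    c1 = (size[0] // 2, size[1] // 2 - sep // 2)
    c2 = (size[0] // 2, size[1] // 2 + sep // 2)
    g1 = np.exp(-((yy - c1[0]) ** 2 + (xx - c1[1]) ** 2) / (2 * sigma ** 2))
    g2 = np.exp(-((yy - c2[0]) ** 2 + (xx - c2[1]) ** 2) / (2 * sigma ** 2))
    img = height * np.maximum(g1, g2)
    # lift the saddle so the valley depth (peak - saddle) equals `valley`
    ridge = np.exp(-((yy - c1[0]) ** 2) / (2 * sigma ** 2))
    bar = (height - valley) * ridge * (np.abs(xx - size[1] // 2) <= sep // 2)
    return np.clip(np.rint(np.maximum(img, bar)), 0, 255).astype(np.uint8), c1, c2


class TestSplitByBrightness:
    def test_bimodal_objects(self):
        img = np.zeros((30, 60), np.uint8)
        img[5:25, 5:25] = 60
        img[5:25, 35:55] = 200
        mask = (img > 0).astype(np.uint8)
        bright, dark = split_by_brightness(img, mask)
        assert (dark[5:25, 5:25] == 60).all() and bright[5:25, 5:25].sum() == 0
        assert (bright[5:25, 35:55] == 200).all() and dark[5:25, 35:55].sum() == 0

    def test_partition_property_random(self, rng):
        img = rng.integers(0, 255, (60, 60)).astype(np.uint8)
        mask = (rng.random((60, 60)) < 0.5).astype(np.uint8)
        bright, dark = split_by_brightness(img, mask)
        m = mask.astype(bool)
        assert ((bright > 0) & (dark > 0)).sum() == 0
        merged = np.where(bright > 0, bright, dark)
        # union restores the masked image wherever it is nonzero
        assert np.array_equal(merged[m & (img > 0)], img[m & (img > 0)])
        assert merged[~m].sum() == 0

    def test_empty_mask(self):
        bright, dark = split_by_brightness(np.ones((5, 5), np.uint8),
                                           np.zeros((5, 5), np.uint8))
        assert bright.sum() == 0 and dark.sum() == 0

    def test_constant_masked_region_warns(self):
        img = np.full((10, 10), 80, np.uint8)
        with pytest.warns(UserWarning):
            bright, dark = split_by_brightness(img, np.ones((10, 10), np.uint8))
        assert (dark == 80).all() and bright.sum() == 0


class TestHMaximaSeeds:
    def test_valley_depth_against_h(self):
        img, _, _ = _two_bumps(height=100, valley=50)
        assert h_maxima_seeds(img, 30).max() == 2
        assert h_maxima_seeds(img, 60).max() == 1

    def test_constant_image_single_seed(self):
        seeds = h_maxima_seeds(np.full((12, 12), 40, np.uint8), 10)
        assert seeds.max() == 1

    def test_single_bump_one_seed_any_h(self):
        yy, xx = np.mgrid[0:31, 0:31]
        img = np.rint(90 * np.exp(-((yy - 15) ** 2 + (xx - 15) ** 2) / 40.0)
                      ).astype(np.uint8)
        for h in (1, 10, 40, 80):
            assert h_maxima_seeds(img, h).max() == 1

    def test_monotone_in_h(self, rng):
        img = rng.integers(0, 200, (50, 50)).astype(np.uint8)
        counts = [h_maxima_seeds(img, h).max() for h in (1, 3, 8, 20, 50, 120)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_h(self):
        with pytest.raises(ValueError):
            h_maxima_seeds(np.zeros((5, 5), np.uint8), 0)


class TestSeededWatershed:
    def test_disjoint_blobs(self):
        img = np.zeros((20, 40), np.uint8)
        img[5:15, 5:15] = 100
        img[5:15, 25:35] = 100
        mask = (img > 0).astype(np.uint8)
        seeds = np.zeros_like(img, np.int32)
        seeds[10, 10] = 1
        seeds[10, 30] = 2
        out = seeded_watershed(img, seeds, mask)
        assert set(np.unique(out[5:15, 5:15])) == {1}
        assert set(np.unique(out[5:15, 25:35])) == {2}
        assert (out[mask == 0] == 0).all()

    def test_one_blob_one_seed(self):
        img = np.zeros((20, 20), np.uint8)
        img[5:15, 5:15] = 120
        mask = (img > 0).astype(np.uint8)
        seeds = np.zeros_like(img, np.int32)
        seeds[10, 10] = 1
        out = seeded_watershed(img, seeds, mask)
        assert (out[5:15, 5:15] == 1).all()

    def test_touching_equal_bumps_split_at_valley(self):
        img, c1, c2 = _two_bumps(height=120, valley=60, sep=30)
        mask = (img > 20).astype(np.uint8)
        seeds = np.zeros_like(img, np.int32)
        seeds[c1] = 1
        seeds[c2] = 2
        out = seeded_watershed(img, seeds, mask)
        # each peak keeps its own basin; the split falls near the midline
        assert out[c1] == 1 and out[c2] == 2
        mid = (c1[1] + c2[1]) // 2
        left = out[:, :mid - 3]
        right = out[:, mid + 3:]
        assert 2 not in left and 1 not in right

    def test_no_seed_errors(self):
        with pytest.raises(ValueError):
            seeded_watershed(np.zeros((5, 5), np.uint8),
                             np.zeros((5, 5), np.int32),
                             np.ones((5, 5), np.uint8))


class TestSegmentNuclei:
    def test_recovers_well_separated_truth_count(self):
        image, truth = generate_core(well_separated_spec(rng_seed=21))
        corrected, mask, _ = preprocess_core(
            image, PreprocessConfig(isolated_margin_px=None))
        labels, records = segment_nuclei(corrected, mask, h=10)
        assert abs(len(records) - truth.n_nuclei) <= 2
        report = evaluate_segmentation(labels, truth)
        assert report.pct_correct >= 90.0

    def test_empty_mask_empty_result(self):
        labels, records = segment_nuclei(np.zeros((10, 10), np.uint8),
                                         np.zeros((10, 10), np.uint8))
        assert labels.max() == 0 and records == []

    def test_bright_and_dark_nuclei_both_found(self):
        img = np.full((40, 80), 0, np.uint8)
        img[10:30, 8:28] = 90      # dark tumor-like nucleus
        img[10:30, 48:68] = 210    # bright lymphocyte-like nucleus
        mask = (img > 0).astype(np.uint8)
        labels, records = segment_nuclei(img, mask, h=10, smooth_kernel=0)
        assert len(records) == 2
        means = sorted(r.mean_intensity for r in records)
        assert means[0] == pytest.approx(90, abs=1)
        assert means[1] == pytest.approx(210, abs=1)

    def test_label_partition_is_disjoint(self, processed_core):
        labels = processed_core.labels
        records = processed_core.records
        seen = np.zeros(labels.shape, dtype=bool)
        for rec in records:
            assert not seen[rec.coords[:, 0], rec.coords[:, 1]].any()
            seen[rec.coords[:, 0], rec.coords[:, 1]] = True
        assert seen.sum() == (labels > 0).sum()


class TestEvaluateSegmentation:
    def test_identical_is_all_correct(self):
        truth = np.zeros((30, 30), np.int32)
        truth[2:10, 2:10] = 1
        truth[15:25, 15:25] = 2
        rep = evaluate_segmentation(truth.copy(), truth)
        assert (rep.correct, rep.over_segmented, rep.under_segmented) == (2, 0, 0)
        assert rep.pct_correct == 100.0

    def test_split_nucleus_counts_over(self):
        truth = np.zeros((20, 20), np.int32)
        truth[2:18, 2:18] = 1
        result = truth.copy()
        result[2:18, 10:18] = 2
        rep = evaluate_segmentation(result, truth)
        assert rep.over_segmented == 1 and rep.total == 1

    def test_merged_nuclei_count_under(self):
        truth = np.zeros((20, 40), np.int32)
        truth[5:15, 5:15] = 1
        truth[5:15, 25:35] = 2
        result = np.where(truth > 0, 1, 0)
        rep = evaluate_segmentation(result, truth)
        assert rep.under_segmented == 2 and rep.correct == 0

    def test_counts_partition_total(self, rng):
        truth = np.zeros((60, 60), np.int32)
        k = 1
        for i in range(0, 60, 12):
            for j in range(0, 60, 12):
                truth[i + 1:i + 10, j + 1:j + 10] = k
                k += 1
        # randomly merge/split some labels in the result
        result = truth.copy()
        result[result == 3] = 2
        result[30:36, 37:41] = 99
        rep = evaluate_segmentation(result, truth)
        assert rep.correct + rep.over_segmented + rep.under_segmented == rep.total

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros((5, 5), np.int32),
                                  np.zeros((6, 6), np.int32))

    def test_report_requires_consistent_counts(self):
        with pytest.raises(ValueError):
            SegmentationReport(10, 5, 2, 1)


def test_records_match_regionprops_basics(processed_core):
    for rec in processed_core.records[:10]:
        assert rec.area_px == len(rec.coords)
        assert rec.min_intensity <= rec.median_intensity <= rec.max_intensity
        assert rec.minor_axis_px <= rec.major_axis_px + 1e-9
        assert 0.0 <= rec.eccentricity <= 1.0
        assert 0.0 < rec.extent <= 1.0
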