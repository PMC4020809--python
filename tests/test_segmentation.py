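import numpy as np
import pytest

from conftest import make_spectrogram
from wildscan.pipeline import PipelineConfig, extract_recording
from wildscan.segmentation import (
    SegmentationConfig,
    binarize,
    enhance_image,
    extract_rois,
    filter_masks,
    label_components,
    reconstruct_spectrogram,
    segment,
)


def flood_fill_count(mask, connectivity=8):
    """Independent BFS flood-fill component counter."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols:
                            if mask[nr, nc] and not seen[nr, nc]:
                                seen[nr, nc] = True
                                stack.append((nr, nc))
    return count


class TestEnhance:
    def test_constant_image_maps_to_zero(self):
        spec = make_spectrogram(np.full((20, 30), 0.4))
        assert np.allclose(enhance_image(spec, 4), 0.0)

    def test_single_bright_pixel_survives(self):
        img = np.zeros((8, 8))
        img[3, 4] = 1.0
        out = enhance_image(make_spectrogram(img), 4)
        # opening erases the lone pixel, so subtraction restores it
        assert out[3, 4] == 1.0
        assert np.count_nonzero(out) == 1

    def test_gradient_suppressed_blob_kept(self):
        rows = np.linspace(0.0, 0.6, 64)
        img = np.tile(rows[:, None], (1, 64))
        img[30:33, 20:40] += 0.4  # thin ridge-like blob
        out = enhance_image(make_spectrogram(img), 4)
        gradient_region = out[:20, :]
        assert gradient_region.max() <= 0.1 * 0.6
        assert out[31, 25:35].min() > 0.2

    def test_oversized_selem_rejected(self):
        with pytest.raises(ValueError, match="exceeds image"):
            enhance_image(make_spectrogram(np.zeros((5, 100))), 10)

    def test_blur_variant_also_flattens_gradient(self):
        rows = np.linspace(0.0, 0.6, 64)
        img = np.tile(rows[:, None], (1, 64))
        img[30:33, 20:40] += 0.4
        out = enhance_image(make_spectrogram(img), method="blur")
        assert out[31, 25:35].max() > out[:20, :].max()


class TestBinarize:
    def test_permutation_of_1_to_100_keeps_exactly_10(self, rng):
        img = rng.permutation(np.arange(1.0, 101.0)).reshape(10, 10)
        assert binarize(img, 0.9).sum() == 10

    def test_uniform_pixels_keep_about_one_tenth(self, rng):
        img = rng.uniform(size=1000).reshape(20, 50)
        frac = binarize(img, 0.9).mean()
        assert 0.08 <= frac <= 0.12

    def test_constant_image_all_false(self):
        assert binarize(np.full((5, 5), 3.0), 0.9).sum() == 0

    def test_percentile_bounds_checked(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((3, 3)), 1.5)


class TestLabelComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:4, 1:4] = True
        mask[10:13, 10:13] = True
        comps = label_components(mask)
        assert len(comps) == 2
        assert sorted(int(c.sum()) for c in comps) == [9, 9]

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(label_components(mask, connectivity=8)) == 1
        assert len(label_components(mask, connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_counts_match_flood_fill_oracle(self, connectivity, rng):
        for _ in range(20):
            mask = rng.uniform(size=(50, 50)) < 0.3
            comps = label_components(mask, connectivity)
            assert len(comps) == flood_fill_count(mask, connectivity)
            # mask conservation: component sizes partition the true pixels
            assert sum(int(c.sum()) for c in comps) == int(mask.sum())

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), dtype=bool)) == []

    def test_ordering_by_min_row_then_col(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5:8, 0:2] = True
        mask[0:2, 5:8] = True
        comps = label_components(mask)
        assert comps[0][0, 5]  # top component first
        assert comps[1][5, 0]


class TestFilterMasks:
    def test_size_threshold(self):
        masks = []
        for size in (50, 99, 100, 150):
            m = np.zeros((300, 300), dtype=bool)
            m[100, :size] = True
            masks.append(m)
        assert len(filter_masks(masks, min_pixels=100, border_rows=2)) == 2

    def test_border_touching_dropped(self):
        m = np.zeros((50, 50), dtype=bool)
        m[0:4, 0:50] = True  # 200 pixels touching row 0
        assert filter_masks([m], min_pixels=100, border_rows=2) == []
        assert len(filter_masks([m], min_pixels=100, border_rows=0)) == 1

    def test_empty_input(self):
        assert filter_masks([], 100, 2) == []


class TestExtractRois:
    def test_rectangular_mask_crop_identity(self, rng):
        values = rng.uniform(size=(30, 40))
        spec = make_spectrogram(values)
        mask = np.zeros((30, 40), dtype=bool)
        mask[10:15, 3:10] = True
        (roi,) = extract_rois(spec, [mask])
        assert np.array_equal(roi.patch, values[10:15, 3:10])
        assert (roi.freq_lo, roi.freq_hi) == (10, 15)
        assert roi.n_frames == 7
        assert roi.frames == (3, 10)

    def test_l_shaped_mask_zeroes_non_mask_corner(self):
        values = np.arange(16.0).reshape(4, 4) + 1.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:4, 0] = True
        mask[3, 0:4] = True
        spec = make_spectrogram(values)
        (roi,) = extract_rois(spec, [mask])
        assert roi.patch.shape == (4, 4)
        assert roi.patch[0, 3] == 0.0  # non-mask corner zeroed
        assert roi.patch[3, 3] == values[3, 3]

    def test_unmasked_extraction_keeps_raw_rectangle(self):
        values = np.arange(16.0).reshape(4, 4) + 1.0
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:4, 0] = True
        mask[3, 0:4] = True
        (roi,) = extract_rois(make_spectrogram(values), [mask], masked=False)
        assert np.array_equal(roi.patch, values)


class TestReconstruct:
    def test_no_masks_gives_silence(self):
        spec = make_spectrogram(np.ones((6, 6)))
        assert reconstruct_spectrogram(spec, []).values.sum() == 0.0

    def test_full_mask_is_identity(self, rng):
        spec = make_spectrogram(rng.uniform(size=(10, 12)))
        out = reconstruct_spectrogram(spec, [np.ones((10, 12), dtype=bool)])
        assert np.array_equal(out.values, spec.values)

    def test_elementwise_oracle_and_projection(self, rng):
        spec = make_spectrogram(rng.uniform(size=(20, 20)))
        masks = [rng.uniform(size=(20, 20)) < 0.2 for _ in range(3)]
        union = masks[0] | masks[1] | masks[2]
        out = reconstruct_spectrogram(spec, masks)
        assert np.all(out.values[~union] == 0.0)
        assert np.array_equal(out.values[union], spec.values[union])
        again = reconstruct_spectrogram(out, masks)
        assert np.array_equal(again.values, out.values)


class TestPipelineDeterminismAndRecovery:
    def test_same_spectrogram_same_catalogue(self, tiny_corpus):
        from wildscan.audio import compute_spectrogram, normalize_amplitude

        spec = compute_spectrogram(normalize_amplitude(tiny_corpus.clips[1]))
        _, cat_a = segment(spec)
        _, cat_b = segment(spec)
        assert len(cat_a) == len(cat_b)
        for a, b in zip(cat_a, cat_b):
            assert np.array_equal(a.patch, b.patch)
            assert (a.freq_lo, a.freq_hi) == (b.freq_lo, b.freq_hi)

    def test_min_pixels_invariant(self, tiny_extracted):
        cfg, extracted = tiny_extracted
        for ex in extracted:
            for roi in ex.catalog:
                assert roi.n_pixels >= cfg.segmentation.min_pixels

    def test_single_planted_call_recovered_with_iou(self, one_call_clip):
        clip, sp, (t0, t1) = one_call_clip
        cfg = PipelineConfig()
        ex = extract_recording(clip, cfg)
        hzpp = ex.spec.freq_hz_per_pixel
        spf = ex.spec.sec_per_frame
        truth = (sp.band[0] / hzpp, sp.band[1] / hzpp, t0 / spf, t1 / spf)
        ious = []
        for roi in ex.catalog:
            c0, c1 = roi.frames
            inter_f = max(0.0, min(roi.freq_hi, truth[1]) - max(roi.freq_lo, truth[0]))
            inter_t = max(0.0, min(c1, truth[3]) - max(c0, truth[2]))
            inter = inter_f * inter_t
            area_roi = (roi.freq_hi - roi.freq_lo) * (c1 - c0)
            area_truth = (truth[1] - truth[0]) * (truth[3] - truth[2])
            ious.append(inter / (area_roi + area_truth - inter))
        assert sum(iou >= 0.5 for iou in ious) == 1
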