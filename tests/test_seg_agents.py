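import numpy as np
import pytest
from scipy import ndimage

from cognimage.seg_agents import (IntensityWindow, PreprocessSpec, derive_box,
                                  extract_candidates, external_predict,
                                  preprocess, refine_region, threshold_segment)


class TestThresholdSegment:
    def test_uniform_image_below_window_is_empty(self):
        labels = threshold_segment(np.zeros((4, 4)), IntensityWindow(10, 20))
        assert labels.max() == 0

    def test_printed_grid_two_components(self):
        # 5 in-range pixels forming two 8-connected components of sizes 3 and 2
        grid = np.array([
            [5, 5, 0, 0],
            [0, 5, 0, 0],
            [0, 0, 0, 5],
            [0, 0, 5, 0],
        ], dtype=float)
        labels = threshold_segment(grid, IntensityWindow(1, 9))
        assert labels.max() == 2
        sizes = sorted(np.bincount(labels.ravel())[1:])
        assert sizes == [2, 3]

    def test_matches_per_voxel_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            img = rng.uniform(-100, 100, size=(6, 7, 8))
            lo = float(rng.uniform(-100, 50))
            hi = lo + float(rng.uniform(0, 100))
            area = rng.random(img.shape) < 0.7
            labels = threshold_segment(img, IntensityWindow(lo, hi), area)
            brute = np.zeros(img.shape, dtype=bool)
            for idx in np.ndindex(img.shape):
                brute[idx] = (lo <= img[idx] <= hi) and area[idx]
            assert np.array_equal(labels > 0, brute)

    def test_phantom_window_covers_kidneys_and_stray(self, abdominal):
        labels = threshold_segment(abdominal.image, IntensityWindow(300, 2000))
        fg = labels > 0
        for key in ("kidney_left", "kidney_right", "stray"):
            assert fg[abdominal.masks[key]].mean() > 0.95

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            IntensityWindow(5, 1)


class TestExtractCandidates:
    def test_empty_labels_give_no_candidates(self):
        assert extract_candidates(np.zeros((3, 3), dtype=int)) == []

    def test_min_size_filters_smallest(self):
        labels = np.zeros((10,  10), dtype=int)
        labels[0, 0:5] = 1
        labels[5, 0:3] = 2
        labels[9, 0] = 3
        cands = extract_candidates(labels, min_size=2)
        assert sorted(c.size for c in cands) == [3, 5]

    def test_candidates_partition_the_foreground(self):
        rng = np.random.default_rng(1)
        img = rng.random((12, 12, 12))
        labels = threshold_segment(img, IntensityWindow(0.7, 1.0))
        cands = extract_candidates(labels)
        union = np.zeros(img.shape, dtype=bool)
        total = 0
        for c in cands:
            assert not np.logical_and(union, c.mask).any()   # pairwise disjoint
            union |= c.mask
            total += c.size
        assert np.array_equal(union, labels > 0)
        assert total == int((labels > 0).sum())


class TestRefineRegion:
    def test_solid_square_unchanged_by_fill(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        out = refine_region(mask, [("fill_holes",)], (1.0, 1.0))
        assert np.array_equal(out, mask)

    def test_ring_fills_to_solid_disk(self):
        yy, xx = np.mgrid[:21, :21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        ring = (r2 <= 64) & (r2 >= 25)
        disk = r2 <= 64
        out = refine_region(ring, [("fill_holes",)], (1.0, 1.0))
        assert out.sum() == disk.sum()

    def test_setwise_relations_on_random_masks(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            mask = ndimage.binary_dilation(rng.random((20, 20)) < 0.1)
            opened = refine_region(mask, [("open", 1.0)], (1.0, 1.0))
            closed = refine_region(mask, [("close", 1.0)], (1.0, 1.0))
            filled = refine_region(mask, [("fill_holes",)], (1.0, 1.0))
            assert not np.any(opened & ~mask)        # open shrinks
            assert not np.any(mask & ~closed)        # close grows
            assert not np.any(mask & ~filled)        # fill grows

    def test_closing_reduces_boundary_roughness(self, abdominal):
        rng = np.random.default_rng(3)
        mask = abdominal.masks["kidney_left"] & (rng.random(abdominal.image.shape) < 0.9)
        def roughness(m):
            eroded = ndimage.binary_erosion(m)
            perimeter = (m & ~eroded).sum()
            return perimeter ** 2 / m.sum()
        out = refine_region(mask, [("close", 3.0)], abdominal.spacing)
        assert roughness(out) < roughness(mask)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            refine_region(np.ones((5, 5), dtype=bool), [("close", 100.0)], (1.0, 1.0))


class TestDeriveBox:
    def test_degenerate_offset_yields_single_slice(self):
        box = derive_box((10, 10, 10), (1, 1, 1), (5.0, 5.0, 5.0), 5.0,
                         (0.9, 0.9), (0.0, 0.0), "above")
        zs = np.nonzero(np.any(box, axis=(1, 2)))[0]
        assert list(zs) == [5]
        assert box[5].sum() == 1

    def test_extent_matches_spacing_arithmetic(self):
        spacing = (3.0, 2.0, 2.0)
        shape = (40, 50, 50)
        center = (60.0, 50.0, 50.0)
        box = derive_box(shape, spacing, center, 60.0, (100.0, 100.0),
                         (5.0, 25.0), "above")
        zs = np.nonzero(np.any(box, axis=(1, 2)))[0] * spacing[0]
        assert zs.min() >= 60.0 - 25.0 and zs.max() <= 60.0 - 5.0
        xs = np.nonzero(np.any(box, axis=(0, 1)))[0] * spacing[2]
        assert xs.min() >= 0.0 and xs.max() <= 100.0
        # slab thickness: 20 mm at 3 mm slices -> 6 or 7 slices
        assert len(np.unique(zs)) in (6, 7)

    def test_below_direction_flips_the_slab(self):
        box = derive_box((20, 9, 9), (1, 1, 1), (4.0, 4.0, 4.0), 10.0,
                         (9.0, 9.0), (2.0, 5.0), "below")
        zs = np.nonzero(np.any(box, axis=(1, 2)))[0]
        assert zs.min() == 12 and zs.max() == 15


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess(np.full((4, 4), 7.0), PreprocessSpec())
        assert out.shape == (1, 4, 4)
        assert np.all(out == 0.0)

    def test_centile_clip_matches_percentile_oracle(self):
        grid = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 100.0]])
        out = preprocess(grid, PreprocessSpec(channels=(
            (("centile_clip", 10, 90), ("minmax",)),)))[0]
        lo, hi = np.percentile(grid, [10, 90])
        expected = (np.clip(grid, lo, hi) - lo) / (hi - lo)
        assert np.allclose(out, expected)

    def test_two_channel_spec_runs_in_unit_range(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(16, 16))
        spec = PreprocessSpec(channels=(
            (("bias_field",), ("minmax",)),
            (("centile_clip", 2, 98), ("histeq",)),
        ))
        out = preprocess(img, spec)
        assert out.shape == (2, 16, 16)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_local_histogram_source_raises_in_box_contrast(self):
        # a faint object inside a box, on a bright background: normalizing by
        # the local histogram stretches in-box contrast
        img = np.full((32, 32), 1000.0)
        img[8:24, 8:24] = 100.0
        img[14:18, 14:18] = 150.0
        box = np.zeros_like(img, dtype=bool)
        box[8:24, 8:24] = True
        whole = preprocess(img, PreprocessSpec())[0]
        local = preprocess(img, PreprocessSpec(), source_mask=box)[0]
        contrast = lambda ch: ch[14:18, 14:18].mean() - ch[8:24, 8:24].min()
        assert contrast(local) > contrast(whole)

    def test_too_many_channels_rejected(self):
        with pytest.raises(ValueError):
            PreprocessSpec(channels=((("minmax",),),) * 4)


class TestExternalPredict:
    def test_identity_hook_reproduces_truth_components(self, abdominal):
        truth = abdominal.masks["kidney_left"] | abdominal.masks["kidney_right"]
        labels = external_predict(abdominal.image, lambda img, sp: truth)
        assert labels.max() == 2
        assert np.array_equal(labels > 0, truth)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            external_predict(np.zeros((4, 4)), lambda img, sp: np.zeros((3, 3)))
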