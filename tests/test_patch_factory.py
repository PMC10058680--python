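import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import helaseg as hs
from helaseg.patch_factory import PatchError, pairs_per_slice


class TestGridPositions:
    @pytest.mark.parametrize("length,patch,stride,expected", [
        (2000, 128, 64, 30),    # the ROI slice grid: 30 x 30 windows
        (8192, 128, 64, 127),   # full-frame grid per side
        (128, 128, 64, 1),      # exact fit
    ])
    def test_known_counts(self, length, patch, stride, expected):
        assert len(hs.grid_positions(length, patch, stride)) == expected

    def test_patch_larger_than_length_rejected(self):
        with pytest.raises(PatchError):
            hs.grid_positions(64, 128, 64)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(length=st.integers(8, 300), patch=st.integers(4, 64),
           stride=st.integers(1, 48))
    def test_matches_window_enumeration(self, length, patch, stride):
        """Offsets are exactly the admissible window starts, brute-forced."""
        if patch > length:
            return
        expected = [o for o in range(length) if o + patch <= length
                    and o % stride == 0]
        assert hs.grid_positions(length, patch, stride) == expected


class TestExtractPairs:
    def test_pair_count_formula(self, rng):
        vol = rng.integers(0, 255, (4, 96, 96), dtype=np.uint8)
        lab = rng.integers(0, 4, (4, 96, 96), dtype=np.uint8)
        pairs = hs.extract_pairs(vol, lab, patch=32, overlap=0.5)
        g = len(hs.grid_positions(96, 32, 16))
        assert len(pairs) == 4 * g * g
        assert pairs_per_slice(96, 32, 0.5) == g * g

    def test_single_exact_fit_slice(self, rng):
        vol = rng.integers(0, 255, (1, 128, 128), dtype=np.uint8)
        lab = np.zeros((1, 128, 128), dtype=np.uint8)
        assert len(hs.extract_pairs(vol, lab)) == 1

    def test_labels_copied_verbatim(self, rng):
        vol = rng.integers(0, 255, (2, 64, 64), dtype=np.uint8)
        lab = rng.integers(0, 4, (2, 64, 64), dtype=np.uint8)
        for p in hs.extract_pairs(vol, lab, patch=32, overlap=0.5):
            z, r, c, _ = p.origin
            np.testing.assert_array_equal(p.label, lab[z, r:r + 32, c:c + 32])
            np.testing.assert_array_equal(p.image, vol[z, r:r + 32, c:c + 32])

    def test_slice_range_selects_slices(self, rng):
        vol = rng.integers(0, 255, (10, 32, 32), dtype=np.uint8)
        lab = np.zeros_like(vol)
        pairs = hs.extract_pairs(vol, lab, "1:2:10", patch=32)
        assert {p.origin[0] for p in pairs} == {0, 2, 4, 6, 8}

    def test_out_of_range_slice_errors(self, rng):
        vol = rng.integers(0, 255, (3, 32, 32), dtype=np.uint8)
        with pytest.raises(Exception):
            hs.extract_pairs(vol, np.zeros_like(vol), "1:1:5", patch=32)

    def test_incongruent_volumes_rejected(self, rng):
        vol = rng.integers(0, 255, (2, 32, 32), dtype=np.uint8)
        with pytest.raises(PatchError):
            hs.extract_pairs(vol, np.zeros((2, 16, 16), dtype=np.uint8))


class TestStrategies:
    def test_manual_strategy_counts(self, multi_cell_scene):
        scene = multi_cell_scene
        pairs = hs.build_training_set(
            "s3_multi135k", roi=scene.roi_image, gt_multi=scene.roi_labels,
            slice_range="1:2:16", patch=32)
        side = scene.roi_image.shape[1]
        assert len(pairs) == 8 * pairs_per_slice(side, 32)

    def test_missing_gt_variant_is_configuration_error(self, multi_cell_scene):
        with pytest.raises(PatchError, match="ground truth"):
            hs.build_training_set("s1_single36k", roi=multi_cell_scene.roi_image,
                                  gt_multi=multi_cell_scene.roi_labels)

    def test_auto_strategy_count_and_shortfall(self, multi_cell_scene):
        """Strategy-4 pair count is (pairs per crop) x (detected cells) x
        (frames); a frame with fewer detectable cells contributes less."""
        scene = multi_cell_scene
        frames = [scene.frame_image.data[8]]
        pairs = hs.build_training_set("s4_auto135k", frames=frames,
                                      n_cells=10, crop=96, patch=32)
        per_crop = pairs_per_slice(96, 32)
        n_detected = len({p.origin[3] for p in pairs})
        assert n_detected < 10                       # only 3 cells exist
        assert len(pairs) == per_crop * n_detected

    def test_union_is_concatenation(self, multi_cell_scene):
        scene = multi_cell_scene
        kw = dict(roi=scene.roi_image, gt_multi=scene.roi_labels,
                  frames=[scene.frame_image.data[8]])
        s3 = hs.build_training_set("s3_multi135k", roi=kw["roi"],
                                   gt_multi=kw["gt_multi"],
                                   slice_range="1:2:16", patch=32)
        s4 = hs.build_training_set("s4_auto135k", frames=kw["frames"],
                                   n_cells=3, crop=96, patch=32)
        s5 = hs.build_training_set("s5_union270k", slice_range="1:2:16",
                                   n_cells=3, crop=96, patch=32, **kw)
        assert len(s5) == len(s3) + len(s4)

    def test_full_scale_recipes_match_study_arithmetic(self):
        """At full scale the recipes yield the published pair counts:
        900/slice, 36k for 40 slices, 135k for 150 slices or 10x15 crops,
        270k for the union."""
        per_slice = pairs_per_slice(2000, 128, 0.5)
        assert per_slice == 900
        s1 = hs.STRATEGIES["s1_single36k"]
        assert per_slice * len(hs.parse_slice_range(s1.slice_range)) == 36_000
        s3 = hs.STRATEGIES["s3_multi135k"]
        assert per_slice * len(hs.parse_slice_range(s3.slice_range)) == 135_000
        s4 = hs.STRATEGIES["s4_auto135k"]
        n_frames = len(hs.parse_slice_range(s4.slice_range))
        assert pairs_per_slice(s4.crop, 128, 0.5) * s4.n_cells * n_frames == 135_000
        assert 135_000 + 135_000 == 270_000


def test_save_and_load_pairs_roundtrip(tmp_path, rng):
    vol = rng.integers(0, 255, (1, 64, 64), dtype=np.uint8)
    lab = rng.integers(0, 4, (1, 64, 64), dtype=np.uint8)
    pairs = hs.extract_pairs(vol, lab, patch=32, overlap=0.5)
    manifest = hs.save_pairs(pairs, tmp_path, strategy="s3_multi135k")
    back = hs.load_pairs(manifest)
    assert len(back) == len(pairs)
    for a, b in zip(pairs, back):
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.label, b.label)
        assert a.origin == b.origin
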