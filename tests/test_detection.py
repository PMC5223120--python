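"""Background modelling, segmentation, persistence, blobs, classification."""

import numpy as np
import pytest
from skimage.measure import label as sk_label

from myrmeco.detection import (
    SegmentationParams,
    build_background,
    classify_frame,
    cm_to_px,
    detect_blobs,
    detect_sequence,
    persistence_filter,
    px_to_cm,
    segment_dark,
    segment_difference,
)
from myrmeco.stitching import RawImage
from myrmeco.synthetic import SceneTruth, SeedTruth, render_frame, render_empty_frames


def _frame(arr):
    return RawImage(np.asarray(arr, dtype=np.uint8))


def _const_frames(rgb, n=3, shape=(8, 8)):
    arr = np.zeros(shape + (3,), dtype=np.uint8)
    arr[:] = rgb
    return [_frame(arr) for _ in range(n)]


class TestBuildBackground:
    def test_constant_pixel_is_its_own_mode(self):
        bg = build_background(_const_frames((50, 50, 50), n=15))
        assert tuple(bg.pixels[3, 3]) == (50, 50, 50)
        assert bg.n_frames_used == 15

    def test_majority_triplet_wins(self):
        frames = _const_frames((10, 10, 10), n=10) + _const_frames((200, 0, 0), n=5)
        bg = build_background(frames)
        assert tuple(bg.pixels[0, 0]) == (10, 10, 10)

    def test_tie_broken_lexicographically(self):
        frames = (
            _const_frames((200, 0, 0), n=7)
            + _const_frames((10, 10, 10), n=7)
            + _const_frames((99, 99, 99), n=1)
        )
        bg = build_background(frames)
        assert tuple(bg.pixels[0, 0]) == (10, 10, 10)

    def test_mismatched_dimensions_raise(self):
        frames = _const_frames((1, 2, 3), n=2) + _const_frames((1, 2, 3), shape=(9, 9), n=1)
        with pytest.raises(ValueError, match="dimension"):
            build_background(frames)

    def test_manual_patch_overwrites_region(self):
        bg = build_background(_const_frames((80, 80, 80)), manual_patches=[((0, 2, 0, 2), (5, 6, 7))])
        assert tuple(bg.pixels[1, 1]) == (5, 6, 7)
        assert tuple(bg.pixels[3, 3]) == (80, 80, 80)


class TestSegmentation:
    def setup_method(self):
        self.params = SegmentationParams(diff_threshold=20, dark_threshold=80)
        self.bg = build_background(_const_frames((100, 100, 100)))

    def test_identical_frame_gives_empty_mask(self):
        mask = segment_difference(_const_frames((100, 100, 100))[0], self.bg, self.params)
        assert not mask.any()

    def test_single_differing_pixel(self):
        arr = np.full((8, 8, 3), 100, dtype=np.uint8)
        arr[4, 5] = (130, 100, 100)  # distance 30 > 20
        mask = segment_difference(_frame(arr), self.bg, self.params)
        assert mask.sum() == 1 and mask[4, 5]

    def test_boundary_is_strict(self):
        arr = np.full((8, 8, 3), 100, dtype=np.uint8)
        arr[2, 2] = (120, 100, 100)  # distance exactly 20
        mask = segment_difference(_frame(arr), self.bg, self.params)
        assert not mask.any()

    def test_dark_pass_keeps_only_dark_pixels(self):
        arr = np.full((8, 8, 3), 255, dtype=np.uint8)
        arr[1, 1] = (30, 30, 30)
        frame = _frame(arr)
        all_true = np.ones((8, 8), dtype=bool)
        out = segment_dark(frame, all_true, self.params)
        assert out.sum() == 1 and out[1, 1]

    def test_empty_input_mask_stays_empty(self):
        frame = _const_frames((10, 10, 10))[0]
        out = segment_dark(frame, np.zeros((8, 8), dtype=bool), self.params)
        assert not out.any()


@pytest.mark.parametrize(
    "pattern,expected",
    [((0, 0, 0), 0), ((0, 0, 1), 0), ((0, 1, 0), 0), ((1, 0, 0), 0),
     ((0, 1, 1), 1), ((1, 0, 1), 1), ((1, 1, 0), 1), ((1, 1, 1), 1)],
)
def test_persistence_truth_table(pattern, expected):
    """A pixel survives iff present in at least 2 of 3 consecutive masks."""
    masks = [np.full((2, 2), bool(v)) for v in pattern]
    out = persistence_filter(masks)
    assert out[0, 0] == bool(expected)


def test_persistence_needs_three_masks():
    with pytest.raises(ValueError):
        persistence_filter([np.zeros((2, 2), dtype=bool)] * 2)


class TestDetectBlobs:
    def test_ten_pixel_component(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2, 2:7] = True
        mask[3, 2:7] = True
        blobs = detect_blobs(mask, SegmentationParams())
        assert len(blobs) == 1
        assert blobs[0].size_px == 10
        assert blobs[0].centroid_px == (4.0, 2.5)

    def test_empty_mask_gives_empty_list(self):
        assert detect_blobs(np.zeros((5, 5), dtype=bool), SegmentationParams()) == []

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(detect_blobs(mask, SegmentationParams(connectivity=4))) == 2
        assert len(detect_blobs(mask, SegmentationParams(connectivity=8))) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_independent_labelling_oracle(self, connectivity, rng):
        mask = rng.random((60, 60)) < 0.35
        blobs = detect_blobs(mask, SegmentationParams(connectivity=connectivity))
        oracle = sk_label(mask, connectivity=1 if connectivity == 4 else 2)
        assert len(blobs) == oracle.max()
        assert sum(b.size_px for b in blobs) == int(mask.sum())
        oracle_sizes = sorted(np.bincount(oracle.ravel())[1:])
        assert sorted(b.size_px for b in blobs) == oracle_sizes


class TestClassifyFrame:
    def _run(self, persistent_sizes, moving_sizes):
        h = 40
        persistent = np.zeros((h, h), dtype=bool)
        moving = np.zeros((h, h), dtype=bool)
        row = 2
        for s in persistent_sizes:
            persistent[row, 2 : 2 + s] = True
            row += 3
        for s in moving_sizes:
            moving[row, 2 : 2 + s] = True
            row += 3
        return classify_frame(persistent, moving, SegmentationParams(), 0.677, (20, 20))

    def test_size_ten_persistent_blob_is_seed(self):
        det = self._run([10], [])
        assert len(det.seeds) == 1 and det.seeds[0].label == "seed"

    def test_size_25_persistent_blob_discarded_as_static_ant(self):
        det = self._run([25], [])
        assert not det.seeds
        assert len(det.discarded) == 1

    def test_moving_blob_is_ant_regardless_of_size(self):
        det = self._run([], [30])
        assert len(det.ants) == 1 and det.ants[0].label == "ant"

    def test_no_blob_in_both_classes(self):
        det = self._run([10, 25], [3, 30])
        seed_px = {tuple(p) for b in det.seeds for p in b.pixel_set}
        ant_px = {tuple(p) for b in det.ants for p in b.pixel_set}
        disc_px = {tuple(p) for b in det.discarded for p in b.pixel_set}
        assert not (seed_px & ant_px)
        assert not (seed_px & disc_px)


class TestCoordinates:
    def test_nest_centre_maps_to_origin(self):
        assert px_to_cm((50, 60), 0.677, (50, 60)) == (0.0, 0.0)

    def test_100px_right_of_nest(self):
        x, y = px_to_cm((150, 60), 0.677, (50, 60))
        assert x == pytest.approx(6.77)
        assert y == 0.0

    def test_round_trip(self, rng):
        for _ in range(10):
            p = tuple(rng.uniform(-50, 50, 2))
            back = px_to_cm(cm_to_px(p, 0.677, (30, 40)), 0.677, (30, 40))
            np.testing.assert_allclose(back, p, atol=1e-9)

    def test_zero_resolution_raises(self):
        with pytest.raises(ValueError):
            px_to_cm((0, 0), 0.0, (0, 0))


class TestEndToEnd:
    def _detect_count(self, truth, offset=0.0):
        bg = build_background(render_empty_frames(truth, 5))
        frames = []
        for f in range(3):
            img = render_frame(truth, f)
            if offset:
                shifted = np.clip(img.pixels.astype(float) + offset, 0, 255)
                img = RawImage(shifted.astype(np.uint8), resolution=img.resolution,
                               timestamp=img.timestamp)
            frames.append(img)
        dets = detect_sequence(frames, bg, SegmentationParams(), truth.nest_centre_px)
        return len(dets[0].seeds)

    def _truth(self):
        rng = np.random.default_rng(99)
        seeds = [
            SeedTruth(float(x), float(y), float(w))
            for (x, y), w in zip(rng.uniform(-6, 6, (12, 2)), rng.uniform(1, 2.5, 12))
        ]
        return SceneTruth(seeds=seeds, arena_radius_cm=10.0, noise_sigma=0.0, rng_seed=1)

    def test_noise_free_static_scene_detects_exact_count(self):
        assert self._detect_count(self._truth()) == 12

    @pytest.mark.parametrize("offset", [-20.0, 20.0])
    def test_count_invariant_to_global_luminance_offset(self, offset):
        truth = self._truth()
        base = self._detect_count(truth)
        assert self._detect_count(truth, offset=offset) == base
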