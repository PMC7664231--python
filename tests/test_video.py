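"""Corner detection, Lucas-Kanade ROI tracking, cropping, label files."""

import numpy as np
import pytest

from sheepvitals.synthetic import Occluder, generate_rgb_scene
from sheepvitals.video import (FrameStack, LKConfig, NoTrackableFeaturesError,
                               TrackedROI, crop_stack, detect_corner_features,
                               read_frame_dir, read_label_file, track_roi,
                               write_frame_dir, write_label_file)

from conftest import make_scene


def checker_frame(h=100, w=100, square=(40, 40, 20, 20), lo=64, hi=200):
    frame = np.full((h, w), lo, dtype=np.uint8)
    x, y, sw, sh = square
    frame[y:y + sh, x:x + sw] = hi
    return np.repeat(frame[:, :, None], 3, axis=2)


class TestCornerDetection:
    def test_square_corners_found(self):
        frame = checker_frame()
        pts = detect_corner_features(frame, (30, 30, 40, 40))
        corners = np.array([[40, 40], [60, 40], [40, 60], [60, 60]], float)
        # the 4 strongest features cluster at the square's corners
        for pt in pts[:4]:
            assert np.min(np.linalg.norm(corners - pt, axis=1)) <= 2.0

    def test_uniform_region_has_no_features(self):
        frame = np.full((60, 60, 3), 128, dtype=np.uint8)
        with pytest.raises(NoTrackableFeaturesError, match="no trackable"):
            detect_corner_features(frame, (10, 10, 30, 30))

    def test_features_stay_inside_frame_for_edge_roi(self):
        frame = checker_frame(square=(2, 2, 12, 12))
        pts = detect_corner_features(frame, (0, 0, 30, 30))
        assert (pts[:, 0] >= 0).all() and (pts[:, 1] >= 0).all()
        assert (pts[:, 0] < 100).all() and (pts[:, 1] < 100).all()

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            detect_corner_features(checker_frame(), (80, 80, 40, 40))


class TestTracking:
    def test_static_scene_box_constant(self):
        spec = make_scene(n_frames=30, noise_sd=0, amp_hr=0, amp_rr=0)
        stack, _ = generate_rgb_scene(spec)
        track = track_roi(stack, spec.roi_true)
        assert track.valid.all()
        assert np.allclose(track.boxes, track.boxes[0])

    def test_pure_translation_recovered(self):
        spec = make_scene(width=200, height=48, roi_true=(10, 12, 24, 20),
                          n_frames=150, motion=(1.0, 0.0), noise_sd=0.5,
                          amp_hr=0, amp_rr=0, seed=7)
        stack, truth = generate_rgb_scene(spec)
        track = track_roi(stack, spec.roi_true)
        err = np.abs(track.boxes[:, :2] - truth["roi"][:, :2])
        assert err.max() <= 1.5  # within ~1 px of truth throughout

    def test_drift_bound_on_static_scene(self):
        # drift <= 1 px per 100 frames
        spec = make_scene(n_frames=120, noise_sd=1.0, amp_hr=0, amp_rr=0,
                          seed=9)
        stack, _ = generate_rgb_scene(spec)
        track = track_roi(stack, spec.roi_true)
        drift = np.abs(track.boxes[-1, :2] - track.boxes[0, :2])
        assert drift.max() <= 1.2

    def test_full_occlusion_flags_invalid_and_reacquires(self):
        x, y, w, h = 20, 10, 24, 20
        bar = Occluder(x=16, width=32, frame_start=40, frame_end=70, value=0)
        spec = make_scene(width=80, height=48, roi_true=(x, y, w, h),
                          n_frames=100, noise_sd=0, amp_hr=0, amp_rr=0,
                          occluders=(bar,), seed=5)
        stack, _ = generate_rgb_scene(spec)
        track = track_roi(stack, (x, y, w, h))
        assert not track.valid[45:70].any()      # lost during the bar
        assert track.valid[75:].all()            # re-acquired afterwards
        assert np.abs(track.boxes[90, :2] - np.array([x, y])).max() <= 2.0

    def test_empty_stack_rejected(self):
        stack = FrameStack(frames=np.zeros((0, 10, 10, 3), np.uint8), fps=30)
        with pytest.raises(ValueError):
            track_roi(stack, (1, 1, 4, 4))

    def test_seed_box_outside_frame_rejected(self):
        spec = make_scene(n_frames=3)
        stack, _ = generate_rgb_scene(spec)
        with pytest.raises(ValueError, match="seed box"):
            track_roi(stack, (-5, -5, 20, 16))


class TestCrop:
    def test_static_crop_is_pixel_identical_subarray(self):
        spec = make_scene(n_frames=10, noise_sd=1.0)
        stack, _ = generate_rgb_scene(spec)
        x, y, w, h = spec.roi_true
        track = TrackedROI.static(spec.roi_true, 10)
        crop = crop_stack(stack, track)
        assert (crop.frames == stack.frames[:, y:y + h, x:x + w]).all()

    def test_moving_crop_registers_planted_content(self):
        spec = make_scene(width=120, height=48, roi_true=(10, 12, 24, 20),
                          n_frames=40, motion=(1.0, 0.0), noise_sd=0,
                          amp_hr=0, amp_rr=0)
        stack, truth = generate_rgb_scene(spec)
        track = TrackedROI(boxes=truth["roi"], valid=np.ones(40, bool),
                           source="label-file")
        crop = crop_stack(stack, track)
        assert (crop.frames == crop.frames[0]).all()

    def test_label_file_track_equivalent(self, tmp_path):
        spec = make_scene(n_frames=8)
        stack, _ = generate_rgb_scene(spec)
        track = TrackedROI.static(spec.roi_true, 8)
        path = write_label_file(track, tmp_path / "labels.csv")
        crop_a = crop_stack(stack, track)
        crop_b = crop_stack(stack, read_label_file(path))
        assert (crop_a.frames == crop_b.frames).all()

    def test_mismatched_track_rejected(self):
        spec = make_scene(n_frames=8)
        stack, _ = generate_rgb_scene(spec)
        with pytest.raises(ValueError, match="covers"):
            crop_stack(stack, TrackedROI.static(spec.roi_true, 5))


class TestLabelFiles:
    def test_round_trip(self, tmp_path):
        boxes = np.array([[1, 2, 10, 8], [2, 2, 10, 8], [3, 3, 10, 8]], float)
        track = TrackedROI(boxes=boxes, valid=np.array([1, 0, 1], bool))
        path = write_label_file(track, tmp_path / "t.csv")
        back = read_label_file(path)
        np.testing.assert_allclose(back.boxes, track.boxes)
        assert (back.valid == track.valid).all()
        assert back.source == "label-file"

    def test_gap_error_names_missing_frame(self, tmp_path):
        path = tmp_path / "gap.csv"
        rows = "\n".join(f"{i},0,0,5,5" for i in list(range(10)) + [11])
        path.write_text("frame,x,y,w,h\n" + rows + "\n")
        with pytest.raises(ValueError, match=r"\[10\]"):
            read_label_file(path)

    def test_one_based_header_honoured(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("# index_base: 1\nframe,x,y,w,h\n1,4,5,6,7\n2,4,5,6,7\n")
        track = read_label_file(path)
        assert track.n_frames == 2
        np.testing.assert_allclose(track.boxes[0], [4, 5, 6, 7])


class TestFrameDirIO:
    def test_png_round_trip(self, tmp_path):
        spec = make_scene(n_frames=5)
        stack, _ = generate_rgb_scene(spec)
        write_frame_dir(stack, tmp_path / "s")
        back = read_frame_dir(tmp_path / "s")
        assert (back.frames == stack.frames).all()
        assert back.fps == stack.fps

    def test_missing_frame_gap_error(self, tmp_path):
        spec = make_scene(n_frames=4)
        stack, _ = generate_rgb_scene(spec)
        write_frame_dir(stack, tmp_path / "s")
        (tmp_path / "s" / "frame_000002.png").unlink()
        with pytest.raises(ValueError, match="missing"):
            read_frame_dir(tmp_path / "s")
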