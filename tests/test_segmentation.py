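"""Segmentation, trajectory extraction, tip location, and tube length."""

import numpy as np
import pytest
from skimage.transform import rotate as sk_rotate

from tipkinetics import synthetic as syn
from tipkinetics.exceptions import SegmentationError, TipLocationError, TrajectoryError
from tipkinetics.segmentation import (
    SegmentationConfig,
    extract_trajectory,
    locate_tip,
    segment_frame,
    time_projection,
    tube_length,
)


class TestSegmentFrame:
    def test_noiseless_frame_overlaps_halfmax_support(self, noiseless_stack):
        stack, truth, geom = noiseless_stack
        t = 50
        mask = segment_frame(stack.frames[t], geom.pixel_size)
        gt = syn.support_mask(truth.tip_um[t], truth.sigma_um[t], geom)
        jaccard = (mask & gt).sum() / (mask | gt).sum()
        assert jaccard >= 0.95

    def test_constant_frame_rejected(self):
        with pytest.raises(SegmentationError, match="constant"):
            segment_frame(np.zeros((32, 32)), 0.2)

    def test_binary_blob_is_fixed_point(self):
        blob = np.zeros((40, 40), bool)
        blob[10:30, 12:28] = True
        cfg = SegmentationConfig(smooth_sigma_px=0.0, close_radius_um=0.0)
        mask = segment_frame(blob.astype(float), 0.2, cfg)
        assert np.array_equal(mask, blob)


class TestTimeProjection:
    def test_identical_frames_project_to_themselves(self, noiseless_stack):
        stack, _, _ = noiseless_stack
        from tipkinetics.stack import TimeLapseStack

        two = TimeLapseStack(
            frames=np.stack([stack.frames[0]] * 2), pixel_size=stack.pixel_size, dt=stack.dt
        )
        np.testing.assert_array_equal(time_projection(two), stack.frames[0])

    def test_projection_dominates_every_frame(self, noiseless_stack):
        stack, _, _ = noiseless_stack
        proj = time_projection(stack)
        assert (proj[None] >= stack.frames).all()

    def test_growing_tube_projection_support_is_final_support(self, noiseless_stack):
        stack, _, geom = noiseless_stack
        proj_mask = segment_frame(time_projection(stack), geom.pixel_size)
        final_mask = segment_frame(stack.frames[-1], geom.pixel_size)
        jaccard = (proj_mask & final_mask).sum() / (proj_mask | final_mask).sum()
        assert jaccard >= 0.98


class TestTrajectory:
    def test_straight_tube_centerline_recovered(self, noiseless_stack):
        stack, _, geom = noiseless_stack
        mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(mask, geom.pixel_size, base_hint=(32, 0), extend="both")
        # true centerline is the row through the tube axis
        orth = np.abs(traj.points[:, 0] - geom.base_point()[0])
        assert orth.mean() < 2.0

    def test_one_pixel_line_is_its_own_trajectory(self):
        line = np.zeros((20, 60), bool)
        line[10, 5:55] = True
        traj = extract_trajectory(line, 0.1, extend="none")
        np.testing.assert_allclose(traj.points[:, 0], 10.0, atol=1e-9)
        assert traj.arclength[-1] == pytest.approx((50 - 1) * 0.1)

    def test_cycle_has_no_trajectory(self):
        ring = np.zeros((40, 40), bool)
        rr, cc = np.mgrid[:40, :40]
        d = np.hypot(rr - 20, cc - 20)
        ring[(d > 10) & (d < 14)] = True
        with pytest.raises(TrajectoryError):
            extract_trajectory(ring, 0.1)


class TestLocateTip:
    def test_full_mask_gives_total_arclength(self, noiseless_stack):
        stack, _, geom = noiseless_stack
        mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(mask, geom.pixel_size, base_hint=(32, 0), extend="both")
        assert locate_tip(mask, traj) == pytest.approx(traj.length_um)

    def test_half_mask_gives_half_arclength(self, noiseless_stack):
        stack, _, geom = noiseless_stack
        mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(mask, geom.pixel_size, base_hint=(32, 0), extend="both")
        half = mask.copy()
        half[:, mask.shape[1] // 2 :] = False
        s = locate_tip(half, traj)
        # base is at the left border, so half image ~ half the tube extent
        expected = mask.shape[1] // 2 * geom.pixel_size
        assert s == pytest.approx(expected, abs=3 * geom.pixel_size)

    def test_disjoint_mask_raises(self, noiseless_stack):
        stack, _, geom = noiseless_stack
        mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(mask, geom.pixel_size, base_hint=(32, 0))
        empty = np.zeros_like(mask)
        empty[0, 0] = True
        with pytest.raises(TipLocationError):
            locate_tip(empty, traj)

    def test_tip_tracks_ground_truth_within_three_pixels(self):
        kp = syn.KinematicsParams(w0=0.4, Aw=0.05)
        geom = syn.TubeGeometry(pixel_size=0.25, image_shape=(52, 448))
        truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
        stack = syn.render_stack(truth, geom, seed=3)
        proj_mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(proj_mask, geom.pixel_size, base_hint=(26, 0), extend="both")
        errs = [
            abs(locate_tip(segment_frame(stack.frames[t], geom.pixel_size), traj) - truth.tip_um[t])
            for t in range(0, stack.n_frames, 10)
        ]
        assert max(errs) <= 3 * geom.pixel_size

    def test_tip_monotone_on_noiseless_growth(self, short_noiseless_stack):
        stack, _, geom = short_noiseless_stack
        proj_mask = segment_frame(time_projection(stack), geom.pixel_size)
        traj = extract_trajectory(proj_mask, geom.pixel_size, base_hint=(36, 0), extend="both")
        s = [
            locate_tip(segment_frame(f, geom.pixel_size), traj) for f in stack.frames
        ]
        assert (np.diff(s) >= -1e-9).all()


class TestTubeLength:
    def test_straight_line_length(self):
        line = np.zeros((50, 220), bool)
        line[25, 10:210] = True
        assert tube_length(line, 0.2) == pytest.approx((200 - 1) * 0.2, abs=2 * 0.2)

    def test_empty_mask_raises(self):
        with pytest.raises(TrajectoryError):
            tube_length(np.zeros((20, 20), bool), 0.2)

    def test_rotation_invariance(self, noiseless_stack):
        stack, _, _ = noiseless_stack
        geom = syn.TubeGeometry(image_shape=(160, 560))
        kp = syn.KinematicsParams()
        truth = syn.generate_kinematics(kp, base_length_um=geom.base_length)
        frame = syn.render_stack(truth, geom, seed=0).frames[-1]
        mask = segment_frame(frame, geom.pixel_size)
        L0 = tube_length(mask, geom.pixel_size)
        assert tube_length(np.rot90(mask), geom.pixel_size) == pytest.approx(L0, rel=0.005)
        f30 = sk_rotate(frame, 30, resize=True, preserve_range=True, order=1, cval=frame.min())
        L30 = tube_length(segment_frame(f30, geom.pixel_size), geom.pixel_size)
        assert L30 == pytest.approx(L0, rel=0.03)


class TestPipelineInvariances:
    def test_masks_subset_of_projection_mask(self, short_noiseless_stack):
        stack, _, geom = short_noiseless_stack
        proj_mask = segment_frame(time_projection(stack), geom.pixel_size)
        for t in range(0, stack.n_frames, 15):
            m = segment_frame(stack.frames[t], geom.pixel_size)
            outside = (m & ~proj_mask).sum() / m.sum()
            assert outside < 0.005  # boundary-pixel slack only

    def test_tip_positions_translation_invariant(self, short_noiseless_stack):
        from tipkinetics.pipeline import analyze_stack
        from tipkinetics.stack import TimeLapseStack

        stack, _, geom = short_noiseless_stack
        a = analyze_stack(stack)
        shifted = np.roll(np.roll(stack.frames, 4, axis=1), 6, axis=2)
        b = analyze_stack(TimeLapseStack(frames=shifted, pixel_size=stack.pixel_size, dt=stack.dt))
        rel_a = a.s_tip - a.s_tip[0]
        rel_b = b.s_tip - b.s_tip[0]
        assert np.abs(rel_a - rel_b).max() <= stack.pixel_size
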