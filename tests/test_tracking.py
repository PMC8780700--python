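import numpy as np
import pytest

from headgest import synth, tracking
from headgest.tracking import (
    NoFaceDetectedError,
    LostTargetError,
    ReferencePose,
    TrackerConfig,
    build_target_model,
    detect_reference,
    kalman_track,
    meanshift_step,
    normalize_reference,
    track_video,
)


def _image(w=640, h=480, color=(70, 90, 120)):
    img = np.empty((h, w, 3), np.uint8)
    img[:] = color
    return img


def _patch(img, x, y, w, h, color):
    img[y : y + h, x : x + w] = color
    return img


class TestDetectReference:
    def test_largest_candidate_wins(self):
        rects = [(10, 10, 100, 100), (300, 300, 60, 60)]
        ref = detect_reference(_image(), detector=lambda img: rects)
        assert (ref.x, ref.y, ref.w, ref.h) == (10, 10, 100, 100)

    def test_single_candidate_identity(self):
        ref = detect_reference(_image(), detector=lambda img: [(50, 40, 80, 90)])
        assert (ref.x, ref.y, ref.w, ref.h) == (50, 40, 80, 90)

    def test_no_candidates_raises(self):
        with pytest.raises(NoFaceDetectedError):
            detect_reference(_image(), detector=lambda img: [])

    def test_invalid_image_raises(self):
        with pytest.raises(ValueError):
            detect_reference(np.empty((0, 0, 3)))

    def test_skin_blob_detector_finds_rendered_head(self, clean_session):
        frame = next(iter(synth.render_frames(clean_session)))
        ref = detect_reference(frame)
        # rendered head: 100 px wide ellipse centred at (320, 240)
        assert abs((ref.x + ref.w / 2) - 320) < 5
        assert 90 <= ref.w <= 110


class TestNormalizeReference:
    @pytest.mark.parametrize("w,expected_scale", [(100, 1.0), (50, 2.0)])
    def test_roi_scale_follows_3w_rule(self, w, expected_scale):
        ref = ReferencePose(x=200, y=150, w=w, h=w, frame_size=(640, 480))
        _, ref_roi, tr = normalize_reference(ref, _image(), roi_width=300)
        assert tr.scale == pytest.approx(expected_scale, abs=1e-9)
        assert ref_roi.roi_scale == pytest.approx(expected_scale, abs=1e-9)

    def test_off_centre_face_maps_to_roi_centre(self):
        ref = ReferencePose(x=100, y=50, w=90, h=110, frame_size=(640, 480))
        _, ref_roi, tr = normalize_reference(ref, _image(), roi_width=300)
        mapped = tr.map_points(np.array([ref.center]))[0]
        assert np.allclose(mapped, (150, 150), atol=1.0)

    def test_idempotent_on_normalized_reference(self):
        ref = ReferencePose(x=250, y=180, w=100, h=100, frame_size=(640, 480))
        roi, ref_roi, _ = normalize_reference(ref, _image(), roi_width=300)
        roi2, ref_roi2, tr2 = normalize_reference(ref_roi, roi, roi_width=300)
        assert tr2.scale == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(ref_roi2.center, ref_roi.center, atol=1.0)

    def test_mismatched_frame_raises(self):
        ref = ReferencePose(x=10, y=10, w=50, h=50, frame_size=(100, 100))
        with pytest.raises(ValueError):
            normalize_reference(ref, _image())


class TestTargetModel:
    def test_twenty_percent_shrink(self):
        ref = ReferencePose(x=100, y=90, w=100, h=120, frame_size=(300, 300))
        model = build_target_model(_patch(_image(300, 300), 0, 0, 300, 300, (214, 166, 122)), ref)
        assert model.target_size == (80.0, 96.0)

    def test_search_region_fifty_percent_larger_than_reference(self):
        ref = ReferencePose(x=100, y=90, w=100, h=120, frame_size=(300, 300))
        model = build_target_model(_image(300, 300, (214, 166, 122)), ref)
        assert model.search_size == (150.0, 180.0)

    def test_uniform_patch_single_bin(self):
        ref = ReferencePose(x=100, y=100, w=80, h=80, frame_size=(300, 300))
        model = build_target_model(_image(300, 300, (200, 120, 60)), ref)
        assert model.hist.max() == pytest.approx(1.0)
        assert model.hist.sum() == pytest.approx(1.0)

    def test_degenerate_rectangle_raises(self):
        ref = ReferencePose(x=10, y=10, w=1, h=1, frame_size=(300, 300))
        with pytest.raises(ValueError):
            build_target_model(_image(300, 300), ref, shrink=1.0)


class TestMeanShift:
    def _scene(self, dx=0, dy=0):
        img = _image(300, 300)
        _patch(img, 110 + dx, 110 + dy, 80, 80, (214, 166, 122))
        return img

    def _model(self):
        ref = ReferencePose(x=110, y=110, w=80, h=80, frame_size=(300, 300))
        return build_target_model(self._scene(), ref)

    def test_stationary_target_zero_shift(self):
        pos = meanshift_step(self._scene(), self._model(), (150, 150))
        assert np.hypot(pos[0] - 150, pos[1] - 150) < 1.0

    def test_recovers_known_translation(self):
        # oracle: the true displacement of the rendered square
        pos = meanshift_step(self._scene(dx=7, dy=-4), self._model(), (150, 150))
        assert abs(pos[0] - 157) < 1.0 and abs(pos[1] - 146) < 1.0

    def test_result_stays_inside_search_region(self):
        model = self._model()
        pos = meanshift_step(self._scene(dx=7, dy=-4), model, (150, 150))
        sw, sh = model.search_size
        assert abs(pos[0] - 150) <= sw / 2 and abs(pos[1] - 150) <= sh / 2

    def test_lost_target_on_background_only(self):
        with pytest.raises(LostTargetError):
            meanshift_step(_image(300, 300), self._model(), (150, 150))


class TestKalman:
    def test_stationary_noiseless_velocity_converges_to_zero(self):
        t = np.arange(100) / 30.0
        x, y, vx, vy = kalman_track(t, np.full(100, 5.0), np.full(100, -3.0))
        assert abs(vx[-1]) < 1e-6 and abs(vy[-1]) < 1e-6

    def test_linear_motion_velocity_within_one_percent(self):
        v = 40.0
        t = np.arange(120) / 30.0
        x, y, vx, vy = kalman_track(t, 10 + v * t, np.zeros_like(t))
        assert vx[60:] == pytest.approx(v, rel=0.01)
        assert np.allclose(x[60:], 10 + v * t[60:], rtol=0.01)

    def test_noise_variance_reduced(self, rng):
        t = np.arange(600) / 30.0
        zx = rng.normal(0, 2.0, len(t))
        zy = rng.normal(0, 2.0, len(t))
        x, y, vx, vy = kalman_track(t, zx, zy, sigma_a=50.0, sigma_m=2.0)
        assert np.var(x[50:]) < np.var(zx[50:])

    def test_non_monotone_timestamps_raise(self):
        with pytest.raises(ValueError):
            kalman_track(np.array([0.0, 0.1, 0.1]), np.zeros(3), np.zeros(3))


class TestTrackVideo:
    def test_single_frame_trajectory(self, clean_session):
        frame = next(iter(synth.render_frames(clean_session)))
        traj, ref = track_video([frame], TrackerConfig(frame_rate=30.0))
        assert len(traj) == 1
        assert traj.vx[0] == 0.0 and traj.vy[0] == 0.0

    def test_no_face_raises(self):
        with pytest.raises(NoFaceDetectedError):
            track_video([_image()], TrackerConfig(frame_rate=30.0))

    def test_empty_source_raises(self):
        with pytest.raises(tracking.TrackingError):
            track_video([], TrackerConfig())

    def test_reference_rect_override_skips_detection(self, clean_session):
        frame = next(iter(synth.render_frames(clean_session)))
        cfg = TrackerConfig(frame_rate=30.0, reference_rect=(270, 185, 100, 115))
        traj, ref = track_video([frame, frame, frame], cfg)
        assert len(traj) == 3
        assert ref.w == 100

    def test_short_render_tracks_motion(self, rng):
        # short clip with one reach: tracked displacement follows ground truth
        cfg = synth.SessionConfig(
            n_valid_reaches=1, reach_amplitude=60.0, duration=7.0, noise_sigma=0.0, seed=3
        )
        session = synth.gen_session(cfg)
        traj, _ = track_video(synth.render_frames(session), TrackerConfig(frame_rate=30.0))
        first = next(iter(synth.render_frames(session)))
        _, _, tr = normalize_reference(detect_reference(first), first)
        true_roi = tr.map_points(np.column_stack([session.true.x + 320, session.true.y + 240]))
        dx = (traj.x - traj.x[0]) - (true_roi[:, 0] - true_roi[0, 0])
        dy = (traj.y - traj.y[0]) - (true_roi[:, 1] - true_roi[0, 1])
        assert np.sqrt(np.mean(dx**2 + dy**2)) < 2.0
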