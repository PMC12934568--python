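import numpy as np
import pytest

from tractdistill.autograd import Tensor
from tractdistill.fod import FODField, single_fiber_coefficients
from tractdistill.geometry import ScalarVolume, VoxelGrid
from tractdistill.models import StudentModel, TeacherModel
from tractdistill.phantom import BundleSpec, make_phantom
from tractdistill.tracking import (
    TrackingParams,
    sign_align,
    track_deterministic,
    track_with_model,
)


def _uniform_field(grid, direction):
    c = single_fiber_coefficients(direction, 4)
    coeffs = np.tile(c, grid.shape + (1,))
    return FODField(grid, 4, coeffs)


def _full_mask(grid):
    return ScalarVolume(grid, np.ones(grid.shape))


def _slab_mask(grid):
    """Thin slab through the grid center: few seeds, long x-extent."""
    m = np.zeros(grid.shape)
    cy = grid.shape[1] // 2
    m[:, cy : cy + 2, cy : cy + 2] = 1.0
    return ScalarVolume(grid, m)


class TestTrackingParams:
    def test_validation(self, small_grid):
        mask = _full_mask(small_grid)
        with pytest.raises(ValueError):
            TrackingParams(mask=mask, step_mm=0.0)
        with pytest.raises(ValueError):
            TrackingParams(mask=mask, max_angle_deg=95.0)
        with pytest.raises(ValueError):
            TrackingParams(mask=mask, min_length_mm=300.0, max_length_mm=200.0)


class TestSignAlign:
    def test_parallel_unchanged(self):
        d = np.array([0.0, 0, 1])
        assert np.allclose(sign_align(d, d), d)

    def test_antiparallel_flipped(self):
        d = np.array([0.0, 0, 1])
        assert np.allclose(sign_align(-d, d), d)

    def test_never_negative_dot(self, rng):
        c = rng.normal(size=(1000, 3))
        p = rng.normal(size=(1000, 3))
        out = sign_align(c, p)
        assert np.all(np.sum(out * p, axis=1) >= 0)


class TestTrackDeterministic:
    def test_uniform_field_gives_straight_streamlines(self, small_grid):
        field = _uniform_field(small_grid, [1.0, 0, 0])
        params = TrackingParams(mask=_slab_mask(small_grid), seed=1)
        tg = track_deterministic(field, params)
        assert len(tg) > 0
        for s in tg.streamlines:
            assert np.ptp(s[:, 1]) < params.step_mm
            assert np.ptp(s[:, 2]) < params.step_mm
            assert np.ptp(s[:, 0]) > 20.0  # spans most of the 30 mm extent

    def test_empty_mask_rejected(self, small_grid):
        field = _uniform_field(small_grid, [1.0, 0, 0])
        mask = ScalarVolume(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError, match="empty"):
            track_deterministic(field, TrackingParams(mask=mask))

    def test_grid_mismatch_rejected(self, small_grid):
        field = _uniform_field(small_grid, [1.0, 0, 0])
        other = VoxelGrid.isotropic((8, 8, 8), 2.0)
        with pytest.raises(ValueError, match="grid"):
            track_deterministic(field, TrackingParams(mask=_full_mask(other)))

    def test_no_peak_no_streamline(self, small_grid):
        field = FODField(small_grid, 4, np.zeros(small_grid.shape + (15,)))
        params = TrackingParams(mask=_slab_mask(small_grid), min_length_mm=1.0, seed=0)
        assert len(track_deterministic(field, params)) == 0

    def test_curvature_stop_on_tight_arc(self, small_grid):
        # arc radius 4 mm at step 2 mm turns ~29 deg/step; a 10 deg limit
        # must stop tracking well before the arc is covered
        spec = BundleSpec.arc(
            center=(15.0, 15.0, 15.0), arc_radius_mm=7.0, normal=(0, 0, 1),
            angle_start=0.0, angle_end=np.pi, radius_mm=2.0,
            n_streamlines=10, bundle_id=1,
        )
        ds = make_phantom([spec], small_grid, noise_sd=0.0, seed=3)
        loose = TrackingParams(mask=ds.wm_mask, step_mm=2.0, max_angle_deg=45.0,
                               min_length_mm=4.0, seed=1)
        tight = TrackingParams(mask=ds.wm_mask, step_mm=2.0, max_angle_deg=10.0,
                               min_length_mm=4.0, seed=1)
        long_tg = track_deterministic(ds.fod_field, loose)
        short_tg = track_deterministic(ds.fod_field, tight)
        mean_len = lambda tg: np.mean(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in tg.streamlines]
        )
        assert mean_len(short_tg) < mean_len(long_tg)

    def test_emitted_constraints_hold(self, straight_phantom):
        params = TrackingParams(mask=straight_phantom.wm_mask, seed=5,
                                min_length_mm=10.0, max_length_mm=40.0)
        tg = track_deterministic(straight_phantom.fod_field, params)
        assert len(tg) > 0
        cos_lim = np.cos(np.radians(params.max_angle_deg)) - 1e-9
        for s in tg.streamlines:
            seg = np.diff(s, axis=0)
            length = np.linalg.norm(seg, axis=1).sum()
            assert params.min_length_mm <= length <= params.max_length_mm + params.step_mm
            d = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            assert np.all(np.sum(d[1:] * d[:-1], axis=1) >= cos_lim)

    def test_determinism(self, straight_phantom):
        params = TrackingParams(mask=straight_phantom.wm_mask, seed=5)
        a = track_deterministic(straight_phantom.fod_field, params)
        b = track_deterministic(straight_phantom.fod_field, params)
        assert len(a) == len(b)
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa, sb)


class _ConstantDirectionTeacher(TeacherModel):
    """Stub emitting theta=pi/2, phi=0 (the +x axis) at every step."""

    def forward(self, x, state):
        b = x.data.shape[0]
        if state is None:
            state = self.zero_state(b)
        theta = Tensor(np.full((b, 1), np.pi / 2))
        phi = Tensor(np.zeros((b, 1)))
        return theta, phi, Tensor(np.ones((b, self.feature_width))), state


class TestTrackWithModel:
    def test_constant_direction_stub_tracks_straight(self, small_grid):
        model = _ConstantDirectionTeacher(15)
        field = _uniform_field(small_grid, [1.0, 0, 0])
        params = TrackingParams(mask=_full_mask(small_grid), seed=2)
        tg = track_with_model(model, field, params)
        assert len(tg) > 0
        for s in tg.streamlines:
            assert np.ptp(s[:, 1]) < 1e-6
            assert np.ptp(s[:, 2]) < 1e-6
            assert np.ptp(s[:, 0]) > 20.0

    def test_model_input_mismatch(self, small_grid):
        model = _ConstantDirectionTeacher(15)
        with pytest.raises(TypeError, match="FODField"):
            track_with_model(
                model, _full_mask(small_grid),
                TrackingParams(mask=_full_mask(small_grid)),
            )

    def test_student_needs_flair_and_context(self, small_grid):
        student = StudentModel(4, (6, 5))
        field = _uniform_field(small_grid, [1.0, 0, 0])
        with pytest.raises(TypeError, match="student"):
            track_with_model(student, field, TrackingParams(mask=_full_mask(small_grid)))

    def test_constraints_and_determinism(self, small_grid):
        model = _ConstantDirectionTeacher(15)
        field = _uniform_field(small_grid, [1.0, 0, 0])
        params = TrackingParams(mask=_full_mask(small_grid), seed=3,
                                max_length_mm=20.0, min_length_mm=5.0)
        a = track_with_model(model, field, params)
        b = track_with_model(model, field, params)
        assert len(a) == len(b) > 0
        for sa, sb in zip(a.streamlines, b.streamlines):
            assert np.array_equal(sa, sb)
            length = np.linalg.norm(np.diff(sa, axis=0), axis=1).sum()
            assert params.min_length_mm <= length <= params.max_length_mm + params.step_mm
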