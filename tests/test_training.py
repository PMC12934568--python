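import numpy as np
import pytest

from tractdistill.fod import n_coefficients
from tractdistill.geometry import Tractogram, VoxelGrid
from tractdistill.models import StudentModel, TeacherModel, build_student_from_teacher
from tractdistill.tracking import TrackingParams, track_deterministic
from tractdistill.training import (
    TrainConfig,
    TrainingSequence,
    resample_streamline,
    streamlines_to_sequences,
    train_student,
    train_teacher,
)


@pytest.fixture(scope="module")
def reference(straight_phantom):
    params = TrackingParams(mask=straight_phantom.wm_mask, seed=2)
    tg = track_deterministic(straight_phantom.fod_field, params)
    assert len(tg) > 10
    return tg


class TestResampling:
    def test_straight_line_labels(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        tg = Tractogram([pts], VoxelGrid.isotropic((4, 4, 4), 2.0))
        seqs = streamlines_to_sequences(tg, 1.0)
        assert len(seqs) == 1
        assert np.allclose(seqs[0].labels, [[1, 0, 0], [1, 0, 0]])

    def test_label_count_is_points_minus_one(self, rng):
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(30, 3)), axis=0)
        rs = resample_streamline(pts, 1.0)
        seq = TrainingSequence(rs, np.diff(rs, axis=0) / np.linalg.norm(np.diff(rs, axis=0), axis=1, keepdims=True))
        assert len(seq.labels) == len(seq.points) - 1

    def test_quarter_circle_length_preserved(self):
        t = np.linspace(0, np.pi / 2, 500)
        pts = np.stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)], axis=1)
        rs = resample_streamline(pts, 1.0)
        total = np.linalg.norm(np.diff(rs, axis=0), axis=1).sum()
        assert total == pytest.approx(5 * np.pi, rel=0.02)

    def test_uniform_spacing_except_final_segment(self):
        t = np.linspace(0, np.pi / 2, 500)
        pts = np.stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)], axis=1)
        rs = resample_streamline(pts, 1.0)
        spacing = np.linalg.norm(np.diff(rs, axis=0), axis=1)
        assert np.allclose(spacing[:-1], 1.0, atol=1e-4)

    def test_short_streamlines_skipped(self, small_grid):
        short = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        ok = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        tg = Tractogram([short, ok], small_grid)
        assert len(streamlines_to_sequences(tg, 1.0)) == 1

    def test_canonical_orientation_merges_reversed_copies(self, small_grid):
        pts = np.array([[0.0, 0, 0], [3.0, 0.5, 0], [6.0, 0, 0]])
        tg = Tractogram([pts, pts[::-1].copy()], small_grid)
        seqs = streamlines_to_sequences(tg, 1.0)
        assert np.allclose(seqs[0].points, seqs[1].points)


class TestTrainConfig:
    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_bad_lr_and_optimizer(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=1, learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=1, optimizer_name="sgd")


class TestTrainTeacher:
    def test_loss_decreases_and_bounded(self, straight_phantom, reference):
        teacher = TeacherModel(n_coefficients(4), seed=0)
        cfg = TrainConfig(epochs=25, seed=3, max_streamlines=24, batch_streamlines=8)
        _, records = train_teacher(teacher, straight_phantom.fod_field, reference, cfg)
        losses = [r.loss for r in records]
        assert all(0.0 <= l <= 2.0 for l in losses)
        assert losses[-1] < losses[0]
        assert all(np.isfinite(l) for l in losses)

    def test_seeded_runs_reproduce_history(self, straight_phantom, reference):
        histories = []
        for _ in range(2):
            teacher = TeacherModel(n_coefficients(4), seed=0)
            cfg = TrainConfig(epochs=5, seed=3, max_streamlines=16, batch_streamlines=8)
            _, records = train_teacher(teacher, straight_phantom.fod_field, reference, cfg)
            histories.append([r.loss for r in records])
        assert np.allclose(histories[0], histories[1], atol=1e-6)

    def test_empty_reference_rejected(self, straight_phantom):
        empty = Tractogram([], straight_phantom.grid)
        with pytest.raises(ValueError, match="empty"):
            train_teacher(
                TeacherModel(n_coefficients(4)), straight_phantom.fod_field, empty,
                TrainConfig(epochs=1),
            )


class TestTrainStudent:
    def _train(self, phantom, reference, epochs=10):
        teacher = TeacherModel(n_coefficients(4), seed=0)
        tcfg = TrainConfig(epochs=10, seed=3, max_streamlines=16, batch_streamlines=8)
        teacher, _ = train_teacher(teacher, phantom.fod_field, reference, tcfg)
        student = build_student_from_teacher(
            teacher,
            {"in_channels": 1 + phantom.context.n_channels, "channels": (6, 6)},
            seed=5,
        )
        frozen_before = {
            k: p.data.copy()
            for k, p in student.named_parameters().items()
            if student.frozen_mask[k]
        }
        trainable_before = {
            k: p.data.copy()
            for k, p in student.named_parameters().items()
            if not student.frozen_mask[k]
        }
        scfg = TrainConfig(epochs=epochs, seed=4, max_streamlines=16, batch_streamlines=8)
        student, records = train_student(
            student, teacher, phantom.fod_field, phantom.flair, phantom.context,
            reference, scfg,
        )
        return student, records, frozen_before, trainable_before

    def test_frozen_weights_conserved_trainables_move(self, straight_phantom, reference):
        student, records, frozen_before, trainable_before = self._train(
            straight_phantom, reference
        )
        params = student.named_parameters()
        for k, v in frozen_before.items():
            assert np.array_equal(params[k].data, v), f"frozen {k} changed"
        assert any(
            not np.array_equal(params[k].data, v) for k, v in trainable_before.items()
        )
        losses = [r.loss for r in records]
        assert all(0.0 <= l <= 4.0 for l in losses)
        assert losses[-1] < losses[0]
        assert all(r.alignment is not None and r.alignment >= 0 for r in records)

    def test_student_not_from_teacher_rejected(self, straight_phantom, reference):
        teacher = TeacherModel(n_coefficients(4), seed=0)
        other = TeacherModel(n_coefficients(4), seed=99)
        student = build_student_from_teacher(
            other, {"in_channels": 1 + straight_phantom.context.n_channels, "channels": (6, 6)},
            seed=5,
        )
        with pytest.raises(ValueError, match="frozen"):
            train_student(
                student, teacher, straight_phantom.fod_field, straight_phantom.flair,
                straight_phantom.context, reference, TrainConfig(epochs=1),
            )

    def test_unfrozen_student_rejected(self, straight_phantom, reference):
        teacher = TeacherModel(n_coefficients(4), seed=0)
        fresh = StudentModel(1 + straight_phantom.context.n_channels, (6, 6))
        with pytest.raises(ValueError, match="frozen"):
            train_student(
                fresh, teacher, straight_phantom.fod_field, straight_phantom.flair,
                straight_phantom.context, reference, TrainConfig(epochs=1),
            )

    def test_zero_encoder_triggers_zero_norm_guard(self, straight_phantom, reference):
        teacher = TeacherModel(n_coefficients(4), seed=0)
        student = build_student_from_teacher(
            teacher,
            {"in_channels": 1 + straight_phantom.context.n_channels, "channels": (6, 6)},
            seed=5,
        )
        for name, p in student.named_parameters().items():
            if name.startswith(("conv_encoder", "input_mlp")):
                p.data = np.zeros_like(p.data)
        with pytest.raises(ValueError, match="zero-norm"):
            train_student(
                student, teacher, straight_phantom.fod_field, straight_phantom.flair,
                straight_phantom.context, reference, TrainConfig(epochs=1),
            )
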