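"""Supervised sequence extraction and the two distillation training stages.

Stage 1 trains the teacher to predict, at every resampled streamline point,
the unit direction to the next point from the trilinearly sampled FOD
coefficients, under the cosine direction loss.  Stage 2 builds the student
from the teacher (frozen GRU hidden layer + output MLP), runs the teacher
in inference mode to provide target feature representations f_T, and
optimizes the combined direction + feature-alignment loss over the
student's trainable parameters only.

Sequences are canonically oriented (deterministic rule on the end-to-end
displacement) rather than duplicated in both directions: with inputs that
depend only on position, the two orientations of one streamline present
identical input sequences with opposite labels, which makes the
direction-regression problem ill-posed; a consistent orientation removes
the degeneracy, and tracking stays orientation-free through bidirectional
propagation with per-step sign alignment.

Resampling walks the polyline at uniform arc-length steps; the terminal
partial segment is kept when longer than half a step so total length is
preserved, and only that final segment may deviate from the configured
spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, no_grad
from .fod import FODField, fod_sample
from .geometry import ScalarVolume, Tractogram
from .models import StudentModel, TeacherModel
from .nn import DTYPE, Adam

__all__ = [
    "TrainingSequence",
    "TrainConfig",
    "LossRecord",
    "resample_streamline",
    "streamlines_to_sequences",
    "train_teacher",
    "train_student",
    "loss_history_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainingSequence:
    """Resampled points plus unit direction labels (one fewer than points)."""

    points: np.ndarray  # (N, 3) world mm
    labels: np.ndarray  # (N-1, 3) unit vectors

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.points) - 1:
            raise ValueError("label count must be point count - 1")
        norms = np.linalg.norm(self.labels, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("labels must be unit norm within 1e-6")


@dataclass
class TrainConfig:
    epochs: int
    learning_rate: float = 1e-3
    batch_streamlines: int = 16
    seed: int = 0
    step_mm: float = 1.0
    optimizer_name: str = "adam"
    val_fraction: float = 0.2
    max_streamlines: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer_name != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class LossRecord:
    """Per-epoch mean training loss (with component breakdown for stage 2)."""

    epoch: int
    loss: float
    direction: float | None = None
    alignment: float | None = None
    val_loss: float | None = None


def loss_history_frame(records: list[LossRecord]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in records])


def resample_streamline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Uniform arc-length resampling along the polyline at ``step_mm``.

    The endpoint is appended when the trailing remainder exceeds half a
    step, preserving total length at the cost of one non-uniform final
    segment.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.arange(0.0, total + 1e-12, step_mm)
    if total - t[-1] > 0.5 * step_mm:
        t = np.append(t, total)
    out = np.empty((len(t), 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, pts[:, d])
    return out


def _canonical_orientation(points: np.ndarray) -> np.ndarray:
    """Orient a streamline by a deterministic rule: the dominant component
    of the end-to-end displacement must be positive."""
    disp = points[-1] - points[0]
    if np.linalg.norm(disp) < 1e-9:
        disp = points[len(points) // 2] - points[0]
    k = int(np.argmax(np.abs(disp)))
    return points[::-1].copy() if disp[k] < 0 else points


def streamlines_to_sequences(
    tractogram: Tractogram, step_mm: float
) -> list[TrainingSequence]:
    """Arc-length resample every streamline and derive direction labels.

    Streamlines shorter than ``2 * step_mm`` are skipped (logged count).
    """
    out: list[TrainingSequence] = []
    skipped = 0
    for pts in tractogram.streamlines:
        if np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() < 2.0 * step_mm:
            skipped += 1
            continue
        rs = resample_streamline(_canonical_orientation(pts), step_mm)
        diffs = np.diff(rs, axis=0)
        labels = diffs / np.linalg.norm(diffs, axis=1, keepdims=True)
        out.append(TrainingSequence(rs, labels))
    if skipped:
        logger.info("streamlines_to_sequences: skipped %d short streamlines", skipped)
    return out


# ---------------------------------------------------------------------------
# batching helpers


def _pack_sequences(seqs: list[TrainingSequence]):
    """Pad to (S, T, .) arrays: query points (points[:-1]), labels, mask."""
    S = len(seqs)
    T = max(len(s.labels) for s in seqs)
    pts = np.zeros((S, T, 3))
    labels = np.zeros((S, T, 3), dtype=DTYPE)
    mask = np.zeros((S, T), dtype=DTYPE)
    for i, s in enumerate(seqs):
        n = len(s.labels)
        pts[i, :n] = s.points[:-1]
        labels[i, :n] = s.labels
        mask[i, :n] = 1.0
    return pts, labels, mask


def _split_indices(n: int, val_fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    if n - n_val < 1:
        n_val = 0
    return perm[n_val:], perm[:n_val]


def _direction_dot(theta: Tensor, phi: Tensor, labels_t: np.ndarray) -> Tensor:
    """<pred unit direction, label> built from spherical-angle tensors."""
    lx, ly, lz = labels_t[:, 0:1], labels_t[:, 1:2], labels_t[:, 2:3]
    st = theta.sin()
    return st * phi.cos() * lx + st * phi.sin() * ly + theta.cos() * lz


def _teacher_epoch_loss(model, x, labels, mask) -> Tensor:
    """Masked mean cosine direction loss over a padded batch (autograd)."""
    B, T, _ = x.shape
    state = model.zero_state(B)
    acc = None
    for t in range(T):
        theta, phi, _, state = model.forward(Tensor(x[:, t]), state)
        dot = _direction_dot(theta, phi, labels[:, t])
        li = ((1.0 - dot) * mask[:, t : t + 1]).sum()
        acc = li if acc is None else acc + li
    return acc * (1.0 / mask.sum())


def train_teacher(
    teacher: TeacherModel,
    field: FODField,
    reference: Tractogram,
    config: TrainConfig,
) -> tuple[TeacherModel, list[LossRecord]]:
    """Stage 1: fit the teacher to reference streamline propagation.

    Hidden state is carried along each sequence and reset between
    streamlines; per-epoch mean losses (train, and validation when the
    split is non-empty) are recorded.  Deterministic given ``config.seed``
    up to floating-point reduction order.
    """
    if len(reference) == 0:
        raise ValueError("empty reference tractogram")
    seqs = streamlines_to_sequences(reference, config.step_mm)
    if not seqs:
        raise ValueError("no usable training sequences (all too short)")
    rng = np.random.default_rng(config.seed)
    if config.max_streamlines is not None and len(seqs) > config.max_streamlines:
        keep = rng.choice(len(seqs), size=config.max_streamlines, replace=False)
        seqs = [seqs[i] for i in sorted(keep)]

    pts, labels, mask = _pack_sequences(seqs)
    inputs = np.stack(
        [
            fod_sample(field, p, out_of_field="error").astype(DTYPE)
            for p in pts
        ]
    )
    train_idx, val_idx = _split_indices(len(seqs), config.val_fraction, rng)
    opt = Adam(teacher.trainable_parameters(), lr=config.learning_rate)
    records: list[LossRecord] = []

    for epoch in range(1, config.epochs + 1):
        order = train_idx[rng.permutation(len(train_idx))]
        tot = wsum = 0.0
        for lo in range(0, len(order), config.batch_streamlines):
            b = order[lo : lo + config.batch_streamlines]
            loss = _teacher_epoch_loss(teacher, inputs[b], labels[b], mask[b])
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = float(mask[b].sum())
            tot += loss.item() * w
            wsum += w
        val = None
        if len(val_idx):
            with no_grad():
                val = _teacher_epoch_loss(
                    teacher, inputs[val_idx], labels[val_idx], mask[val_idx]
                ).item()
        records.append(LossRecord(epoch, tot / wsum, val_loss=val))
    return teacher, records


def _teacher_features(teacher, inputs, mask) -> np.ndarray:
    """f_T per sequence point, teacher in inference mode: (S, T, F)."""
    S, T, _ = inputs.shape
    out = np.zeros((S, T, teacher.feature_width), dtype=DTYPE)
    with no_grad():
        state = teacher.zero_state(S)
        for t in range(T):
            _, _, f, state = teacher.forward(Tensor(inputs[:, t]), state)
            out[:, t] = f.data
    return out


def _corner_weights(grid, pts: np.ndarray):
    """Flat voxel row indices + trilinear weights of each point's 8 corners."""
    idx = grid.world_to_voxel(pts.reshape(-1, 3))
    if not np.all(grid.contains_index(idx)):
        raise ValueError("sequence point outside the grid")
    shape = np.asarray(grid.shape)
    base = np.clip(np.floor(idx).astype(int), 0, shape - 2)
    frac = idx - base
    corners = np.empty((len(idx), 8), dtype=np.int64)
    weights = np.empty((len(idx), 8), dtype=DTYPE)
    for c in range(8):
        off = np.array([(c >> 2) & 1, (c >> 1) & 1, c & 1])
        cc = base + off
        corners[:, c] = (cc[:, 0] * shape[1] + cc[:, 1]) * shape[2] + cc[:, 2]
        weights[:, c] = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
    lead = pts.shape[:-1]
    return corners.reshape(lead + (8,)), weights.reshape(lead + (8,))


def _student_epoch_loss(student, feat_table, corners, weights, f_t, labels, mask):
    """Masked mean of Eq.-2-style loss (direction + feature alignment)."""
    B, T, _ = labels.shape
    state = student.zero_state(B)
    dir_acc = align_acc = None
    for t in range(T):
        xt = feat_table.weighted_gather(corners[:, t], weights[:, t])
        theta, phi, f_s, state = student.forward(xt, state)
        m = mask[:, t : t + 1]
        dot = _direction_dot(theta, phi, labels[:, t])
        dl = ((1.0 - dot) * m).sum()

        ns = (f_s * f_s).sum(axis=1, keepdims=True).sqrt()
        if np.any((ns.data < 1e-12) & (m > 0)):
            raise ValueError("zero-norm student feature vector: alignment undefined")
        ft = f_t[:, t]
        nt = np.linalg.norm(ft, axis=1, keepdims=True)
        if np.any((nt < 1e-12) & (m > 0)):
            raise ValueError("zero-norm teacher feature vector: alignment undefined")
        cos = (f_s * ft).sum(axis=1, keepdims=True) / (ns * nt.astype(DTYPE))
        al = ((1.0 - cos) * m).sum()
        dir_acc = dl if dir_acc is None else dir_acc + dl
        align_acc = al if align_acc is None else align_acc + al
    inv = 1.0 / mask.sum()
    return dir_acc * inv, align_acc * inv


def train_student(
    student: StudentModel,
    teacher: TeacherModel,
    field: FODField,
    flair: ScalarVolume,
    context: ScalarVolume,
    reference: Tractogram,
    config: TrainConfig,
) -> tuple[StudentModel, list[LossRecord]]:
    """Stage 2: distill the frozen teacher into the FLAIR/context student.

    The teacher supplies target features f_T in inference mode; only the
    student's trainable parameters (encoder, input MLP, GRU input layer)
    are optimized; its frozen parameters stay bit-identical.
    """
    if len(reference) == 0:
        raise ValueError("empty reference tractogram")
    if flair.grid != field.grid or context.grid != field.grid:
        raise ValueError("flair/context/FOD grids must match")
    frozen = [k for k, v in student.frozen_mask.items() if v]
    if not frozen:
        raise ValueError("student has no frozen parameters; build it from a teacher")
    sp = student.named_parameters()
    tp = teacher.named_parameters()
    for k in frozen:
        if k not in tp or not np.array_equal(sp[k].data, tp[k].data):
            raise ValueError("student frozen weights do not match this teacher")

    seqs = streamlines_to_sequences(reference, config.step_mm)
    if not seqs:
        raise ValueError("no usable training sequences (all too short)")
    rng = np.random.default_rng(config.seed)
    if config.max_streamlines is not None and len(seqs) > config.max_streamlines:
        keep = rng.choice(len(seqs), size=config.max_streamlines, replace=False)
        seqs = [seqs[i] for i in sorted(keep)]

    pts, labels, mask = _pack_sequences(seqs)
    fod_inputs = np.stack(
        [fod_sample(field, p, out_of_field="error").astype(DTYPE) for p in pts]
    )
    f_t = _teacher_features(teacher, fod_inputs, mask)
    volume = np.concatenate([flair.values[..., None], context.values], axis=3)
    if volume.shape[3] != student.encoder_in_channels:
        raise ValueError(
            f"student encoder expects {student.encoder_in_channels} channels, "
            f"flair+context provide {volume.shape[3]}"
        )
    corners, weights = _corner_weights(field.grid, pts)

    train_idx, val_idx = _split_indices(len(seqs), config.val_fraction, rng)
    opt = Adam(student.trainable_parameters(), lr=config.learning_rate)
    records: list[LossRecord] = []

    for epoch in range(1, config.epochs + 1):
        order = train_idx[rng.permutation(len(train_idx))]
        tot_d = tot_a = wsum = 0.0
        for lo in range(0, len(order), config.batch_streamlines):
            b = order[lo : lo + config.batch_streamlines]
            feat_table = student.encode(volume)
            dl, al = _student_epoch_loss(
                student, feat_table, corners[b], weights[b], f_t[b], labels[b], mask[b]
            )
            loss = dl + al
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = float(mask[b].sum())
            tot_d += dl.item() * w
            tot_a += al.item() * w
            wsum += w
        val = None
        if len(val_idx):
            with no_grad():
                feat_table = student.encode(volume)
                dl, al = _student_epoch_loss(
                    student, feat_table, corners[val_idx], weights[val_idx],
                    f_t[val_idx], labels[val_idx], mask[val_idx],
                )
                val = dl.item() + al.item()
        records.append(
            LossRecord(
                epoch,
                (tot_d + tot_a) / wsum,
                direction=tot_d / wsum,
                alignment=tot_a / wsum,
                val_loss=val,
            )
        )
    return student, records
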