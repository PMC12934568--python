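"""Teacher and student propagation networks and their losses.

The teacher maps a trilinearly sampled FOD coefficient vector through an
input MLP (its output is the feature representation f_T entering the GRU
input layer), two stacked GRU layers modeling streamline dynamics, and an
output MLP regressing the next propagation direction as spherical angles
(theta squashed to [0, pi] by a sigmoid, phi wrapped into (-pi, pi) by a
tanh), so the converted direction is always unit norm.

The student replaces the FOD pathway with a 3-D convolutional encoder over
a FLAIR + anatomical-context channel stack, a fresh input MLP, and a fresh
GRU input layer; the GRU *hidden* layer and the output MLP are copied
bit-exactly from a trained teacher and frozen ("model stitching": the
trainable GRU input layer learns to map structural features into the
representation the frozen teacher layers expect).

Losses: the direction loss is one minus the cosine between predicted and
label directions (range [0, 2]); the student loss adds the same cosine
penalty between the student and teacher feature representations at the GRU
input layer (range [0, 4]).
"""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor, no_grad
from .nn import DTYPE, Conv3dEncoder, GRUCell, MLP, Module

__all__ = [
    "TeacherModel",
    "StudentModel",
    "cosine_direction_loss",
    "student_loss",
    "teacher_forward",
    "student_forward",
    "build_student_from_teacher",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


def _cosine(a: np.ndarray, b: np.ndarray, name: str) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError(f"zero-norm {name}: cosine undefined")
    return np.sum(a * b, axis=-1) / (na * nb)


def cosine_direction_loss(d_pred, d_label) -> float | np.ndarray:
    """``1 - <d_pred, d_label> / (|d_pred| |d_label|)``.

    Range [0, 2]; invariant to positive rescaling of either argument.
    Raises on zero-norm input.
    """
    a = np.asarray(d_pred, dtype=float)
    b = np.asarray(d_label, dtype=float)
    out = 1.0 - _cosine(a, b, "direction")
    return float(out) if out.ndim == 0 else out


def student_loss(d_pred, d_label, f_s, f_t) -> float | np.ndarray:
    """Direction loss plus feature-alignment loss, range [0, 4]."""
    align = 1.0 - _cosine(
        np.asarray(f_t, dtype=float), np.asarray(f_s, dtype=float), "feature vector"
    )
    out = cosine_direction_loss(d_pred, d_label) + align
    return float(out) if np.ndim(out) == 0 else out


class _PropagationCore(Module):
    """Input MLP -> GRU input layer -> GRU hidden layer -> output MLP."""

    def __init__(self, n_in: int, feature_width: int, hidden_width: int,
                 rng: np.random.Generator):
        self.input_mlp = MLP([n_in, 64, 64, feature_width], rng)
        self.gru_input = GRUCell(feature_width, hidden_width, rng)
        self.gru_hidden = GRUCell(hidden_width, hidden_width, rng)
        self.output_mlp = MLP([hidden_width, 64, 2], rng)
        self.n_in = n_in
        self.feature_width = feature_width
        self.hidden_width = hidden_width

    def zero_state(self, batch: int) -> tuple[Tensor, Tensor]:
        return self.gru_input.zero_state(batch), self.gru_hidden.zero_state(batch)

    def forward(self, x: Tensor, state: tuple[Tensor, Tensor] | None):
        """Returns (theta, phi, f, new_state); theta/phi are (B, 1)."""
        if x.data.ndim != 2 or x.data.shape[1] != self.n_in:
            raise ValueError(f"expected input width {self.n_in}, got {x.data.shape}")
        if state is None:
            state = self.zero_state(x.data.shape[0])
        f = self.input_mlp(x)
        h1 = self.gru_input(f, state[0])
        h2 = self.gru_hidden(h1, state[1])
        raw = self.output_mlp(h2)
        theta = raw.slice_cols(0, 1).sigmoid() * np.pi
        phi = raw.slice_cols(1, 2).tanh() * np.pi
        return theta, phi, f, (h1, h2)


class TeacherModel(_PropagationCore):
    """Stage-1 network: FOD coefficients -> next streamline direction."""

    def __init__(self, n_coefficients: int = 15, feature_width: int = 64,
                 hidden_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        super().__init__(n_coefficients, feature_width, hidden_width, rng)
        self.seed = int(seed)

    @property
    def config(self) -> dict:
        return {
            "n_coefficients": self.n_in,
            "feature_width": self.feature_width,
            "hidden_width": self.hidden_width,
            "seed": self.seed,
        }


class StudentModel(_PropagationCore):
    """Stage-2 network: FLAIR + context encoder feeding frozen teacher layers.

    Do not construct directly for distillation -- use
    :func:`build_student_from_teacher`, which copies and freezes the
    teacher's GRU hidden layer and output MLP.
    """

    def __init__(self, encoder_in_channels: int, encoder_channels: tuple[int, ...] = (16, 32, 8),
                 feature_width: int = 64, hidden_width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.conv_encoder = Conv3dEncoder(encoder_in_channels, encoder_channels, rng)
        super().__init__(encoder_channels[-1], feature_width, hidden_width, rng)
        self.seed = int(seed)
        self.encoder_in_channels = int(encoder_in_channels)
        self.encoder_channels = tuple(encoder_channels)

    @property
    def config(self) -> dict:
        return {
            "encoder_in_channels": self.encoder_in_channels,
            "encoder_channels": list(self.encoder_channels),
            "feature_width": self.feature_width,
            "hidden_width": self.hidden_width,
            "seed": self.seed,
        }

    @property
    def frozen_mask(self) -> dict[str, bool]:
        """True for every parameter frozen at construction from the teacher."""
        return {k: not p.requires_grad for k, p in self.named_parameters().items()}

    def encode(self, volume: np.ndarray) -> Tensor:
        """Feature table (n_voxels, C) of the FLAIR+context volume."""
        return self.conv_encoder(volume)


def build_student_from_teacher(
    teacher: TeacherModel,
    encoder_config: dict,
    seed: int = 0,
) -> StudentModel:
    """Construct a student whose GRU hidden layer and output MLP are the
    teacher's, copied bit-exactly and frozen.

    ``encoder_config`` needs ``in_channels`` and optionally ``channels``
    (conv channel widths, last entry = encoder output width).
    """
    channels = tuple(encoder_config.get("channels", (16, 32, 8)))
    student = StudentModel(
        encoder_in_channels=int(encoder_config["in_channels"]),
        encoder_channels=channels,
        feature_width=teacher.feature_width,
        hidden_width=teacher.hidden_width,
        seed=seed,
    )
    for mod in ("gru_hidden", "output_mlp"):
        src = getattr(teacher, mod).named_parameters()
        dst = getattr(student, mod).named_parameters()
        if set(src) != set(dst):
            raise ValueError("teacher/student width incompatibility")
        for k in src:
            if src[k].data.shape != dst[k].data.shape:
                raise ValueError(f"teacher/student width incompatibility at {mod}.{k}")
            dst[k].data = src[k].data.copy()
            dst[k].requires_grad = False
    return student


def _forward_numpy(model: _PropagationCore, x: np.ndarray, hidden):
    x = np.asarray(x, dtype=DTYPE)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if hidden is not None:
        hidden = tuple(Tensor(np.atleast_2d(np.asarray(h, dtype=DTYPE))) for h in hidden)
    with no_grad():
        theta, phi, f, state = model.forward(Tensor(xb), hidden)
    th, ph = theta.data[:, 0], phi.data[:, 0]
    fv = f.data
    st = tuple(s.data for s in state)
    if single:
        return (float(th[0]), float(ph[0])), fv[0], tuple(s[0] for s in st)
    return (th, ph), fv, st


def teacher_forward(model: TeacherModel, fod_coeffs, hidden=None):
    """Single inference step: ((theta, phi), f_T, new_hidden).

    ``hidden=None`` means the zero initial state.  Deterministic given
    parameters and inputs.
    """
    return _forward_numpy(model, fod_coeffs, hidden)


def student_forward(model: StudentModel, encoder_features, hidden=None):
    """Single inference step on pre-sampled encoder features:
    ((theta, phi), f_S, new_hidden)."""
    return _forward_numpy(model, encoder_features, hidden)


def save_checkpoint(model: TeacherModel | StudentModel, path) -> None:
    """Serialize parameters + config + frozen mask (npz, versioned)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": type(model).__name__,
        "config": model.config,
        "frozen": [k for k, p in model.named_parameters().items() if not p.requires_grad],
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TeacherModel | StudentModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg = meta["config"]
    if meta["kind"] == "TeacherModel":
        model: TeacherModel | StudentModel = TeacherModel(**cfg)
    elif meta["kind"] == "StudentModel":
        cfg = dict(cfg)
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        model = StudentModel(**cfg)
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']}")
    model.load_state_dict(state)
    for k in meta["frozen"]:
        model.named_parameters()[k].requires_grad = False
    return model
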