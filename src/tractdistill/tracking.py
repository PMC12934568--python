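"""Streamline tracking: deterministic FOD-peak reference and model-based.

Both trackers share seeding (jittered positions inside mask voxels),
bidirectional propagation (second branch from the negated first direction,
fresh recurrent state per branch), the per-step curvature stop, the mask /
out-of-field stop, a shared length budget across the two branches, and the
minimum-length filter.

The reference tracker follows, at each step, the FOD peak nearest the
incoming direction (deterministic "SD-stream"-style propagation).  The
model tracker replaces the peak with a recurrent network's predicted
spherical angles; the first step direction comes from the model itself at
the seed with zero hidden state, so the interface never requires FOD
access (the student has none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad
from .fod import DirectionSet, FODField, default_direction_set, fod_peak, fod_sample
from .geometry import (
    ScalarVolume,
    Tractogram,
    VoxelGrid,
    sample_trilinear,
    spherical_to_unit,
)
from .models import StudentModel, TeacherModel
from .nn import DTYPE

__all__ = ["TrackingParams", "track_deterministic", "track_with_model", "sign_align"]


@dataclass
class TrackingParams:
    """Tracker configuration.

    step_mm: propagation step (default half the 2 mm working voxel).
    max_angle_deg: per-step curvature limit.  min_amplitude: FOD peak
    threshold (reference tracker only).  min/max_length_mm: emitted
    streamline length bounds (max is a budget shared by the two branches).
    seeds_per_voxel: jittered seeds per mask voxel.  seed: RNG seed for the
    jitter.
    """

    mask: ScalarVolume
    step_mm: float = 1.0
    max_angle_deg: float = 30.0
    min_amplitude: float = 0.1
    min_length_mm: float = 10.0
    max_length_mm: float = 200.0
    seeds_per_voxel: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")
        if not 0.0 < self.max_angle_deg < 90.0:
            raise ValueError("max_angle_deg must be in (0, 90)")
        if self.min_length_mm >= self.max_length_mm:
            raise ValueError("min_length_mm must be < max_length_mm")
        if self.seeds_per_voxel < 1:
            raise ValueError("seeds_per_voxel must be >= 1")

    def to_dict(self) -> dict:
        return {
            "step_mm": self.step_mm,
            "max_angle_deg": self.max_angle_deg,
            "min_amplitude": self.min_amplitude,
            "min_length_mm": self.min_length_mm,
            "max_length_mm": self.max_length_mm,
            "seeds_per_voxel": self.seeds_per_voxel,
            "seed": self.seed,
        }


def sign_align(candidate: np.ndarray, previous: np.ndarray) -> np.ndarray:
    """Flip ``candidate`` (rows) so its dot product with ``previous`` is >= 0.

    Directions regressed as spherical angles are orientation-ambiguous
    along a streamline; alignment with the motion direction resolves the
    sign.
    """
    c = np.asarray(candidate, dtype=float)
    p = np.asarray(previous, dtype=float)
    dots = np.sum(c * p, axis=-1, keepdims=True)
    return np.where(dots < 0, -c, c)


def _seed_points(params: TrackingParams) -> np.ndarray:
    grid = params.mask.grid
    vox = np.argwhere(params.mask.values > 0.5)
    if len(vox) == 0:
        raise ValueError("empty tracking mask")
    rng = np.random.default_rng(params.seed)
    reps = np.repeat(vox, params.seeds_per_voxel, axis=0)
    jitter = rng.uniform(-0.5, 0.5, size=reps.shape)
    return grid.voxel_to_world(reps + jitter)


def _in_mask(mask: ScalarVolume, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask lookup; out-of-grid counts as outside."""
    idx = np.round(mask.grid.world_to_voxel(np.atleast_2d(points))).astype(int)
    shape = np.asarray(mask.grid.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(idx), dtype=bool)
    safe = np.clip(idx, 0, shape - 1)
    vals = mask.values[safe[:, 0], safe[:, 1], safe[:, 2]] > 0.5
    out[ok] = vals[ok]
    return out


def track_deterministic(field: FODField, params: TrackingParams) -> Tractogram:
    """Deterministic FOD-peak tractography.

    From each jittered seed the initial direction is the global FOD peak;
    each branch then repeatedly samples the FOD at the current point, takes
    the peak nearest the incoming direction, checks the curvature limit,
    and advances ``step_mm``.  A branch stops on mask exit / out-of-field,
    missing peak, curvature violation, or exhausting the shared length
    budget.  Streamlines shorter than ``min_length_mm`` are discarded.
    """
    grid = field.grid
    if params.mask.grid != grid:
        raise ValueError("mask grid does not match FOD grid")
    dirset = default_direction_set()
    cos_limit = np.cos(np.radians(params.max_angle_deg))
    seeds = _seed_points(params)

    def branch(p0: np.ndarray, d0: np.ndarray, budget: float) -> list[np.ndarray]:
        pts: list[np.ndarray] = []
        p, d, length = p0, d0, 0.0
        while length + params.step_mm <= budget + 1e-9:
            coeffs = fod_sample(field, p)
            if np.any(np.isnan(coeffs)):
                break
            peak = fod_peak(
                coeffs, d, dirset, params.min_amplitude, sh_order=field.sh_order
            )
            if peak is None:
                break
            if float(peak @ d) < cos_limit:
                break
            p_new = p + params.step_mm * peak
            if not _in_mask(params.mask, p_new)[0]:
                break
            pts.append(p_new)
            length += params.step_mm
            p, d = p_new, peak
        return pts

    streamlines: list[np.ndarray] = []
    for seed_pt in seeds:
        coeffs = fod_sample(field, seed_pt)
        if np.any(np.isnan(coeffs)):
            continue
        d0 = fod_peak(coeffs, None, dirset, params.min_amplitude, sh_order=field.sh_order)
        if d0 is None:
            continue
        fwd = branch(seed_pt, d0, params.max_length_mm)
        used = params.step_mm * len(fwd)
        bwd = branch(seed_pt, -d0, params.max_length_mm - used)
        pts = bwd[::-1] + [seed_pt] + fwd
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        if np.linalg.norm(np.diff(arr, axis=0), axis=1).sum() >= params.min_length_mm:
            streamlines.append(arr)
    return Tractogram(streamlines, grid)


def _model_sampler(model, inputs, grid: VoxelGrid):
    """Returns fn(points)->(N, C) input features, NaN rows when out of field."""
    if isinstance(model, StudentModel):
        if isinstance(inputs, (tuple, list)):
            flair, context = inputs
            if flair.grid != grid or context.grid != grid:
                raise ValueError("flair/context grids do not match the tracking grid")
            stack = np.concatenate([flair.values[..., None], context.values], axis=3)
        elif isinstance(inputs, ScalarVolume):
            if inputs.grid != grid:
                raise ValueError("input grid does not match the tracking grid")
            stack = inputs.values
        else:
            raise TypeError("student tracking needs (flair, context) volumes")
        if stack.shape[3] != model.encoder_in_channels:
            raise ValueError(
                f"student encoder expects {model.encoder_in_channels} channels, "
                f"got {stack.shape[3]}"
            )
        with no_grad():
            table = model.encode(stack).data
        feat_vol = ScalarVolume(grid, table.reshape(grid.shape + (table.shape[1],)))
        return lambda pts: sample_trilinear(feat_vol, pts)
    if isinstance(model, TeacherModel):
        if not isinstance(inputs, FODField):
            raise TypeError("teacher tracking needs a FODField input")
        if inputs.grid != grid:
            raise ValueError("FOD grid does not match the tracking grid")
        return lambda pts: fod_sample(inputs, pts)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def track_with_model(
    model: TeacherModel | StudentModel,
    inputs,
    params: TrackingParams,
) -> Tractogram:
    """Recurrent streamline propagation with a trained network.

    Seeding, bidirectional branches, curvature/length stopping and the
    length filter mirror :func:`track_deterministic`; the propagation
    direction is the model's predicted (theta, phi) converted to a unit
    vector and sign-aligned with the previous step.  All seeds propagate in
    lockstep (batched inference).
    """
    grid = params.mask.grid
    sampler = _model_sampler(model, inputs, grid)
    seeds = _seed_points(params)
    n = len(seeds)
    cos_limit = np.cos(np.radians(params.max_angle_deg))
    max_steps = int(np.ceil(params.max_length_mm / params.step_mm))

    def propagate(prev0: np.ndarray | None, budgets: np.ndarray):
        """One branch for all seeds at once; returns per-seed point lists
        and (for the first branch) the raw first directions."""
        paths: list[list[np.ndarray]] = [[] for _ in range(n)]
        active = np.ones(n, dtype=bool)
        h = model.zero_state(n)
        p = seeds.copy()
        lengths = np.zeros(n)
        prev = None if prev0 is None else prev0.copy()
        first_dirs = np.zeros((n, 3))
        for step_i in range(max_steps):
            x = sampler(p)
            bad = np.any(np.isnan(x), axis=1)
            active &= ~bad
            if not np.any(active):
                break
            x = np.where(np.isnan(x), 0.0, x).astype(DTYPE)
            with no_grad():
                theta, phi, _, h = model.forward(Tensor(x), h)
            d = spherical_to_unit(theta.data[:, 0], phi.data[:, 0])
            if prev is not None:
                d = sign_align(d, prev)
                turn_ok = np.sum(d * prev, axis=1) >= cos_limit
                active &= turn_ok
            if step_i == 0:
                first_dirs = d.copy()
            p_new = p + params.step_mm * d
            active &= _in_mask(params.mask, p_new)
            active &= lengths + params.step_mm <= budgets + 1e-9
            for i in np.flatnonzero(active):
                paths[i].append(p_new[i])
            lengths[active] += params.step_mm
            p = np.where(active[:, None], p_new, p)
            prev = d if prev is None else np.where(active[:, None], d, prev)
        return paths, first_dirs, lengths

    fwd_paths, first_dirs, fwd_lengths = propagate(None, np.full(n, params.max_length_mm))
    bwd_paths, _, _ = propagate(-first_dirs, params.max_length_mm - fwd_lengths)

    streamlines: list[np.ndarray] = []
    for i in range(n):
        pts = bwd_paths[i][::-1] + [seeds[i]] + fwd_paths[i]
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        if np.linalg.norm(np.diff(arr, axis=0), axis=1).sum() >= params.min_length_mm:
            streamlines.append(arr)
    return Tractogram(streamlines, grid)
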