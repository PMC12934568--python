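"""Shared coordinate, direction, and volume types.

All streamline points live in world millimeters; voxel indices follow the
NIfTI convention where the integer index (i, j, k) refers to the voxel
*center* and the affine maps index -> world. Conversion between the two
frames happens only at sampling time, so volumes with different resolutions
can share one world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "Tractogram",
    "OutOfFieldError",
    "validate_streamline",
    "streamline_length",
    "sample_trilinear",
    "spherical_to_unit",
    "unit_to_spherical",
]


class OutOfFieldError(ValueError):
    """A sample point fell outside the interpolation domain of a grid."""


@dataclass(frozen=True)
class VoxelGrid:
    """Image geometry: array shape plus voxel-index -> world-mm affine.

    Parameters
    ----------
    shape : triple of int
        Number of voxels along each axis; every entry >= 1.
    affine : (4, 4) array
        Homogeneous voxel-index -> world transform. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine rotation/zoom block is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "_inv_affine", np.linalg.inv(affine))

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_mm: float = 2.0) -> "VoxelGrid":
        """Axis-aligned grid with isotropic spacing and zero world origin."""
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to continuous voxel indices (inverse affine)."""
        points = np.asarray(points, dtype=float)
        inv = self._inv_affine
        return points @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=float)
        return indices @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        """True where a continuous index lies in the interpolation domain.

        The domain is [0, n-1] per axis: the region where a full 8-corner
        neighborhood (or its degenerate boundary form) exists.
        """
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        hi = np.asarray(self.shape, dtype=float) - 1.0
        return np.all((idx >= 0.0) & (idx <= hi), axis=-1)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, VoxelGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )


@dataclass
class ScalarVolume:
    """One or more channels of real values on a :class:`VoxelGrid`.

    ``values`` has shape ``grid.shape`` (single channel) or
    ``grid.shape + (C,)``.
    """

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape[:3] != self.grid.shape or self.values.ndim not in (3, 4):
            raise ValueError(
                f"value shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 3 else self.values.shape[3]


def validate_streamline(points: np.ndarray) -> np.ndarray:
    """Check streamline invariants; returns the points as a float array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("a streamline needs >= 2 world-mm 3-vectors")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline has non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ValueError("consecutive streamline points must be distinct")
    return pts


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length in mm."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class Tractogram:
    """A collection of streamlines with their reference grid.

    ``bundle_ids`` optionally labels each streamline with an integer bundle
    id (phantom ground truth or seed-region assignment).
    """

    streamlines: list[np.ndarray]
    grid: VoxelGrid
    bundle_ids: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.streamlines = [validate_streamline(s) for s in self.streamlines]
        if self.bundle_ids is not None:
            self.bundle_ids = np.asarray(self.bundle_ids, dtype=int)
            if self.bundle_ids.shape != (len(self.streamlines),):
                raise ValueError("bundle_ids must have one entry per streamline")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices: np.ndarray) -> "Tractogram":
        indices = np.asarray(indices)
        ids = None if self.bundle_ids is None else self.bundle_ids[indices]
        return Tractogram([self.streamlines[i] for i in indices], self.grid, ids)


def sample_trilinear(
    volume: ScalarVolume,
    points_world: np.ndarray,
    *,
    out_of_field: str = "nan",
) -> np.ndarray:
    """Trilinearly interpolate a volume at world-mm points.

    Returns an array of shape ``(n_points,)`` for single-channel volumes or
    ``(n_points, C)``; a single point gives a 0-d / ``(C,)`` result.

    Out-of-field points (continuous index outside ``[0, n-1]`` on any axis)
    are handled per ``out_of_field``: ``"nan"`` returns the NaN sentinel so
    callers such as the trackers can treat it as a stop condition, while
    ``"error"`` raises :class:`OutOfFieldError` (training-time contract).
    """
    pts = np.asarray(points_world, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx = volume.grid.world_to_voxel(pts)
    inside = volume.grid.contains_index(idx)
    if not np.all(inside):
        if out_of_field == "error":
            bad = pts[~inside][0]
            raise OutOfFieldError(f"point {bad} outside grid {volume.grid.shape}")
        if out_of_field != "nan":
            raise ValueError(f"unknown out_of_field mode {out_of_field!r}")

    vals = volume.values
    multi = vals.ndim == 4
    shape = np.asarray(volume.grid.shape)
    safe = np.where(inside[:, None], idx, 0.0)
    base = np.minimum(np.floor(safe).astype(int), shape - 2)
    base = np.maximum(base, 0)
    frac = safe - base

    out_shape = (len(pts), vals.shape[3]) if multi else (len(pts),)
    out = np.zeros(out_shape, dtype=float)
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        c = base + off
        v = vals[c[:, 0], c[:, 1], c[:, 2]]
        out += w[:, None] * v if multi else w * v
    out[~inside] = np.nan
    return out[0] if single else out


def spherical_to_unit(theta, phi) -> np.ndarray:
    """Unit vector(s) from polar angle theta (from +z) and azimuth phi.

    ``(sin t cos p, sin t sin p, cos t)``; broadcasts over array inputs with
    the vector axis last.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(phi))):
        raise ValueError("theta/phi must be finite")
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def unit_to_spherical(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`spherical_to_unit` for unit vectors.

    theta in [0, pi]; phi in (-pi, pi], normalized to 0 at the poles so the
    round-trip is deterministic despite the azimuth degeneracy there.
    """
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    if not np.all(np.abs(n - 1.0) < 1e-6):
        raise ValueError("unit_to_spherical expects unit vectors (|norm-1| < 1e-6)")
    theta = np.arccos(np.clip(v[..., 2] / n, -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    at_pole = np.minimum(theta, np.pi - theta) < 1e-12
    phi = np.where(at_pole, 0.0, phi)
    # arctan2 returns -pi for direction (-1, -0, 0); fold onto (-pi, pi]
    phi = np.where(phi <= -np.pi, np.pi, phi)
    return theta, phi
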