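"""Fiber orientation distributions as even-order real spherical harmonics.

Basis convention (fixed so saved FOD volumes are interoperable and
deterministic): coefficients are ordered over even degrees l = 0, 2, ..., L
and, within each degree, orders m = -l, ..., l.  With ``Y_l^m`` the complex
spherical harmonic including the Condon-Shortley phase (scipy's
``sph_harm_y``), the real basis function for index (l, m) is::

    m < 0 :  sqrt(2) * Re(Y_l^{|m|})
    m = 0 :  Y_l^0            (real)
    m > 0 :  sqrt(2) * Im(Y_l^{m})

the "descoteaux"-style ordering used by common diffusion tools.  Only even
degrees appear, so every expansion is antipodally symmetric:
amplitude(d) == amplitude(-d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .geometry import ScalarVolume, VoxelGrid, sample_trilinear, unit_to_spherical

__all__ = [
    "n_coefficients",
    "sh_basis",
    "sh_evaluate",
    "DirectionSet",
    "FODField",
    "fod_sample",
    "fod_peak",
    "single_fiber_coefficients",
]


def n_coefficients(sh_order: int) -> int:
    """Number of even-degree real SH coefficients up to degree ``sh_order``."""
    if sh_order < 0 or sh_order % 2:
        raise ValueError("sh_order must be a non-negative even integer")
    return (sh_order + 1) * (sh_order + 2) // 2


def sh_basis(sh_order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real symmetric SH basis.

    Parameters
    ----------
    sh_order : even int
    directions : (N, 3) unit vectors

    Returns
    -------
    (N, n_coefficients) array with columns in (l, m) order as documented in
    the module docstring.
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    theta, phi = unit_to_spherical(dirs / np.linalg.norm(dirs, axis=-1, keepdims=True))
    cols = []
    for l in range(0, sh_order + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                cols.append(np.sqrt(2.0) * y.real)
            elif m == 0:
                cols.append(y.real)
            else:
                cols.append(np.sqrt(2.0) * y.imag)
    return np.stack(cols, axis=-1)


def sh_evaluate(coefficients: np.ndarray, direction: np.ndarray, sh_order: int) -> float | np.ndarray:
    """Amplitude sum_j c_j Y_j(theta, phi) of an SH expansion at direction(s)."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape[-1] != n_coefficients(sh_order):
        raise ValueError(
            f"expected {n_coefficients(sh_order)} coefficients for order {sh_order}, "
            f"got {coefficients.shape[-1]}"
        )
    basis = sh_basis(sh_order, direction)
    amp = basis @ coefficients if coefficients.ndim == 1 else np.einsum(
        "nj,nj->n", basis, coefficients
    )
    return float(amp[0]) if np.ndim(direction) == 1 and amp.size == 1 else amp


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly-uniform unit vectors on the upper hemisphere (z > 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z * z)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass
class DirectionSet:
    """Antipodally symmetric evaluation set for discrete peak search.

    Built as ``n // 2`` Fibonacci-spiral points on the upper hemisphere plus
    their antipodes.  ``angular_spacing_rad`` estimates the mean spacing
    ``sqrt(4 pi / n)``; neighbor lists (6 nearest) support local-maximum
    detection.
    """

    directions: np.ndarray
    neighbors: np.ndarray
    angular_spacing_rad: float

    @classmethod
    def make(cls, n: int = 724) -> "DirectionSet":
        if n < 100:
            raise ValueError("peak search needs a direction set of >= 100 points")
        half = _fibonacci_hemisphere(n // 2)
        dirs = np.concatenate([half, -half], axis=0)
        tree = cKDTree(dirs)
        _, nb = tree.query(dirs, k=7)
        return cls(dirs, nb[:, 1:], float(np.sqrt(4.0 * np.pi / len(dirs))))

    def __post_init__(self) -> None:
        self._basis_cache: dict[int, np.ndarray] = {}
        self._pinv_cache: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.directions)

    def basis(self, sh_order: int) -> np.ndarray:
        if sh_order not in self._basis_cache:
            self._basis_cache[sh_order] = sh_basis(sh_order, self.directions)
        return self._basis_cache[sh_order]

    def basis_pinv(self, sh_order: int) -> np.ndarray:
        if sh_order not in self._pinv_cache:
            self._pinv_cache[sh_order] = np.linalg.pinv(self.basis(sh_order))
        return self._pinv_cache[sh_order]


_DEFAULT_DIRSET: DirectionSet | None = None


def default_direction_set() -> DirectionSet:
    global _DEFAULT_DIRSET
    if _DEFAULT_DIRSET is None:
        _DEFAULT_DIRSET = DirectionSet.make(724)
    return _DEFAULT_DIRSET


@dataclass
class FODField:
    """Per-voxel even-order SH coefficient vectors on a grid."""

    grid: VoxelGrid
    sh_order: int
    coefficients: np.ndarray  # shape grid.shape + (n_coefficients,)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = self.grid.shape + (n_coefficients(self.sh_order),)
        if self.coefficients.shape != expected:
            raise ValueError(
                f"coefficient array shape {self.coefficients.shape} != {expected} "
                f"for sh_order {self.sh_order}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("FOD coefficients contain non-finite values")

    def as_volume(self) -> ScalarVolume:
        return ScalarVolume(self.grid, self.coefficients)


def fod_sample(
    field: FODField, points_world: np.ndarray, *, out_of_field: str = "nan"
) -> np.ndarray:
    """Channel-wise trilinear interpolation of SH coefficients.

    By linearity, interpolating coefficients then evaluating an amplitude
    equals interpolating the per-corner amplitudes.
    """
    return sample_trilinear(field.as_volume(), points_world, out_of_field=out_of_field)


def _cap_directions(center: np.ndarray, radius_rad: float, n: int = 24) -> np.ndarray:
    """Deterministic spiral of directions in a spherical cap around center."""
    i = np.arange(1, n + 1)
    ang = radius_rad * np.sqrt(i / n)
    azi = i * np.pi * (3.0 - np.sqrt(5.0))
    # orthonormal frame around the cap axis
    a = np.array([1.0, 0.0, 0.0]) if abs(center[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(center, a)
    u /= np.linalg.norm(u)
    v = np.cross(center, u)
    d = (
        np.cos(ang)[:, None] * center
        + np.sin(ang)[:, None] * (np.cos(azi)[:, None] * u + np.sin(azi)[:, None] * v)
    )
    return np.concatenate([center[None, :], d], axis=0)


def fod_peak(
    coefficients: np.ndarray,
    prior_direction: np.ndarray | None,
    dirset: DirectionSet | None = None,
    min_amplitude: float = 0.1,
    *,
    sh_order: int | None = None,
    refine: bool = True,
) -> np.ndarray | None:
    """Discrete FOD peak, optionally the one nearest a prior direction.

    Amplitudes are evaluated on ``dirset``; local maxima (against the 6
    nearest neighbors) with amplitude >= ``min_amplitude`` are candidates.
    With a prior, candidates are sign-flipped into the prior's hemisphere and
    the one with the largest dot product wins; without a prior the global
    maximum wins (sign chosen so the largest-magnitude component is
    positive).  One spiral cap-refinement pass sharpens the discrete result
    below the set's angular spacing.  Returns ``None`` when no candidate
    clears the threshold.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if dirset is None:
        dirset = default_direction_set()
    if len(dirset) == 0:
        raise ValueError("empty direction set")
    if sh_order is None:
        # infer from coefficient count
        L = 0
        while n_coefficients(L) < coefficients.shape[-1]:
            L += 2
        if n_coefficients(L) != coefficients.shape[-1]:
            raise ValueError(f"coefficient count {coefficients.shape[-1]} matches no even order")
        sh_order = L

    amp = dirset.basis(sh_order) @ coefficients
    is_max = np.all(amp[:, None] >= amp[dirset.neighbors], axis=1)
    cand = np.flatnonzero(is_max & (amp >= min_amplitude))
    if cand.size == 0:
        return None

    dirs = dirset.directions[cand]
    if prior_direction is not None:
        prior = np.asarray(prior_direction, dtype=float)
        dots = dirs @ prior
        dirs = np.where(dots[:, None] < 0, -dirs, dirs)
        best = dirs[np.argmax(np.abs(dots))]
    else:
        best = dirs[np.argmax(amp[cand])]

    if refine:
        radius = dirset.angular_spacing_rad
        for _ in range(2):
            cap = _cap_directions(best, radius)
            a = sh_basis(sh_order, cap) @ coefficients
            best = cap[int(np.argmax(a))]
            radius /= 3.0
    if prior_direction is not None and best @ np.asarray(prior_direction, dtype=float) < 0:
        best = -best
    elif prior_direction is None:
        k = int(np.argmax(np.abs(best)))
        if best[k] < 0:
            best = -best
    return best / np.linalg.norm(best)


def single_fiber_coefficients(
    direction: np.ndarray,
    sh_order: int = 4,
    power: int = 8,
    dirset: DirectionSet | None = None,
) -> np.ndarray:
    """SH coefficients of a single-fiber FOD kernel aligned with ``direction``.

    The kernel is the axially symmetric function ``|d . v|^power`` projected
    onto the even-order basis by least squares on the direction set.  Being
    axially symmetric about ``v``, its SH truncation keeps its (antipodal)
    maxima exactly at ``+-v``.
    """
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    if dirset is None:
        dirset = default_direction_set()
    target = np.abs(dirset.directions @ v) ** power
    return dirset.basis_pinv(sh_order) @ target
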