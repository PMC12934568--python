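"""Synthetic white-matter fiber phantoms.

A phantom packages everything a tracking / distillation experiment needs in
one co-registered frame with analytically known geometry:

* an SH FOD field whose per-voxel peak follows the local bundle tangent
  (crossing voxels get the coefficient sum of both single-fiber kernels),
* a FLAIR-like scalar contrast derived monotonically from fiber density
  (``1 - 0.6 * normalized density`` plus Gaussian noise, then
  percentile-normalized) so white matter is darker than background, giving
  the student an invertible density cue,
* an anatomical-context stack: five tissue-probability channels (summing to
  one) plus one smoothed probability map per bundle,
* a binary white-matter mask and the ground-truth tractogram with bundle
  ids.

Everything is a deterministic function of (specs, grid, noise_sd, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .evaluation import streamline_density
from .fod import FODField, n_coefficients, single_fiber_coefficients
from .geometry import ScalarVolume, Tractogram, VoxelGrid

__all__ = [
    "BundleSpec",
    "PhantomDataset",
    "make_phantom",
    "normalize_flair",
    "TISSUE_CHANNELS",
]

#: Tissue-probability channel order in the context stack.  The phantom fills
#: white matter from smoothed bundle support and assigns the complement to
#: the cortical-GM channel (a stand-in for all non-WM tissue); the remaining
#: channels are zero.
TISSUE_CHANNELS = ("cortical_gm", "subcortical_gm", "wm", "csf", "pathology")

_FINE_STEP_MM = 0.25


@dataclass(frozen=True)
class BundleSpec:
    """Parametric description of one fiber bundle.

    ``kind`` selects the centerline family ("straight", "arc", "helix");
    ``params`` holds that family's geometry in world mm (see the
    constructors).  ``radius_mm`` is the tube radius around the centerline,
    ``n_streamlines`` how many parallel-offset streamlines to draw.
    """

    kind: str
    params: dict
    radius_mm: float
    n_streamlines: int
    bundle_id: int

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown centerline family {self.kind!r}")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")

    # -- constructors -------------------------------------------------
    @classmethod
    def straight(cls, start, end, radius_mm, n_streamlines, bundle_id) -> "BundleSpec":
        return cls(
            "straight",
            {"start": [float(x) for x in start], "end": [float(x) for x in end]},
            float(radius_mm), int(n_streamlines), int(bundle_id),
        )

    @classmethod
    def arc(cls, center, arc_radius_mm, normal, angle_start, angle_end,
            radius_mm, n_streamlines, bundle_id) -> "BundleSpec":
        """Circular arc of radius ``arc_radius_mm`` in the plane with the
        given normal, swept from ``angle_start`` to ``angle_end`` radians."""
        return cls(
            "arc",
            {
                "center": [float(x) for x in center],
                "arc_radius_mm": float(arc_radius_mm),
                "normal": [float(x) for x in normal],
                "angle_start": float(angle_start),
                "angle_end": float(angle_end),
            },
            float(radius_mm), int(n_streamlines), int(bundle_id),
        )

    @classmethod
    def helix(cls, center, axis, helix_radius_mm, pitch_mm, angle_start, angle_end,
              radius_mm, n_streamlines, bundle_id) -> "BundleSpec":
        """Helix around ``axis`` through ``center``; ``pitch_mm`` is the axial
        advance per full turn."""
        return cls(
            "helix",
            {
                "center": [float(x) for x in center],
                "axis": [float(x) for x in axis],
                "helix_radius_mm": float(helix_radius_mm),
                "pitch_mm": float(pitch_mm),
                "angle_start": float(angle_start),
                "angle_end": float(angle_end),
            },
            float(radius_mm), int(n_streamlines), int(bundle_id),
        )

    # -- geometry -----------------------------------------------------
    def _frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.asarray(self.params.get("normal", self.params.get("axis")), dtype=float)
        n = n / np.linalg.norm(n)
        a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return n, u, v

    def centerline(self, n_samples: int) -> np.ndarray:
        p = self.params
        if self.kind == "straight":
            t = np.linspace(0.0, 1.0, n_samples)[:, None]
            s, e = np.asarray(p["start"]), np.asarray(p["end"])
            return s + t * (e - s)
        t = np.linspace(p["angle_start"], p["angle_end"], n_samples)
        _, u, v = self._frame()
        c = np.asarray(p["center"], dtype=float)
        if self.kind == "arc":
            r = p["arc_radius_mm"]
            return c + r * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
        n, u, v = self._frame()
        r = p["helix_radius_mm"]
        return (
            c
            + r * (np.cos(t)[:, None] * u + np.sin(t)[:, None] * v)
            + (p["pitch_mm"] * t / (2.0 * np.pi))[:, None] * n
        )

    def arc_length(self) -> float:
        pts = self.centerline(2048)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params,
            "radius_mm": self.radius_mm,
            "n_streamlines": self.n_streamlines,
            "bundle_id": self.bundle_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BundleSpec":
        return cls(d["kind"], d["params"], d["radius_mm"], d["n_streamlines"], d["bundle_id"])


@dataclass
class PhantomDataset:
    """All phantom outputs on one shared grid (see module docstring)."""

    fod_field: FODField
    flair: ScalarVolume
    context: ScalarVolume
    wm_mask: ScalarVolume
    truth: Tractogram
    seed: int
    specs: list[BundleSpec] = field(default_factory=list)
    noise_sd: float = 0.0

    @property
    def grid(self) -> VoxelGrid:
        return self.fod_field.grid

    @property
    def bundle_ids(self) -> list[int]:
        return [s.bundle_id for s in self.specs]

    def student_input(self) -> ScalarVolume:
        """FLAIR channel concatenated with the context stack."""
        return ScalarVolume(
            self.grid,
            np.concatenate([self.flair.values[..., None], self.context.values], axis=3),
        )


def normalize_flair(volume: ScalarVolume) -> ScalarVolume:
    """Clamp intensities at their 99.9th percentile, then scale it to one.

    The clamp value becomes the image maximum; division by it (so the
    maximum is exactly 1) is this package's choice of scale.
    """
    p = float(np.percentile(volume.values, 99.9))
    if p <= 0:
        raise ValueError(f"degenerate image: 99.9th percentile {p} <= 0")
    return ScalarVolume(volume.grid, np.minimum(volume.values, p) / p)


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent + parallel-transported normal/binormal along a fine polyline."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    n = len(points)
    normals = np.empty_like(tang)
    a = np.array([1.0, 0.0, 0.0]) if abs(tang[0, 0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    normals[0] = np.cross(tang[0], a)
    normals[0] /= np.linalg.norm(normals[0])
    for i in range(1, n):
        w = normals[i - 1] - (normals[i - 1] @ tang[i]) * tang[i]
        normals[i] = w / np.linalg.norm(w)
    binormals = np.cross(tang, normals)
    return tang, normals, binormals


def _bundle_streamlines(
    spec: BundleSpec, rng: np.random.Generator, point_spacing_mm: float = 1.0
) -> list[np.ndarray]:
    """Parallel offsets of the centerline within the tube radius."""
    length = spec.arc_length()
    fine = spec.centerline(max(int(length / _FINE_STEP_MM), 8))
    _, normals, binormals = _parallel_transport_frames(fine)
    stride = max(int(round(point_spacing_mm / _FINE_STEP_MM)), 1)
    sl = slice(None, None, stride)
    out = []
    for _ in range(spec.n_streamlines):
        r = spec.radius_mm * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2.0 * np.pi)
        off = r * math.cos(ang) * normals + r * math.sin(ang) * binormals
        out.append((fine + off)[sl].copy())
    return out


def make_phantom(
    specs: list[BundleSpec],
    grid: VoxelGrid | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    sh_order: int = 4,
) -> PhantomDataset:
    """Generate a deterministic phantom dataset from bundle specs.

    Raises if any bundle's streamlines leave the grid's interpolation
    domain (the error names the offending bundle).
    """
    if grid is None:
        grid = VoxelGrid.isotropic((32, 32, 32), 2.0)
    if not specs:
        raise ValueError("at least one BundleSpec required")
    step = float(min(grid.voxel_size))
    for spec in specs:
        if spec.arc_length() < 4.0 * step:
            raise ValueError(f"bundle {spec.bundle_id}: centerline shorter than 4 steps")

    rng = np.random.default_rng(seed)
    coeffs = np.zeros(grid.shape + (n_coefficients(sh_order),))
    all_streamlines: list[np.ndarray] = []
    all_ids: list[int] = []
    bundle_masks: dict[int, np.ndarray] = {}

    for spec in specs:
        lines = _bundle_streamlines(spec, rng)
        for ln in lines:
            if not np.all(grid.contains_index(grid.world_to_voxel(ln))):
                raise ValueError(f"bundle {spec.bundle_id} leaves the grid")
        tg = Tractogram(lines, grid)
        _, mask = streamline_density(tg, grid)
        bundle_masks[spec.bundle_id] = mask.values.astype(bool)

        # tangent of the nearest centerline sample orients the voxel FOD
        fine = spec.centerline(max(int(spec.arc_length() / _FINE_STEP_MM), 8))
        tang, _, _ = _parallel_transport_frames(fine)
        vox = np.argwhere(bundle_masks[spec.bundle_id])
        centers = grid.voxel_to_world(vox)
        _, nearest = cKDTree(fine).query(centers)
        for (i, j, k), t in zip(vox, tang[nearest]):
            coeffs[i, j, k] += single_fiber_coefficients(t, sh_order)

        all_streamlines.extend(lines)
        all_ids.extend([spec.bundle_id] * len(lines))

    truth = Tractogram(all_streamlines, grid, np.asarray(all_ids))
    density_vol, wm_mask = streamline_density(truth, grid)
    density = density_vol.values
    dmax = density.max()
    if dmax <= 0:
        raise ValueError("phantom produced an empty density volume")

    flair_clean = 1.0 - 0.6 * density / dmax
    flair_noisy = flair_clean + rng.normal(0.0, noise_sd, size=grid.shape)
    flair = normalize_flair(ScalarVolume(grid, flair_noisy))

    wm_p = np.clip(gaussian_filter(wm_mask.values.astype(float), sigma=1.0), 0.0, 1.0)
    tissue = np.zeros(grid.shape + (len(TISSUE_CHANNELS),))
    tissue[..., TISSUE_CHANNELS.index("wm")] = wm_p
    tissue[..., TISSUE_CHANNELS.index("cortical_gm")] = 1.0 - wm_p
    bundle_ch = [
        np.clip(gaussian_filter(bundle_masks[s.bundle_id].astype(float), sigma=1.0), 0.0, 1.0)
        for s in specs
    ]
    context = ScalarVolume(grid, np.concatenate([tissue, np.stack(bundle_ch, axis=3)], axis=3))

    return PhantomDataset(
        fod_field=FODField(grid, sh_order, coeffs),
        flair=flair,
        context=context,
        wm_mask=wm_mask,
        truth=truth,
        seed=int(seed),
        specs=list(specs),
        noise_sd=float(noise_sd),
    )
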