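"""NIfTI / TRK / TCK readers and writers and phantom dataset serialization.

Volumes are NIfTI-1 via nibabel.  FOD volumes are 4-D NIfTI with the SH
coefficient channels in the basis order documented in
:mod:`tractdistill.fod`, accompanied by a JSON sidecar (same stem,
``.json``) recording ``sh_order`` and the basis name.  Tractograms are TRK
or TCK (by extension); points are stored and returned in world mm
regardless of each format's internal voxel-order conventions.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fod import FODField, n_coefficients
from .geometry import ScalarVolume, Tractogram, VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_fod",
    "write_fod",
    "read_tractogram",
    "write_tractogram",
    "save_phantom_dataset",
    "load_phantom_dataset",
]

SH_BASIS_NAME = "real-symmetric-descoteaux-style"
SIDECAR_VERSION = 1


def _grid_from_nifti(img) -> VoxelGrid:
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"non-invertible affine in {img.get_filename()}")
    return VoxelGrid(img.shape[:3], affine)


def read_volume(path) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    return ScalarVolume(_grid_from_nifti(img), np.asarray(img.get_fdata()))


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), volume.grid.affine)
    nib.save(img, str(path))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_fod(field: FODField, path) -> None:
    path = Path(path)
    write_volume(ScalarVolume(field.grid, field.coefficients), path)
    meta = {
        "version": SIDECAR_VERSION,
        "sh_order": field.sh_order,
        "basis": SH_BASIS_NAME,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_fod(path) -> FODField:
    path = Path(path)
    vol = read_volume(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"FOD sidecar {sidecar} missing")
    meta = json.loads(sidecar.read_text())
    order = int(meta["sh_order"])
    if vol.values.ndim != 4 or vol.values.shape[3] != n_coefficients(order):
        raise ValueError(
            f"{path}: {vol.values.shape} does not hold {n_coefficients(order)} "
            f"SH coefficients for order {order}"
        )
    if meta.get("basis") != SH_BASIS_NAME:
        raise ValueError(f"{path}: unknown SH basis {meta.get('basis')!r}")
    return FODField(vol.grid, order, vol.values)


def _trk_header(grid: VoxelGrid) -> dict:
    return {
        nib.streamlines.trk.Field.VOXEL_TO_RASMM: grid.affine.astype(np.float32),
        nib.streamlines.trk.Field.VOXEL_SIZES: grid.voxel_size.astype(np.float32),
        nib.streamlines.trk.Field.DIMENSIONS: np.asarray(grid.shape, dtype=np.int16),
        nib.streamlines.trk.Field.VOXEL_ORDER: b"RAS",
    }


def write_tractogram(tractogram: Tractogram, path) -> None:
    path = Path(path)
    data_per_streamline = {}
    if tractogram.bundle_ids is not None:
        data_per_streamline["bundle_id"] = tractogram.bundle_ids[:, None].astype(float)
    nib_tg = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines],
        data_per_streamline=data_per_streamline or None,
        affine_to_rasmm=np.eye(4),
    )
    suffix = path.name.lower()
    if suffix.endswith(".trk"):
        nib.streamlines.save(nib_tg, str(path), header=_trk_header(tractogram.grid))
    elif suffix.endswith(".tck"):
        nib.streamlines.save(nib_tg, str(path))
    else:
        raise ValueError(f"unknown tractogram extension on {path} (use .trk or .tck)")


def read_tractogram(path, grid: VoxelGrid | None = None) -> Tractogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.name.lower()
    if not (suffix.endswith(".trk") or suffix.endswith(".tck")):
        raise ValueError(f"unknown tractogram extension on {path} (use .trk or .tck)")
    tf = nib.streamlines.load(str(path))
    if suffix.endswith(".trk") and grid is None:
        hdr = tf.header
        grid = VoxelGrid(
            tuple(int(d) for d in hdr[nib.streamlines.trk.Field.DIMENSIONS]),
            np.asarray(hdr[nib.streamlines.trk.Field.VOXEL_TO_RASMM], dtype=float),
        )
    if grid is None:
        raise ValueError("TCK files carry no grid; pass the reference VoxelGrid")
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    bundle_ids = None
    dps = tf.tractogram.data_per_streamline
    if "bundle_id" in dps and len(streamlines):
        bundle_ids = np.asarray(dps["bundle_id"]).ravel().astype(int)
    return Tractogram(streamlines, grid, bundle_ids)


def save_phantom_dataset(dataset, out_dir) -> None:
    """Write a phantom to a directory: NIfTI volumes, TRK truth, JSON sidecar
    holding the generating specs and seed for exact regeneration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fod(dataset.fod_field, out / "fod.nii.gz")
    write_volume(dataset.flair, out / "flair.nii.gz")
    write_volume(dataset.context, out / "context.nii.gz")
    write_volume(dataset.wm_mask, out / "wm_mask.nii.gz")
    write_tractogram(dataset.truth, out / "truth.trk")
    sidecar = {
        "version": SIDECAR_VERSION,
        "seed": dataset.seed,
        "noise_sd": dataset.noise_sd,
        "grid": {
            "shape": list(dataset.grid.shape),
            "affine": dataset.grid.affine.tolist(),
        },
        "specs": [s.to_dict() for s in dataset.specs],
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom_dataset(in_dir):
    """Load a phantom directory written by :func:`save_phantom_dataset`."""
    from .phantom import BundleSpec, PhantomDataset

    p = Path(in_dir)
    sidecar = json.loads((p / "phantom.json").read_text())
    return PhantomDataset(
        fod_field=read_fod(p / "fod.nii.gz"),
        flair=read_volume(p / "flair.nii.gz"),
        context=read_volume(p / "context.nii.gz"),
        wm_mask=read_volume(p / "wm_mask.nii.gz"),
        truth=read_tractogram(p / "truth.trk"),
        seed=int(sidecar["seed"]),
        specs=[BundleSpec.from_dict(d) for d in sidecar["specs"]],
        noise_sd=float(sidecar["noise_sd"]),
    )
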