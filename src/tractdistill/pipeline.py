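"""End-to-end phantom -> teacher -> student experiment pipeline.

``run_demo`` wires the whole method together on a synthetic phantom:

1. generate a phantom (bundles, FOD field, FLAIR-like contrast, context),
2. deterministic FOD-peak reference tractography on the white-matter mask,
3. stage-1 teacher training on the reference streamlines, then tracking
   with the teacher,
4. student construction with frozen teacher layers, stage-2 distillation
   training on FLAIR + context only, then tracking with the student
   (no FOD access),
5. evaluation: whole-phantom Dice against the reference, bundle adjacency,
   and the per-bundle comparison report.

Every random choice derives from the single ``seed`` argument.  Presets
scale the experiment: ``"full"`` is the standard desk-scale study
(32-voxel grid, two bundles, 200-epoch stages), ``"tiny"`` a minutes-scale
variant used for smoke and determinism checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import (
    bundle_adjacency,
    compare_methods,
    streamline_density,
    voxel_dice,
)
from .fod import n_coefficients
from .geometry import ScalarVolume, Tractogram, VoxelGrid, sample_trilinear
from .models import TeacherModel, build_student_from_teacher
from .phantom import BundleSpec, PhantomDataset, TISSUE_CHANNELS, make_phantom
from .tracking import TrackingParams, track_deterministic, track_with_model
from .training import TrainConfig, loss_history_frame, train_student, train_teacher

__all__ = ["DemoConfig", "run_demo", "label_streamlines_by_bundle"]

_MOD = 2**31


@dataclass
class DemoConfig:
    """Scale parameters of the demo experiment."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_mm: float = 2.0
    n_streamlines_per_bundle: int = 50
    noise_sd: float = 0.02
    sh_order: int = 4
    two_bundles: bool = True
    teacher_epochs: int = 200
    student_epochs: int = 200
    teacher_batch: int = 16
    student_batch: int = 32
    teacher_max_streamlines: int | None = 128
    student_max_streamlines: int | None = 96
    learning_rate: float = 1e-3
    step_mm: float = 1.0
    encoder_channels: tuple[int, ...] = (12, 12, 8)
    write_tractograms: bool = True

    @classmethod
    def preset(cls, name: str) -> "DemoConfig":
        if name == "full":
            return cls()
        if name == "tiny":
            return cls(
                grid_shape=(16, 16, 16),
                n_streamlines_per_bundle=12,
                two_bundles=False,
                teacher_epochs=8,
                student_epochs=8,
                teacher_batch=8,
                student_batch=8,
                teacher_max_streamlines=24,
                student_max_streamlines=24,
                encoder_channels=(8, 8),
            )
        raise ValueError(f"unknown preset {name!r}")


def demo_bundle_specs(config: DemoConfig) -> list[BundleSpec]:
    """Bundle layout scaled to the demo grid extent."""
    extent = (np.asarray(config.grid_shape) - 1) * config.voxel_mm
    n = config.n_streamlines_per_bundle
    if not config.two_bundles:
        y = z = extent[1] / 2.0
        specs = [
            BundleSpec.straight(
                (0.12 * extent[0], y, z), (0.88 * extent[0], y, z),
                radius_mm=0.04 * extent[0] + 1.0, n_streamlines=n, bundle_id=1,
            )
        ]
        return specs
    # straight bundle along x in the lower-y half, arc in the upper-y half
    specs = [
        BundleSpec.straight(
            (0.13 * extent[0], 0.29 * extent[1], 0.29 * extent[2]),
            (0.87 * extent[0], 0.29 * extent[1], 0.29 * extent[2]),
            radius_mm=3.5, n_streamlines=n, bundle_id=1,
        ),
        BundleSpec.arc(
            center=(0.48 * extent[0], 0.68 * extent[1], 0.48 * extent[2]),
            arc_radius_mm=0.225 * float(extent.min()),
            normal=(1.0, 0.0, 0.0),
            angle_start=-np.pi / 2.0,
            angle_end=np.pi / 2.0,
            radius_mm=3.0, n_streamlines=n, bundle_id=2,
        ),
    ]
    return specs


def label_streamlines_by_bundle(
    tractogram: Tractogram, dataset: PhantomDataset
) -> Tractogram:
    """Assign each streamline the bundle whose probability map it traverses
    most strongly (mean of the bundle channel along its points)."""
    n_tissue = len(TISSUE_CHANNELS)
    bundle_vol = ScalarVolume(dataset.grid, dataset.context.values[..., n_tissue:])
    ids = np.asarray(dataset.bundle_ids)
    labels = []
    for pts in tractogram.streamlines:
        probs = sample_trilinear(bundle_vol, pts)
        probs = np.nan_to_num(np.atleast_2d(probs), nan=0.0)
        labels.append(ids[int(np.argmax(probs.mean(axis=0)))])
    return Tractogram(tractogram.streamlines, tractogram.grid, np.asarray(labels))


def run_demo(seed: int, out_dir=None, preset: str | DemoConfig = "full") -> dict:
    """Run the full pipeline; returns metrics, loss histories and report.

    Writes loss CSVs, the report table, a manifest and (optionally)
    tractograms under ``out_dir`` when given.
    """
    config = DemoConfig.preset(preset) if isinstance(preset, str) else preset
    base = int(seed) % _MOD

    def sub(k: int) -> int:
        return (base + 101 * k) % _MOD

    grid = VoxelGrid.isotropic(config.grid_shape, config.voxel_mm)
    specs = demo_bundle_specs(config)
    dataset = make_phantom(specs, grid, noise_sd=config.noise_sd, seed=sub(0),
                           sh_order=config.sh_order)

    params = TrackingParams(mask=dataset.wm_mask, step_mm=config.step_mm, seed=sub(1))
    reference = track_deterministic(dataset.fod_field, params)
    if len(reference) == 0:
        raise RuntimeError("reference tracking produced no streamlines")

    teacher = TeacherModel(n_coefficients(config.sh_order), seed=sub(2))
    teacher_cfg = TrainConfig(
        epochs=config.teacher_epochs, learning_rate=config.learning_rate,
        batch_streamlines=config.teacher_batch, seed=sub(3),
        step_mm=config.step_mm, max_streamlines=config.teacher_max_streamlines,
    )
    teacher, teacher_records = train_teacher(
        teacher, dataset.fod_field, reference, teacher_cfg
    )
    teacher_tracked = track_with_model(
        teacher, dataset.fod_field,
        TrackingParams(mask=dataset.wm_mask, step_mm=config.step_mm, seed=sub(4)),
    )

    n_context = dataset.context.n_channels
    student = build_student_from_teacher(
        teacher,
        {"in_channels": 1 + n_context, "channels": config.encoder_channels},
        seed=sub(5),
    )
    student_cfg = TrainConfig(
        epochs=config.student_epochs, learning_rate=config.learning_rate,
        batch_streamlines=config.student_batch, seed=sub(6),
        step_mm=config.step_mm, max_streamlines=config.student_max_streamlines,
    )
    student, student_records = train_student(
        student, teacher, dataset.fod_field, dataset.flair, dataset.context,
        reference, student_cfg,
    )
    student_tracked = track_with_model(
        student, (dataset.flair, dataset.context),
        TrackingParams(mask=dataset.wm_mask, step_mm=config.step_mm, seed=sub(7)),
    )

    _, ref_mask = streamline_density(reference, grid)
    _, truth_mask = streamline_density(dataset.truth, grid)
    _, teacher_mask = streamline_density(teacher_tracked, grid)
    metrics = {
        "reference_vs_truth_dice": voxel_dice(ref_mask, truth_mask),
        "teacher_vs_reference_dice": (
            voxel_dice(teacher_mask, ref_mask) if len(teacher_tracked) else 0.0
        ),
        "teacher_bundle_adjacency_mm": (
            bundle_adjacency(reference, teacher_tracked) if len(teacher_tracked) else np.nan
        ),
        "teacher_final_loss": teacher_records[-1].loss,
        "student_final_loss": student_records[-1].loss,
        "student_final_alignment": student_records[-1].alignment,
        "n_reference_streamlines": len(reference),
        "n_teacher_streamlines": len(teacher_tracked),
        "n_student_streamlines": len(student_tracked),
    }
    if len(student_tracked):
        _, student_mask = streamline_density(student_tracked, grid)
        metrics["student_vs_reference_dice"] = voxel_dice(student_mask, ref_mask)
        metrics["student_bundle_adjacency_mm"] = bundle_adjacency(reference, student_tracked)
    else:
        metrics["student_vs_reference_dice"] = 0.0
        metrics["student_bundle_adjacency_mm"] = np.nan

    ref_labeled = label_streamlines_by_bundle(reference, dataset)
    candidates = {"teacher": label_streamlines_by_bundle(teacher_tracked, dataset)}
    if len(student_tracked):
        candidates["student"] = label_streamlines_by_bundle(student_tracked, dataset)
    report = compare_methods(ref_labeled, candidates)

    result = {
        "config": config,
        "seed": int(seed),
        "metrics": metrics,
        "report": report,
        "teacher_records": teacher_records,
        "student_records": student_records,
        "dataset": dataset,
        "reference": reference,
        "teacher_tracked": teacher_tracked,
        "student_tracked": student_tracked,
        "teacher": teacher,
        "student": student,
    }
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: dict, out: Path) -> None:
    from . import io as tio

    out.mkdir(parents=True, exist_ok=True)
    loss_history_frame(result["teacher_records"]).to_csv(out / "teacher_loss.csv", index=False)
    loss_history_frame(result["student_records"]).to_csv(out / "student_loss.csv", index=False)
    result["report"].to_csv(out / "report.csv", index=False)
    cfg = result["config"]
    manifest = {
        "seed": result["seed"],
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
        "metrics": {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in result["metrics"].items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if cfg.write_tractograms:
        tio.write_tractogram(result["reference"], out / "reference.trk")
        tio.write_tractogram(result["teacher_tracked"], out / "teacher.trk")
        if len(result["student_tracked"]):
            tio.write_tractogram(result["student_tracked"], out / "student.trk")
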