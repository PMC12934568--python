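# tractdistill

Teacher-student recurrent tractography: can streamline propagation learned
from diffusion-derived fiber orientation distributions (FODs) be distilled
into a network that tracks from a FLAIR-like structural contrast plus
population-level anatomical context — with no diffusion input at all?

`tractdistill` implements that question end to end for researchers
studying cross-modal white-matter representation: a deterministic FOD-peak
reference tracker, the two-stage teacher-student framework with
frozen-weight transfer, a synthetic fiber-phantom generator that makes the
whole pipeline testable without any scanner data, and a tractogram
evaluation suite.

## The method

**Stage 1 (teacher).** At each point `p_i` of a reference streamline, the
teacher receives the trilinearly sampled SH coefficient vector of the FOD
and predicts the direction to the next point as spherical angles
(theta, phi) through an MLP, two stacked GRU layers (hidden state carried
along the streamline), and an output MLP.  It minimizes the cosine
direction loss

    L_cos^T = 1 - <d_pred, d_label> / (|d_pred| |d_label|)

**Stage 2 (student).** The student is built *from* the teacher: its GRU
hidden layer and output MLP are copied bit-exactly and frozen; a 3-D
convolutional encoder over the FLAIR + context channels, a fresh input
MLP, and a trainable GRU input layer form the new front end.  With `f_T`
and `f_S` the teacher/student feature representations entering the GRU
input layer, the student minimizes

    L_cos^S = L_cos^T + 1 - <f_T, f_S> / (|f_T| |f_S|)

so the trainable front end is pushed to *map* structural features into the
representation the frozen diffusion-trained layers expect (model
stitching).  Tracking with either model is bidirectional with per-step
sign alignment and the usual curvature/length/mask stopping rules.

Evaluation follows standard tractometry: voxel-wise Dice on streamline
occupancy masks, bundle adjacency (mean distance from reference points to
the nearest candidate point), four geometric bundle properties (average
fiber length, volume, effective-cylinder diameter, surface area), and
Mann-Whitney U tests (exact under ties for small samples).

See `docs/methods.md` for conventions, parameter defaults and
limitations.

## Worked example

```python
from tractdistill.pipeline import run_demo

result = run_demo(seed=1, out_dir="demo_out", preset="full")
for k, v in result["metrics"].items():
    print(k, v)
```

This generates a two-bundle phantom (straight bundle + 180-degree arc on a
32-voxel, 2 mm grid), tracks it deterministically, trains the teacher and
the distilled student for 200 epochs each, tracks with both models, and
prints (seed 1):

```
reference_vs_truth_dice 0.9806678383128296
teacher_vs_reference_dice 0.9783174327840416
teacher_bundle_adjacency_mm 0.35077336536595205
teacher_final_loss 0.00037445681837116435
student_final_loss 0.01093944528196871
student_final_alignment 0.01011576693958142
n_reference_streamlines 505
n_teacher_streamlines 462
n_student_streamlines 440
student_vs_reference_dice 0.9755244755244755
student_bundle_adjacency_mm 0.3781955229277549
```

Reading the numbers: the deterministic tracker recovers the phantom's true
bundles almost perfectly (Dice 0.98); the teacher reproduces the reference
tractogram from FOD input (Dice 0.98, mean final direction loss 4e-4, i.e.
sub-degree angular error); and the student — tracking from the FLAIR-like
volume and context channels only, through the teacher's frozen layers —
still covers 98% of the reference voxels with streamlines on average
0.38 mm from it.  `demo_out/` holds the loss histories, the per-bundle
report table (`report.csv`) and the tractograms (TRK).

The same pipeline is scriptable from the shell:

```sh
tractdistill demo --seed 1 --out demo_out
tractdistill phantom --spec spec.json --seed 3 --out ds/
tractdistill track-ref --fod ds/fod.nii.gz --mask ds/wm_mask.nii.gz --out ref.trk
```

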