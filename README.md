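# onquant

Segmentation and cross-sectional quantification of thin tubular structures
(optic nerve) in 3D MR volumes. The pipeline:

1. **phantoms** — synthetic volumes (bright eye globes, a dark curved
   "nerve" tube wrapped in a bright "CSF" shell, bias field, noise) with
   analytic ground truth (centerline, radius and area profiles), so every
   stage is testable without any clinical data.
2. **preprocess** — spherical-Hough eye-centroid detection, in-plane head
   rotation (applied only above a 5° threshold), single-pass rotation +
   resampling to 0.3 mm isotropic, fixed 144×240×112-voxel per-eye VOIs,
   z-normalization, and a polynomial bias-flattening hook.
3. **segnet** — a 3D U-Net (two 3×3×3 conv + BN + ReLU blocks per level,
   max-pool / transposed-conv transitions, skip concatenations, sigmoid
   head) with Dice loss, Adam, on-the-fly augmentation and early stopping.
   Implemented in pure numpy with hand-written backprop (no deep-learning
   framework required); the CPU-tested path is a toy configuration
   (base 8 features, depth 4, 64³ input). Includes largest-connected-
   component postprocessing.
4. **metrics** — DSC, one-voxel-tolerance DSC, precision/recall, HD95, ASD
   (surface-voxel, world-mm conventions) and ICC(A,1) (two-way
   mixed-effects, absolute agreement, single rater), all oracle-checked
   against exhaustive brute-force implementations in the tests.
5. **quantify** — mask → anti-aliased marching-cubes surface → medial
   centerline (distance-field-weighted shortest path between automatically
   detected tube endpoints, trimmed and extended to the tube caps) →
   cross-sectional area, circular-equivalent (CE) diameter and maximal-
   inscribed-sphere (MIS) diameter sampled every 0.1 mm by exact mesh/plane
   intersection.
6. **compare** — coronal-plane ablation (a_cor·cosθ correction,
   θ = arccos(c·v_cor)), MAE-minimizing offset alignment to reference
   measurements at 0/3/5 mm, MAE/ICC/Bland–Altman agreement, and a radial
   intensity-model baseline with a quality flag for absent or asymmetric
   CSF annuli.

World convention: RAS, array axis *i* = world axis *i*, the coronal plane
has normal (0, 1, 0). I/O is NIfTI (nibabel); profiles and reports are CSV
and JSON.

## CLI

```bash
phantom make --spec spec.json --out dir/ --seed 1
prep run head.nii.gz --out dir/ [--no-bias-correction] [--angle-threshold 5]
segnet train --config cfg.json --data dir/ --out model.ckpt.npz --seed 1
segnet predict model.ckpt.npz voi.nii.gz --out mask.nii.gz --largest-component
onq-metrics eval --truth-dir t/ --pred-dir p/ --out report.csv
quantify run mask.nii.gz --out profile.csv [--endpoints x1,y1,z1,x2,y2,z2]
compare ablation masks/ --out ablation.csv
compare agreement auto.csv manual.csv --out report.json
```

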