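# histoseg

Fast, contrast-adaptive Bayesian segmentation of brain volumes with a
high-granularity probabilistic atlas.

Atlas-based Bayesian segmentation models a scan as a draw from a generative
model: each voxel takes an anatomical label from a spatially deformed
probabilistic atlas prior, and its log-intensity from a Gaussian mixture of
the label's tissue class, shifted by a smooth additive bias field
(multiplicative before the log transform).  Classical inference alternates
registration, bias, and mixture updates in deeply nested loops and is far too
slow at sub-millimetre working resolutions.  This package implements the fast
single-pass approximation: every parameter group is estimated once, in a
fixed order, using a coarse whole-brain segmentation (produced upstream by
any robust 1 mm method) as a guide.

The pipeline:

1. **Mask preprocessing** — the coarse segmentation is linearly upsampled,
   box-smoothed and thresholded at 0.5 to produce a brain mask on the scan
   grid (CSF and extracerebral tissue are excluded; they are not modelled).
2. **Bias field** — a 3D DCT basis (order 6 on a full head, 343 functions;
   the order scales with the field of view) is fitted in a *single* M-step of
   generalized EM with responsibilities fixed to the Gaussian-blurred
   (σ = 0.5 mm) one-hot encoding of eight coarse tissue classes, alternating
   closed-form class moments and precision-weighted least squares for the
   coefficients.
3. **Contrast synthesis** — per-structure robust statistics (median for the
   mean, 1.4826 × MAD for the standard deviation) feed a small set of linear
   recipe rules that assign an intensity to each of the 16 atlas tissue
   classes; the grouped atlas is rendered as a noise-free *synthetic
   anatomical volume* matching the scan's contrast and resolution.
4. **Registration** — the synthetic volume (plus protocol-grouped atlas label
   maps) is registered to the scan with a greedy multiscale diffeomorphic
   scheme: the loss is −(LNCC + 2.5 · softDice) on the fixed grid, its
   gradient is smoothed (σ = 1.0 voxels), one Adam step (lr = 0.5) is
   composed into the running displacement, and the field is smoothed again
   (σ = 0.25 voxels).  The pyramid starts at ~4 mm and halves to the native
   voxel size.
5. **EM + redistribution** — with bias and deformation fixed, plain EM
   estimates the grouped-class Gaussian mixture at the working resolution
   (0.4 mm in vivo; min(0.2 mm, scan) ex vivo).  Class posteriors are
   redistributed to the fine ROIs in proportion to the warped atlas, giving
   fine posteriors, hard labels, and soft ROI volumes in mm³.

A fully synthetic **phantom** module generates every input the pipeline needs
(smooth multi-ROI probabilistic atlases, images sampled from the generative
model under a known bias field and a known smooth diffeomorphic deformation,
and coarse segmentations with controllable boundary errors), so the whole
method is testable without any imaging data.

## Worked example

```python
from histoseg.validation import phantom_end_to_end

metrics = phantom_end_to_end(seed=1)
for k in ("max_class_mean_rel_err", "max_class_std_rel_err",
          "bias_field_correlation", "mean_dice_large_rois",
          "jacobian_positive_fraction"):
    print(f"{k}: {metrics[k]:.4f}")
```

prints (seed 1, 64³ phantom, 24 ROIs in 6 tissue classes):

```
max_class_mean_rel_err: 0.0033
max_class_std_rel_err: 0.0109
bias_field_correlation: 0.9968
mean_dice_large_rois: 0.9313
jacobian_positive_fraction: 0.9992
```

i.e. the pipeline recovers every class's log-intensity mean within 0.4% and
standard deviation within ~1%, reconstructs the simulated multiplicative
bias field with correlation 0.997, segments large ROIs at a mean Dice of
0.93 against the sampled ground-truth labels, and produces a deformation
whose Jacobian determinant is positive on >99.9% of the brain (i.e. the warp
is diffeomorphic almost everywhere).

The command-line tool runs the same pipeline on files:

```bash
mri-histoseg --i scan.nii.gz --o out/ --mode invivo --side left \
    --coarse_seg coarse.nii.gz --atlas atlas_dir/ --yaml_path configs/
```

writing the hard segmentation (working and native grids), a soft-volume CSV,
and, on request, the bias-corrected image, the deformation field, its log10
Jacobian determinant, and an RGB posterior composite.  All flag defaults
(`--bf_mode dct`, `--skip 1`, `--resolution 0.4`,
`--smoothing_steps_HRmask 3`, `--smooth_grad_sigma 1.0`,
`--smooth_warp_sigma 0.25`, `--optimizer_lr 0.5`, `--cc_kernel_size 7`,
`--rel_weight_labeldiff 2.5`) are fixed and used in all validation runs.

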