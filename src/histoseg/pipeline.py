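"""End-to-end fast segmentation pipeline.

Stages: mask preprocessing -> single-M-step bias-field estimation -> robust
intensity statistics + recipe -> synthetic anatomical volume at the scan's
contrast and resolution -> centroid-based affine initialisation -> greedy
multiscale diffeomorphic registration (LNCC + soft Dice) -> EM over grouped
tissue classes at the working resolution -> redistribution of class
posteriors to fine ROIs -> hard labels and soft ROI volumes.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import uniform_filter

from . import __version__
from .atlas import (LabelGrouping, ProbabilisticAtlas, group_probabilities,
                    resample_probability_maps)
from .bias import (build_basis, correct_image, default_bf_order,
                   fit_bias_single_mstep, soft_segmentation)
from .em import (SegmentationResult, fit_gmm_em, hard_segmentation,
                 init_params_from_stats, redistribute_posteriors, roi_volumes,
                 working_resolution)
from .generative import log_transform
from .registration import (RegistrationConfig, _downsample,
                           affine_initialize, jacobian_map,
                           run_multiscale_registration)
from .synthesis import (IntensityRecipe, class_means_from_recipe, match_resolution,
                        robust_stats, synthesize_volume)
from .types import CoarseSegmentation, ImageVolume, resample_to_grid

logger = logging.getLogger("histoseg")

BIAS_FIT_MAX_RES_MM = 2.0    # bias estimated at <= 2 mm on large images
BIAS_FIT_NATIVE_BUDGET = 400_000  # native-resolution fit below this voxel count
EM_PRIOR_FLOOR = 0.5         # min foreground prior sum for a voxel to enter EM


def preprocess_mask(coarse: CoarseSegmentation, target_shape, target_affine,
                    smoothing_steps: int = 3,
                    brain_label_ids: list[int] | None = None) -> np.ndarray:
    """Brain mask on the target grid: linear interpolation of the binary
    coarse-label mask, ``smoothing_steps`` passes of a normalised 3x3x3 box
    kernel, threshold at 0.5."""
    if smoothing_steps < 0:
        raise ValueError("smoothing_steps must be >= 0")
    ids = brain_label_ids if brain_label_ids is not None \
        else sorted(set(coarse.protocol) - {0})
    binary = np.isin(coarse.labels, ids).astype(float)
    m = resample_to_grid(binary, coarse.affine, tuple(target_shape), target_affine,
                         order=1)
    for _ in range(smoothing_steps):
        m = uniform_filter(m, 3, mode="constant")
    mask = m > 0.5
    if not mask.any():
        raise ValueError("empty brain mask after preprocessing")
    return mask


def _working_grid(scan: ImageVolume, resolution_mm: float):
    """Isotropic working grid covering the scan's field of view."""
    vs = scan.voxel_size
    scale = vs / resolution_mm
    shape = tuple(max(2, int(round(scan.shape[ax] * scale[ax]))) for ax in range(3))
    A = scan.affine.copy()
    A[:3, :3] = scan.affine[:3, :3] / scale[None, :]
    A[:3, 3] = scan.affine[:3, :3] @ (0.5 / scale - 0.5) + scan.affine[:3, 3]
    return shape, A


def segment(scan: ImageVolume, coarse: CoarseSegmentation, atlas: ProbabilisticAtlas,
            grouping: LabelGrouping, recipe: IntensityRecipe,
            bias_classes: dict[str, list[int]], atlas_to_protocol: dict[int, int],
            mode: str = "invivo", side: str = "left",
            brain_label_ids: list[int] | None = None,
            resolution: float | None = None, skip: int = 1, skip_bf: bool = False,
            bf_mode: str = "dct", bf_order: int | None = None,
            smoothing_steps_HRmask: int = 3,
            reg_config: RegistrationConfig | None = None, seed: int = 0,
            out_dir=None, write_bias_corrected: bool = False, write_rgb: bool = False,
            save_field: bool = False, save_jacobian: bool = False,
            save_atlas_nonlinear_reg: bool = False, verbose: bool = False):
    """Run the full pipeline; returns ``(SegmentationResult, manifest)``.

    ``bias_classes`` maps bias-estimation class names to coarse-protocol
    label ids; ``atlas_to_protocol`` maps atlas ROI ids to protocol ids (the
    registration's label-Dice grouping, independent of the intensity
    grouping).  All stages are deterministic given the inputs and ``seed``.
    """
    if mode not in ("invivo", "exvivo", "cerebrum", "hemi"):
        raise ValueError(f"unknown mode {mode!r}")
    if side not in ("left", "right"):
        raise ValueError(f"unknown side {side!r}")
    rng_seed = int(seed) % (2 ** 31)
    reg_config = reg_config or RegistrationConfig()
    t_start = time.time()
    stage_times: dict[str, float] = {}
    manifest: dict = {"version": __version__, "seed": rng_seed, "mode": mode,
                      "side": side, "numpy": np.__version__}

    def _stage(name):
        stage_times[name] = time.time()

    def _done(name):
        stage_times[name] = time.time() - stage_times[name]
        logger.info("stage %s: %.1f s", name, stage_times[name])

    # ---- mask preprocessing -------------------------------------------------
    _stage("mask")
    mask = preprocess_mask(coarse, scan.shape, scan.affine,
                           smoothing_steps_HRmask, brain_label_ids)
    log_img, mask = log_transform(scan.voxels, mask)
    _done("mask")

    # ---- bias field ---------------------------------------------------------
    _stage("bias")
    scan_res = float(np.min(scan.voxel_size))
    coarse_on_scan = np.rint(resample_to_grid(coarse.labels.astype(float),
                                              coarse.affine, scan.shape, scan.affine,
                                              order=0)).astype(np.int32)
    if skip_bf:
        bias_model, bias_field = None, None
        corrected = scan.voxels.astype(float)
    else:
        if np.prod(scan.shape) <= BIAS_FIT_NATIVE_BUDGET:
            fit_res = scan_res
        else:
            fit_res = max(BIAS_FIT_MAX_RES_MM, scan_res)
        logv_fit, fit_shape, _ = _downsample(log_img, scan.voxel_size, fit_res)
        mask_fit, _, _ = _downsample(mask.astype(float), scan.voxel_size, fit_res)
        # soft maps built at native resolution, then taken through the same
        # anti-aliasing operator as the image, so "interior" voxels are ones
        # whose blurred intensity is single-class
        soft_native = soft_segmentation(coarse_on_scan, scan.voxel_size,
                                        bias_classes, sigma_mm=0.5)
        soft = {c: _downsample(m, scan.voxel_size, fit_res)[0]
                for c, m in soft_native.items()}
        if bf_order is None:
            fov_mm = float(np.max(np.asarray(scan.shape) * scan.voxel_size))
            bf_order = default_bf_order(fov_mm)
        basis = build_basis(fit_shape, bf_mode, bf_order)
        manifest["bf_order"] = bf_order
        bias_model, _, bounds = fit_bias_single_mstep(logv_fit, soft, basis,
                                                      mask_fit > 0.5)
        bias_field = bias_model.field(scan.shape)
        corrected = correct_image(scan.voxels, bias_field, mask)
        manifest["bias_alternations"] = len(bounds)
    corrected_img = ImageVolume(corrected, scan.affine, mask)
    _done("bias")

    # ---- robust statistics + contrast synthesis -----------------------------
    _stage("synthesis")
    coarse_scan = CoarseSegmentation(coarse_on_scan, scan.affine,
                                     dict(coarse.protocol))
    stats = robust_stats(corrected_img, coarse_scan, mask)
    class_means, class_stds = class_means_from_recipe(stats, recipe, grouping.classes)
    class_maps = group_probabilities(atlas, grouping)
    synthetic = synthesize_volume(class_maps, class_means, atlas.affine)
    synthetic = match_resolution(synthetic, scan.voxel_size)
    _done("synthesis")

    # ---- affine + nonlinear registration ------------------------------------
    _stage("registration")
    protocol_ids = sorted(set(atlas_to_protocol.values()))
    atlas_protocol_maps: dict[int, np.ndarray] = {}
    for lid, pid in atlas_to_protocol.items():
        m = atlas.dense_map(lid)
        atlas_protocol_maps[pid] = atlas_protocol_maps.get(pid, 0) + m
    init_affine = affine_initialize(atlas_protocol_maps, atlas.affine,
                                    coarse.labels, coarse.affine)
    # one-hot protocol targets, blurred by ~1 voxel to match the softness of
    # the atlas label maps so the Dice optimum sits at alignment rather than
    # at boundary compression
    from scipy.ndimage import gaussian_filter
    fixed_label_maps = {pid: gaussian_filter(
        resample_to_grid((coarse.labels == pid).astype(float), coarse.affine,
                         scan.shape, scan.affine, order=1), 1.0, mode="nearest")
        for pid in protocol_ids}
    deformation, reg_diag = run_multiscale_registration(
        corrected_img, synthetic, atlas_protocol_maps, fixed_label_maps,
        init_affine, reg_config, verbose=verbose)
    manifest["registration"] = {k: v for k, v in reg_diag.items()
                                if k != "loss_histories"}
    _done("registration")

    # ---- EM at the working resolution ---------------------------------------
    _stage("em")
    res = resolution if resolution is not None else working_resolution(mode, scan_res)
    work_shape, work_affine = _working_grid(scan, res)
    log_corr = np.log(np.maximum(corrected, 1e-30))
    log_work = resample_to_grid(np.where(mask, log_corr, 0.0), scan.affine,
                                work_shape, work_affine, order=1)
    mask_work = resample_to_grid(mask.astype(float), scan.affine, work_shape,
                                 work_affine, order=1) > 0.5

    coords = deformation.atlas_coordinates(work_shape, work_affine, atlas.affine)
    class_warped = resample_probability_maps(class_maps, coords)
    roi_maps = {d.label_id: atlas.dense_map(d.label_id) for d, _, _ in atlas.rois}
    roi_warped = resample_probability_maps(roi_maps, coords)

    fg = np.zeros(work_shape)
    for c in grouping.classes:
        fg += class_warped[c]
    em_mask = mask_work & (fg > EM_PRIOR_FLOOR)
    priors = {c: np.where(fg > EM_PRIOR_FLOOR,
                          class_warped[c] / np.maximum(fg, 1e-12), 0.0)
              for c in grouping.classes}

    init = init_params_from_stats(class_means, class_stds, grouping)
    params, resp, ll_history = fit_gmm_em(log_work, priors, init, em_mask, skip=skip)
    fine = redistribute_posteriors(resp, roi_warped, grouping)
    hard = hard_segmentation(fine, em_mask)
    names = {d.label_id: d.name for d, _, _ in atlas.rois}
    volumes = roi_volumes(fine, res, names)
    _done("em")

    result = SegmentationResult(class_responsibilities=resp, fine_posteriors=fine,
                                hard_labels=hard, volume_table=volumes,
                                working_affine=np.asarray(work_affine),
                                params=params, ll_history=ll_history)
    manifest["em_iterations"] = len(ll_history)
    manifest["working_resolution_mm"] = res
    manifest["stage_seconds"] = {k: round(v, 3) for k, v in stage_times.items()}
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    manifest["config"] = {"skip": skip, "skip_bf": skip_bf, "bf_mode": bf_mode,
                          "smoothing_steps_HRmask": smoothing_steps_HRmask,
                          "optimizer_lr": reg_config.optimizer_lr,
                          "smooth_grad_sigma": reg_config.smooth_grad_sigma,
                          "smooth_warp_sigma": reg_config.smooth_warp_sigma,
                          "cc_kernel_size": reg_config.cc_kernel_size,
                          "rel_weight_labeldiff": reg_config.rel_weight_labeldiff}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(hard.astype(np.int16), work_affine),
                 str(out / "seg.nii.gz"))
        hard_native = np.rint(resample_to_grid(hard.astype(float), work_affine,
                                               scan.shape, scan.affine,
                                               order=0)).astype(np.int16)
        nib.save(nib.Nifti1Image(hard_native, scan.affine),
                 str(out / "seg_native.nii.gz"))
        volumes.to_csv(out / "volumes.csv", index=False)
        if write_bias_corrected and bias_field is not None:
            corrected_img.to_nifti(out / "bias_corrected.nii.gz")
        if write_rgb:
            rgb = np.zeros(hard.shape + (3,), dtype=np.float32)
            for d, _, _ in atlas.rois:
                if d.label_id in fine:
                    p = np.asarray(fine[d.label_id], np.float32)
                    for ch in range(3):
                        rgb[..., ch] += p * d.color[ch]
            nib.save(nib.Nifti1Image(np.clip(rgb, 0, 255).astype(np.uint8),
                                     work_affine), str(out / "posteriors_rgb.nii.gz"))
        if save_field:
            field = np.moveaxis(deformation.displacement, 0, -1).astype(np.float32)
            nib.save(nib.Nifti1Image(field, scan.affine), str(out / "field.nii.gz"))
        if save_jacobian:
            logdet = jacobian_map(deformation.displacement, log10=True)
            nib.save(nib.Nifti1Image(logdet.astype(np.float32), scan.affine),
                     str(out / "jacobian_log10.nii.gz"))
        if save_atlas_nonlinear_reg:
            reg_atlas = np.zeros(work_shape, dtype=np.float32)
            for lid, m in roi_warped.items():
                reg_atlas = np.maximum(reg_atlas, m)
            nib.save(nib.Nifti1Image(reg_atlas, work_affine),
                     str(out / "atlas_registered_maxprob.nii.gz"))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result, {"manifest": manifest, "deformation": deformation,
                    "bias": bias_model, "stats": stats,
                    "class_means": class_means, "synthetic": synthetic,
                    "registration": reg_diag, "mask": mask}
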