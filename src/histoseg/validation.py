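"""Self-contained validation studies on phantom data.

Two experiments exercise the pipeline end to end under the generative model:

* :func:`phantom_end_to_end` — generate a phantom study (atlas, sampled scan,
  corrupted coarse segmentation), run the full segmentation pipeline at
  default settings, and measure recovery of every latent quantity: bias
  field, Gaussian parameters, deformation, fine-ROI segmentation.
* :func:`deformation_recovery` — the registration-only experiment: deform the
  phantom image by a known smooth diffeomorphic field and register the
  undeformed image (plus label maps) back to it with the composite
  LNCC + soft-Dice loss at default settings.
"""
from __future__ import annotations

import time

import numpy as np
from scipy.ndimage import map_coordinates

from .evaluation import dice_scores
from .phantom import (DEFAULT_GRID, DEFAULT_N_CLASSES, DEFAULT_N_ROIS,
                      corrupt_coarse_segmentation, make_phantom_atlas,
                      make_smooth_deformation, phantom_bias_grouping,
                      phantom_protocol, phantom_recipe, sample_image)
from .pipeline import segment
from .registration import RegistrationConfig, run_multiscale_registration
from .synthesis import IntensityRecipe
from .types import ImageVolume

LARGE_ROI_VOXELS = 500


def phantom_end_to_end(seed: int = 1, grid_shape=DEFAULT_GRID,
                       n_rois: int = DEFAULT_N_ROIS,
                       n_classes: int = DEFAULT_N_CLASSES,
                       error_rate: float = 0.05, skip: int = 1,
                       skip_bf: bool = False, verbose: bool = False) -> dict:
    """Full-pipeline recovery study at the phantom's native resolution.

    Returns a dict of scalar metrics: worst relative errors of recovered
    class means/stds, correlation of the recovered log-bias field with the
    truth, mean endpoint error of the recovered total deformation, fraction
    of positive Jacobians, mean Dice over large ROIs, EM monotonicity, and
    posterior-mass conservation.
    """
    seed = int(seed) % (2 ** 31)
    t0 = time.time()
    atlas, grouping = make_phantom_atlas(seed, grid_shape, n_rois, n_classes)
    image, truth = sample_image(atlas, grouping, seed=seed)
    roi_to_protocol, names = phantom_protocol(atlas)
    coarse = corrupt_coarse_segmentation(truth.true_labels, roi_to_protocol, names,
                                         error_rate=error_rate, seed=seed + 4,
                                         affine=atlas.affine)
    recipe = IntensityRecipe(phantom_recipe(atlas, grouping, names))
    bias_classes = phantom_bias_grouping(grouping, roi_to_protocol, names)

    result, extra = segment(image, coarse, atlas, grouping, recipe, bias_classes,
                            roi_to_protocol, resolution=float(atlas.resolution),
                            skip=skip, skip_bf=skip_bf, seed=seed, verbose=verbose)
    mask = image.mask

    # parameter recovery
    mean_errs, std_errs = [], []
    for c in grouping.classes:
        mt = truth.true_params.means[c][0]
        st = truth.true_params.stds[c][0]
        mean_errs.append(abs(result.params.means[c][0] - mt) / abs(mt))
        std_errs.append(abs(result.params.stds[c][0] - st) / st)

    # bias recovery (correlation of mean-free log fields inside the mask)
    if extra["bias"] is not None:
        rec = extra["bias"].field(image.shape)[mask]
        tru = truth.true_bias.field()[mask]
        bias_corr = float(np.corrcoef(rec - rec.mean(), tru - tru.mean())[0, 1])
    else:
        bias_corr = np.nan

    # deformation: recovered total mapping vs the generating field
    coords_rec = extra["deformation"].atlas_coordinates(image.shape, image.affine,
                                                        atlas.affine)
    coords_true = np.indices(image.shape, dtype=float) \
        + truth.true_deformation.displacement
    epe = np.sqrt(((coords_rec - coords_true) ** 2).sum(0))[mask]

    # EM diagnostics
    ll = np.asarray(result.ll_history)
    em_monotone = bool(np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1])))

    # conservation: fine posteriors sum back to class responsibilities
    cons_err = 0.0
    for c in grouping.classes:
        total = np.zeros(result.hard_labels.shape)
        present = False
        for lid in grouping.labels_of(c):
            if lid in result.fine_posteriors:
                total += result.fine_posteriors[lid]
                present = True
        if present:
            r = np.asarray(result.class_responsibilities[c])
            sel = total > 0
            if sel.any():
                cons_err = max(cons_err, float(np.abs(total - r)[sel].max()))

    dd = dice_scores(result.hard_labels, truth.true_labels)
    big = dd[dd.n_b > LARGE_ROI_VOXELS]

    return {
        "max_class_mean_rel_err": float(max(mean_errs)),
        "max_class_std_rel_err": float(max(std_errs)),
        "bias_field_correlation": bias_corr,
        "registration_mean_epe_voxels": float(epe.mean()),
        "jacobian_positive_fraction":
            float(extra["manifest"]["registration"]["jacobian_positive_fraction"]),
        "mean_dice_large_rois": float(big.dice.mean()),
        "n_large_rois": int(len(big)),
        "em_monotone": em_monotone,
        "em_iterations": len(ll),
        "posterior_conservation_max_err": cons_err,
        "elapsed_s": time.time() - t0,
        "result": result,
        "extra": extra,
        "truth": truth,
    }


def deformation_recovery(seed: int = 1, grid_shape=DEFAULT_GRID,
                         n_rois: int = DEFAULT_N_ROIS,
                         n_classes: int = DEFAULT_N_CLASSES,
                         max_displacement: float = 6.0,
                         config: RegistrationConfig | None = None) -> dict:
    """Register the phantom image to a known smooth deformation of itself.

    The fixed image is the sampled phantom image warped by a random smooth
    diffeomorphic field with the given maximum displacement; the moving side
    is the undeformed image plus the atlas protocol label maps.  Measures the
    mean endpoint error of the recovered field inside the brain.
    """
    seed = int(seed) % (2 ** 31)
    t0 = time.time()
    atlas, grouping = make_phantom_atlas(seed, grid_shape, n_rois, n_classes)
    image, truth = sample_image(atlas, grouping, seed=seed, max_displacement=1e-6)
    ut = make_smooth_deformation(seed + 7, atlas.grid_shape, max_displacement)
    idx = np.indices(atlas.grid_shape, dtype=float)
    fixed_vox = map_coordinates(image.voxels, idx + ut, order=1, mode="nearest")
    mask = map_coordinates((truth.true_labels > 0).astype(float), idx + ut,
                           order=1) > 0.5
    fixed = ImageVolume(fixed_vox, atlas.affine, mask=mask)
    moving = ImageVolume(image.voxels, atlas.affine)

    roi_to_protocol, _ = phantom_protocol(atlas)
    moving_maps: dict[int, np.ndarray] = {}
    for lid, pid in roi_to_protocol.items():
        moving_maps[pid] = moving_maps.get(pid, 0) + atlas.dense_map(lid)
    fixed_maps = {pid: map_coordinates(m, idx + ut, order=1)
                  for pid, m in moving_maps.items()}

    deformation, diag = run_multiscale_registration(
        fixed, moving, moving_maps, fixed_maps, np.eye(4),
        config or RegistrationConfig())
    epe = np.sqrt(((deformation.displacement - ut) ** 2).sum(0))[mask]
    return {
        "mean_epe_voxels": float(epe.mean()),
        "p95_epe_voxels": float(np.percentile(epe, 95)),
        "jacobian_positive_fraction": diag["jacobian_positive_fraction"],
        "max_displacement_voxels": float(max_displacement),
        "elapsed_s": time.time() - t0,
    }
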