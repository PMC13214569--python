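"""Target-contrast synthetic anatomical volume.

To register a probabilistic atlas to a scan of arbitrary contrast, the
pipeline first estimates robust per-structure intensity statistics from the
coarse segmentation (median for the mean, 1.4826 x MAD for the standard
deviation), maps them to the atlas tissue classes through a small set of
linear "recipe" rules, and renders the grouped atlas as a noise-free
expectation image at the scan's resolution.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .types import CoarseSegmentation, ImageVolume

MAD_SCALE = 1.4826           # makes the MAD consistent for a Gaussian sigma
MIN_STRUCTURE_VOXELS = 10
STD_FLOOR_FRACTION = 1e-4    # of the robust intensity range
FWHM_TO_SIGMA = 2.355        # FWHM = 2 sqrt(2 ln 2) sigma


@dataclass
class StructureStats:
    median: float
    std: float
    n_voxels: int
    usable: bool = True


def robust_stats(image: ImageVolume, coarse: CoarseSegmentation,
                 mask: np.ndarray | None = None) -> dict[str, StructureStats]:
    """Median / scaled-MAD intensity statistics per coarse-protocol structure.

    Structures with fewer than 10 voxels are flagged unusable; the std is
    floored at a small fraction of the robust intensity range so degenerate
    (constant) structures stay well-posed.
    """
    labels = coarse.labels
    if labels.shape != image.shape:
        raise ValueError("image and coarse segmentation must share a grid")
    valid = np.ones(image.shape, bool) if mask is None else mask
    vox = image.voxels
    inside = vox[valid & (labels > 0)]
    rng = (np.percentile(inside, 99) - np.percentile(inside, 1)) if inside.size else 1.0
    floor = STD_FLOOR_FRACTION * max(rng, 1e-12)

    out: dict[str, StructureStats] = {}
    for lid, name in coarse.protocol.items():
        vals = vox[valid & (labels == lid)]
        if vals.size < MIN_STRUCTURE_VOXELS:
            out[name] = StructureStats(np.nan, np.nan, int(vals.size), usable=False)
            continue
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        out[name] = StructureStats(med, max(MAD_SCALE * mad, floor), int(vals.size))
    return out


@dataclass
class IntensityRecipe:
    """Linear rules mapping structure statistics to tissue-class means.

    ``rules[class] = {structure_name: coefficient}``; coefficients normally
    sum to 1 but darkening/brightening rules may break that deliberately.
    """

    rules: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, classes: list[str], protocol_names: set[str]) -> None:
        for c in classes:
            if c not in self.rules:
                raise ValueError(f"no intensity rule for class {c!r}")
            unknown = set(self.rules[c]) - protocol_names
            if unknown:
                raise ValueError(f"rule for {c!r} references unknown structures {unknown}")


def class_means_from_recipe(stats: dict[str, StructureStats], recipe: IntensityRecipe,
                            classes: list[str]) -> tuple[dict[str, float], dict[str, float]]:
    """Apply the recipe; returns per-class (mean, std).

    Terms referencing unusable structures are dropped and their weight is
    redistributed proportionally over the remaining terms (with a warning);
    the class std is the absolute-coefficient-weighted average of structure
    stds, a deliberately conservative spread estimate.
    """
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for c in classes:
        rule = recipe.rules[c]
        usable = {s: a for s, a in rule.items() if stats.get(s) and stats[s].usable}
        if not usable:
            raise ValueError(f"rule for class {c!r} has no usable structure")
        if len(usable) < len(rule):
            dropped = set(rule) - set(usable)
            warnings.warn(f"class {c!r}: dropped unusable structures {sorted(dropped)}; "
                          "weight redistributed")
            scale = sum(rule.values()) / sum(usable.values()) \
                if abs(sum(usable.values())) > 1e-12 else 1.0
            usable = {s: a * scale for s, a in usable.items()}
        means[c] = float(sum(a * stats[s].median for s, a in usable.items()))
        wa = sum(abs(a) for a in usable.values())
        stds[c] = float(sum(abs(a) * stats[s].std for s, a in usable.items()) / max(wa, 1e-12))
    return means, stds


def synthesize_volume(class_maps: dict[str, np.ndarray], class_means: dict[str, float],
                      affine: np.ndarray, background_mean: float = 0.0) -> ImageVolume:
    """Noise-free expectation image of the grouped atlas.

    v(x) = sum_c p_c(x) mu_c + p_bg(x) mu_bg, with background mean 0 by
    default (the scan is skull-stripped and CSF shares the background class).
    """
    first = next(iter(class_maps.values()))
    out = np.zeros(first.shape, dtype=np.float64)
    total = np.zeros(first.shape, dtype=np.float64)
    for c, p in class_maps.items():
        out += np.asarray(p, dtype=np.float64) * class_means[c]
        total += p
    if background_mean != 0.0:
        out += np.clip(1.0 - total, 0.0, 1.0) * background_mean
    return ImageVolume(voxels=out, affine=affine)


def match_resolution(volume: ImageVolume, target_voxel_size) -> ImageVolume:
    """Resample to a coarser grid with an anti-aliasing Gaussian PSF.

    When downsampling along an axis the image is first blurred with a
    Gaussian whose FWHM equals the target spacing (sigma = spacing/2.355 in
    source units), then trilinearly resampled.  Upsampling passes through
    with interpolation only.
    """
    src = volume.voxel_size
    tgt = np.broadcast_to(np.asarray(target_voxel_size, dtype=float), (3,)).copy()
    if np.allclose(src, tgt, rtol=1e-6):
        return ImageVolume(volume.voxels.copy(), volume.affine.copy(),
                           None if volume.mask is None else volume.mask.copy())
    sigma_vox = np.where(tgt > src + 1e-9, (tgt / FWHM_TO_SIGMA) / src, 0.0)
    blurred = gaussian_filter(np.asarray(volume.voxels, dtype=float), sigma_vox,
                              mode="nearest")
    new_shape = tuple(max(1, int(round(volume.shape[ax] * src[ax] / tgt[ax])))
                      for ax in range(3))
    scale = np.array([src[ax] / tgt[ax] for ax in range(3)])
    # voxel-center alignment: target index i maps to source index (i+0.5)/scale-0.5
    idx = np.indices(new_shape, dtype=float)
    coords = (idx + 0.5) / scale.reshape(3, 1, 1, 1) - 0.5
    vals = map_coordinates(blurred, coords, order=1, mode="nearest")
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = volume.affine[:3, :3] / scale[None, :] * 1.0
    # keep voxel-center alignment of the first voxel
    shift = (0.5 / scale - 0.5)
    new_affine[:3, 3] = volume.affine[:3, :3] @ shift + volume.affine[:3, 3]
    return ImageVolume(voxels=vals, affine=new_affine)
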