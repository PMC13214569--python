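"""Synthetic phantom data: the test bed for the whole pipeline.

Generates (i) smooth multi-ROI probabilistic atlases (Gaussian-smoothed
Voronoi cells inside an ellipsoidal "brain"), (ii) images sampled from the
full generative model — categorical labels from the deformed atlas prior,
log-domain class Gaussians, a multiplicative bias field, a known smooth
diffeomorphic deformation — and (iii) degraded coarse segmentations with
controllable boundary label errors.  All randomness flows through explicit
seeds; regeneration from (seed, config) is bit-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .atlas import (LabelGrouping, ProbabilisticAtlas, ROIDescriptor, _tight_bbox,
                    resample_probability_maps, save_atlas)
from .bias import BiasFieldModel, build_basis
from .generative import GaussianParams
from .registration import Deformation, jacobian_map
from .types import CoarseSegmentation, ImageVolume

DEFAULT_GRID = (64, 64, 64)
DEFAULT_N_ROIS = 24
DEFAULT_N_CLASSES = 6
DEFAULT_VOXEL_MM = 1.0
DEFORMATION_SMOOTHING_VOXELS = 8.0
DEFAULT_MAX_DISPLACEMENT = 4.0   # voxels
DEFAULT_BIAS_AMPLITUDE = 0.15    # log units (~15% multiplicative inhomogeneity)
DEFAULT_ERROR_RATE = 0.05
ROI_SMOOTHING_VOXELS = 1.2       # ~1-voxel partial-volume transition, as at 1 mm
#: log-intensity class means/stds: MRI-like contrast (max ratio ~e ~ 2.7x)
DEFAULT_CLASS_MEANS = (3.6, 3.8, 4.0, 4.2, 4.4, 4.6)
DEFAULT_CLASS_STDS = (0.05, 0.045, 0.04, 0.04, 0.035, 0.035)


@dataclass
class PhantomTruth:
    atlas: ProbabilisticAtlas
    grouping: LabelGrouping
    true_params: GaussianParams
    true_bias: BiasFieldModel
    true_deformation: Deformation
    true_labels: np.ndarray
    seed: int


def make_phantom_atlas(seed: int, grid_shape=DEFAULT_GRID, n_rois: int = DEFAULT_N_ROIS,
                       n_classes: int = DEFAULT_N_CLASSES,
                       voxel_mm: float = DEFAULT_VOXEL_MM
                       ) -> tuple[ProbabilisticAtlas, LabelGrouping]:
    """Smooth blob-shaped ROI probability maps partitioned into tissue classes."""
    if not (n_rois >= n_classes >= 2):
        raise ValueError("need n_rois >= n_classes >= 2")
    grid_shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)
    shape = np.asarray(grid_shape, float)
    center = (shape - 1) / 2.0
    semi = 0.42 * shape
    idx = np.indices(grid_shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    brain = gaussian_filter((r2 <= 1.0).astype(float), 1.5, mode="constant")
    brain = np.clip(brain, 0.0, 1.0)

    # Voronoi seeds inside the ellipsoid (rejection sampling)
    seeds = []
    while len(seeds) < n_rois:
        p = rng.uniform(0, 1, 3) * (shape - 1)
        if sum(((p[a] - center[a]) / semi[a]) ** 2 for a in range(3)) < 0.7:
            seeds.append(p)
    seeds = np.asarray(seeds)
    d2 = np.stack([sum((idx[a] - s[a]) ** 2 for a in range(3)) for s in seeds])
    cell = np.argmin(d2, axis=0)

    smoothed = np.stack([gaussian_filter((cell == k).astype(float),
                                         ROI_SMOOTHING_VOXELS, mode="nearest")
                         for k in range(n_rois)])
    total = np.maximum(smoothed.sum(axis=0), 1e-12)
    probs = smoothed / total * brain[None]

    rois = []
    for k in range(n_rois):
        lid = k + 1
        color = tuple(int(c) for c in rng.integers(0, 256, 3))
        cls = f"class_{k % n_classes}"
        t = _tight_bbox(probs[k].astype(np.float32), np.zeros(3, dtype=int))
        assert t is not None
        rois.append((ROIDescriptor(lid, f"roi_{lid}", color, cls), t[0],
                     np.ascontiguousarray(t[1], dtype=np.float32)))

    affine = np.diag([voxel_mm] * 3 + [1.0])
    atlas = ProbabilisticAtlas(grid_shape, affine, voxel_mm, rois)
    atlas.validate()
    grouping = LabelGrouping(classes=[f"class_{c}" for c in range(n_classes)],
                             roi_to_class={k + 1: f"class_{k % n_classes}"
                                           for k in range(n_rois)},
                             components_per_class={f"class_{c}": 1
                                                   for c in range(n_classes)})
    return atlas, grouping


def default_phantom_params(grouping: LabelGrouping) -> GaussianParams:
    n = len(grouping.classes)
    means = {c: np.array([DEFAULT_CLASS_MEANS[i % len(DEFAULT_CLASS_MEANS)]])
             for i, c in enumerate(grouping.classes)}
    stds = {c: np.array([DEFAULT_CLASS_STDS[i % len(DEFAULT_CLASS_STDS)]])
            for i, c in enumerate(grouping.classes)}
    weights = {c: np.array([1.0]) for c in grouping.classes}
    return GaussianParams(list(grouping.classes), weights, means, stds)


def make_smooth_deformation(seed: int, grid_shape, max_displacement: float
                            ) -> np.ndarray:
    """White-noise vector field smoothed with sigma=8 voxels, scaled to the
    requested maximum displacement magnitude."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((3, *grid_shape))
    u = np.stack([gaussian_filter(u[c], DEFORMATION_SMOOTHING_VOXELS, mode="constant")
                  for c in range(3)])
    mag = np.sqrt((u ** 2).sum(axis=0)).max()
    return u * (max_displacement / max(mag, 1e-12))


def true_bias_model(seed: int, grid_shape, amplitude: float = DEFAULT_BIAS_AMPLITUDE,
                    order: int = 2) -> BiasFieldModel:
    """Random low-order DCT bias field with zero DC mode, scaled to +/- amplitude."""
    rng = np.random.default_rng(seed)
    basis = build_basis(grid_shape, "dct", order)
    coeff = rng.standard_normal(basis.n_functions)
    coeff[0] = 0.0
    field = basis.field(coeff)
    peak = np.abs(field).max()
    return BiasFieldModel(basis, coeff * (amplitude / max(peak, 1e-12)))


def sample_image(atlas: ProbabilisticAtlas, grouping: LabelGrouping,
                 params: GaussianParams | None = None,
                 bias: BiasFieldModel | None = None,
                 max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
                 seed: int = 0) -> tuple[ImageVolume, PhantomTruth]:
    """Draw one image from the generative model under a known deformation.

    Labels are sampled from the deformed atlas's categorical prior (background
    takes the residual mass), log-intensities from the label's class mixture,
    the bias is added in the log domain, and the result exponentiated.
    Background voxels are set to zero (masked out downstream).
    """
    params = params or default_phantom_params(grouping)
    bias = bias if bias is not None else true_bias_model(seed + 1, atlas.grid_shape)
    u = make_smooth_deformation(seed + 2, atlas.grid_shape, max_displacement)
    det = jacobian_map(u)
    if det.min() <= 0:
        raise ValueError("requested deformation is not diffeomorphic "
                         f"(min Jacobian {det.min():.3f})")

    idx = np.indices(atlas.grid_shape, dtype=float)
    coords = idx + u
    roi_maps = {d.label_id: atlas.dense_map(d.label_id) for d, _, _ in atlas.rois}
    warped = resample_probability_maps(roi_maps, coords)

    rng = np.random.default_rng(seed + 3)
    lids = sorted(warped)
    stackp = np.stack([np.asarray(warped[k], np.float64) for k in lids])
    cum = np.cumsum(stackp, axis=0)
    uvar = rng.uniform(0, 1, atlas.grid_shape)
    labels = np.zeros(atlas.grid_shape, dtype=np.int32)
    chosen = np.zeros(atlas.grid_shape, dtype=bool)
    for i, k in enumerate(lids):
        sel = (~chosen) & (uvar < cum[i])
        labels[sel] = k
        chosen |= sel

    logx = np.zeros(atlas.grid_shape)
    for k in lids:
        sel = labels == k
        if not sel.any():
            continue
        c = grouping.roi_to_class[k]
        w, mu, sd = params.weights[c], params.means[c], params.stds[c]
        comp = rng.choice(len(w), size=int(sel.sum()), p=w / w.sum())
        logx[sel] = mu[comp] + sd[comp] * rng.standard_normal(int(sel.sum()))
    logx += bias.field()
    vox = np.where(labels > 0, np.exp(logx), 0.0)

    image = ImageVolume(voxels=vox, affine=atlas.affine.copy(), mask=labels > 0)
    deformation = Deformation(pre_affine=np.eye(4), displacement=u,
                              fixed_affine=atlas.affine.copy())
    truth = PhantomTruth(atlas=atlas, grouping=grouping, true_params=params,
                         true_bias=bias, true_deformation=deformation,
                         true_labels=labels, seed=seed)
    return image, truth


def corrupt_coarse_segmentation(true_labels: np.ndarray, roi_to_protocol: dict[int, int],
                                protocol_names: dict[int, str],
                                error_rate: float = DEFAULT_ERROR_RATE, seed: int = 0,
                                affine: np.ndarray | None = None,
                                downsample: int = 1) -> CoarseSegmentation:
    """Protocol-level projection of the true labels with boundary label noise.

    A fraction ``error_rate`` of boundary voxels (those with a 6-neighbour of
    a different label) is flipped to a random differing neighbour's label;
    deterministic per seed.
    """
    if not 0.0 <= error_rate <= 0.3:
        raise ValueError("error_rate must be in [0, 0.3]")
    lut = np.zeros(int(true_labels.max()) + 1, dtype=np.int32)
    for roi, prot in roi_to_protocol.items():
        lut[roi] = prot
    lab = lut[true_labels]
    affine = np.eye(4) if affine is None else np.asarray(affine, float)
    if downsample > 1:
        lab = lab[::downsample, ::downsample, ::downsample]
        A = affine.copy()
        A[:3, :3] *= downsample
        affine = A

    rng = np.random.default_rng(seed)
    boundary = np.zeros(lab.shape, bool)
    neighbours = []
    for ax in range(3):
        for sh in (1, -1):
            n = np.roll(lab, sh, axis=ax)
            # roll wraps; suppress the wrapped face
            sl = [slice(None)] * 3
            sl[ax] = 0 if sh == 1 else -1
            n[tuple(sl)] = lab[tuple(sl)]
            neighbours.append(n)
            boundary |= n != lab
    out = lab.copy()
    if error_rate > 0 and boundary.any():
        bidx = np.flatnonzero(boundary.ravel())
        flip = bidx[rng.uniform(0, 1, bidx.size) < error_rate]
        nstack = np.stack([n.ravel()[flip] for n in neighbours])  # (6, n_flip)
        cur = lab.ravel()[flip]
        pick = np.full(flip.size, -1, dtype=np.int64)
        order = rng.integers(0, 6, size=(flip.size,))
        for off in range(6):
            cand = nstack[(order + off) % 6, np.arange(flip.size)]
            pick = np.where((pick < 0) & (cand != cur), cand, pick)
        ok = pick >= 0
        flat = out.ravel()
        flat[flip[ok]] = pick[ok]
        out = flat.reshape(lab.shape)
    return CoarseSegmentation(labels=out, affine=affine, protocol=dict(protocol_names))


# ---------------------------------------------------------------------------
# complete on-disk study

def phantom_protocol(atlas: ProbabilisticAtlas) -> tuple[dict[int, int], dict[int, str]]:
    """One protocol structure per ROI (identity mapping)."""
    roi_to_protocol = {lid: lid for lid in atlas.label_ids}
    names = {lid: f"struct_{lid}" for lid in atlas.label_ids}
    return roi_to_protocol, names


def phantom_recipe(atlas: ProbabilisticAtlas, grouping: LabelGrouping,
                   protocol_names: dict[int, str]) -> dict[str, dict[str, float]]:
    """Identity-style recipe: each class averages the structures of its ROIs."""
    rules: dict[str, dict[str, float]] = {}
    for c in grouping.classes:
        lids = grouping.labels_of(c)
        rules[c] = {protocol_names[lid]: 1.0 / len(lids) for lid in lids}
    return rules


def phantom_bias_grouping(grouping: LabelGrouping,
                          roi_to_protocol: dict[int, int],
                          protocol_names: dict[int, str]) -> dict[str, list[int]]:
    """Bias-estimation classes: the intensity classes, in protocol label ids."""
    return {c: sorted(roi_to_protocol[lid] for lid in grouping.labels_of(c))
            for c in grouping.classes}


def write_fixture(path, seed: int = 0, grid_shape=DEFAULT_GRID,
                  n_rois: int = DEFAULT_N_ROIS, n_classes: int = DEFAULT_N_CLASSES,
                  max_displacement: float = DEFAULT_MAX_DISPLACEMENT,
                  error_rate: float = DEFAULT_ERROR_RATE) -> dict:
    """Emit a complete on-disk test case: atlas dir, scan, coarse seg, YAMLs, truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    atlas, grouping = make_phantom_atlas(seed, grid_shape, n_rois, n_classes)
    image, truth = sample_image(atlas, grouping, max_displacement=max_displacement,
                                seed=seed)
    roi_to_protocol, names = phantom_protocol(atlas)
    coarse = corrupt_coarse_segmentation(truth.true_labels, roi_to_protocol, names,
                                         error_rate=error_rate, seed=seed + 4,
                                         affine=atlas.affine)
    save_atlas(atlas, path / "atlas")
    image.to_nifti(path / "scan.nii.gz")
    coarse.to_nifti(path / "coarse_seg.nii.gz")

    ydir = path / "yaml"
    ydir.mkdir(exist_ok=True)
    (ydir / "combined_atlas_labels_fireants.yaml").write_text(yaml.safe_dump(
        {c: grouping.labels_of(c) for c in grouping.classes}))
    (ydir / "gmm_components_fireants.yaml").write_text(yaml.safe_dump(
        dict(grouping.components_per_class)))
    (ydir / "recipe_intensities_cheating_image_fireants.yaml").write_text(yaml.safe_dump(
        phantom_recipe(atlas, grouping, names)))
    (ydir / "protocol.yaml").write_text(yaml.safe_dump({
        "names": {int(k): v for k, v in names.items()},
        "atlas_to_protocol": {int(k): int(v) for k, v in roi_to_protocol.items()},
        "brain_label_ids": [int(k) for k in sorted(names)],
        "bias_classes": phantom_bias_grouping(grouping, roi_to_protocol, names)}))

    (path / "truth.json").write_text(json.dumps({
        "seed": seed, "grid_shape": list(grid_shape), "n_rois": n_rois,
        "n_classes": n_classes, "max_displacement": max_displacement,
        "error_rate": error_rate,
        "class_means": {c: truth.true_params.means[c].tolist()
                        for c in grouping.classes},
        "class_stds": {c: truth.true_params.stds[c].tolist()
                       for c in grouping.classes}}, indent=1))
    return {"atlas": atlas, "grouping": grouping, "image": image, "truth": truth,
            "coarse": coarse, "path": path}
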