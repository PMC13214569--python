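"""Probabilistic atlas model and sparse bounding-box storage.

The atlas assigns each voxel a categorical distribution over anatomical ROIs;
the residual probability (1 minus the foreground sum) is background and is
never stored.  Each ROI is kept only inside a tight bounding box, which makes
deformation and posterior computations cheap for atlases with hundreds of
small structures.

On-disk layout (one directory per atlas)::

    atlas.json                 grid shape, affine, resolution
    labels.csv                 header "id,name,R,G,B,class"
    roi_<id>.nii.gz            float32 probability sub-volume inside the box
    roi_<id>.json              {"label_id": id, "bbox": [xlo,xhi,ylo,yhi,zlo,zhi]}

Boxes are half-open ``[lo, hi)`` in 0-based voxel indices and re-tightened on
load so that zero-padded inputs normalise to the canonical representation.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

PROB_SUM_TOL = 1e-6


class AtlasFormatError(RuntimeError):
    """Malformed atlas directory (missing sidecar, bad table...)."""


class AtlasValidationError(ValueError):
    """Atlas content violates a model invariant."""


@dataclass(frozen=True)
class ROIDescriptor:
    label_id: int
    name: str
    color: tuple[int, int, int] = (128, 128, 128)
    tissue_class: str = ""

    def __post_init__(self):
        if self.label_id < 1:
            raise AtlasValidationError("label_id must be >= 1")
        if any(c < 0 or c > 255 for c in self.color):
            raise AtlasValidationError("color components must be in [0, 255]")


@dataclass
class LabelGrouping:
    """Partition of atlas ROIs into tissue classes with GMM component counts."""

    classes: list[str]
    roi_to_class: dict[int, str]
    components_per_class: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.classes:
            raise AtlasValidationError("class list is empty")
        for lid, cls in self.roi_to_class.items():
            if cls not in self.classes:
                raise AtlasValidationError(f"label {lid} mapped to unknown class {cls!r}")
        for cls in self.classes:
            n = self.components_per_class.setdefault(cls, 1)
            if n < 1:
                raise AtlasValidationError("component counts must be >= 1")

    def labels_of(self, cls: str) -> list[int]:
        return sorted(k for k, v in self.roi_to_class.items() if v == cls)


def _tight_bbox(vol: np.ndarray, offset: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Crop to the nonzero extent; returns (bbox, cropped) or None if all zero."""
    nz = np.nonzero(vol)
    if nz[0].size == 0:
        return None
    lo = np.array([a.min() for a in nz])
    hi = np.array([a.max() + 1 for a in nz])
    box = np.empty(6, dtype=int)
    box[0::2] = offset + lo
    box[1::2] = offset + hi
    return box, vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


@dataclass
class ProbabilisticAtlas:
    """Sparse per-ROI probability maps on a common grid."""

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    resolution: float
    rois: list[tuple[ROIDescriptor, np.ndarray, np.ndarray]]  # (descriptor, bbox6, probs)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        ids = [d.label_id for d, _, _ in self.rois]
        if len(ids) != len(set(ids)):
            raise AtlasValidationError("duplicate label_ids")
        self.rois.sort(key=lambda r: r[0].label_id)

    @property
    def label_ids(self) -> list[int]:
        return [d.label_id for d, _, _ in self.rois]

    def descriptor(self, label_id: int) -> ROIDescriptor:
        for d, _, _ in self.rois:
            if d.label_id == label_id:
                return d
        raise KeyError(label_id)

    def dense_map(self, label_id: int) -> np.ndarray:
        """Full-grid float32 probability map of one ROI."""
        for d, box, probs in self.rois:
            if d.label_id == label_id:
                out = np.zeros(self.grid_shape, dtype=np.float32)
                out[box[0]:box[1], box[2]:box[3], box[4]:box[5]] = probs
                return out
        raise KeyError(label_id)

    def foreground_sum(self) -> np.ndarray:
        """Per-voxel sum of all ROI probabilities (background = 1 - this)."""
        out = np.zeros(self.grid_shape, dtype=np.float64)
        for _, box, probs in self.rois:
            out[box[0]:box[1], box[2]:box[3], box[4]:box[5]] += probs
        return out

    def validate(self) -> None:
        for d, box, probs in self.rois:
            if probs.min() < -PROB_SUM_TOL or probs.max() > 1 + PROB_SUM_TOL:
                raise AtlasValidationError(f"ROI {d.label_id}: probabilities outside [0, 1]")
            if np.any(box[0::2] < 0) or np.any(box[1::2] > np.array(self.grid_shape)):
                raise AtlasValidationError(f"ROI {d.label_id}: box outside grid")
        s = self.foreground_sum()
        if s.max() > 1 + PROB_SUM_TOL:
            raise AtlasValidationError(f"per-voxel probability sum exceeds 1: {s.max():.8f}")

    def tighten(self) -> "ProbabilisticAtlas":
        """Re-crop every box to the minimal nonzero extent."""
        rois = []
        for d, box, probs in self.rois:
            t = _tight_bbox(np.asarray(probs), box[0::2])
            if t is None:  # keep zero-mass ROIs as degenerate 1-voxel boxes
                rois.append((d, np.array([box[0], box[0] + 1, box[2], box[2] + 1,
                                          box[4], box[4] + 1]),
                             np.zeros((1, 1, 1), dtype=np.float32)))
            else:
                rois.append((d, t[0], np.ascontiguousarray(t[1], dtype=np.float32)))
        return ProbabilisticAtlas(self.grid_shape, self.affine, self.resolution, rois)


def save_atlas(atlas: ProbabilisticAtlas, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"grid_shape": list(atlas.grid_shape),
            "affine": np.asarray(atlas.affine).tolist(),
            "resolution": atlas.resolution}
    (path / "atlas.json").write_text(json.dumps(meta, indent=1))
    with open(path / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "name", "R", "G", "B", "class"])
        for d, _, _ in atlas.rois:
            w.writerow([d.label_id, d.name, *d.color, d.tissue_class])
    for d, box, probs in atlas.rois:
        nib.save(nib.Nifti1Image(np.asarray(probs, dtype=np.float32), np.eye(4)),
                 str(path / f"roi_{d.label_id}.nii.gz"))
        (path / f"roi_{d.label_id}.json").write_text(
            json.dumps({"label_id": int(d.label_id), "bbox": [int(b) for b in box]}))


def load_atlas(path) -> ProbabilisticAtlas:
    path = Path(path)
    try:
        meta = json.loads((path / "atlas.json").read_text())
    except FileNotFoundError as e:
        raise AtlasFormatError(f"missing atlas.json in {path}") from e
    rois = []
    with open(path / "labels.csv") as fh:
        for row in csv.DictReader(fh):
            lid = int(row["id"])
            d = ROIDescriptor(lid, row["name"],
                              (int(row["R"]), int(row["G"]), int(row["B"])),
                              row["class"])
            sidecar = path / f"roi_{lid}.json"
            if not sidecar.exists():
                raise AtlasFormatError(f"missing sidecar {sidecar.name}")
            box = np.asarray(json.loads(sidecar.read_text())["bbox"], dtype=int)
            probs = np.asarray(nib.load(str(path / f"roi_{lid}.nii.gz")).dataobj,
                               dtype=np.float32)
            if probs.min() < 0 or probs.max() > 1 + PROB_SUM_TOL:
                raise AtlasValidationError(f"ROI {lid}: probabilities outside [0, 1]")
            rois.append((d, box, probs))
    atlas = ProbabilisticAtlas(tuple(meta["grid_shape"]), np.asarray(meta["affine"]),
                               float(meta["resolution"]), rois).tighten()
    atlas.validate()
    return atlas


def remove_and_inpaint(atlas: ProbabilisticAtlas, removed: set[int]) -> ProbabilisticAtlas:
    """Delete ROIs and hand their probability mass to nearby survivors.

    At every voxel where a removed ROI carried mass, that mass is added to the
    surviving ROI that is the modal (argmax) label of the nearest voxel whose
    modal label survives (Euclidean distance on the atlas grid, ties resolved
    by the lowest surviving label_id).  Total per-voxel mass is conserved.
    """
    removed = set(removed)
    keep = [r for r in atlas.rois if r[0].label_id not in removed]
    if not keep:
        raise AtlasValidationError("cannot remove all ROIs")
    unknown = removed - set(atlas.label_ids)
    if unknown:
        raise AtlasValidationError(f"labels not in atlas: {sorted(unknown)}")

    removed_mass = np.zeros(atlas.grid_shape, dtype=np.float64)
    for d, box, probs in atlas.rois:
        if d.label_id in removed:
            removed_mass[box[0]:box[1], box[2]:box[3], box[4]:box[5]] += probs
    if removed_mass.max() <= 0:
        return ProbabilisticAtlas(atlas.grid_shape, atlas.affine, atlas.resolution,
                                  [(d, box.copy(), probs.copy()) for d, box, probs in keep])

    # modal label per voxel over all ROIs (background where no ROI has mass)
    best_p = np.zeros(atlas.grid_shape, dtype=np.float32)
    best_l = np.zeros(atlas.grid_shape, dtype=np.int32)
    for d, box, probs in atlas.rois:  # sorted by id: strict > keeps lowest id on ties
        sl = (slice(box[0], box[1]), slice(box[2], box[3]), slice(box[4], box[5]))
        upd = probs > best_p[sl]
        best_p[sl][upd] = probs[upd]
        best_l[sl][upd] = d.label_id
    surviving_ids = [d.label_id for d, _, _ in keep]

    # nearest survivor label with lowest-id tie-break: one EDT per survivor
    vs = atlas.resolution
    best_dist = np.full(atlas.grid_shape, np.inf)
    nearest = np.zeros(atlas.grid_shape, dtype=np.int32)
    for lid in surviving_ids:
        seed = best_l == lid
        if not seed.any():
            continue
        dist = distance_transform_edt(~seed, sampling=vs)
        upd = dist < best_dist - 1e-9  # strict: earlier (lower) id wins ties
        best_dist[upd] = dist[upd]
        nearest[upd] = lid
    unreachable = ~np.isfinite(best_dist) & (removed_mass > 0)
    if unreachable.any():
        # no voxel's modal label survives: give the mass to the survivor with
        # the largest local probability (lowest id on ties)
        sbest_p = np.full(atlas.grid_shape, -1.0, dtype=np.float32)
        sbest_l = np.full(atlas.grid_shape, surviving_ids[0], dtype=np.int32)
        for d, box, probs in keep:
            sl = (slice(box[0], box[1]), slice(box[2], box[3]), slice(box[4], box[5]))
            upd = probs > sbest_p[sl]
            sbest_p[sl][upd] = probs[upd]
            sbest_l[sl][upd] = d.label_id
        nearest[unreachable] = sbest_l[unreachable]
        best_dist[unreachable] = 0.0

    dense = {lid: atlas.dense_map(lid).astype(np.float64) for lid in surviving_ids}
    for lid in surviving_ids:
        gain = (nearest == lid) & (removed_mass > 0)
        if gain.any():
            dense[lid][gain] += removed_mass[gain]
    rois = []
    for d, _, _ in keep:
        vol = dense[d.label_id]
        t = _tight_bbox(vol, np.zeros(3, dtype=int))
        if t is None:
            rois.append((d, np.array([0, 1, 0, 1, 0, 1]), np.zeros((1, 1, 1), np.float32)))
        else:
            rois.append((d, t[0], np.ascontiguousarray(t[1], dtype=np.float32)))
    out = ProbabilisticAtlas(atlas.grid_shape, atlas.affine, atlas.resolution, rois)
    out.validate()
    return out


def group_probabilities(atlas: ProbabilisticAtlas,
                        grouping: LabelGrouping) -> dict[str, np.ndarray]:
    """Voxelwise sum of ROI maps per tissue class (dense full-grid maps)."""
    missing = set(atlas.label_ids) - set(grouping.roi_to_class)
    if missing:
        raise AtlasValidationError(f"labels without a tissue class: {sorted(missing)}")
    maps = {c: np.zeros(atlas.grid_shape, dtype=np.float32) for c in grouping.classes}
    for d, box, probs in atlas.rois:
        maps[grouping.roi_to_class[d.label_id]][
            box[0]:box[1], box[2]:box[3], box[4]:box[5]] += probs
    return maps


def resample_probability_maps(maps: dict[str, np.ndarray] | list[np.ndarray],
                              coords: np.ndarray) -> dict[str, np.ndarray] | list[np.ndarray]:
    """Trilinearly sample probability maps at atlas-grid voxel coordinates.

    ``coords`` has shape (3, *target_shape); samples outside the atlas get 0.
    Per-voxel sums are renormalised only where they exceed 1, preserving
    partial-volume semantics at the brain edge.
    """
    if not np.isfinite(coords).all():
        raise ValueError("non-finite deformation coordinates")
    items = maps.items() if isinstance(maps, dict) else enumerate(maps)
    out: dict | list = {} if isinstance(maps, dict) else [None] * len(maps)
    total = np.zeros(coords.shape[1:], dtype=np.float64)
    for key, m in items:
        w = map_coordinates(np.asarray(m, dtype=np.float32), coords, order=1,
                            mode="constant", cval=0.0)
        out[key] = w
        total += w
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-12), 1.0)
    keys = out.keys() if isinstance(out, dict) else range(len(out))
    for key in keys:
        out[key] = (out[key] * scale).astype(np.float32)
    return out


def resample_atlas(atlas: ProbabilisticAtlas, deformation, target_shape,
                   target_affine) -> dict[int, np.ndarray]:
    """Warp every ROI map of the atlas onto a target grid.

    ``deformation`` is a :class:`histoseg.registration.Deformation` mapping
    target-grid coordinates into atlas coordinates.
    """
    coords = deformation.atlas_coordinates(target_shape, target_affine, atlas.affine)
    maps = {d.label_id: atlas.dense_map(d.label_id) for d, _, _ in atlas.rois}
    return resample_probability_maps(maps, coords)  # type: ignore[return-value]
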