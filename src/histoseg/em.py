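"""Final EM over grouped tissue classes and redistribution to fine ROIs.

With the bias field and the atlas deformation fixed, the Gaussian mixture
parameters of the grouped tissue classes are the only unknowns left, so the
lower bound can be maximised globally at each iteration (plain EM, not GEM).
The E-step responsibilities at convergence give a probabilistic segmentation
into tissue classes; probability mass is then redistributed to each class's
constituent ROIs in proportion to the warped atlas, yielding fine-grained
posteriors, hard labels and a soft-volume table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .atlas import LabelGrouping
from .generative import GaussianParams, gmm_log_likelihood

EM_REL_TOL = 1e-5
EM_MAX_ITER = 100
MIN_CLASS_RESP = 10.0      # voxels; below this a class is frozen at init
VAR_FLOOR_FRACTION = 1e-4  # of the squared robust intensity range
COMPONENT_SPLIT = 0.5      # components seeded at mean +/- 0.5 std

#: default working resolutions (mm): in vivo fixed; ex vivo capped by the scan
WORKING_RESOLUTION_INVIVO = 0.4
WORKING_RESOLUTION_EXVIVO = 0.2


def working_resolution(mode: str, scan_resolution_mm: float) -> float:
    if mode == "exvivo":
        return min(WORKING_RESOLUTION_EXVIVO, scan_resolution_mm)
    return WORKING_RESOLUTION_INVIVO


def init_params_from_stats(class_means: dict[str, float], class_stds: dict[str, float],
                           grouping: LabelGrouping, log_domain: bool = True
                           ) -> GaussianParams:
    """Seed the mixture from robust class statistics.

    Intensity-domain medians/MADs map to log-domain as mu = log(median),
    sigma = mad/median (delta method).  Multi-component classes split the
    seed mean at +/- 0.5 sigma with equal weights.
    """
    weights, means, stds = {}, {}, {}
    for c in grouping.classes:
        n = grouping.components_per_class[c]
        m, s = class_means[c], class_stds[c]
        if log_domain:
            m_log = np.log(max(m, 1e-12))
            s_log = max(s / max(m, 1e-12), 1e-4)
        else:
            m_log, s_log = m, max(s, 1e-6)
        if n == 1:
            mus = np.array([m_log])
        else:
            mus = m_log + COMPONENT_SPLIT * s_log * np.linspace(-1, 1, n)
        weights[c] = np.full(n, 1.0 / n)
        means[c] = mus
        stds[c] = np.full(n, s_log)
    return GaussianParams(list(grouping.classes), weights, means, stds)


def fit_gmm_em(log_image: np.ndarray, class_priors: dict[str, np.ndarray],
               init: GaussianParams, mask: np.ndarray | None = None,
               bias: np.ndarray | None = None, skip: int = 1,
               max_iter: int = EM_MAX_ITER):
    """EM for the grouped-class GMM with fixed priors and bias.

    ``skip`` subsamples voxels by that stride per axis for the M-step only
    (the final E-step always runs on the full grid).  Returns ``(params,
    responsibilities, ll_history)`` with the history of mean log-likelihoods
    (non-decreasing up to numerical tolerance).
    """
    if skip < 1:
        raise ValueError("skip must be >= 1")
    shape = log_image.shape
    mask = np.ones(shape, bool) if mask is None else mask
    params = init.copy()
    classes = params.classes

    sub = (slice(None, None, skip),) * 3
    x_sub = (log_image - (0.0 if bias is None else bias))[sub]
    mask_sub = mask[sub]
    xs = x_sub[mask_sub]
    priors_sub = {c: np.asarray(class_priors[c], float)[sub][mask_sub] for c in classes}
    rng = max(np.percentile(xs, 99) - np.percentile(xs, 1), 1e-9)
    var_floor = VAR_FLOOR_FRACTION * rng ** 2

    history: list[float] = []
    for _ in range(max_iter):
        # E-step on the subsampled grid: per-component responsibilities
        comp_logp = {}
        vox_ll = np.full(xs.shape, -np.inf)
        stack = []
        keys = []
        for c in classes:
            w, mu, sd = params.weights[c], params.means[c], params.stds[c]
            lp = (np.log(np.maximum(priors_sub[c], 1e-300))[None, :]
                  + np.log(np.maximum(w, 1e-300))[:, None]
                  - 0.5 * np.log(2 * np.pi) - np.log(sd)[:, None]
                  - 0.5 * ((xs[None, :] - mu[:, None]) / sd[:, None]) ** 2)
            lp[:, priors_sub[c] <= 0] = -np.inf
            comp_logp[c] = lp
            stack.append(lp)
            keys.append(c)
        all_lp = np.concatenate(stack, axis=0)
        vox_ll = logsumexp(all_lp, axis=0)
        valid = np.isfinite(vox_ll)
        mean_ll = float(vox_ll[valid].mean()) if valid.any() else -np.inf
        history.append(mean_ll)

        # M-step: closed-form weighted moments per component
        for c in classes:
            r = np.exp(comp_logp[c] - vox_ll[None, :])
            r[:, ~valid] = 0.0
            n_cm = r.sum(axis=1)
            n_c = n_cm.sum()
            if n_c < MIN_CLASS_RESP:
                warnings.warn(f"class {c!r}: responsibility mass {n_c:.1f} voxels; "
                              "frozen at init")
                continue
            mu = (r @ xs) / np.maximum(n_cm, 1e-12)
            var = np.maximum((r @ xs ** 2) / np.maximum(n_cm, 1e-12) - mu ** 2, var_floor)
            params.weights[c] = n_cm / n_c
            params.means[c] = mu
            params.stds[c] = np.sqrt(var)

        if len(history) >= 2:
            prev = history[-2]
            if abs(history[-1] - prev) < EM_REL_TOL * max(abs(prev), 1e-12):
                break

    # final E-step at the full working grid
    _, resp, _ = gmm_log_likelihood(log_image, bias, class_priors, params, mask)
    return params, resp, history


def redistribute_posteriors(responsibilities: dict[str, np.ndarray],
                            warped_roi_maps: dict[int, np.ndarray],
                            grouping: LabelGrouping) -> dict[int, np.ndarray]:
    """Split each class posterior across its ROIs by atlas proportion.

    p_jk = r_jc(k) * A_kj / sum_{k' in c} A_k'j; zero where the class has no
    atlas mass, so per-voxel mass is conserved exactly per class.
    """
    fine: dict[int, np.ndarray] = {}
    for c in grouping.classes:
        lids = [k for k in grouping.labels_of(c) if k in warped_roi_maps]
        if not lids:
            continue
        total = np.zeros_like(np.asarray(warped_roi_maps[lids[0]], float))
        for k in lids:
            total += warped_roi_maps[k]
        r = np.asarray(responsibilities[c], float)
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(total > 0, 1.0 / np.maximum(total, 1e-30), 0.0)
        for k in lids:
            fine[k] = (r * warped_roi_maps[k] * inv).astype(np.float32)
    return dict(sorted(fine.items()))


def hard_segmentation(fine_posteriors: dict[int, np.ndarray],
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Argmax ROI label per voxel (background 0); ties go to the lowest id."""
    lids = sorted(fine_posteriors)
    first = np.asarray(fine_posteriors[lids[0]])
    best_p = np.zeros(first.shape, dtype=np.float32)
    best_l = np.zeros(first.shape, dtype=np.int32)
    for lid in lids:
        p = np.asarray(fine_posteriors[lid], np.float32)
        upd = p > best_p  # strict: earlier (lower) label wins ties
        best_p[upd] = p[upd]
        best_l[upd] = lid
    fg = 1.0 - sum(np.asarray(fine_posteriors[k], np.float64) for k in lids)
    best_l[best_p <= fg] = 0  # background residual wins (ties included)
    if mask is not None:
        best_l[~mask] = 0
    return best_l


def roi_volumes(fine_posteriors: dict[int, np.ndarray], voxel_size,
                names: dict[int, str] | None = None) -> pd.DataFrame:
    """Soft (expected) ROI volumes in mm^3, one row per label, sorted by id."""
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    vox_mm3 = float(np.prod(vs))
    rows = [{"label_id": lid,
             "name": (names or {}).get(lid, str(lid)),
             "volume_mm3": float(np.asarray(p, np.float64).sum() * vox_mm3)}
            for lid, p in sorted(fine_posteriors.items())]
    return pd.DataFrame(rows, columns=["label_id", "name", "volume_mm3"])


@dataclass
class SegmentationResult:
    class_responsibilities: dict[str, np.ndarray]
    fine_posteriors: dict[int, np.ndarray]
    hard_labels: np.ndarray
    volume_table: pd.DataFrame
    working_affine: np.ndarray
    params: GaussianParams
    ll_history: list[float]
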