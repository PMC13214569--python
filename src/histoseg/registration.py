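"""Greedy multiscale diffeomorphic registration with a composite similarity.

The moving image (the synthetic anatomical volume rendered from the atlas)
is registered to the fixed input scan in greedy, non-symmetric mode: the
loss — local normalized cross-correlation plus a weighted soft-Dice term on
protocol-grouped label maps — lives on the fixed grid, its gradient with
respect to the dense displacement is smoothed with a Gaussian, one Adam step
is taken, the incremental update is composed into the running warp, and the
composed field is smoothed again.  There is no explicit regularisation term;
smoothness comes from the two Gaussian smoothings and the coarse-to-fine
pyramid.

Displacements are stored in fixed-grid voxel units.  A voxel at index x maps
to moving coordinates via ``pre_affine o (id + u)``: the warped fixed-grid
position ``x + u(x)`` is sent through the fixed affine, the inverse of the
atlas-to-scan pre-affine, and the inverse atlas affine.
"""
from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import (binary_dilation, gaussian_filter, map_coordinates,
                           uniform_filter)

from .generative import _central_diff
from .types import ImageVolume, apply_affine

VAR_FLOOR_FRACTION = 1e-6   # LNCC local-variance floor, fraction of global variance
DICE_EPS = 1e-6
ADAM_BETAS = (0.9, 0.999)
# The Adam second moment is pooled over the field (a scalar preconditioner)
# rather than kept per voxel: per-voxel normalisation turns noise-level
# gradients into full-size steps, which roughens the field and stalls the
# optimisation; the pooled variant preserves the spatial coherence of the
# smoothed gradient.  Steps are additionally capped at lr voxels.
ADAM_EPS = 1e-30
EARLY_STOP_PATIENCE = 25  # iterations without loss improvement before stopping


@dataclass
class Deformation:
    """Affine pre-alignment plus a dense displacement on the fixed grid."""

    pre_affine: np.ndarray            # atlas -> scan world, 4x4
    displacement: np.ndarray          # (3, nx, ny, nz), fixed voxel units
    fixed_affine: np.ndarray          # fixed-grid voxel -> world

    def __post_init__(self):
        self.pre_affine = np.asarray(self.pre_affine, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.fixed_affine = np.asarray(self.fixed_affine, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nx, ny, nz)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite")

    @classmethod
    def identity(cls, fixed_shape, fixed_affine, pre_affine=None) -> "Deformation":
        return cls(np.eye(4) if pre_affine is None else pre_affine,
                   np.zeros((3, *fixed_shape)), fixed_affine)

    def atlas_coordinates(self, target_shape, target_affine,
                          atlas_affine) -> np.ndarray:
        """Atlas-grid voxel coordinates for every voxel of a target grid."""
        idx = np.indices(tuple(target_shape), dtype=float)
        to_fixed = np.linalg.inv(self.fixed_affine) @ np.asarray(target_affine)
        x = np.tensordot(to_fixed[:3, :3], idx, axes=(1, 0)) \
            + to_fixed[:3, 3].reshape(3, 1, 1, 1)
        u = np.stack([map_coordinates(self.displacement[c], x, order=1, mode="nearest")
                      for c in range(3)])
        z = x + u
        M = np.linalg.inv(atlas_affine) @ np.linalg.inv(self.pre_affine) @ self.fixed_affine
        return np.tensordot(M[:3, :3], z, axes=(1, 0)) + M[:3, 3].reshape(3, 1, 1, 1)


@dataclass
class RegistrationConfig:
    optimizer_lr: float = 0.5
    smooth_grad_sigma: float = 1.0
    smooth_warp_sigma: float = 0.25
    cc_kernel_size: int = 7
    rel_weight_labeldiff: float = 2.5
    pyramid_start_mm: float = 4.0
    pyramid_factor: float = 2.0
    # per-level iteration budget: a scalar applies to every level (early
    # stopping trims converged coarse levels); a sequence gives explicit
    # coarse-to-fine budgets
    iterations_per_level: int | tuple = 100
    mask_dilation_voxels: int = 3

    def __post_init__(self):
        if self.cc_kernel_size < 3 or self.cc_kernel_size % 2 == 0:
            raise ValueError("cc_kernel_size must be odd and >= 3")
        if self.optimizer_lr <= 0:
            raise ValueError("optimizer_lr must be positive")
        if self.smooth_grad_sigma < 0 or self.smooth_warp_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")


# ---------------------------------------------------------------------------
# similarity terms

def _local_moments(F, M, size):
    muF = uniform_filter(F, size, mode="nearest")
    muM = uniform_filter(M, size, mode="nearest")
    cov = uniform_filter(F * M, size, mode="nearest") - muF * muM
    varF = uniform_filter(F * F, size, mode="nearest") - muF ** 2
    varM = uniform_filter(M * M, size, mode="nearest") - muM ** 2
    return muF, muM, cov, varF, varM


def lncc(fixed: np.ndarray, moving: np.ndarray, kernel_size: int = 7,
         mask: np.ndarray | None = None) -> float:
    """Mean squared local correlation over masked voxels (box window)."""
    v, _ = _lncc_value_grad(np.asarray(fixed, float), np.asarray(moving, float),
                            kernel_size, mask, need_grad=False)
    return v


def _lncc_value_grad(F, M, size, mask, need_grad=True):
    muF, muM, cov, varF, varM = _local_moments(F, M, size)
    gv = max(float(F.var()), 1e-30)
    floor = VAR_FLOOR_FRACTION * gv
    B = np.maximum(varF, floor)
    C = np.maximum(varM, floor)
    cc = cov * cov / (B * C)
    if mask is None:
        mask = np.ones(F.shape, bool)
    n = max(int(mask.sum()), 1)
    value = float(cc[mask].sum() / n)
    if not need_grad:
        return value, None
    # exact gradient of the masked window sum: every window y containing x
    # contributes [2A/(BC)](F(x)-muF_y)/k^3 - [2A^2/(BC^2)](M(x)-muM_y)/k^3;
    # summing over y turns the coefficient fields into box filters.
    c1 = np.where(mask, 2 * cov / (B * C), 0.0)
    c2 = np.where(mask, 2 * cov ** 2 / (B * C ** 2), 0.0)
    g = (F * uniform_filter(c1, size, mode="constant")
         - uniform_filter(c1 * muF, size, mode="constant")
         - M * uniform_filter(c2, size, mode="constant")
         + uniform_filter(c2 * muM, size, mode="constant")) / n
    return value, g


def soft_dice(p_maps: dict, q_maps: dict, eps: float = DICE_EPS) -> float:
    """Mean over labels of 2*sum(pq)/(sum p^2 + sum q^2 + eps).

    The squared-denominator (V-Net) form is used because it is maximised
    exactly at proportional overlap (Cauchy-Schwarz): identical soft maps
    score 1, whereas the plain-sum denominator rewards concentrating
    probability mass instead of aligning it.  For binary maps the two forms
    coincide.  Labels empty in both segmentations are skipped.
    """
    vals = []
    for k in p_maps:
        p = np.asarray(p_maps[k], float)
        q = np.asarray(q_maps[k], float)
        sp2, sq2 = float((p * p).sum()), float((q * q).sum())
        if sp2 == 0.0 and sq2 == 0.0:
            continue
        vals.append(2.0 * float((p * q).sum()) / (sp2 + sq2 + eps))
    if not vals:
        raise ValueError("no label has mass in either segmentation")
    return float(np.mean(vals))


def _soft_dice_grad(p, q, eps=DICE_EPS):
    """d dice_k / dp for one label (dice_k = 2 sum pq / (sum p^2 + sum q^2))."""
    S = float((p * p).sum() + (q * q).sum() + eps)
    num = 2.0 * float((p * q).sum())
    return (2.0 * q - (2.0 * num / S) * p) / S, num / S


# ---------------------------------------------------------------------------
# geometry helpers

def _warp(vol, pos):
    return map_coordinates(vol, pos, order=1, mode="nearest")


def _downsample(vol, src_spacing, tgt_spacing, order=1):
    """Anti-aliased resample of a fixed-grid volume to a coarser level grid."""
    src = np.asarray(src_spacing, float)
    tgt = np.broadcast_to(np.asarray(tgt_spacing, float), (3,))
    scale = src / tgt
    sigma = np.where(tgt > src + 1e-9, (tgt / 2.355) / src, 0.0)
    blurred = gaussian_filter(np.asarray(vol, float), sigma, mode="nearest") \
        if sigma.max() > 0 else np.asarray(vol, float)
    shape = tuple(max(2, int(round(vol.shape[ax] * scale[ax]))) for ax in range(3))
    idx = np.indices(shape, dtype=float)
    coords = (idx + 0.5) / scale.reshape(3, 1, 1, 1) - 0.5
    return map_coordinates(blurred, coords, order=order, mode="nearest"), shape, scale


def affine_initialize(atlas_label_maps: dict[int, np.ndarray], atlas_affine: np.ndarray,
                      coarse_labels: np.ndarray, coarse_affine: np.ndarray,
                      allow_affine: bool = True) -> np.ndarray:
    """Least-squares affine (atlas -> scan world) from matched structure centroids.

    Atlas centroids are probability-weighted; coarse centroids are voxel-count
    centroids of the matching protocol label.  Falls back to a similarity
    transform when the centroid set is rank-deficient.
    """
    P, Q, W = [], [], []
    for lid, pm in atlas_label_maps.items():
        m = np.asarray(pm, float)
        w = m.sum()
        sel = coarse_labels == lid
        if w <= 0 or not sel.any():
            continue
        ci = np.array([ (m * g).sum() / w for g in np.indices(m.shape, dtype=float) ])
        P.append(apply_affine(atlas_affine, ci.reshape(3, 1, 1, 1)).ravel())
        cj = np.array(np.nonzero(sel), dtype=float).mean(axis=1)
        Q.append(apply_affine(coarse_affine, cj.reshape(3, 1, 1, 1)).ravel())
        W.append(w)
    if len(P) < 4:
        raise ValueError("need at least 4 matched structures")
    P, Q = np.array(P), np.array(Q)
    W = np.sqrt(np.array(W))[:, None]
    X = np.hstack([P, np.ones((len(P), 1))])
    sol, res, rank, _ = np.linalg.lstsq(X * W, Q * W, rcond=None)
    out = np.eye(4)
    if rank == 4 and allow_affine:
        out[:3, :3] = sol[:3].T
        out[:3, 3] = sol[3]
        return out
    # similarity fallback (Umeyama)
    muP, muQ = P.mean(0), Q.mean(0)
    Pc, Qc = P - muP, Q - muQ
    U, S, Vt = np.linalg.svd(Qc.T @ Pc)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    s = np.trace(np.diag(S) @ D) / max((Pc ** 2).sum() / len(P), 1e-30) / len(P)
    out[:3, :3] = s * R
    out[:3, 3] = muQ - s * R @ muP
    return out


def jacobian_map(displacement: np.ndarray, log10: bool = False) -> np.ndarray:
    """Determinant of the Jacobian of (id + u), central differences."""
    u = np.asarray(displacement, float)
    J = np.empty((3, 3) + u.shape[1:])
    for i in range(3):
        for ax in range(3):
            J[i, ax] = _central_diff(u[i], ax) + (1.0 if i == ax else 0.0)
    det = (J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
           - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
           + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0]))
    return np.log10(np.maximum(det, 1e-12)) if log10 else det


# ---------------------------------------------------------------------------
# multiscale optimisation

def _level_spacings(native_mm: float, start_mm: float, factor: float) -> list[float]:
    spacings = []
    s = start_mm
    while s > native_mm * 1.25:
        spacings.append(s)
        s /= factor
    spacings.append(native_mm)
    return spacings


def _smooth_vec(u, sigma):
    if sigma <= 0:
        return u
    return np.stack([gaussian_filter(u[c], sigma, mode="nearest") for c in range(3)])


def run_multiscale_registration(fixed: ImageVolume, moving: ImageVolume,
                                moving_label_maps: dict[int, np.ndarray],
                                fixed_label_maps: dict[int, np.ndarray],
                                init_affine: np.ndarray,
                                config: RegistrationConfig | None = None,
                                verbose: bool = False):
    """Greedy compositive registration of the synthetic volume to the scan.

    ``moving`` and ``moving_label_maps`` live on the atlas grid (the label
    maps are the atlas ROIs grouped to the coarse protocol); ``fixed`` and
    ``fixed_label_maps`` live on the scan grid.  Returns ``(Deformation,
    diagnostics)`` where diagnostics include the per-level loss histories.
    """
    config = config or RegistrationConfig()
    native = float(np.min(fixed.voxel_size))
    spacings = _level_spacings(native, config.pyramid_start_mm, config.pyramid_factor)
    n_levels = len(spacings)
    if np.iterable(config.iterations_per_level):
        sched = list(config.iterations_per_level)
        iters = [int(sched[min(i, len(sched) - 1)]) for i in range(n_levels)]
    else:
        iters = [int(config.iterations_per_level)] * n_levels

    fmask = fixed.mask if fixed.mask is not None else np.ones(fixed.shape, bool)
    label_ids = sorted(set(moving_label_maps) & set(fixed_label_maps))
    atlas_inv = None  # built per level

    u = None
    prev_scale = None
    histories = []
    t0 = time.time()
    for li, sp in enumerate(spacings):
        F, shape_l, scale = _downsample(fixed.voxels, fixed.voxel_size, sp)
        mk, _, _ = _downsample(fmask.astype(float), fixed.voxel_size, sp)
        mask_l = binary_dilation(mk > 0.5, iterations=config.mask_dilation_voxels)
        # level affine: voxel -> world
        A_l = fixed.affine.copy()
        A_l[:3, :3] = fixed.affine[:3, :3] / scale[None, :]
        A_l[:3, 3] = fixed.affine[:3, :3] @ (0.5 / scale - 0.5) + fixed.affine[:3, 3]
        # moving image and labels brought to the level grid through the affine only
        M_chain = np.linalg.inv(moving.affine) @ np.linalg.inv(init_affine) @ A_l
        idx = np.indices(shape_l, dtype=float)
        ac = np.tensordot(M_chain[:3, :3], idx, axes=(1, 0)) \
            + M_chain[:3, 3].reshape(3, 1, 1, 1)
        # anti-alias the moving image to the level resolution so both sides
        # of the similarity have matched smoothness
        mov_sigma = np.where(sp > moving.voxel_size + 1e-9,
                             (sp / 2.355) / moving.voxel_size, 0.0)
        mov_vox = gaussian_filter(np.asarray(moving.voxels, float), mov_sigma,
                                  mode="nearest") if mov_sigma.max() > 0 \
            else np.asarray(moving.voxels, float)
        M0 = map_coordinates(mov_vox, ac, order=1, mode="constant", cval=0.0)
        G0 = np.stack(np.gradient(M0))
        # label channels: moving on level grid (via affine), fixed downsampled
        Lm, Gm, Lf = {}, {}, {}
        for k in label_ids:
            lm = np.asarray(moving_label_maps[k], float)
            if mov_sigma.max() > 0:
                lm = gaussian_filter(lm, mov_sigma, mode="nearest")
            Lm[k] = map_coordinates(lm, ac, order=1, mode="constant", cval=0.0)
            Gm[k] = np.stack(np.gradient(Lm[k]))
            Lf[k], _, _ = _downsample(fixed_label_maps[k], fixed.voxel_size, sp)
        # displacement carried over from the previous level
        if u is None:
            u = np.zeros((3, *shape_l))
        else:
            ratio = scale / prev_scale  # voxels get smaller: u grows in voxel units
            idx2 = np.indices(shape_l, dtype=float)
            coords = (idx2 + 0.5) / ratio.reshape(3, 1, 1, 1) - 0.5
            u = np.stack([map_coordinates(u[c], coords, order=1, mode="nearest")
                          * ratio[c] for c in range(3)])
        prev_scale = scale

        m = np.zeros_like(u)
        v = 0.0
        lr = config.optimizer_lr
        base = np.indices(shape_l, dtype=float)
        history = []
        it = 0
        retried = False
        best_loss = np.inf
        best_u = u.copy()
        since_best = 0
        while it < iters[li]:
            pos = base + u
            Mw = _warp(M0, pos)
            cc_val, gM = _lncc_value_grad(F, Mw, config.cc_kernel_size, mask_l)
            g = gM[None] * np.stack([_warp(G0[c], pos) for c in range(3)])
            dice_vals = []
            for k in label_ids:
                pw = _warp(Lm[k], pos)
                q = Lf[k]
                if pw.sum() == 0.0 and q.sum() == 0.0:
                    continue
                gP, dval = _soft_dice_grad(pw, q)
                dice_vals.append(dval)
                gk = gP * config.rel_weight_labeldiff / max(len(label_ids), 1)
                g += gk[None] * np.stack([_warp(Gm[k][c], pos) for c in range(3)])
            dice_val = float(np.mean(dice_vals)) if dice_vals else 0.0
            loss = -(cc_val + config.rel_weight_labeldiff * dice_val)
            if not np.isfinite(loss):
                if retried:
                    raise RuntimeError(f"non-finite loss at level {li}, iter {it}")
                lr /= 2.0
                m[:] = 0.0
                v[:] = 0.0
                retried = True
                continue
            history.append(loss)
            if loss < best_loss - 1e-12:
                best_loss = loss
                best_u = u.copy()
                since_best = 0
            else:
                since_best += 1
                if since_best >= EARLY_STOP_PATIENCE:
                    break
            g[:, ~mask_l] = 0.0
            g = _smooth_vec(g, config.smooth_grad_sigma)
            it += 1
            m = ADAM_BETAS[0] * m + (1 - ADAM_BETAS[0]) * g
            v = ADAM_BETAS[1] * v + (1 - ADAM_BETAS[1]) * float((g * g)[:, mask_l].mean())
            mhat = m / (1 - ADAM_BETAS[0] ** it)
            vhat = v / (1 - ADAM_BETAS[1] ** it)
            step = lr * mhat / (np.sqrt(vhat) + ADAM_EPS)  # ascent on similarity
            mag = np.sqrt((step ** 2).sum(axis=0)).max()
            if mag > lr:  # trust region: no voxel moves more than lr per step
                step *= lr / mag
            # compositive update: x -> x + step(x) + u(x + step(x))
            posd = base + step
            u = step + np.stack([_warp(u[c], posd) for c in range(3)])
            u = _smooth_vec(u, config.smooth_warp_sigma)
        u = best_u if np.isfinite(best_loss) else u
        histories.append(history)
        if verbose:
            print(f"level {li} ({sp:.2f} mm, {shape_l}): loss {history[0]:.4f} -> "
                  f"{history[-1]:.4f} [{time.time() - t0:.1f}s]")

    deformation = Deformation(pre_affine=init_affine, displacement=u,
                              fixed_affine=fixed.affine)
    det = jacobian_map(u)
    diagnostics = {
        "loss_histories": histories,
        "level_spacings_mm": spacings,
        "jacobian_positive_fraction": float((det[fmask] > 0).mean()) if fmask.any() else 1.0,
        "elapsed_s": time.time() - t0,
    }
    return deformation, diagnostics
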