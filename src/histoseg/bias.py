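"""Bias-field estimation from a coarse segmentation.

MRI intensity inhomogeneity is modelled as a smooth multiplicative field,
additive after log-transforming the image.  The field is a linear combination
of low-order basis functions (3D DCT by default, 343 functions at per-axis
order 6).  Estimation performs a *single M-step* of generalized EM with
responsibilities fixed to a Gaussian-blurred one-hot encoding of a small set
of tissue classes from the coarse segmentation: class moments and basis
coefficients are updated alternately in closed form until the field stops
changing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

RIDGE_FRACTION = 1e-8   # ridge on the normal equations, numerical safety only
CONVERGENCE_FRACTION = 1e-4  # of the robust intensity range
MAX_ALTERNATIONS = 50
MM_PER_DCT_MODE = 33.0  # FOV per basis mode: a ~200 mm head gives order 6
DEFAULT_INTERIOR_CONFIDENCE = 0.99  # exclude partial-volume boundary voxels


def default_bf_order(fov_mm: float) -> int:
    """Per-axis DCT order matched to the field of view.

    One mode per ~33 mm keeps the coarsest basis wavelength at anatomical
    scale regardless of crop size: a whole head (~200 mm) gets order 6, a
    small ex vivo block proportionally fewer modes.  Clipped to [2, 6].
    """
    return int(np.clip(round(fov_mm / MM_PER_DCT_MODE), 2, 6))

#: Coarse-protocol tissue classes used for bias estimation.
DEFAULT_BIAS_CLASSES = (
    "cerebral gray matter", "cerebellar gray matter", "cerebral white matter",
    "cerebellar white matter", "brainstem", "cerebrospinal fluid", "thalamus",
    "pallidum",
)


def _dct_cols(n: int, order: int, n_ref: int) -> np.ndarray:
    """Orthonormal DCT-II columns of frequencies 0..order, evaluated on an
    ``n``-point grid but scaled for the ``n_ref``-point reference grid (so the
    same coefficients describe the field at any resolution)."""
    s = (np.arange(n) + 0.5) / n  # normalized voxel-center coordinate in [0,1]
    cols = np.empty((n, order + 1))
    for f in range(order + 1):
        scale = np.sqrt((1.0 if f == 0 else 2.0) / n_ref)
        cols[:, f] = scale * np.cos(np.pi * f * s)
    return cols


def _poly_cols(n: int, order: int) -> np.ndarray:
    x = 2.0 * (np.arange(n) + 0.5) / n - 1.0
    return np.stack([x ** a for a in range(order + 1)], axis=1)


@dataclass
class BiasBasis:
    """Separable basis: each function is a product of three 1D columns."""

    basis_kind: str
    order: int
    grid_shape: tuple[int, int, int]
    triples: list[tuple[int, int, int]]  # per-function column indices
    cols: tuple[np.ndarray, np.ndarray, np.ndarray]  # 1D columns per axis

    @property
    def n_functions(self) -> int:
        return len(self.triples)

    def design_matrix(self, index_arrays: tuple[np.ndarray, np.ndarray, np.ndarray]
                      ) -> np.ndarray:
        """(n_voxels, B) design matrix at the given voxel indices."""
        cx = self.cols[0][index_arrays[0]]
        cy = self.cols[1][index_arrays[1]]
        cz = self.cols[2][index_arrays[2]]
        A = np.empty((index_arrays[0].size, self.n_functions))
        for b, (i, j, k) in enumerate(self.triples):
            A[:, b] = cx[:, i] * cy[:, j] * cz[:, k]
        return A

    def field(self, coefficients: np.ndarray,
              target_shape: tuple[int, int, int] | None = None) -> np.ndarray:
        """Evaluate the field analytically on the native or a finer/coarser grid."""
        shape = target_shape or self.grid_shape
        cols = []
        for ax in range(3):
            n = shape[ax]
            if self.basis_kind == "dct" or (self.basis_kind == "hybrid" and ax < 2):
                cols.append(_dct_cols(n, self.order, self.grid_shape[ax]))
            else:
                cols.append(_poly_cols(n, self.order))
        out = np.zeros(shape)
        c = np.asarray(coefficients, dtype=float)
        for b, (i, j, k) in enumerate(self.triples):
            if c[b] == 0.0:
                continue
            out += c[b] * (cols[0][:, i][:, None, None]
                           * cols[1][:, j][None, :, None]
                           * cols[2][:, k][None, None, :])
        return out


def build_basis(grid_shape, basis_kind: str = "dct", order: int = 6) -> BiasBasis:
    """Construct the separable bias basis.

    dct: all (order+1)^3 products of 1D DCT-II modes, orthonormal over the
    full grid, ordered lexicographically in frequency (so order 6 gives 343
    functions and the first function is the DC mode).  polynomial: monomials
    x^a y^b z^c with a+b+c <= order on [-1,1]-scaled coordinates.  hybrid:
    DCT in-plane x polynomial through-plane (for thick-slice acquisitions).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    grid_shape = tuple(int(s) for s in grid_shape)
    o = order
    if basis_kind == "dct":
        triples = [(i, j, k) for i in range(o + 1) for j in range(o + 1)
                   for k in range(o + 1)]
        cols = tuple(_dct_cols(grid_shape[ax], o, grid_shape[ax]) for ax in range(3))
    elif basis_kind == "polynomial":
        triples = [(a, b, c) for a in range(o + 1) for b in range(o + 1)
                   for c in range(o + 1) if a + b + c <= o]
        cols = tuple(_poly_cols(grid_shape[ax], o) for ax in range(3))
    elif basis_kind == "hybrid":
        triples = [(i, j, c) for i in range(o + 1) for j in range(o + 1)
                   for c in range(o + 1)]
        cols = (_dct_cols(grid_shape[0], o, grid_shape[0]),
                _dct_cols(grid_shape[1], o, grid_shape[1]),
                _poly_cols(grid_shape[2], o))
    else:
        raise ValueError(f"unknown basis kind {basis_kind!r}")
    return BiasBasis(basis_kind, o, grid_shape, triples, cols)  # type: ignore[arg-type]


@dataclass
class BiasFieldModel:
    basis: BiasBasis
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.n_functions,):
            raise ValueError("coefficient length must match the basis")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")

    def field(self, target_shape=None) -> np.ndarray:
        return self.basis.field(self.coefficients, target_shape)


def soft_segmentation(labels: np.ndarray, voxel_size, class_to_labels: dict[str, list[int]],
                      sigma_mm: float = 0.5) -> dict[str, np.ndarray]:
    """Blurred one-hot class maps from an integer label volume.

    Each class's one-hot indicator is convolved with an isotropic Gaussian of
    physical width ``sigma_mm`` (sigma in voxels = sigma_mm / spacing per
    axis; zero-padded convolution).  Classes absent from the volume yield an
    empty map.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sig = sigma_mm / voxel_size
    out = {}
    for cls, ids in class_to_labels.items():
        onehot = np.isin(labels, ids).astype(float)
        out[cls] = gaussian_filter(onehot, sig, mode="constant") if sigma_mm > 0 else onehot
    return out


def fit_bias_single_mstep(log_image: np.ndarray, soft_maps: dict[str, np.ndarray],
                          basis: BiasBasis, mask: np.ndarray | None = None,
                          interior_confidence: float = DEFAULT_INTERIOR_CONFIDENCE):
    """One fixed-responsibility M-step: alternate class moments and coefficients.

    Boundary partial-volume voxels violate the single-class intensity
    assumption and leak anatomy into the field, so the fit is restricted to
    voxels whose largest soft responsibility reaches ``interior_confidence``
    (the blurred one-hot is < 1 only within ~1 voxel of a class boundary);
    pass 0 to use every masked voxel.  Returns ``(BiasFieldModel, stats,
    lower_bounds)`` where ``stats`` maps class name to ``(mean, std)`` of
    bias-corrected log-intensities and ``lower_bounds`` is the
    per-alternation fixed-responsibility bound (non-decreasing).
    """
    shape = log_image.shape
    mask = np.ones(shape, bool) if mask is None else mask
    if interior_confidence > 0 and soft_maps:
        peak = np.max(np.stack([np.asarray(m) for m in soft_maps.values()]), axis=0)
        interior = mask & (peak >= interior_confidence)
        if interior.sum() >= 10 * basis.n_functions:
            mask = interior
    classes = [c for c in soft_maps if soft_maps[c][mask].sum() > 0]
    if not classes:
        raise ValueError("no class has mass inside the mask")
    x = log_image[mask]
    R = np.stack([np.asarray(soft_maps[c], dtype=float)[mask] for c in classes])
    robust_range = max(np.percentile(x, 99) - np.percentile(x, 1), 1e-12)

    idx = np.nonzero(mask)
    A = basis.design_matrix(idx)
    B = basis.n_functions
    coeff = np.zeros(B)
    bias = A @ coeff
    bounds = []
    var_floor = (1e-4 * robust_range) ** 2

    for _ in range(MAX_ALTERNATIONS):
        # (a) class moments of bias-corrected log-intensities
        xc = x - bias
        n_c = R.sum(axis=1)
        mu = (R @ xc) / n_c
        var = np.maximum((R @ xc ** 2) / n_c - mu ** 2, var_floor)
        # (b) precision-weighted least squares for the coefficients
        prec = R / var[:, None]                     # r_jc / sigma_c^2
        w = prec.sum(axis=0)                        # per-voxel weight
        t = (prec * (x[None, :] - mu[:, None])).sum(axis=0) / w
        AtW = A.T * w[None, :]
        normal = AtW @ A
        normal += RIDGE_FRACTION * np.trace(normal) / B * np.eye(B)
        new_coeff = np.linalg.solve(normal, AtW @ t)
        new_bias = A @ new_coeff

        resid = (x[None, :] - new_bias[None, :] - mu[:, None]) ** 2 / var[:, None]
        bound = float(np.sum(R * (-0.5 * np.log(2 * np.pi * var)[:, None] - 0.5 * resid)))
        bounds.append(bound)
        delta = np.abs(new_bias - bias).max()
        coeff, bias = new_coeff, new_bias
        if delta < CONVERGENCE_FRACTION * robust_range:
            break

    stats = {c: (float(mu[i]), float(np.sqrt(var[i]))) for i, c in enumerate(classes)}
    return BiasFieldModel(basis, coeff), stats, bounds


def correct_image(voxels: np.ndarray, bias_field: np.ndarray,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Divide out the bias, re-centred so the masked median intensity is kept.

    Works in the log domain (subtract the field, shift so the corrected
    masked median log-intensity equals the original), then exponentiates.
    """
    mask = (voxels > 0) if mask is None else (mask & (voxels > 0))
    logv = np.log(np.maximum(voxels, 1e-30))
    corrected = logv - bias_field
    if mask.any():
        corrected += np.median(logv[mask]) - np.median(corrected[mask])
    out = np.where(voxels > 0, np.exp(corrected), voxels)
    return out
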