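"""Diagnostic implementation of the generative segmentation model.

The model: each voxel draws an anatomical label from the (deformed) atlas
prior, and its log-intensity from a Gaussian mixture of the label's tissue
class, shifted by a smooth additive bias field (multiplicative before the log
transform).  The deformation carries a membrane-energy penalty.  These
routines evaluate the resulting log-posterior objective and the per-voxel
class responsibilities; they are diagnostics, not the fast pipeline's
optimisation target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

LOG_EPS_FRACTION = 1e-6  # epsilon for log transform, relative to robust max


@dataclass
class GaussianParams:
    """Per-tissue-class Gaussian mixture parameters in log-intensity units."""

    classes: list[str]
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    means: dict[str, np.ndarray] = field(default_factory=dict)
    stds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for c in self.classes:
            w = np.atleast_1d(np.asarray(self.weights[c], dtype=float))
            m = np.atleast_1d(np.asarray(self.means[c], dtype=float))
            s = np.atleast_1d(np.asarray(self.stds[c], dtype=float))
            if not (w.shape == m.shape == s.shape):
                raise ValueError(f"class {c!r}: mismatched component shapes")
            if np.any(s <= 0):
                raise ValueError(f"class {c!r}: stds must be positive")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"class {c!r}: weights must be >= 0 and sum to 1")
            self.weights[c], self.means[c], self.stds[c] = w, m, s

    def copy(self) -> "GaussianParams":
        return GaussianParams(list(self.classes),
                              {c: self.weights[c].copy() for c in self.classes},
                              {c: self.means[c].copy() for c in self.classes},
                              {c: self.stds[c].copy() for c in self.classes})


@dataclass
class ObjectiveBreakdown:
    data_term: float
    regularizer: float
    total: float
    lam: float

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if abs(self.total - (self.data_term - self.regularizer)) > 1e-9 * max(
                1.0, abs(self.total)):
            raise ValueError("total must equal data_term - regularizer")


def log_transform(image_voxels: np.ndarray, mask: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform intensities; non-positive voxels are dropped from the mask."""
    v = np.asarray(image_voxels, dtype=float)
    mask = np.ones(v.shape, bool) if mask is None else mask.copy()
    robust_max = np.percentile(v[mask], 99.5) if mask.any() else 1.0
    eps = LOG_EPS_FRACTION * max(robust_max, 1e-30)
    mask &= v > 0
    return np.log(np.maximum(v, eps)), mask


def _class_log_mixture(x: np.ndarray, w: np.ndarray, mu: np.ndarray,
                       sigma: np.ndarray) -> np.ndarray:
    """log sum_m w_m N(x; mu_m, sigma_m), stable via log-sum-exp."""
    comp = (np.log(np.maximum(w, 1e-300))[:, None]
            - 0.5 * np.log(2 * np.pi) - np.log(sigma)[:, None]
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2)
    return logsumexp(comp, axis=0)


def gmm_log_likelihood(log_image: np.ndarray, bias: np.ndarray | None,
                       priors: dict[str, np.ndarray], params: GaussianParams,
                       mask: np.ndarray | None = None):
    """Per-voxel mixture log-likelihood and class responsibilities.

    Returns ``(ll, resp, n_excluded)`` where ``ll`` is a full-grid array of
    per-voxel log-likelihoods (0 outside the mask), ``resp`` maps class name
    to its responsibility map, and ``n_excluded`` counts masked voxels with
    zero total prior mass (excluded with a warning count rather than an
    error).
    """
    shape = log_image.shape
    mask = np.ones(shape, bool) if mask is None else mask
    x = log_image[mask] - (0.0 if bias is None else np.asarray(bias)[mask])

    classes = params.classes
    logp = np.empty((len(classes), x.size))
    for i, c in enumerate(classes):
        pr = np.asarray(priors[c], dtype=float)[mask]
        logp[i] = np.where(pr > 0, np.log(np.maximum(pr, 1e-300)), -np.inf)
        logp[i] += _class_log_mixture(x, params.weights[c], params.means[c],
                                      params.stds[c])
    ll_vox = logsumexp(logp, axis=0)
    valid = np.isfinite(ll_vox)
    n_excluded = int((~valid).sum())

    resp_flat = np.exp(logp - ll_vox[None, :])
    resp_flat[:, ~valid] = 0.0

    ll = np.zeros(shape)
    ll[mask] = np.where(valid, ll_vox, 0.0)
    resp = {}
    for i, c in enumerate(classes):
        r = np.zeros(shape)
        r[mask] = resp_flat[i]
        resp[c] = r
    return ll, resp, n_excluded


def _central_diff(u: np.ndarray, axis: int) -> np.ndarray:
    """Central differences with replicate boundary, in voxel units."""
    up = np.concatenate([u.take([0], axis), u, u.take([-1], axis)], axis)
    n = u.shape[axis]
    return (up.take(range(2, n + 2), axis) - up.take(range(0, n), axis)) / 2.0


def membrane_energy(displacement: np.ndarray) -> float:
    """Sum over voxels and components of the squared spatial gradient.

    ``displacement`` has shape (3, nx, ny, nz) in voxel units.  The stencil is
    central differences with replicate boundary, so boundary derivatives are
    halved one-sided differences.
    """
    u = np.asarray(displacement, dtype=float)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError("displacement must have shape (3, nx, ny, nz)")
    e = 0.0
    for comp in range(3):
        for axis in range(3):
            e += float(np.sum(_central_diff(u[comp], axis) ** 2))
    return e


def evaluate_objective(log_image: np.ndarray, bias: np.ndarray | None,
                       priors: dict[str, np.ndarray], params: GaussianParams,
                       displacement: np.ndarray | None = None, lam: float = 0.0,
                       mask: np.ndarray | None = None) -> ObjectiveBreakdown:
    """Full log-posterior objective: data log-likelihood minus membrane penalty.

    ``lam`` defaults to 0: the fast pipeline never optimises this objective,
    and the deformation prior's weight is not otherwise determined.
    """
    ll, _, _ = gmm_log_likelihood(log_image, bias, priors, params, mask)
    data = float(ll.sum())
    reg = lam * membrane_energy(displacement) if (displacement is not None and lam > 0) \
        else 0.0
    return ObjectiveBreakdown(data_term=data, regularizer=reg, total=data - reg, lam=lam)
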