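"""Exact propagation of first/second-order statistics through linear denoisers.

Every layer of the linear denoising family is an affine map of the
vectorized feature tensor: z_d = W_d z_{d-1} + b_d, with W_d sparse
(3x3 local support).  Consequently the class-mean difference and the
covariance matrix of the layer-d features are

    delta_d = W_d ... W_1 delta_0          (biases cancel in the difference)
    K_d     = W_d ... W_1 K_0 W_1^T ... W_d^T

which lets the regularized Hotelling observer be evaluated at every
layer without sampling.  Feature covariances are huge (channels x pixels
square), so the default code path keeps the factored square root
B_d = W_d ... W_1 K_0^{1/2}; the singular values of K_d are the squared
singular values of B_d and RHO templates live in B_d's left singular
subspace.  A dense path exists for small grids and is the contract check
for the factored one.

Feature tensors are vectorized channels-fastest: index = (h*W + w)*C + c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._roc import empirical_auc
from .phantom_imaging import ImageEnsemble
from .linear_observers import (CovarianceEstimate, DEFAULT_LAMBDA_GRID)

__all__ = [
    "LayerOperator", "SpectrumResult", "conv_layer_operator",
    "propagate_covariance", "propagate_covariance_factor",
    "propagate_mean_difference", "layer_output_ensemble",
    "layerwise_rho_auc", "singular_spectrum", "covariance_sqrt_factor",
]


@dataclass
class LayerOperator:
    """Explicit affine form of one convolutional layer."""

    matrix: sp.spmatrix            # (out_pixels*c_out, in_pixels*c_in)
    bias: np.ndarray               # (out_pixels*c_out,)
    in_shape: tuple[int, int, int]   # (H, W, C_in)
    out_shape: tuple[int, int, int]  # (H, W, C_out)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Affine action on a vector or a (n, dim) stack of vectors."""
        x = np.asarray(x)
        if x.ndim == 1:
            return self.matrix @ x + self.bias
        return (self.matrix @ x.T).T + self.bias


@dataclass
class SpectrumResult:
    """Descending singular values of a covariance matrix."""

    values: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if (np.diff(self.values) > 1e-9 * max(self.values[0], 1.0)).any():
            raise ValueError("spectrum must be nonincreasing")

    @property
    def sigma_max(self) -> float:
        return float(self.values[0])

    def retained_rank(self, lam: float) -> int:
        return int((self.values > lam * self.sigma_max).sum())


def _shift_matrix(n: int, d: int) -> sp.csr_matrix:
    """n x n matrix with S[i, i+d] = 1 where valid (zero-padded shift)."""
    if d >= 0:
        diag = np.ones(n - d)
    else:
        diag = np.ones(n + d)
    return sp.diags(diag, offsets=d, shape=(n, n), format="csr")


def conv_layer_operator(weight: np.ndarray, bias: np.ndarray,
                        image_shape: tuple[int, int]) -> LayerOperator:
    """Materialize a 3x3 same-padded convolution as a sparse matrix + bias.

    weight: (3, 3, c_in, c_out); output pixel (h, w, f) sums
    x[h+ky-1, w+kx-1, c] * weight[ky, kx, c, f] over the valid window.
    """
    h, w = image_shape
    c_in, c_out = weight.shape[2], weight.shape[3]
    mat = None
    for ky in range(3):
        sy = _shift_matrix(h, ky - 1)
        for kx in range(3):
            sx = _shift_matrix(w, kx - 1)
            s = sp.kron(sy, sx, format="csr")
            term = sp.kron(s, sp.csr_matrix(weight[ky, kx].T), format="csr")
            mat = term if mat is None else mat + term
    bias_vec = np.tile(np.asarray(bias, dtype=np.float64), h * w)
    return LayerOperator(matrix=mat.tocsr(), bias=bias_vec,
                         in_shape=(h, w, c_in), out_shape=(h, w, c_out))


def _check_chain(operators: Sequence[LayerOperator], upto: Optional[int]) -> int:
    upto = len(operators) if upto is None else upto
    if not (1 <= upto <= len(operators)):
        raise ValueError("layer index out of range")
    for a, b in zip(operators[:-1], operators[1:]):
        if a.out_shape != b.in_shape:
            raise ValueError("inconsistent operator dimension chain")
    return upto


def propagate_covariance(k0: np.ndarray, operators: Sequence[LayerOperator],
                         upto: Optional[int] = None) -> np.ndarray:
    """Dense K_d = W_d ... W_1 K_0 W_1^T ... W_d^T (small grids only).

    The result is symmetrized against floating-point drift.  For large
    feature spaces use :func:`propagate_covariance_factor`.
    """
    upto = _check_chain(operators, upto)
    k = np.asarray(k0, dtype=np.float64)
    if k.shape[0] != operators[0].matrix.shape[1]:
        raise ValueError("K0 dimension does not match the first operator")
    for op in operators[:upto]:
        k = op.matrix @ (op.matrix @ k).T
    return 0.5 * (k + k.T)


def covariance_sqrt_factor(k0: np.ndarray) -> np.ndarray:
    """Symmetric PSD square-root factor A with A A^T = K0 (eigh-based)."""
    vals, vecs = np.linalg.eigh(0.5 * (k0 + k0.T))
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def propagate_covariance_factor(factor: np.ndarray,
                                operators: Sequence[LayerOperator],
                                upto: Optional[int] = None) -> np.ndarray:
    """Propagate a covariance square-root factor: B_d = W_d ... W_1 A.

    ``factor`` is any A with A A^T = K_0.  The returned B satisfies
    B B^T = K_d without K_d ever being formed densely.
    """
    upto = _check_chain(operators, upto)
    b = np.asarray(factor, dtype=np.float64)
    for op in operators[:upto]:
        b = op.matrix @ b
    return b


def propagate_mean_difference(delta: np.ndarray,
                              operators: Sequence[LayerOperator],
                              upto: Optional[int] = None) -> np.ndarray:
    """delta_d = W_d ... W_1 delta (biases cancel in the class difference)."""
    upto = _check_chain(operators, upto)
    d = np.asarray(delta, dtype=np.float64).ravel()
    if d.shape[0] != operators[0].matrix.shape[1]:
        raise ValueError("delta dimension does not match the first operator")
    for op in operators[:upto]:
        d = op.matrix @ d
    return d


def layer_output_ensemble(model, images: np.ndarray, upto: int,
                          batch_size: int = 500) -> np.ndarray:
    """Vectorized feature tensors after ``upto`` layers of a linear denoiser.

    upto = 0 returns the raw images vectorized; upto = D reproduces the
    normalized-space output of ``denoise`` (the raw-intensity rescaling of
    the last layer is applied so that the full-depth output matches
    ``model.denoise`` exactly).
    """
    if model.arch.family != "linear":
        raise ValueError("layer outputs are propagated for the linear family only")
    images = np.asarray(images)
    n = len(images)
    if upto == 0:
        return images.reshape(n, -1).astype(np.float64)
    d = model.arch.depth
    out = []
    for a in range(0, n, batch_size):
        b = min(a + batch_size, n)
        x = ((images[a:b] - model.mu) / model.sigma).astype(np.float32)[..., None]
        y = model.forward_normalized(x, training=False, upto_layer=upto)
        if upto == d:
            y = y * model.sigma + model.mu
        out.append(y.reshape(b - a, -1).astype(np.float64))
    return np.concatenate(out, axis=0)


def singular_spectrum(k: np.ndarray, source: str = "",
                      factor: bool = False) -> SpectrumResult:
    """Singular values of a covariance matrix, descending.

    With ``factor=True`` the input is a square-root factor B and the
    spectrum of K = B B^T is returned (squared singular values of B).
    """
    k = np.asarray(k)
    if factor:
        svals = np.linalg.svd(k, compute_uv=False) ** 2
    else:
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("covariance must be square")
        svals = np.linalg.svd(0.5 * (k + k.T), compute_uv=False)
    return SpectrumResult(values=np.sort(svals)[::-1], source=source)


def _layer_rho_templates(b: np.ndarray, delta_d: np.ndarray,
                         lambdas: Sequence[float]):
    """RHO templates at one layer from the covariance factor (K = b b^T).

    Uses the Gram matrix G = b^T b: its eigenvalues are the singular
    values of K, and K's pseudo-inverse applied to the propagated mean
    difference is b G_r^{-2} b^T delta on the retained subspace.  Returns
    {lambda: (rank, template vector in layer-d feature space)}.
    """
    g = b.T @ b
    vals, vecs = np.linalg.eigh(0.5 * (g + g.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    db = b.T @ delta_d
    out = {}
    for lam in sorted(set(lambdas), reverse=True):
        r = int((vals > lam * vals[0]).sum())
        if r == 0:
            continue
        coef = (vecs[:, :r].T @ db) / vals[:r] ** 2
        out[lam] = (r, b @ (vecs[:, :r] @ coef))
    return out


def layerwise_rho_auc(model, cov0: CovarianceEstimate,
                      validation: ImageEnsemble, test: ImageEnsemble,
                      lambdas: Sequence[float] = DEFAULT_LAMBDA_GRID,
                      layers: Optional[Sequence[int]] = None) -> dict:
    """RHO AUC at selected layer outputs of a trained linear denoiser.

    For each requested layer d (1..D), the input covariance and class-mean
    difference are propagated analytically, the regularization threshold
    is selected on the validation set (same sweep protocol as in image
    space), and the empirical AUC of the resulting template on the test
    set is reported.  Because every layer is affine, a layer-space
    template w_d scores an image g as (W_d...W_1 g)^T w_d; the biases
    shift both classes equally and cancel in the ROC, so templates are
    pulled back to image space once and applied directly to the raw
    images — no feature ensembles are ever materialized.

    Returns {layer: {"auc": float, "lam": float, "rank": int}}.
    """
    from .denoisers import extract_layer_operators

    ops = extract_layer_operators(model)
    d_total = len(ops)
    layers = list(range(1, d_total + 1)) if layers is None else sorted(layers)
    a0 = covariance_sqrt_factor(cov0.pooled)
    v0, v1 = validation.split_classes()
    t0, t1 = test.split_classes()
    v0 = v0.reshape(len(v0), -1).astype(np.float64)
    v1 = v1.reshape(len(v1), -1).astype(np.float64)
    t0 = t0.reshape(len(t0), -1).astype(np.float64)
    t1 = t1.reshape(len(t1), -1).astype(np.float64)
    results = {}
    b = a0
    dlt = cov0.delta_mean
    done = 0
    for layer in layers:
        for op in ops[done:layer]:
            b = op.matrix @ b
            dlt = op.matrix @ dlt
        done = layer
        templates = _layer_rho_templates(b, dlt, lambdas)
        best = None
        for lam, (rank, w_d) in templates.items():
            w_img = w_d
            for op in reversed(ops[:layer]):   # pull back to image space
                w_img = op.matrix.T @ w_img
            auc = empirical_auc(v0 @ w_img, v1 @ w_img).auc
            if best is None or auc > best[0]:
                best = (auc, lam, rank, w_img)
        _, lam, rank, w_img = best
        auc = empirical_auc(t0 @ w_img, t1 @ w_img).auc
        results[layer] = {"auc": auc, "lam": lam, "rank": rank}
    return results
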