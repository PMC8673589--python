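"""Linear numerical observers for SKE/BKS binary signal detection.

Implements the Hotelling observer (HO), its truncated-SVD regularized
variant (RHO), the channelized Hotelling observer (CHO) with
difference-of-Gaussians channels and internal noise, and the
non-prewhitening matched filter (NPWMF), together with the two covariance
estimation routes (empirical and decomposition).

The HO template is ``w = K_g^{-1} dg`` where ``K_g = (K0 + K1)/2`` is the
pooled class covariance and ``dg`` the class-mean difference (equal to
the signal image ``s`` for a linear system and an SKE task).  The RHO
replaces the inverse by the Moore-Penrose inverse of the low-rank
approximation that keeps singular values above ``lambda * sigma_max``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._roc import empirical_auc
from .phantom_imaging import ImageEnsemble, NoiseParams

__all__ = [
    "CovarianceEstimate", "LinearObserverTemplate", "RhoConfig", "ChannelSet",
    "InternalNoiseParams", "DogChannelParams",
    "estimate_covariance_empirical", "estimate_covariance_decomposition",
    "hotelling_template", "rho_template", "select_rho_lambda",
    "dog_channel_matrix", "channelize", "cho_statistics",
    "npwmf_template", "apply_linear_template",
]

DEFAULT_LAMBDA_GRID = (1e-3, 1e-4, 1e-5, 1e-6, 1e-7)

MAX_HO_CONDITION = 1e12


@dataclass
class CovarianceEstimate:
    """Class means and covariances, pooled as K_g = (K0 + K1) / 2."""

    mean0: np.ndarray
    mean1: np.ndarray
    k0: np.ndarray
    k1: np.ndarray
    method: str = "empirical"
    n0: int = 0
    n1: int = 0

    @property
    def pooled(self) -> np.ndarray:
        return 0.5 * (self.k0 + self.k1)

    @property
    def delta_mean(self) -> np.ndarray:
        return self.mean1 - self.mean0


@dataclass
class LinearObserverTemplate:
    """A template vector w; the test statistic is t(g) = w.T vec(g)."""

    w: np.ndarray
    kind: str
    lam: Optional[float] = None
    rank: Optional[int] = None


@dataclass
class RhoConfig:
    lam: float
    candidates: tuple = DEFAULT_LAMBDA_GRID
    validation_auc: Optional[dict] = None

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError("lambda must lie in (0, 1)")


@dataclass
class DogChannelParams:
    """Difference-of-Gaussians radial frequency channels.

    Channel j (j = 1..n_channels) has profile
    C_j(rho) = exp(-0.5 (rho / (Q sigma_j))^2) - exp(-0.5 (rho / sigma_j)^2)
    with sigma_j = sigma0 * alpha^j, rho in cycles/pixel.
    """

    sigma0: float = 0.005
    alpha: float = 1.4
    q: float = 1.67
    n_channels: int = 10

    def __post_init__(self):
        if self.sigma0 <= 0 or self.alpha <= 1 or self.q <= 1:
            raise ValueError("require sigma0 > 0, alpha > 1, Q > 1")


@dataclass
class ChannelSet:
    """Channel matrix T (channels x pixels) with its construction metadata."""

    t: np.ndarray
    params: DogChannelParams
    shape: tuple[int, int]
    center: tuple[float, float]


@dataclass
class InternalNoiseParams:
    """Channel internal noise: K_int = level * diag(K_v)."""

    level: float = 2.5

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("internal noise level must be nonnegative")


def _vec(images: np.ndarray) -> np.ndarray:
    """(N, H, W) or (N, P) -> (N, P) float64."""
    images = np.asarray(images)
    return images.reshape(len(images), -1).astype(np.float64)


def estimate_covariance_empirical(absent: np.ndarray,
                                  present: np.ndarray) -> CovarianceEstimate:
    """Unbiased sample means/covariances per class from image stacks."""
    g0, g1 = _vec(absent), _vec(present)
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need at least two samples per class")
    return CovarianceEstimate(
        mean0=g0.mean(axis=0), mean1=g1.mean(axis=0),
        k0=np.cov(g0, rowvar=False), k1=np.cov(g1, rowvar=False),
        method="empirical", n0=len(g0), n1=len(g1))


def estimate_covariance_decomposition(targets_absent: np.ndarray,
                                      targets_present: np.ndarray,
                                      noise: NoiseParams) -> CovarianceEstimate:
    """Covariance decomposition: K(g) = K(background) + K(noise).

    Uses noise-free image stacks per class.  For uncorrelated mixed
    Poisson-Gaussian noise, K(noise) = diag(mean noise-free image)
    + sigma^2 I (the Poisson part only when enabled).
    """
    b0, b1 = _vec(targets_absent), _vec(targets_present)
    if len(b0) < 2 or len(b1) < 2:
        raise ValueError("need at least two noise-free samples per class")
    p = b0.shape[1]
    out = []
    for b in (b0, b1):
        kb = np.cov(b, rowvar=False)
        mean = b.mean(axis=0)
        knoise = np.zeros((p, p))
        if noise.poisson:
            knoise[np.diag_indices(p)] += np.maximum(mean, 0.0)
        knoise[np.diag_indices(p)] += noise.gaussian_std ** 2
        out.append((mean, kb + knoise))
    (m0, k0), (m1, k1) = out
    return CovarianceEstimate(mean0=m0, mean1=m1, k0=k0, k1=k1,
                              method="decomposition", n0=len(b0), n1=len(b1))


def hotelling_template(cov: CovarianceEstimate) -> LinearObserverTemplate:
    """HO template w = K_g^{-1} dg; refuses ill-conditioned covariances."""
    k = cov.pooled
    cond = np.linalg.cond(k)
    if not np.isfinite(cond) or cond > MAX_HO_CONDITION:
        raise np.linalg.LinAlgError(
            f"pooled covariance is ill-conditioned (cond={cond:.3g}); "
            "use the regularized Hotelling observer (rho_template) instead")
    w = np.linalg.solve(k, cov.delta_mean)
    return LinearObserverTemplate(w=w, kind="HO")


def _sym_eig(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigendecomposition of a symmetric PSD matrix."""
    vals, vecs = np.linalg.eigh(0.5 * (k + k.T))
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def rho_template(cov: CovarianceEstimate, lam: float,
                 _eig: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> LinearObserverTemplate:
    """RHO template: truncated-SVD pseudo-inverse of K_g applied to dg.

    Keeps singular values > lam * sigma_max.  For a symmetric PSD K the
    singular values coincide with the eigenvalues, so an eigendecomposition
    is used (and may be passed in to amortize a lambda sweep).
    """
    if not (0.0 < lam < 1.0):
        raise ValueError("lambda must lie in (0, 1)")
    vals, vecs = _sym_eig(cov.pooled) if _eig is None else _eig
    keep = vals > lam * vals[0]
    r = int(keep.sum())
    u = vecs[:, :r]
    w = u @ ((u.T @ cov.delta_mean) / vals[:r])
    return LinearObserverTemplate(w=w, kind="RHO", lam=lam, rank=r)


def select_rho_lambda(cov: CovarianceEstimate,
                      validation: ImageEnsemble,
                      candidates: Sequence[float] = DEFAULT_LAMBDA_GRID,
                      ) -> tuple[RhoConfig, LinearObserverTemplate]:
    """Pick the lambda maximizing validation AUC (ties -> larger lambda).

    One eigendecomposition is shared across the sweep.
    """
    candidates = sorted(set(candidates), reverse=True)
    if not candidates:
        raise ValueError("candidate grid must be nonempty")
    g0, g1 = validation.split_classes()
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("validation set must contain both classes")
    eig = _sym_eig(cov.pooled)
    best = None
    aucs = {}
    for lam in candidates:  # descending: ties resolve to larger lambda
        tpl = rho_template(cov, lam, _eig=eig)
        auc = empirical_auc(apply_linear_template(tpl.w, g0),
                            apply_linear_template(tpl.w, g1)).auc
        aucs[lam] = auc
        if best is None or auc > best[0]:
            best = (auc, lam, tpl)
    _, lam, tpl = best
    return RhoConfig(lam=lam, candidates=tuple(candidates),
                     validation_auc=aucs), tpl


def dog_channel_matrix(shape: tuple[int, int],
                       params: DogChannelParams | None = None,
                       center: tuple[float, float] | None = None) -> ChannelSet:
    """Build DOG channel templates on the DFT frequency grid.

    Each radial-frequency profile is converted to a real spatial template
    centered at the (known) signal location via an inverse DFT with a
    linear phase shift.  Rows are not normalized; any common scale cancels
    in the channelized Hotelling statistic.
    """
    params = params or DogChannelParams()
    h, w = shape
    if h < 2 or w < 2:
        raise ValueError("degenerate grid")
    if center is None:
        center = (h / 2.0, w / 2.0)
    fr = np.fft.fftfreq(h)[:, None]
    fc = np.fft.fftfreq(w)[None, :]
    rho = np.sqrt(fr ** 2 + fc ** 2)
    phase = np.exp(-2j * np.pi * (fr * center[0] + fc * center[1]))
    rows = []
    for j in range(1, params.n_channels + 1):
        sj = params.sigma0 * params.alpha ** j
        prof = (np.exp(-0.5 * (rho / (params.q * sj)) ** 2)
                - np.exp(-0.5 * (rho / sj) ** 2))
        tmpl = np.fft.ifft2(prof * phase).real
        rows.append(tmpl.ravel())
    return ChannelSet(t=np.asarray(rows), params=params, shape=shape,
                      center=tuple(center))


def channelize(channels: ChannelSet | np.ndarray, images: np.ndarray) -> np.ndarray:
    """v = T vec(g) per image; returns (N, n_channels)."""
    t = channels.t if isinstance(channels, ChannelSet) else np.asarray(channels)
    g = _vec(images)
    if g.shape[1] != t.shape[1]:
        raise ValueError("channel matrix and image size mismatch")
    return g @ t.T


def cho_statistics(v_absent: np.ndarray, v_present: np.ndarray,
                   v_test: np.ndarray,
                   internal: InternalNoiseParams,
                   rng: np.random.Generator) -> np.ndarray:
    """CHO test statistics with internal channel noise.

    The channelized covariance K_v and mean difference are estimated from
    the calibration sets (v_absent, v_present); the statistic for each
    test vector v is t = [(K_v + K_int)^{-1} dv].T (v + v_int) with
    v_int ~ N(0, K_int), K_int = level * diag(K_v), drawn independently
    per image from the provided seeded generator.
    """
    cov = estimate_covariance_empirical(v_absent, v_present)
    kv = cov.pooled
    kint = internal.level * np.diag(np.diag(kv))
    ktot = kv + kint
    cond = np.linalg.cond(ktot)
    if not np.isfinite(cond) or cond > MAX_HO_CONDITION:
        raise np.linalg.LinAlgError("channelized covariance is singular")
    w = np.linalg.solve(ktot, cov.delta_mean)
    v = _vec(v_test)
    if internal.level > 0:
        # K_int is diagonal, so channel draws are independent
        std = np.sqrt(np.diag(kint))
        v = v + rng.normal(0.0, 1.0, size=v.shape) * std
    return v @ w


def npwmf_template(cov: CovarianceEstimate) -> LinearObserverTemplate:
    """Non-prewhitening matched filter: w = dg (first-order statistics only)."""
    return LinearObserverTemplate(w=cov.delta_mean.copy(), kind="NPWMF")


def apply_linear_template(w: np.ndarray | LinearObserverTemplate,
                          images: np.ndarray) -> np.ndarray:
    """t_i = w.T vec(g_i) for a stack of images."""
    if isinstance(w, LinearObserverTemplate):
        w = w.w
    g = _vec(images)
    if g.shape[1] != len(w):
        raise ValueError("template length and image size mismatch")
    return g @ np.asarray(w, dtype=np.float64)
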