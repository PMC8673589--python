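"""ROC analysis primitives shared across observer and experiment modules.

Empirical (Mann-Whitney) AUC is the canonical estimator throughout the
package; its standard error uses the Hanley-McNeil closed form with an
optional bootstrap cross-check.  A Gaussian-moment ("binormal") fit is
provided as an optional cross-check only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ROCResult", "empirical_auc", "hanley_mcneil_se", "bootstrap_auc_se",
           "binormal_auc"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    n0: int
    n1: int
    method: str = "empirical"

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def empirical_auc(t0: np.ndarray, t1: np.ndarray) -> ROCResult:
    """Nonparametric AUC: P(t1 > t0) + 0.5 P(t1 = t0) via the Mann-Whitney U.

    t0: test statistics under the signal-absent class, t1 signal-present.
    """
    t0 = np.asarray(t0, dtype=np.float64).ravel()
    t1 = np.asarray(t1, dtype=np.float64).ravel()
    if len(t0) == 0 or len(t1) == 0:
        raise ValueError("both classes must be nonempty")
    u = stats.mannwhitneyu(t1, t0, alternative="two-sided").statistic
    auc = float(u) / (len(t0) * len(t1))
    se = hanley_mcneil_se(auc, len(t0), len(t1))
    return ROCResult(auc=auc, se=se, n0=len(t0), n1=len(t1))


def hanley_mcneil_se(auc: float, n0: int, n1: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least two samples per class")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n0 * n1)
    return float(np.sqrt(max(var, 0.0)))


def bootstrap_auc_se(t0: np.ndarray, t1: np.ndarray, n_boot: int = 200,
                     rng: np.random.Generator | None = None) -> float:
    """Bootstrap standard error of the empirical AUC (cross-check)."""
    rng = rng or np.random.default_rng(0)
    t0 = np.asarray(t0).ravel()
    t1 = np.asarray(t1).ravel()
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        b0 = t0[rng.integers(0, len(t0), len(t0))]
        b1 = t1[rng.integers(0, len(t1), len(t1))]
        # rank-based AUC without SE recomputation
        u = stats.mannwhitneyu(b1, b0, alternative="two-sided").statistic
        aucs[b] = u / (len(t0) * len(t1))
    return float(aucs.std(ddof=1))


def binormal_auc(t0: np.ndarray, t1: np.ndarray) -> float:
    """Gaussian-moment (binormal) AUC fit: Phi(dmu / sqrt(s0^2 + s1^2))."""
    t0 = np.asarray(t0, dtype=np.float64).ravel()
    t1 = np.asarray(t1, dtype=np.float64).ravel()
    d = t1.mean() - t0.mean()
    s = np.sqrt(t0.var(ddof=1) + t1.var(ddof=1))
    if s == 0:
        return 0.5 if d == 0 else float(d > 0)
    return float(stats.norm.cdf(d / s))
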