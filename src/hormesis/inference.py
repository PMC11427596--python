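"""Shared statistical kernels: cluster-robust covariance, Gaussian likelihood, Wald tests.

These are the inferential primitives the fitting modules build on.  Standard
errors throughout the package are cluster-robust "sandwich" estimates with
clustering on family, because siblings share unmodelled environment and the
usual i.i.d. covariance understates uncertainty for clustered cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class DesignError(ValueError):
    """Raised when a design matrix is rank-deficient or otherwise unusable."""


@dataclass(frozen=True)
class RobustCovariance:
    """Cluster-robust coefficient covariance.

    Attributes
    ----------
    cov : (k, k) ndarray
        Sandwich covariance of the coefficient vector.
    n_clusters : int
        Number of distinct clusters G.
    correction : float
        The CR1 small-sample factor G/(G-1) * (n-1)/(n-k) that was applied.
    """

    cov: np.ndarray
    n_clusters: int
    correction: float


def cluster_robust_cov(
    design: np.ndarray, residuals: np.ndarray, cluster_ids: np.ndarray
) -> RobustCovariance:
    """Sandwich covariance (X'X)^-1 (sum_c X_c'e_c e_c'X_c) (X'X)^-1 with CR1 correction.

    With every cluster a singleton this reduces exactly to the HC1
    heteroskedasticity-robust estimator, since G/(G-1)*(n-1)/(n-k) = n/(n-k)
    when G = n.

    Parameters
    ----------
    design : (n, k) array
    residuals : (n,) array
    cluster_ids : (n,) array of hashable cluster labels

    Raises
    ------
    DesignError
        If X'X is singular.
    ValueError
        If fewer than two clusters are present.
    """
    X = np.asarray(design, dtype=float)
    e = np.asarray(residuals, dtype=float)
    ids = np.asarray(cluster_ids)
    n, k = X.shape
    if e.shape[0] != n or ids.shape[0] != n:
        raise ValueError("design, residuals and cluster_ids must be row-aligned")

    _, codes = np.unique(ids, return_inverse=True)
    G = codes.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance needs at least 2 clusters")

    xtx = X.T @ X
    # rank check before inverting
    if np.linalg.matrix_rank(xtx) < k:
        raise DesignError("singular X'X: design matrix is rank deficient")
    bread = np.linalg.inv(xtx)

    # score per cluster: sum over rows of X_i * e_i, accumulated with bincount
    Xe = X * e[:, None]
    scores = np.zeros((G, k))
    for j in range(k):
        scores[:, j] = np.bincount(codes, weights=Xe[:, j], minlength=G)
    meat = scores.T @ scores

    correction = (G / (G - 1)) * ((n - 1) / (n - k))
    cov = correction * bread @ meat @ bread
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return RobustCovariance(cov=cov, n_clusters=int(G), correction=float(correction))


def gaussian_loglik(residuals: np.ndarray, n: int, k: int) -> float:
    """Profiled Gaussian log-likelihood at the MLE residual variance.

    ll = -n/2 * (ln(2*pi*sigma2_hat) + 1) with sigma2_hat = RSS/n.  Used for
    likelihood-ratio comparison of nested polynomial models.

    A degenerate zero-variance fit would send the likelihood to +infinity;
    that case is guarded and flagged with a warning.
    """
    if n <= k:
        raise ValueError(f"need n > k for a profiled likelihood (n={n}, k={k})")
    e = np.asarray(residuals, dtype=float)
    sigma2 = float(e @ e) / n
    if sigma2 <= np.finfo(float).tiny:
        warnings.warn("zero residual variance: log-likelihood is unbounded", RuntimeWarning)
        return np.inf
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def wald_test(theta_a: float, theta_b: float, var_a: float, var_b: float):
    """Wald chi-square(1) test of equality of two coefficients from disjoint samples.

    W = (theta_a - theta_b)^2 / (var_a + var_b), df = 1.  Independence across
    the two fits is assumed (disjoint clusters).
    """
    denom = var_a + var_b
    if denom <= 0:
        raise ValueError("variance sum must be positive")
    W = (theta_a - theta_b) ** 2 / denom
    p = float(stats.chi2.sf(W, 1))
    return float(W), 1, p
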