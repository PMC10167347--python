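"""Genomic relationship matrix and REML narrow-sense heritability.

The model is the standard single-component animal model
``y = X b + g + e`` with ``g ~ N(0, sigma_g^2 K)`` for a genomic
relationship matrix K and ``e ~ N(0, sigma_e^2 I)``.  After a single
eigendecomposition K = U D U' the covariance is diagonal in the rotated
basis and the restricted likelihood reduces to a one-dimensional profile
in h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2), maximized by bounded scalar
optimization.  The standard error comes from the observed information
(numerical curvature of the profile restricted log-likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .association import DosagePanel, _design, _impute_mean

_BOUND = 1e-6  # optimization clamp; estimates at the clamp are flagged


@dataclass
class GRM:
    """Standardized-genotype relationship matrix (uniform SNP weights)."""

    matrix: np.ndarray
    n_snps_used: int
    ids: list[str]


@dataclass
class H2Estimate:
    h2: float
    sigma_g2: float
    sigma_e2: float
    se: float
    loglik: float
    boundary: bool
    converged: bool


def compute_grm(panel: DosagePanel) -> GRM:
    """GRM = Z Z' / M with Z the column-standardized dosage matrix.

    Monomorphic SNPs are excluded (their count is reported via
    n_snps_used, which covers only the SNPs actually used).
    """
    g = _impute_mean(panel.dosages)
    p = g.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    g = g[:, keep]
    p = p[keep]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs")
    return GRM(matrix=z @ z.T / m, n_snps_used=m, ids=list(panel.ids))


def _reml_profile(h2: float, d: np.ndarray, ytil: np.ndarray, xtil: np.ndarray) -> tuple[float, float]:
    """Restricted log-likelihood profiled over sigma_p^2 and fixed effects.

    Returns (loglik, sigma_p2_hat) for total variance parameterization
    V = sigma_p^2 * (h2 * K + (1 - h2) * I).
    """
    n, q = xtil.shape
    w = h2 * d + (1.0 - h2)
    if np.any(w <= 0):
        return -np.inf, np.nan
    wi = 1.0 / w
    xtwx = xtil.T @ (xtil * wi[:, None])
    xtwy = xtil.T @ (ytil * wi)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan
    r = ytil - xtil @ beta
    rss = float(r @ (r * wi))
    sigma_p2 = rss / (n - q)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(xtil.T @ xtil)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * sigma_p2) + 1.0)
        + np.sum(np.log(w))
        + logdet_xtwx
        - logdet_xtx
    )
    return float(ll), sigma_p2


def reml_h2(
    trait: np.ndarray,
    grm: GRM,
    covariates=None,
    jitter: float = 1e-8,
) -> H2Estimate:
    """REML heritability for one quantitative trait with fixed covariates."""
    y = np.asarray(trait, float)
    n = y.shape[0]
    if grm.matrix.shape[0] != n:
        raise ValueError("GRM size must match trait length")
    x, _ = _design(covariates, n)
    if n <= x.shape[1] + 2:
        raise ValueError("too few individuals for the covariate set")
    k = grm.matrix
    d, u = np.linalg.eigh(k)
    if d.min() < -1e-6 * max(1.0, d.max()):
        d_j, u = np.linalg.eigh(k + jitter * np.eye(n))
        if d_j.min() < 0:
            raise ValueError("GRM not positive semidefinite after jitter")
        d = d_j
    d = np.clip(d, 0.0, None)
    ytil = u.T @ y
    xtil = u.T @ x

    neg = lambda h: -_reml_profile(h, d, ytil, xtil)[0]
    res = optimize.minimize_scalar(neg, bounds=(_BOUND, 1 - _BOUND), method="bounded", options={"xatol": 1e-8})
    h2 = float(res.x)
    ll, sigma_p2 = _reml_profile(h2, d, ytil, xtil)
    boundary = h2 < 10 * _BOUND or h2 > 1 - 10 * _BOUND
    # observed information from the numerical curvature of the profile
    eps = 1e-4
    lo, hi = max(h2 - eps, _BOUND / 2), min(h2 + eps, 1 - _BOUND / 2)
    ll_lo = _reml_profile(lo, d, ytil, xtil)[0]
    ll_hi = _reml_profile(hi, d, ytil, xtil)[0]
    curv = (ll_hi - 2 * ll + ll_lo) / ((hi - h2) * (h2 - lo))
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan
    if boundary:
        warnings.warn("heritability estimate at optimization boundary")
    return H2Estimate(
        h2=h2,
        sigma_g2=h2 * sigma_p2,
        sigma_e2=(1 - h2) * sigma_p2,
        se=se,
        loglik=ll,
        boundary=boundary,
        converged=bool(res.success),
    )
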