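"""Multivariate shape GWAS with a two-block mixed-model approximation.

A full multivariate linear mixed model on all shape principal components
is computationally prohibitive, so the trait covariance is approximated in
two blocks: the first ``k`` PCs (which carry most of the shape variance)
get full genetic and residual covariance matrices ``Vg`` and ``Ve``; every
later PC gets an independent univariate variance pair; all cross-block and
later-PC covariances are fixed at zero.  Centroid size enters as a fixed
covariate.

After rotating by the GRM eigenvectors, each individual's score vector has
block-diagonal covariance ``Omega_i = blockdiag(d_i Vg + Ve,
diag(d_i sg_t^2 + se_t^2))``; scores are whitened by ``Omega_i^{-1/2}``
("corrected PC scores") and SNP dosages by a per-individual scalar weight
(root average precision across traits, the scalar compromise that keeps a
single predictor column per SNP for the multivariate test), both then
residualized on the similarly corrected fixed covariates.  Each SNP is
tested with the Pillai trace from the multivariate regression of corrected
scores on corrected dosage, and genome-wide significance is calibrated by
permutation of the corrected score rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .heritability import GRM, _reml_profile
from .morphometrics import ProcrustesFit


@dataclass
class ShapePCs:
    """PCA of the symmetric shape component in Procrustes tangent space."""

    scores: np.ndarray  # n x T
    eigenvalues: np.ndarray
    loadings: np.ndarray  # T x (k*d)
    mean_flat: np.ndarray
    centroid_size: np.ndarray


@dataclass
class TwoBlockModel:
    k: int
    vg: np.ndarray  # k x k genetic covariance
    ve: np.ndarray  # k x k residual covariance
    block2: pd.DataFrame  # per later trait: sigma_g2, sigma_e2, h2
    beta: np.ndarray  # fixed-effect estimates, (q x T)
    converged: bool
    n_iter: int
    loglik: float


def shape_pca(fit: ProcrustesFit, rank_tol: float = 1e-8) -> ShapePCs:
    """Centered PCA of the symmetric component, in tangent space.

    Configurations are projected onto the Procrustes tangent space at the
    mean (the component along the mean shape, i.e. residual scale
    variation, is removed) so that the similarity and symmetry constraints
    are all linear and the covariance rank equals the closed-form
    symmetric shape-space dimension.  Components with eigenvalue
    > rank_tol x leading eigenvalue are retained.
    """
    if fit.symmetric is None:
        raise ValueError("fit has no symmetric component")
    coords = fit.symmetric.coords
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least three individuals")
    flat = coords.reshape(n, -1)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    mhat = mean_flat / np.linalg.norm(mean_flat)
    tangent = centered - np.outer(centered @ mhat, mhat)
    u, s, vt = np.linalg.svd(tangent, full_matrices=False)
    eig = s**2 / (n - 1)
    t = int(np.sum(eig > rank_tol * eig[0]))
    return ShapePCs(
        scores=u[:, :t] * s[:t],
        eigenvalues=eig[:t],
        loadings=vt[:t],
        mean_flat=mean_flat,
        centroid_size=np.asarray(fit.symmetric.centroid_size, float),
    )


# ---------------------------------------------------------------------------
# two-block covariance fit
# ---------------------------------------------------------------------------


def _fixed_design(pcs: ShapePCs, covariates) -> np.ndarray:
    """Intercept + centroid size + extra covariates; a constant centroid
    size (no size variation) is dropped to keep the design full rank."""
    n = pcs.scores.shape[0]
    parts = [np.ones((n, 1))]
    cs = np.asarray(pcs.centroid_size, float)
    if np.std(cs) > 1e-12:
        parts.append(cs[:, None])
    if covariates is not None:
        c = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        parts.append(c)
    return np.column_stack(parts)


def _gls_beta(ztil, xtil, vinvs):
    """GLS fixed effects for the k-variate block: per-individual k x k
    precision vinvs[i]."""
    n, k = ztil.shape
    q = xtil.shape[1]
    a = np.zeros((q * k, q * k))
    b = np.zeros(q * k)
    for i in range(n):
        xi = xtil[i]
        a += np.kron(np.outer(xi, xi), vinvs[i])
        b += np.kron(xi, vinvs[i] @ ztil[i])
    beta = np.linalg.solve(a, b).reshape(q, k)
    return beta


def fit_two_block(
    pcs: ShapePCs,
    grm: GRM,
    k: int = 10,
    covariates: np.ndarray | pd.DataFrame | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> TwoBlockModel:
    """Fit the two-block mixed-model covariance structure.

    Block 1 (first k PCs): EM for the k-variate variance components
    (Vg, Ve) with per-individual covariance d_i Vg + Ve in the
    GRM-eigenrotated basis, fixed effects re-estimated by GLS each
    iteration, until the relative log-likelihood change is < tol.
    Block 2: per-trait univariate REML (same rotated machinery as the
    heritability module).  Centroid size is always included as a fixed
    covariate alongside the intercept and any extra covariates.
    """
    scores = pcs.scores
    n, t_dim = scores.shape
    if k > t_dim:
        raise ValueError("k exceeds number of shape PCs")
    d, u = np.linalg.eigh(grm.matrix)
    d = np.clip(d, 0.0, None)
    x = _fixed_design(pcs, covariates)
    xtil = u.T @ x
    ztil = u.T @ scores

    z1 = ztil[:, :k]
    # EM on u_i, e_i with z_i = B'x_i + sqrt(d_i) u_i + e_i
    resid0 = z1 - xtil @ np.linalg.lstsq(xtil, z1, rcond=None)[0]
    vg = np.cov(resid0, rowvar=False) * 0.5 + 1e-6 * np.eye(k)
    ve = np.cov(resid0, rowvar=False) * 0.5 + 1e-6 * np.eye(k)
    ll_old = -np.inf
    converged = False
    it = 0
    beta = None
    for it in range(1, max_iter + 1):
        vinvs = np.empty((n, k, k))
        for i in range(n):
            vinvs[i] = np.linalg.inv(d[i] * vg + ve)
        beta = _gls_beta(z1, xtil, vinvs)
        r = z1 - xtil @ beta
        # log-likelihood
        ll = 0.0
        vg_acc = np.zeros((k, k))
        ve_acc = np.zeros((k, k))
        for i in range(n):
            vi_inv = vinvs[i]
            ri = r[i]
            sign, logdet = np.linalg.slogdet(vi_inv)
            ll += 0.5 * (logdet - ri @ vi_inv @ ri - k * np.log(2 * np.pi))
            # E-step
            uhat = np.sqrt(d[i]) * vg @ (vi_inv @ ri)
            ucov = vg - d[i] * vg @ vi_inv @ vg
            ehat = ve @ (vi_inv @ ri)
            ecov = ve - ve @ vi_inv @ ve
            vg_acc += np.outer(uhat, uhat) + ucov
            ve_acc += np.outer(ehat, ehat) + ecov
        vg_new = 0.5 * (vg_acc + vg_acc.T) / n
        ve_new = 0.5 * (ve_acc + ve_acc.T) / n
        if np.isfinite(ll) and abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            vg, ve = vg_new, ve_new
            converged = True
            break
        vg, ve = vg_new, ve_new
        ll_old = ll
    if not converged:
        warnings.warn(f"two-block EM did not converge in {max_iter} iterations")

    rows = []
    beta2 = np.linalg.lstsq(xtil, ztil[:, k:], rcond=None)[0] if t_dim > k else np.empty((x.shape[1], 0))
    for j in range(k, t_dim):
        y = ztil[:, j]
        from scipy import optimize

        neg = lambda h: -_reml_profile(h, d, y, xtil)[0]
        res = optimize.minimize_scalar(neg, bounds=(1e-6, 1 - 1e-6), method="bounded", options={"xatol": 1e-8})
        h2 = float(res.x)
        _, sp2 = _reml_profile(h2, d, y, xtil)
        rows.append({"trait": j, "sigma_g2": h2 * sp2, "sigma_e2": (1 - h2) * sp2, "h2": h2})
    block2 = pd.DataFrame(rows, columns=["trait", "sigma_g2", "sigma_e2", "h2"])
    full_beta = np.column_stack([beta, beta2]) if t_dim > k else beta
    return TwoBlockModel(
        k=k, vg=vg, ve=ve, block2=block2, beta=full_beta, converged=converged, n_iter=it, loglik=ll_old
    )


# ---------------------------------------------------------------------------
# GLS correction and Pillai scan
# ---------------------------------------------------------------------------


def _inv_sqrt_psd(a: np.ndarray, jitter: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(a)
    if w.min() <= 0:
        w, v = np.linalg.eigh(a + jitter * np.eye(a.shape[0]))
        if w.min() <= 0:
            raise np.linalg.LinAlgError("per-individual covariance singular after jitter")
    return (v / np.sqrt(w)) @ v.T


def correct_scores_and_dosage(
    model: TwoBlockModel,
    pcs: ShapePCs,
    grm: GRM,
    dosages: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS-corrected PC scores, dosages and covariates.

    In the GRM-eigenrotated basis, subtract fitted fixed effects, whiten
    each individual's score vector by Omega_i^{-1/2} (matrix structure for
    block 1, scalar per trait for block 2), and whiten dosages and
    covariates by the per-individual scalar root-average-precision weight;
    corrected scores and dosages are finally residualized on the corrected
    covariates (intercept, centroid size, extras), making them exactly
    orthogonal to them in-sample.

    Returns (corrected_scores, corrected_dosages, corrected_covariates).
    """
    scores = pcs.scores
    n, t_dim = scores.shape
    k = model.k
    d, u = np.linalg.eigh(grm.matrix)
    d = np.clip(d, 0.0, None)
    x = _fixed_design(pcs, covariates)
    xtil = u.T @ x
    ztil = u.T @ scores
    gtil = u.T @ np.asarray(dosages, float)
    if gtil.ndim == 1:
        gtil = gtil[:, None]

    r = ztil - xtil @ model.beta
    sg2 = model.block2["sigma_g2"].to_numpy() if len(model.block2) else np.empty(0)
    se2 = model.block2["sigma_e2"].to_numpy() if len(model.block2) else np.empty(0)

    s_corr = np.empty_like(r)
    weights = np.empty(n)
    for i in range(n):
        v1 = d[i] * model.vg + model.ve
        w1 = _inv_sqrt_psd(v1)
        s_corr[i, :k] = w1 @ r[i, :k]
        prec1 = np.diag(w1 @ w1)
        if t_dim > k:
            v2 = d[i] * sg2 + se2
            v2 = np.clip(v2, 1e-12, None)
            s_corr[i, k:] = r[i, k:] / np.sqrt(v2)
            prec = np.concatenate([prec1, 1.0 / v2])
        else:
            prec = prec1
        weights[i] = np.sqrt(prec.mean())

    x_corr = xtil * weights[:, None]
    g_corr = gtil * weights[:, None]
    q, _ = np.linalg.qr(x_corr)
    g_corr = g_corr - q @ (q.T @ g_corr)
    s_corr = s_corr - q @ (q.T @ s_corr)
    return s_corr, g_corr, x_corr


def pillai_scan(
    corrected_dosage: np.ndarray,
    corrected_scores: np.ndarray,
    snp_ids: list[str] | None = None,
    extra_df: int = 0,
) -> pd.DataFrame:
    """Pillai-trace association of the corrected scores with each SNP.

    For a single predictor g: hypothesis SSCP H = a a' / (g'g) with
    a = S'g, error E = S'S - H, and Pillai trace V = tr(H (H+E)^{-1}) =
    a'(S'S)^{-1} a / g'g.  The F approximation with one predictor is
    F = ((n - T - 1 - extra_df) / T) * V / (1 - V) on (T, n - T - 1 -
    extra_df) df; ``extra_df`` can account for covariates already
    residualized out.  Zero-variance corrected dosages give NA.
    """
    s = np.asarray(corrected_scores, float)
    g = np.asarray(corrected_dosage, float)
    if g.ndim == 1:
        g = g[:, None]
    n, t_dim = s.shape
    sts_inv = np.linalg.inv(s.T @ s)
    a = s.T @ g  # T x M
    gg = (g**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.einsum("tm,ts,sm->m", a, sts_inv, a) / gg
    df2 = n - t_dim - 1 - extra_df
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (df2 / t_dim) * v / (1.0 - v)
    p = stats.f.sf(f, t_dim, df2)
    bad = gg <= 0
    v = np.where(bad, np.nan, v)
    f = np.where(bad, np.nan, f)
    p = np.where(bad, np.nan, np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "snp": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(g.shape[1])],
            "pillai": v,
            "F": f,
            "df1": t_dim,
            "df2": df2,
            "p": p,
        }
    )


def permutation_fdr(
    scan: pd.DataFrame,
    corrected_scores: np.ndarray,
    corrected_dosage: np.ndarray,
    n_perm: int = 100,
    fdr: float = 0.05,
    seed: int = 0,
    extra_df: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Permutation FDR for the Pillai scan.

    Rows of the corrected scores are permuted jointly; all SNPs are
    rescanned per permutation.  FDR(p) = (mean permuted count of p' <= p)
    / (observed count of p_obs <= p); the threshold is the largest
    observed p with FDR <= fdr.  Deterministic given the seed.
    """
    if n_perm < 10:
        warnings.warn("fewer than 10 permutations; FDR estimate will be crude")
    rng = np.random.default_rng(seed)
    obs = np.sort(scan["p"].dropna().to_numpy())
    if obs.size == 0:
        return 0.0, scan.assign(significant=False)
    perm_ps = []
    s = np.asarray(corrected_scores, float)
    for _ in range(n_perm):
        sp = s[rng.permutation(s.shape[0])]
        perm_ps.append(pillai_scan(corrected_dosage, sp, extra_df=extra_df)["p"].dropna().to_numpy())
    perm_all = np.sort(np.concatenate(perm_ps))
    n_obs_le = np.arange(1, obs.size + 1)  # count of observed p <= obs[k]
    n_perm_le = np.searchsorted(perm_all, obs, side="right") / n_perm
    fdr_at = n_perm_le / n_obs_le
    ok = np.flatnonzero(fdr_at <= fdr)
    thr = float(obs[ok.max()]) if ok.size else 0.0
    out = scan.assign(significant=scan["p"] <= thr if thr > 0 else False)
    return thr, out


def snp_shape_effect(
    dosage: np.ndarray,
    fit: ProcrustesFit,
    magnify: float = 20.0,
) -> dict:
    """Per-landmark displacement field of one SNP on the symmetric shape.

    Regresses each symmetric-component coordinate on the dosage and
    returns the mean shape with the effect added/subtracted, magnified for
    visualization.
    """
    if fit.symmetric is None:
        raise ValueError("fit has no symmetric component")
    coords = fit.symmetric.coords
    n, k, dd = coords.shape
    g = np.asarray(dosage, float)
    gc = g - g.mean()
    denom = (gc**2).sum()
    slopes = np.tensordot(gc, coords - coords.mean(axis=0), axes=(0, 0)) / denom
    mean_shape = coords.mean(axis=0)
    return {
        "mean_shape": mean_shape,
        "displacement": slopes,
        "plus": mean_shape + magnify * slopes,
        "minus": mean_shape - magnify * slopes,
        "magnify": magnify,
    }
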