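"""Single-trait SNP association and multiple-testing machinery.

Covers the genotype side of the pipeline: genotype PCA for stratification
control, KING-robust kinship filtering, per-trait ordinary-least-squares
GWAS with covariates, genomic-control lambda, effective numbers of
independent traits/SNPs (Li & Ji), Benjamini-Hochberg FDR, LD clumping,
conditional scans, and the two local-ancestry-aware model variants used in
admixed cohorts (SNP1: local-ancestry covariates; TRACTOR:
ancestry-specific allele dosages with a joint F-test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class RankDeficiencyError(ValueError):
    """Covariate matrix is rank deficient."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DosagePanel:
    """SNP dosages with positions and optional phased local ancestry.

    dosages: (n individuals x M SNPs) alternative-allele counts in [0, 2]
    (float; missing = NaN).  snp_table: chrom, pos (1-based), id, ref, alt.
    haplotypes / ancestry: optional (2n x M) phased alleles and per-haplotype
    local-ancestry codes; haplotypes 2i and 2i+1 belong to individual i.
    """

    dosages: np.ndarray
    snp_table: pd.DataFrame
    ids: list[str] = field(default_factory=list)
    haplotypes: np.ndarray | None = None
    ancestry: np.ndarray | None = None
    ancestry_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, float)
        if not self.ids:
            self.ids = [f"ind{i}" for i in range(self.dosages.shape[0])]
        if len(self.ids) != self.dosages.shape[0]:
            raise ValueError("ids must match dosage rows")
        if len(self.snp_table) != self.dosages.shape[1]:
            raise ValueError("snp_table must match dosage columns")
        for chrom, grp in self.snp_table.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within chromosome {chrom}")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * self.dosages.shape[0], self.dosages.shape[1]):
                raise ValueError("haplotypes must be (2n, M)")
            implied = self.haplotypes[0::2].astype(float) + self.haplotypes[1::2].astype(float)
            ok = np.isnan(self.dosages) | (np.abs(implied - self.dosages) < 1e-9)
            if not np.all(ok):
                raise ValueError("dosages inconsistent with phased haplotypes")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, mask: np.ndarray) -> "DosagePanel":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        hap_idx = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return DosagePanel(
            dosages=self.dosages[idx],
            snp_table=self.snp_table,
            ids=[self.ids[i] for i in idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[hap_idx],
            ancestry=None if self.ancestry is None else self.ancestry[hap_idx],
            ancestry_labels=self.ancestry_labels,
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _impute_mean(g: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages."""
    g = np.array(g, float)
    if np.isnan(g).any():
        mu = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = mu[idx[1]]
    return g


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, list[str]]:
    """Covariate design with intercept; raises on rank deficiency, naming columns."""
    if covariates is None:
        c = np.empty((n, 0))
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        c = covariates.to_numpy(float)
        names = [str(x) for x in covariates.columns]
    else:
        c = np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        names = [f"cov{i}" for i in range(c.shape[1])]
    x = np.column_stack([np.ones(n), c])
    names = ["intercept"] + names
    r = np.linalg.matrix_rank(x)
    if r < x.shape[1]:
        # identify offending columns by greedy QR
        bad = []
        keep = np.ones(1)
        basis = x[:, :1]
        for j in range(1, x.shape[1]):
            cand = np.column_stack([basis, x[:, j]])
            if np.linalg.matrix_rank(cand) == basis.shape[1]:
                bad.append(names[j])
            else:
                basis = cand
        raise RankDeficiencyError(f"collinear covariate columns: {bad}")
    return x, names


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y (vector or matrix) on the column space of x."""
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


# ---------------------------------------------------------------------------
# stratification and relatedness
# ---------------------------------------------------------------------------


def genotype_pca(panel: DosagePanel, n_components: int = 6) -> np.ndarray:
    """Principal components of standardized genotypes.

    Each SNP column is centered by 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat));
    scores are the projections on the top right singular vectors.  Sign
    convention: the largest-absolute-loading element of each component is
    positive.
    """
    g = _impute_mean(panel.dosages)
    p = g.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        g = g[:, keep]
        p = p[keep]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    if n_components == 0:
        return np.empty((panel.n, 0))
    if n_components > min(z.shape):
        raise ValueError("n_components exceeds matrix rank")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


def kinship_king(panel: DosagePanel, threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """KING-robust between-family kinship and a relatedness keep-mask.

    phi_ij = (N_het,het - 2 * N_opposite-hom) / (N_het(i) + N_het(j)),
    counting over sites non-missing in both individuals.  Pairs with
    phi > threshold are broken greedily, removing the member genotyped at
    fewer markers first (ties: higher index).  phi of an individual with
    itself is 0.5.
    """
    g = np.asarray(panel.dosages, float)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    obs = ~np.isnan(g)
    het = (g == 1) & obs
    hom0 = (g == 0) & obs
    hom2 = (g == 2) & obs
    het_f = het.astype(float)
    n_hh = het_f @ het_f.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    # per-pair het counts restricted to mutually observed sites
    obs_f = obs.astype(float)
    het_i = het_f @ obs_f.T  # het(i) over sites observed in j
    denom = het_i + het_i.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_hh - 2 * n_opp) / denom, np.nan)
    zero_het = ~(het.any(axis=1))
    if zero_het.any():
        import warnings

        warnings.warn(f"{zero_het.sum()} individual(s) with no heterozygous sites: kinship undefined")
        phi[zero_het, :] = np.nan
        phi[:, zero_het] = np.nan
        np.fill_diagonal(phi, np.where(zero_het, np.nan, 0.5))

    keep = np.ones(n, bool)
    keep[zero_het] = False
    n_markers = obs.sum(axis=1)
    while True:
        cand = np.triu(np.nan_to_num(phi, nan=-1.0), 1)
        cand[~keep, :] = -1
        cand[:, ~keep] = -1
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= threshold:
            break
        drop = i if (n_markers[i], -i) < (n_markers[j], -j) else j
        keep[drop] = False
    return phi, keep


# ---------------------------------------------------------------------------
# GWAS scans
# ---------------------------------------------------------------------------


def gwas_ols(
    trait: pd.Series | np.ndarray,
    panel: DosagePanel,
    covariates: pd.DataFrame | np.ndarray | None = None,
    include_pcs: bool = False,
    n_pcs: int = 6,
    pcs: np.ndarray | None = None,
    model_tag: str | None = None,
) -> pd.DataFrame:
    """Per-SNP least-squares association of a quantitative trait.

    Fits trait ~ dosage + covariates (+ genotype PCs when requested) and
    reports the Wald two-sided p-value for the dosage term.  Missing
    dosages are mean-imputed per SNP.  Implemented by residualizing trait
    and dosages on the covariates (Frisch-Waugh-Lovell), which reproduces
    the full-model estimates exactly.
    """
    y = np.asarray(trait, float)
    n = panel.n
    if y.shape[0] != n:
        raise ValueError("trait length must match panel individuals")
    if np.std(y) == 0:
        raise ValueError("trait has zero variance")
    if include_pcs and pcs is None:
        pcs = genotype_pca(panel, n_pcs)
    cov = covariates
    if pcs is not None and pcs.size:
        pc_df = pd.DataFrame(pcs, columns=[f"PC{i + 1}" for i in range(pcs.shape[1])])
        if cov is None:
            cov = pc_df
        else:
            base = cov if isinstance(cov, pd.DataFrame) else pd.DataFrame(np.asarray(cov, float))
            cov = pd.concat([base.reset_index(drop=True), pc_df], axis=1)
    x, _ = _design(cov, n)
    g = _impute_mean(panel.dosages)
    yr = _residualize(y, x)
    gr = _residualize(g, x)
    gg = (gr**2).sum(axis=0)
    df = n - x.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (gr * yr[:, None]).sum(axis=0) / gg
        rss = (yr**2).sum() - beta**2 * gg
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    p = 2 * stats.t.sf(np.abs(tstat), df)
    p = np.where(np.isfinite(tstat), np.clip(p, np.finfo(float).tiny, 1.0), np.nan)
    out = panel.snp_table[["chrom", "pos", "id", "ref", "alt"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    out["df"] = df
    out["model"] = model_tag or ("pc" if (pcs is not None and pcs.size) else "plain")
    return out


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square(1) quantile of the
    p-values divided by the null median 0.4549364."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def meff_traits(values: pd.DataFrame | np.ndarray) -> float:
    """Effective number of independent traits (Li & Ji estimator).

    Meff = sum over eigenvalues lambda of the trait correlation matrix of
    f(|lambda|), with f(x) = 1{x >= 1} + (x - floor(x)).
    """
    x = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least two traits")
    corr = np.corrcoef(x, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("non-finite correlations (constant trait?)")
    # rounding shields the floor/frac split from eigensolver noise at the
    # estimator's integer discontinuities (e.g. blocks of identical traits)
    lam = np.round(np.abs(np.linalg.eigvalsh(corr)), 9)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def meff_snps(panel: DosagePanel, r2_threshold: float = 0.1, window_bp: int = 1_000_000) -> int:
    """Effective number of independent SNPs by greedy windowed LD pruning.

    Walk SNPs in position order; each retained SNP drops every later SNP
    within window_bp (same chromosome) with squared Pearson dosage
    correlation > r2_threshold.  Returns the retained count.
    """
    g = _impute_mean(panel.dosages)
    sd = g.std(axis=0)
    chrom = panel.snp_table["chrom"].to_numpy()
    pos = panel.snp_table["pos"].to_numpy()
    m = g.shape[1]
    dropped = np.zeros(m, bool)
    z = g - g.mean(axis=0)
    n = g.shape[0]
    for j in range(m):
        if dropped[j]:
            continue
        if sd[j] == 0:
            continue
        later = np.flatnonzero(
            (~dropped)
            & (np.arange(m) > j)
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= window_bp)
        )
        if later.size == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (z[:, later].T @ z[:, j]) / (n * sd[later] * sd[j])
        dropped[later[np.nan_to_num(r) ** 2 > r2_threshold]] = True
    return int((~dropped).sum())


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (threshold, boolean rejected mask): the threshold is p_(k) for
    the largest k with p_(k) <= k*alpha/M, or 0.0 when nothing is rejected.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p)
    ps = p[order]
    ok = ps <= (np.arange(1, m + 1) * alpha / m)
    if not ok.any():
        return 0.0, np.zeros(m, bool)
    k = np.max(np.flatnonzero(ok))
    thr = float(ps[k])
    return thr, p <= thr


def _r2_with(g: np.ndarray, j: int, others: np.ndarray) -> np.ndarray:
    x = g[:, j] - g[:, j].mean()
    y = g[:, others] - g[:, others].mean(axis=0)
    denom = np.sqrt((x**2).sum() * (y**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (y.T @ x) / denom
    return np.nan_to_num(r) ** 2


def ld_clump(
    result: pd.DataFrame,
    panel: DosagePanel,
    p_entry: float = 5e-8,
    r2: float = 0.1,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Greedy LD clumping of significant association results.

    SNPs with p < p_entry seed clumps in ascending-p order; each seed
    claims unclaimed significant SNPs on the same chromosome within
    window_bp with dosage r^2 >= threshold.  When the result table covers
    several traits, each SNP enters with its minimum p across traits.
    """
    g = _impute_mean(panel.dosages)
    snp_idx = {s: i for i, s in enumerate(panel.snp_table["id"])}
    sig = result[result["p"] < p_entry]
    if sig.empty:
        return pd.DataFrame(columns=["clump", "index_snp", "index_p", "members", "span_bp"])
    best = sig.loc[sig.groupby("id")["p"].idxmin()].sort_values("p")
    claimed: set[str] = set()
    rows = []
    for rec in best.itertuples():
        if rec.id in claimed:
            continue
        j = snp_idx[rec.id]
        cand = best[
            (~best["id"].isin(claimed))
            & (best["id"] != rec.id)
            & (best["chrom"] == rec.chrom)
            & ((best["pos"] - rec.pos).abs() <= window_bp)
        ]
        members = [rec.id]
        if not cand.empty:
            idxs = np.array([snp_idx[s] for s in cand["id"]])
            r2v = _r2_with(g, j, idxs)
            members += [s for s, v in zip(cand["id"], r2v) if v >= r2]
        claimed.update(members)
        mem_pos = panel.snp_table.set_index("id").loc[members, "pos"]
        rows.append(
            {
                "clump": len(rows) + 1,
                "index_snp": rec.id,
                "index_p": rec.p,
                "members": members,
                "span_bp": int(mem_pos.max() - mem_pos.min()),
            }
        )
    return pd.DataFrame(rows)


def conditional_scan(
    trait: pd.Series | np.ndarray,
    panel: DosagePanel,
    covariates: pd.DataFrame | np.ndarray | None,
    conditioning_snps: list[str],
    test_snps: list[str] | None = None,
    suggestive: float = 1e-5,
    **gwas_kwargs,
) -> pd.DataFrame:
    """Association scan conditioning on a set of SNPs.

    The conditioning SNP dosages are appended to the covariates and the OLS
    scan re-run; a tested signal whose conditional p exceeds the suggestive
    threshold is classified "reported" (explained by the conditioning set),
    otherwise "independent".  A test SNP perfectly collinear with a
    conditioning SNP is labeled "reported" with a note instead of crashing.
    """
    snp_idx = {s: i for i, s in enumerate(panel.snp_table["id"])}
    missing = [s for s in conditioning_snps if s not in snp_idx]
    if missing:
        raise ValueError(f"conditioning SNPs absent from panel: {missing}")
    g = _impute_mean(panel.dosages)
    cond = g[:, [snp_idx[s] for s in conditioning_snps]]
    if cond.size:
        cond_df = pd.DataFrame(cond, columns=[f"cond_{s}" for s in conditioning_snps])
        if covariates is None:
            cov = cond_df
        else:
            base = covariates if isinstance(covariates, pd.DataFrame) else pd.DataFrame(np.asarray(covariates, float))
            cov = pd.concat([base.reset_index(drop=True), cond_df], axis=1)
    else:
        cov = covariates
    res = gwas_ols(trait, panel, cov, model_tag="conditional", **gwas_kwargs)
    if test_snps is not None:
        res = res[res["id"].isin(test_snps)].copy()
    notes = []
    labels = []
    for rec in res.itertuples():
        if not np.isfinite(rec.p):
            labels.append("reported")
            notes.append("collinear with conditioning set")
        elif rec.p > suggestive:
            labels.append("reported")
            notes.append("")
        else:
            labels.append("independent")
            notes.append("")
    res["classification"] = labels
    res["note"] = notes
    return res


# ---------------------------------------------------------------------------
# local-ancestry-aware models
# ---------------------------------------------------------------------------


def _la_counts(anc_col: np.ndarray, codes: np.ndarray, n: int) -> np.ndarray:
    """Per-individual counts of each non-reference ancestry at one locus.

    Drops both the first ancestry (reference; counts sum to 2 with the
    intercept) and any ancestry with constant count.
    """
    pairs = anc_col.reshape(-1, 2)
    cols = []
    for c in codes[1:]:
        v = (pairs == c).sum(axis=1).astype(float)
        if v.std() > 0:
            cols.append(v)
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _ancestry_structures(panel: DosagePanel):
    if panel.ancestry is None or panel.haplotypes is None:
        raise ValueError("panel lacks phased haplotypes / local ancestry")
    anc = panel.ancestry
    hap = panel.haplotypes
    codes = np.unique(anc)
    return hap, anc, codes


def _ols_pvalue_for_terms(y, x_full, x_reduced, term_cols):
    """F-test of the terms in x_full absent from x_reduced; returns
    (betas, p, df1, df2, collinear_flag)."""
    n = y.shape[0]
    rank_full = np.linalg.matrix_rank(x_full)
    if rank_full < x_full.shape[1]:
        return None, np.nan, 0, 0, True
    beta, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_full = float(((y - x_full @ beta) ** 2).sum())
    beta_r, _, _, _ = np.linalg.lstsq(x_reduced, y, rcond=None)
    rss_red = float(((y - x_reduced @ beta_r) ** 2).sum())
    df1 = x_full.shape[1] - x_reduced.shape[1]
    df2 = n - x_full.shape[1]
    if df1 <= 0 or df2 <= 0 or rss_full <= 0:
        return beta[term_cols], np.nan, df1, df2, True
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    p = float(stats.f.sf(f, df1, df2))
    return beta[term_cols], max(p, np.finfo(float).tiny), df1, df2, False


def snp1_scan(
    trait: pd.Series | np.ndarray,
    panel: DosagePanel,
    covariates: pd.DataFrame | np.ndarray | None = None,
    include_pcs: bool = False,
    n_pcs: int = 6,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Local-ancestry-adjusted scan (SNP1 model).

    Per SNP: trait ~ dosage + local-ancestry counts at the locus +
    covariates (+ PCs).  One ancestry is dropped as reference (counts sum
    to 2).  Wald p-value for the genotype term; a SNP whose dosage is
    collinear with the local-ancestry covariates gets NA p and a
    "collinear" flag.
    """
    y = np.asarray(trait, float)
    hap, anc, codes = _ancestry_structures(panel)
    if include_pcs and pcs is None:
        pcs = genotype_pca(panel, n_pcs)
    cov_mat = _covariate_matrix(covariates, pcs, panel.n)
    g = _impute_mean(panel.dosages)
    rows = []
    for j in range(panel.m):
        la = _la_counts(anc[:, j], codes, panel.n)
        x_full = np.column_stack([np.ones(panel.n), cov_mat, la, g[:, j]])
        if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
            rows.append({"beta": np.nan, "se": np.nan, "p": np.nan, "collinear": True})
            continue
        xtx = x_full.T @ x_full
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (x_full.T @ y)
        resid = y - x_full @ beta
        df = panel.n - x_full.shape[1]
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * xtx_inv[-1, -1])
        t = beta[-1] / se
        rows.append(
            {
                "beta": float(beta[-1]),
                "se": float(se),
                "p": max(float(2 * stats.t.sf(abs(t), df)), np.finfo(float).tiny),
                "collinear": False,
            }
        )
    out = panel.snp_table[["chrom", "pos", "id", "ref", "alt"]].copy()
    for key in ("beta", "se", "p", "collinear"):
        out[key] = [r[key] for r in rows]
    out["n"] = panel.n
    out["model"] = "snp1"
    return out


def tractor_scan(
    trait: pd.Series | np.ndarray,
    panel: DosagePanel,
    covariates: pd.DataFrame | np.ndarray | None = None,
    include_pcs: bool = False,
    n_pcs: int = 6,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Ancestry-partitioned scan (TRACTOR model).

    Per SNP: builds ancestry-specific alternative-allele dosages (count of
    alt alleles carried on haplotypes of each ancestry) plus local-ancestry
    counts, and tests the ancestry-specific genotype terms jointly with an
    F-test (df1 = number of ancestries present at the locus).  Ancestries
    absent at a locus are dropped with the df reduced; full collinearity
    yields NA with a flag.
    """
    y = np.asarray(trait, float)
    hap, anc, codes = _ancestry_structures(panel)
    if include_pcs and pcs is None:
        pcs = genotype_pca(panel, n_pcs)
    cov_mat = _covariate_matrix(covariates, pcs, panel.n)
    rows = []
    for j in range(panel.m):
        anc_j = anc[:, j].reshape(-1, 2)
        hap_j = hap[:, j].reshape(-1, 2).astype(float)
        la = _la_counts(anc[:, j], codes, panel.n)
        g_by_anc = []
        present = []
        for c in codes:
            ga = (hap_j * (anc_j == c)).sum(axis=1)
            if ga.std() > 0:
                g_by_anc.append(ga)
                present.append(c)
        x_reduced = np.column_stack([np.ones(panel.n), cov_mat, la])
        if not g_by_anc:
            rows.append({"p": np.nan, "df": 0, "betas": {}, "collinear": True})
            continue
        x_full = np.column_stack([x_reduced] + g_by_anc)
        term_cols = list(range(x_reduced.shape[1], x_full.shape[1]))
        betas, p, df1, df2, coll = _ols_pvalue_for_terms(y, x_full, x_reduced, term_cols)
        rows.append(
            {
                "p": p,
                "df": df1,
                "betas": {} if betas is None else {int(c): float(b) for c, b in zip(present, betas)},
                "collinear": coll,
            }
        )
    out = panel.snp_table[["chrom", "pos", "id", "ref", "alt"]].copy()
    for key in ("p", "df", "betas", "collinear"):
        out[key] = [r[key] for r in rows]
    out["n"] = panel.n
    out["model"] = "tractor"
    return out


def _covariate_matrix(covariates, pcs, n) -> np.ndarray:
    parts = []
    if covariates is not None:
        c = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        parts.append(c)
    if pcs is not None and np.size(pcs):
        parts.append(np.asarray(pcs, float))
    if not parts:
        return np.empty((n, 0))
    return np.column_stack(parts)
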