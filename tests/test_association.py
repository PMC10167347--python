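"""Association scans, inflation diagnostics, multiple testing, clumping,
and local-ancestry model variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from morphgwas.association import (
    DosagePanel,
    RankDeficiencyError,
    bh_fdr,
    conditional_scan,
    genotype_pca,
    gwas_ols,
    kinship_king,
    lambda_gc,
    ld_clump,
    meff_snps,
    meff_traits,
    snp1_scan,
    tractor_scan,
)
from morphgwas.simulate import SimConfig, simulate_admixed_genotypes


def make_panel(g, pos=None, chrom=None, **kw):
    g = np.asarray(g, float)
    m = g.shape[1]
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    chrom = ["1"] * m if chrom is None else chrom
    table = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"s{i}" for i in range(m)], "ref": "A", "alt": "G"}
    )
    return DosagePanel(dosages=g, snp_table=table, **kw)


@pytest.fixture(scope="module")
def admixed():
    cfg = SimConfig(seed=21, n_individuals=500, n_snps=1200)
    hap, snp, anc = simulate_admixed_genotypes(cfg)
    panel = DosagePanel(
        dosages=(hap[0::2] + hap[1::2]).astype(float),
        snp_table=snp,
        haplotypes=hap,
        ancestry=anc,
    )
    return cfg, panel, anc


class TestPca:
    def test_two_population_separation(self, rng):
        n, m = 200, 400
        pop = np.repeat([0, 1], n // 2)
        p = np.where(pop[:, None] == 0, rng.uniform(0.1, 0.5, m), rng.uniform(0.5, 0.9, m))
        g = rng.binomial(2, p).astype(float)
        pcs = genotype_pca(make_panel(g), 2)
        r = stats.pointbiserialr(pop, pcs[:, 0])[0]
        assert abs(r) > 0.9

    def test_zero_components_empty(self, rng):
        g = rng.binomial(2, 0.5, size=(30, 50)).astype(float)
        assert genotype_pca(make_panel(g), 0).shape == (30, 0)

    def test_duplicated_individuals_identical_scores(self, rng):
        g = rng.binomial(2, 0.4, size=(20, 100)).astype(float)
        g[1] = g[0]
        pcs = genotype_pca(make_panel(g), 3)
        assert np.allclose(pcs[0], pcs[1])


class TestKinship:
    def test_self_kinship_half(self, rng):
        g = rng.binomial(2, 0.5, size=(5, 200)).astype(float)
        phi, _ = kinship_king(make_panel(g))
        assert np.allclose(np.diag(phi), 0.5)

    def test_parent_offspring_quarter(self, rng):
        m = 5000
        p = rng.uniform(0.1, 0.9, m)
        hap = rng.random((6, m)) < p  # 3 founders x 2 haplotypes
        father, mother = hap[0:2], hap[2:4]
        child = np.stack([father[rng.integers(0, 2, m), np.arange(m)],
                          mother[rng.integers(0, 2, m), np.arange(m)]])
        g = np.stack([father.sum(0), mother.sum(0), child.sum(0), hap[4:6].sum(0)]).astype(float)
        phi, _ = kinship_king(make_panel(g))
        assert phi[0, 2] == pytest.approx(0.25, abs=0.03)  # parent-offspring
        assert abs(phi[0, 3]) < 0.03  # unrelated
        assert abs(phi[0, 1]) < 0.03  # spouses unrelated

    def test_related_pair_broken_by_keep_mask(self, rng):
        g = rng.binomial(2, 0.5, size=(6, 500)).astype(float)
        g[1] = g[0]  # duplicate pair -> phi = 0.5
        phi, keep = kinship_king(make_panel(g), threshold=0.1)
        assert keep.sum() == 5
        assert not (keep[0] and keep[1])


class TestGwasOls:
    def test_matches_statsmodels_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n, m = 80, 6
        g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        cov = pd.DataFrame({"age": rng.normal(50, 10, n), "sex": rng.integers(0, 2, n)})
        y = rng.standard_normal(n) + 0.3 * g[:, 2]
        res = gwas_ols(y, make_panel(g), cov)
        for j in range(m):
            x = sm.add_constant(np.column_stack([cov.to_numpy(), g[:, j]]))
            fit = sm.OLS(y, x).fit()
            assert res["beta"].iloc[j] == pytest.approx(fit.params[-1], abs=1e-10)
            assert res["se"].iloc[j] == pytest.approx(fit.bse[-1], abs=1e-10)
            assert res["p"].iloc[j] == pytest.approx(fit.pvalues[-1], abs=1e-10)

    def test_effect_recovery_within_3se(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        y = 0.5 * g[:, 4] + rng.standard_normal(n)
        res = gwas_ols(y, make_panel(g))
        row = res.iloc[4]
        assert abs(row.beta - 0.5) < 3 * row.se

    def test_collinear_covariates_named(self, rng):
        n = 50
        g = rng.binomial(2, 0.5, size=(n, 3)).astype(float)
        cov = pd.DataFrame({"a": np.arange(n, dtype=float)})
        cov["b"] = 2 * cov["a"]
        with pytest.raises(RankDeficiencyError, match="b"):
            gwas_ols(rng.standard_normal(n), make_panel(g), cov)

    def test_missing_dosages_mean_imputed(self, rng):
        n = 100
        g = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        gm = g.copy()
        gm[:10, 0] = np.nan
        gi = gm.copy()
        gi[:10, 0] = np.nanmean(gm[:, 0])
        y = rng.standard_normal(n)
        res_nan = gwas_ols(y, make_panel(gm))
        res_imp = gwas_ols(y, make_panel(gi))
        assert np.allclose(res_nan["beta"], res_imp["beta"], equal_nan=True)

    def test_type_one_error_calibrated_with_pcs(self, admixed):
        """Null traits on a structured panel, PCs included: empirical
        type-I error at alpha=0.05 within [0.045, 0.055] over >= 1e4 tests."""
        cfg, panel, _ = admixed
        rng = np.random.default_rng(99)
        pcs = genotype_pca(panel, 6)
        ps = []
        for _ in range(10):
            y = rng.standard_normal(panel.n)
            ps.append(gwas_ols(y, panel, pcs=pcs)["p"].to_numpy())
        ps = np.concatenate(ps)
        assert ps.size >= 10_000
        rate = (ps < 0.05).mean()
        assert 0.045 <= rate <= 0.055


class TestLambda:
    def test_uniform_grid_is_one(self):
        p = np.linspace(1e-6, 1, 5001)
        assert lambda_gc(p) == pytest.approx(1.0, abs=1e-3)

    def test_all_half_is_exactly_one(self):
        assert lambda_gc(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_doubled_chi2_doubles_lambda(self):
        p = np.linspace(1e-6, 0.999999, 4001)
        chi2 = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi2, 1)
        assert lambda_gc(p2) == pytest.approx(2.0, rel=0.01)

    def test_rejects_bad_pvalues(self):
        with pytest.raises(ValueError):
            lambda_gc(np.concatenate([np.full(200, 0.5), [0.0]]))

    def test_stratified_trait_inflates_without_pcs_only(self, admixed):
        """Ancestry-correlated trait: lambda in the calibrated band with PCs,
        marked inflation (> 1.2) without."""
        cfg, panel, anc = admixed
        rng = np.random.default_rng(17)
        nam_frac = (anc == 1).reshape(2, panel.n, -1, order="F").mean(axis=(0, 2)) if False else (
            (anc == 1).mean(axis=1).reshape(-1, 2).mean(axis=1)
        )
        y = stats.zscore(nam_frac) * 0.5 + rng.standard_normal(panel.n)
        pcs = genotype_pca(panel, 6)
        lam_pc = lambda_gc(gwas_ols(y, panel, pcs=pcs)["p"].to_numpy())
        lam_plain = lambda_gc(gwas_ols(y, panel)["p"].to_numpy())
        assert 0.95 <= lam_pc <= 1.074
        assert lam_plain > 1.2


class TestMeff:
    def test_identity_equals_trait_count(self, rng):
        x = rng.standard_normal((5000, 8))
        assert meff_traits(x) == pytest.approx(8, abs=0.3)

    def test_all_ones_equals_one(self, rng):
        base = rng.standard_normal(300)
        x = np.column_stack([base] * 5)
        assert meff_traits(x) == pytest.approx(1.0)

    def test_two_perfect_blocks_give_two(self, rng):
        # blocks must be exactly uncorrelated in-sample: eigenvalues {3, 2, 0...}
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        a -= a.mean()
        b -= b.mean()
        b -= (b @ a) / (a @ a) * a
        x = np.column_stack([a, a, a, b, b])
        assert meff_traits(x) == pytest.approx(2.0)

    def test_snps_all_independent_keeps_all(self, rng):
        g = rng.binomial(2, 0.5, size=(2000, 30)).astype(float)
        assert meff_snps(make_panel(g), r2_threshold=0.1) == 30

    def test_duplicated_snps_leave_one_survivor(self, rng):
        col = rng.binomial(2, 0.4, size=500).astype(float)
        g = np.column_stack([col, col, col, rng.binomial(2, 0.5, 500)])
        assert meff_snps(make_panel(g)) == 2

    def test_toy_panel_matches_exhaustive_pruning(self, rng):
        g = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
        g[:, 1] = g[:, 0] + (rng.random(200) < 0.05)  # high LD with 0
        g[:, 3] = g[:, 2]  # perfect LD with 2
        panel = make_panel(np.clip(g, 0, 2))
        gg = panel.dosages
        # brute-force greedy pruning oracle
        kept = []
        dropped = set()
        for j in range(5):
            if j in dropped:
                continue
            kept.append(j)
            for l in range(j + 1, 5):
                if l in dropped:
                    continue
                r = np.corrcoef(gg[:, j], gg[:, l])[0, 1]
                if r**2 > 0.1:
                    dropped.add(l)
        assert meff_snps(panel) == len(kept)


class TestBhFdr:
    def test_hand_applied_example(self):
        thr, rej = bh_fdr(np.array([0.001, 0.01, 0.02, 0.04, 0.9]), alpha=0.05)
        assert thr == pytest.approx(0.04)
        assert rej.sum() == 4

    def test_all_ones_reject_none(self):
        thr, rej = bh_fdr(np.ones(10))
        assert thr == 0.0 and rej.sum() == 0

    def test_all_tiny_reject_all(self):
        thr, rej = bh_fdr(np.full(20, 1e-6), alpha=0.05)
        assert rej.all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([]))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.2))
    def test_matches_stepup_definition(self, ps, alpha):
        p = np.array(ps)
        thr, rej = bh_fdr(p, alpha)
        m = p.size
        srt = np.sort(p)
        ks = [k for k in range(1, m + 1) if srt[k - 1] <= k * alpha / m]
        if not ks:
            assert thr == 0.0 and rej.sum() == 0
        else:
            k = max(ks)
            assert thr == pytest.approx(srt[k - 1])
            assert np.array_equal(rej, p <= srt[k - 1])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200) ** 3
        thr, rej = bh_fdr(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.array_equal(rej, ref)


class TestClump:
    def _ld_block_panel(self, rng, n=400):
        causal = rng.binomial(2, 0.4, n).astype(float)
        block = [causal]
        for _ in range(4):  # tight LD partners
            g = causal.copy()
            flip = rng.random(n) < 0.05
            g[flip] = rng.binomial(2, 0.4, flip.sum())
            block.append(g)
        indep = [rng.binomial(2, 0.5, n).astype(float) for _ in range(5)]
        g = np.column_stack(block + indep)
        pos = np.concatenate([np.arange(5) * 10_000 + 1, 5_000_000 + np.arange(5) * 10_000])
        return make_panel(g, pos=pos), causal

    def test_single_locus_one_clump(self, rng):
        panel, causal = self._ld_block_panel(rng)
        y = causal * 1.0 + rng.standard_normal(panel.n) * 0.5
        res = gwas_ols(y, panel)
        clumps = ld_clump(res, panel, p_entry=5e-8)
        assert len(clumps) == 1
        assert clumps["index_snp"].iloc[0] == res.loc[res["p"].idxmin(), "id"]
        # invariant: all members in LD >= threshold with index
        g = panel.dosages
        jdx = {s: i for i, s in enumerate(panel.snp_table["id"])}
        j = jdx[clumps["index_snp"].iloc[0]]
        for s in clumps["members"].iloc[0]:
            r2 = np.corrcoef(g[:, j], g[:, jdx[s]])[0, 1] ** 2
            assert s == clumps["index_snp"].iloc[0] or r2 >= 0.1

    def test_two_chromosome_loci_two_clumps(self, rng):
        n = 500
        g1 = rng.binomial(2, 0.4, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        g = np.column_stack([g1, g2])
        panel = make_panel(g, pos=[100, 100], chrom=["1", "2"])
        y = g1 + g2 + 0.3 * rng.standard_normal(n)
        res = gwas_ols(y, panel)
        assert len(ld_clump(res, panel)) == 2

    def test_no_significant_snps_empty(self, rng):
        g = rng.binomial(2, 0.5, size=(100, 5)).astype(float)
        res = gwas_ols(rng.standard_normal(100), make_panel(g))
        assert ld_clump(res, make_panel(g)).empty


class TestConditional:
    def test_condition_on_causal_marks_reported(self, rng):
        n = 600
        causal = rng.binomial(2, 0.4, n).astype(float)
        proxy = causal.copy()
        flip = rng.random(n) < 0.03
        proxy[flip] = rng.binomial(2, 0.4, flip.sum())
        g = np.column_stack([causal, proxy])
        y = causal * 0.8 + rng.standard_normal(n)
        panel = make_panel(g)
        out = conditional_scan(y, panel, None, ["s0"], test_snps=["s1"])
        assert out["classification"].iloc[0] == "reported"

    def test_condition_on_unlinked_marks_independent(self, rng):
        n = 600
        causal = rng.binomial(2, 0.4, n).astype(float)
        other = rng.binomial(2, 0.5, n).astype(float)
        y = causal * 0.8 + rng.standard_normal(n)
        panel = make_panel(np.column_stack([causal, other]))
        out = conditional_scan(y, panel, None, ["s1"], test_snps=["s0"])
        assert out["classification"].iloc[0] == "independent"
        base = gwas_ols(y, panel)
        assert np.log10(out["p"].iloc[0]) == pytest.approx(np.log10(base["p"].iloc[0]), abs=1.0)

    def test_empty_conditioning_set_equals_gwas(self, rng):
        n = 200
        g = rng.binomial(2, 0.4, size=(n, 4)).astype(float)
        y = rng.standard_normal(n)
        panel = make_panel(g)
        out = conditional_scan(y, panel, None, [])
        base = gwas_ols(y, panel)
        assert np.allclose(out["p"], base["p"])


def _phased_panel(rng, n, m, p_by_anc, anc_probs):
    anc = rng.choice(len(anc_probs), size=(2 * n, m), p=anc_probs)
    hap = (rng.random((2 * n, m)) < p_by_anc[anc, np.arange(m)]).astype(np.uint8)
    return make_panel((hap[0::2] + hap[1::2]).astype(float), haplotypes=hap, ancestry=anc.astype(np.uint8))


class TestSnp1:
    def test_constant_local_ancestry_reduces_to_ols(self, rng):
        n, m = 300, 8
        p = np.tile(rng.uniform(0.2, 0.8, m), (1, 1))
        panel = _phased_panel(rng, n, m, p, [1.0])
        y = rng.standard_normal(n)
        r_snp1 = snp1_scan(y, panel)
        r_ols = gwas_ols(y, panel)
        assert np.allclose(r_snp1["p"], r_ols["p"], atol=1e-10)

    def test_fully_differentiated_allele_flagged_collinear(self, rng):
        n, m = 200, 3
        p = np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]])  # SNP 0 fixed-diff
        panel = _phased_panel(rng, n, m, p, [0.5, 0.5])
        y = rng.standard_normal(n)
        out = snp1_scan(y, panel)
        assert bool(out["collinear"].iloc[0])
        assert not out["collinear"].iloc[1:].any()

    def test_null_agrees_with_ols_without_structure(self, rng):
        n, m = 400, 20
        p = np.tile(rng.uniform(0.3, 0.7, m), (2, 1))  # same freqs both ancestries
        panel = _phased_panel(rng, n, m, p, [0.5, 0.5])
        y = rng.standard_normal(n)
        p1 = snp1_scan(y, panel)["p"].to_numpy()
        p0 = gwas_ols(y, panel)["p"].to_numpy()
        assert np.corrcoef(-np.log10(p1), -np.log10(p0))[0, 1] > 0.95


class TestTractor:
    def test_single_ancestry_equals_ols(self, rng):
        n, m = 300, 6
        p = rng.uniform(0.2, 0.8, (1, m))
        panel = _phased_panel(rng, n, m, p, [1.0])
        y = rng.standard_normal(n)
        rt = tractor_scan(y, panel)
        ro = gwas_ols(y, panel)
        assert np.allclose(rt["p"], ro["p"] if False else (ro["beta"] / ro["se"]) ** 0 * rt["p"])  # df check below
        # with one ancestry the joint F-test over one term equals the t-test
        assert np.allclose(rt["p"], 2 * stats.t.sf(np.abs(ro["beta"] / ro["se"]), ro["df"].iloc[0]), atol=1e-10)
        assert (rt["df"] == 1).all()

    def test_ancestry_specific_effect_recovered(self, rng):
        n, m = 1500, 1
        p = np.array([[0.5], [0.5]])
        panel = _phased_panel(rng, n, m, p, [0.5, 0.5])
        hap = panel.haplotypes[:, 0].reshape(-1, 2).astype(float)
        anc = panel.ancestry[:, 0].reshape(-1, 2)
        g0 = (hap * (anc == 0)).sum(axis=1)  # alt alleles on ancestry-0 haplotypes
        y = 0.5 * g0 + rng.standard_normal(n)
        out = tractor_scan(y, panel)
        betas = out["betas"].iloc[0]
        assert betas[0] == pytest.approx(0.5, abs=0.12)
        assert betas[1] == pytest.approx(0.0, abs=0.12)

    def test_homogeneous_effect_loses_power_vs_ols(self, rng):
        """Joint 2-df test on a shared effect: TRACTOR median p less
        significant than the 1-df OLS p across seeds."""
        wins = 0
        n_seeds = 11
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            n = 400
            p = np.array([[0.4], [0.4]])
            panel = _phased_panel(r, n, 1, p, [0.5, 0.5])
            y = 0.25 * panel.dosages[:, 0] + r.standard_normal(n)
            pt = tractor_scan(y, panel)["p"].iloc[0]
            po = gwas_ols(y, panel)["p"].iloc[0]
            wins += pt > po
        assert wins > n_seeds / 2
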