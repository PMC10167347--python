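# morphgwas

A toolkit for genome-wide association analysis of landmark-based facial and
craniofacial morphology. It reimplements, as a tested and reusable Python
library, the analysis chain used in large-scale 2D face-photograph GWAS of
admixed cohorts and in multivariate 3D skull-shape GWAS:

* **Symmetry-aware phenotyping.** Generalized Procrustes analysis (GPA) with
  *object symmetry*: each configuration is reflected and its paired
  landmarks relabeled, the doubled sample is jointly superimposed, and each
  shape splits into a symmetric component (average of original and aligned
  mirror copy) and an asymmetric component (half-difference). Phenotypes
  are inter-landmark distances (ILDs) on the symmetric component; because
  symmetrized shapes make a distance equal to its mirror-image distance,
  ILDs are deduplicated by reflection orbit. On the default frontal-face
  template (13 bilateral pairs + 8 midline landmarks, k = 34) the
  C(34,2) = 561 pairs collapse to 301 retained distances (260 duplicates).
* **Association.** Covariate-adjusted per-SNP OLS (sex, age, BMI, head
  angles, genetic PCs), genomic-control λ, effective numbers of independent
  traits/SNPs (Li & Ji), Benjamini–Hochberg FDR, LD clumping, conditional
  scans, KING-robust kinship filtering, and the local-ancestry model
  variants used in admixed cohorts (SNP1 and TRACTOR).
* **Heritability.** GRM construction and single-component REML ĥ² via a
  one-time eigendecomposition (profile restricted likelihood in h²).
* **Archaic admixture mapping.** Reference-site filters, introgression-tract
  filters (> 99 % confidence, > 10 kb), recoding of individuals by archaic
  haplotype dosage (0/1/2), merging of consecutive SNPs whose dosage
  columns differ for ≤ 1 % of individuals into segments, a ≥ 1 % frequency
  filter, linear-model association, and ancestry-background cross-tabulation.
* **Multivariate shape GWAS.** Symmetric-component PCA in Procrustes tangent
  space (a 17-pair + 10-midline 3D template has exactly 3p + 2m − 4 = 67
  non-null PCs), a two-block multivariate linear mixed model (full genetic
  and residual covariances for the leading k PCs, independent variance
  pairs for the rest), GLS correction of scores and dosages, Pillai-trace
  SNP tests, and permutation-based FDR.
* **Synthetic cohorts.** A generator for three-way admixed genotypes
  (Balding–Nichols drift, Markov local-ancestry tracts), archaic tracts on
  a target ancestry background, 2D face cohorts with covariate/SNP/pose
  structure, and GRM-structured 3D symmetric configurations — so the whole
  pipeline runs and is testable without access-restricted cohort data.

## Worked example

```python
import morphgwas as mg

cfg = mg.SimConfig(seed=11, n_individuals=300, n_snps=800,
                   causal_effects=((100, 5, 0.5),))   # SNP 100 -> ILD D6, 0.5 SD
bundle = mg.simulate_cohort(cfg)

fit = mg.gpa_object_symmetry(bundle.landmarks, bundle.template)
catalog = mg.ild_catalog(bundle.template)
ilds = mg.compute_ilds(fit, catalog)
print(f"ILDs: {ilds.values.shape[1]} retained "
      f"({catalog.n_total_pairs} pairs, {catalog.n_duplicates_removed} duplicates removed)")

pcs = mg.genotype_pca(bundle.panel, 6)
trait = ilds.values.iloc[:, 5]
y = (trait - trait.mean()) / trait.std()
res = mg.gwas_ols(y, bundle.panel, bundle.covariates, pcs=pcs)
hit = res.iloc[100]
print(f"causal SNP {hit.id}: beta = {hit.beta:.3f} (SE {hit.se:.3f}), p = {hit.p:.2e}")
print(f"lambda_GC = {mg.lambda_gc(res['p'].to_numpy()):.3f}")
```

prints

```
ILDs: 301 retained (561 pairs, 260 duplicates removed)
causal SNP rs101: beta = 0.498 (SE 0.096), p = 3.78e-07
lambda_GC = 1.085
```

The 0.5 SD effect injected at SNP 100 is recovered within one standard
error, and the genomic inflation factor of the PC-adjusted scan sits near 1,
i.e. population stratification in the three-way admixed cohort is
controlled.

There is also a CLI (`morphgwas simulate | phenotype | gwas | admixmap |
mvgwas | report`); `morphgwas simulate --out fixture/` writes a complete
VCF + landmarks + covariates + tracts fixture directory, and
`morphgwas report` runs the end-to-end pipeline with provenance logging.

## Layout

```
src/morphgwas/
  morphometrics.py   GPA, object symmetry, ILD catalog/matrix, QC, agreement
  association.py     PCA, KING, OLS GWAS, lambda, Meff, BH, clumping, SNP1/TRACTOR
  heritability.py    GRM + REML h2
  archaic.py         tract filters, archaic dosage, segment merging, admixture mapping
  mvgwas.py          shape PCA, two-block mvLMM, Pillai scan, permutation FDR
  simulate.py        synthetic admixed/face/skull cohort generator
  io.py, pipeline.py, cli.py
docs/methods.md      model and design notes
```
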