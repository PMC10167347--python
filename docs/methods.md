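# Methods and design notes

## Procrustes analysis with object symmetry

Configurations are centered, scaled to unit centroid size, and iteratively
rotated to the running mean shape; rotations come from the SVD of the
cross-covariance with the determinant corrected so reflections are never
applied (anatomical handedness is preserved). Convergence is declared when
the mean shape moves by less than 1e-10 (max 100 iterations); GPA flags
non-convergence rather than raising.

Object symmetry follows the reflect-and-relabel construction: the mirror
copy of each configuration (first coordinate axis negated, bilateral pairs
swapped; the reflection axis/plane is arbitrary because GPA re-aligns) is
added to the sample and the doubled set superimposed. The mean shape is
symmetrized every iteration. This is not only a convention: with a
mirror-symmetric mean, the optimal rotation of a mirrored configuration is
exactly the mirror of the original's optimal rotation, so the aligned
mirror copy equals the mirrored aligned original and the symmetric
component (their average) is *exactly* invariant under reflect-and-relabel.
The asymmetric component is the residual half-difference.

## ILD catalog

Distances are measured between landmarks of the symmetric component, so
the distance for pair (i, j) equals the distance for its mirror image
(σi, σj). All unordered pairs are grouped into reflection orbits; one
canonical representative (lexicographic minimum) is retained per orbit and
labeled D1, D2, ... in catalog order. Self-dual pairs (bilateral pairs
themselves and midline–midline pairs) form singleton orbits. For p
bilateral pairs and m midline landmarks the number of duplicates removed is
m·p + (C(2p,2) − p)/2; with p = 13, m = 8 this gives 561 pairs, 260
duplicates, 301 retained distances. D-numbering is deterministic but not
meant to reproduce any external labeling scheme.

## Symmetric shape-space dimension and tangent-space PCA

The symmetric component of a k-landmark configuration lies in a linear
subspace of dimension 3p + 2m (3D; midline landmarks are confined to the
symmetry plane) or 2p + m (2D). Superimposition removes scale, the
translations within the symmetry plane, and the rotations that preserve
symmetry, leaving 3p + 2m − 4 (3D) or 2p + m − 2 (2D) non-null dimensions
— 67 for a 17-pair + 10-midline 3D template, 32 for the 13-pair +
8-midline face template.

Shape PCA operates on Procrustes *tangent* coordinates: the component of
each centered configuration along the mean shape is projected out before
the SVD. The centering, rotation and symmetry constraints are linear at
the GPA optimum, but unit centroid size confines configurations to a
sphere; without the tangent projection that curvature contributes spurious
eigenvalues of relative order of the squared shape variation, and the
numeric rank at the default tolerance (1e-8 × leading eigenvalue) would
exceed the closed-form dimension. With the projection the empirical rank
equals the closed form exactly, which the tests verify over a grid of
(p, m, d).

## QC rules

Head pose: an individual is excluded when any of yaw/pitch/roll exceeds an
absolute cap (default 15°) or deviates from the median by more than c
(default 4) normal-consistent MADs. Both thresholds are configurable; the
defaults are the package's choice since only the existence of an exclusion
step, not its threshold, is standard. Trait outliers: per trait and sex
stratum, values outside mean ± 3 SD are excluded in a single pass (no
iterative re-trimming); strata with fewer than two individuals are skipped
with a warning.

## Association

The OLS scan residualizes trait and (per-SNP mean-imputed) dosages on the
covariates once (Frisch–Waugh–Lovell), which reproduces full-model
estimates exactly and keeps genome scans vectorized. λ_GC is the median
association χ²(1) over its null median (0.4549364). Meff for traits is the
Li & Ji spectral estimator Σ f(|λ|), f(x) = 1{x ≥ 1} + frac(x);
eigenvalues are rounded to 9 decimals first because the estimator is
discontinuous at integers and eigensolver noise would otherwise inflate
Meff for exactly-correlated trait blocks. Meff for SNPs is greedy windowed
LD pruning (r² on dosages). BH-FDR is the classical step-up rule.
Clumping seeds on ascending p (minimum across traits per SNP) and claims
in-window SNPs with r² ≥ 0.1; conditional scans append conditioning
dosages to the covariates and classify signals as "reported" when the
conditional p rises above the suggestive threshold 1e-5. The genome-wide
threshold defaults to 5e-8 with the Meff/BH thresholds reported alongside.

KING-robust kinship uses the between-family estimator
φ = (N_het,het − 2·N_opp-hom)/(N_het(i) + N_het(j)) with per-individual
het counts restricted to mutually observed sites; pairs with φ > 0.1 are
broken greedily, removing the member genotyped at fewer markers.

SNP1 adds the local-ancestry counts at the locus as covariates (one
ancestry dropped as reference, constant columns dropped); TRACTOR replaces
the genotype with ancestry-specific allele dosages and tests them jointly
with an F-test (exact under OLS; df = ancestries present at the locus).
Fully differentiated alleles make these designs collinear; both scans flag
the SNP and return NA rather than failing, matching the known behavior of
local-ancestry models in admixed panels.

## Heritability

The GRM is the standardized-genotype cross-product with uniform SNP
weights (LD-adjusted weighting is intentionally out of scope; the choice
is recorded in the output metadata of the pipeline). REML for
y = Xb + g + e, g ~ N(0, σg²K), profiles out σp² = σg² + σe² and the fixed
effects after rotating by the GRM eigenvectors, leaving a bounded 1-D
optimization in h² ∈ [1e-6, 1 − 1e-6]; estimates at the clamp are reported
unclamped with a boundary flag. The SE comes from the numerical curvature
of the profile restricted log-likelihood. The rotated profile equals the
direct matrix-form restricted likelihood, asserted to 1e-8 in the tests.

## Archaic admixture mapping

Site filters (inclusive depth ≥ 20, PASS in both reference call sets,
matching ancestral/derived alleles, ancestral allele present in the
cohort) and tract filters (strictly > 0.99 confidence, strictly > 10 kb)
follow the stated boundary semantics; per-rule drop counts are logged.
Tracts use BED half-open 0-based coordinates and SNP positions are
1-based, so position p is covered iff start < p ≤ end; dosage is the
number of an individual's haplotypes with a covering tract. Segment
merging is greedy left-to-right: a segment extends to the next site iff
the fraction of individuals whose dosage changes between adjacent sites is
≤ 1 % ("genotype change" read as any dosage difference per individual —
the most literal interpretation; counting per-allele changes would only
be stricter). The representative genotype is the first site's column, the
frequency filter (≥ 1 %) is inclusive. Association uses the same linear
model as the SNP GWAS, with a BH threshold over the segment × trait grid.

## Two-block multivariate shape GWAS

A full mvLMM on all T shape PCs is quadratic in T per individual and
impractical; the covariance is modeled in two blocks: the leading k PCs
(default 10) get full genetic (Vg) and residual (Ve) covariances, every
later PC an independent (σg², σe²) pair, and all other covariances are
fixed at zero. Centroid size is always a fixed covariate (dropped
automatically if constant). In the GRM-eigenrotated basis each
individual's covariance is block-diagonal, Ω_i = blockdiag(d_i·Vg + Ve,
diag(d_i·σg² + σe²)). Block 1 is fit by EM (maximum likelihood, with the
fixed effects re-estimated by GLS each iteration; convergence at relative
log-likelihood change < 1e-8, cap 500 iterations, non-convergence
flagged); block 2 by the same 1-D REML as the heritability module.

"Corrected" scores and dosages: fixed effects are removed by GLS under the
fitted model, score residuals are whitened by Ω_i^{-1/2} (matrix structure
for block 1, per-trait scalars for block 2), and dosages and covariates by
a per-individual *scalar* weight — the root mean precision across the
whitened trait space. A matrix-structured dosage whitening would produce a
matrix-valued design per individual and no single predictor column, which
the Pillai test requires; the scalar weight is the natural compromise and
reduces exactly to plain residualization when Ω_i is constant (e.g. GRM =
I, Vg = 0, where the scan provably coincides with classical MANOVA, since
Pillai's trace is invariant under any common nonsingular transform of the
responses). Corrected scores and dosages are finally OLS-residualized on
the corrected covariates, making the in-sample orthogonality exact. A
BLUP-residual alternative would be possible but is not implemented.

For a single predictor, Pillai's trace simplifies to
V = a'(S'S)^{-1}a / (g'g) with a = S'g, and the F approximation
F = ((n − T − 1)/T)·V/(1 − V) on (T, n − T − 1) df is the exact
single-predictor form (at T = 1 it reproduces the regression F-test
exactly). Permutation FDR permutes the corrected score rows jointly,
rescans all SNPs per permutation (default 100), and uses the pooled
estimate FDR(p) = mean permuted count(p' ≤ p) / observed count(≤ p); the
threshold is the largest observed p with FDR ≤ 5 %. A per-permutation
min-p alternative was considered and not implemented; permutations do not
preserve GRM structure (they are applied after GLS whitening, under which
rows are exchangeable by construction).

## Synthetic cohorts: what they emulate and what they do not

Genotypes: per-SNP ancestral frequencies U(0.05, 0.95) drift into three
populations via Balding–Nichols Beta draws with a single Fst parameter
(default 0.12). Local ancestry follows a Markov switch process with
Poisson breakpoints at rate g × genetic distance (1 cM/Mb, default g = 12
generations), ancestries drawn from the admixture proportions (default
0.48/0.46/0.06, a typical three-way admixed Latin American profile);
alleles are sampled from the local ancestry's frequency. Archaic tracts
(exponential length, default mean 127 kb) are placed at the chromosome
midpoint on haplotypes carrying the target ancestry there, at a default
carrier frequency of 0.31, clipped to the contiguous target-ancestry run;
archaic-diagnostic SNPs inside tracts carry the archaic allele; tract
confidence is 1.0 and decoy tracts (low confidence or short) exercise the
filters. Face cohorts superpose sex/age/BMI and causal-SNP displacement
fields along ILD axes (symmetrized so the mirror distance moves equally)
on a symmetric template, plus symmetric individual variation, smaller
fluctuating asymmetry, and bounded (±10°) pose nuisance: in-plane roll
rotation and yaw/pitch foreshortening (cosine scaling), which leaks into
ILDs as in real 2D photographs. Effect sizes are calibrated in
approximate phenotype-SD units via sd(ILD) ≈ √2 × symmetric noise SD.

Not emulated: realistic LD (no coalescent simulation), imputation error,
genotyping missingness patterns, landmarking error structure of automatic
detectors, and selection on introgressed haplotypes. Passing tests
therefore demonstrate the statistical machinery under the assumed
generative model, not robustness to those real-data features.

Default problem sizes (600 individuals × 2000 SNPs; tests use 200–800
individuals, 150–2000 SNPs, 7–25 seeds per recovery check) are the
package's desk-scale choices: large enough for the parameter-recovery
tolerances used (3 SE / 3 Monte-Carlo SE / ±0.07 on a median ĥ² of 0.38),
small enough that the full suite runs in about two minutes.

## Known limitations

* Uniform-weight GRM only (no LD-adjusted weights, no multi-component
  GREML, no bivariate genetic correlations).
* Full mixed-model genome scans (GRM random effect per SNP test) are not
  implemented; the heritability module provides the single-trait LMM
  machinery and the two-block model the multivariate approximation.
* The pipeline approximates per-trait outlier exclusion by masking and
  mean-imputing excluded cells rather than per-trait complete-case
  sample sizes.
* Archaic tract calling itself (an HMM over reference panels) is out of
  scope; tracts are inputs, from the simulator or a caller's BED output.
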