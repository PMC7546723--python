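# Methods

`geacoia` implements a landscape-genomics inference chain for diploid
biallelic SNP data sampled from a spatial hierarchy (individuals nested in
sites/wetlands nested in basins) along an environmental gradient. This note
documents the statistical models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic-data generator does and
does not emulate.

## Data model

Genotypes are alternate-allele dosages in {0, 1, 2} with an explicit
missing mask (`GenotypeTable`). Missing genotypes are imputed per locus by
the most common observed genotype (ties toward the smaller dosage) or by
the locus mean; columns are then centered. Genotypes are centered but not
scaled by default for all ordinations: every locus lives on the common 0–2
dosage scale, so unit-variance scaling would up-weight rare alleles.
Scaling is exposed as a flag. Loci whose observed dosages are all identical
(monomorphic) carry no ordination information and are removed when the
non-candidate pool is built.

## Predictor reduction (CLV + VIF)

Climate enters as a site-level table (19 bioclim-style variables plus
longitude and latitude). Because these variables are strongly collinear,
the predictor set is reduced in two steps:

1. **Clustering of variables around latent components (CLV).** Variables
   are standardized; the quality of a partition is
   Σ_clusters Σ_members cor²(x, latent), with the latent being the first
   principal component of the cluster — equivalently the sum of leading
   eigenvalues of the within-cluster correlation matrices. The directional
   (sign-free, squared-correlation) variant is used because bioclim sign
   orientations are arbitrary. Agglomeration is greedy from singletons,
   merging the pair with the smallest criterion loss; a k-means-style
   consolidation pass then reassigns variables to their best-correlated
   latent, which can only increase the criterion. The automatic cluster
   count keeps the largest k whose next merge would drop the criterion by
   more than 10% (configurable) of the total criterion (= number of
   variables). This heuristic is a declared convention; k is always
   overridable and the full criterion path is reported. Each cluster is
   represented by its best-correlated member variable.
2. **VIF screen.** VIF_j = 1/(1 − R²_j) from regressing predictor j on
   the others (with intercept); the largest-VIF variable is dropped
   iteratively until all VIFs ≤ 10 (configurable). Exactly collinear
   variables get an infinite VIF and are dropped first with a warning.

The pipeline's default predictor set is annual precipitation, annual mean
temperature and mean diurnal range (BIO12, BIO01, BIO02), the canonical
non-redundant trio for a latitudinal temperature/precipitation gradient;
any set can be configured, or derived per-dataset by enabling the
reduction stage.

## RDA and candidate-locus detection

RDA is the PCA of the fitted values of the multivariate regression of the
centered genotype matrix Y (n × p) on the standardized predictors X
(n × q): Ŷ = H Y with H the hat matrix, constrained eigenvalues are those
of ŶᵀŶ/(n−1), and R² = SS(Ŷ)/SS(Y) with Ezekiel's adjustment
1 − (1 − R²)(n−1)/(n−q−1). Numerically the projection uses a QR
decomposition rather than forming H.

Significance uses permutation tests with the (exceedances + 1)/(n_perm + 1)
convention:

* **Global test.** Pseudo-F = (SS_fit/q)/(SS_res/(n−q−1)); rows of X are
  permuted. There are no conditioning covariates in this design, so direct
  permutation of X is exchangeable.
* **Axis tests.** Sequential: axis i is tested conditioning on constrained
  axes 1..i−1 by residualizing both Y and X on them, permuting the
  reduced-model residuals, and comparing the first constrained eigenvalue
  to the full-model residual mean square.

Candidate climate-selected loci are those whose loading (unit-norm
principal-axis coefficient of Ŷ; "species score") on any significant axis
lies more than 2.5 SD (sample SD, ddof = 1) from that axis's mean loading.
The rule is scale-free under any per-axis affine rescaling of loadings, so
the vegan-style scaling choice does not affect the candidate set. A locus
flagged on several axes counts once and is attributed to the first axis in
eigenvalue order. Each candidate is assigned the climate variable its
imputed dosages correlate with most strongly in absolute Pearson r (ties:
lexicographically first name).

The non-candidate pool excludes candidates, any externally supplied
outlier list, and monomorphic loci; a size-matched non-candidate sample is
drawn uniformly without replacement with a recorded seed.

## Co-inertia, RV, and the bootstrap null

Both locus tables are imputed and centered through the same path and
decomposed as PCA triplets with uniform row weights 1/n (divisor-n
covariance, the ade4 convention). The retained axis count is the smallest
reaching 90% cumulative variance (configurable). By default each table is
reconstructed from its retained components before coupling ("truncated"
mode); disabling truncation reproduces classical full-triplet co-inertia.
Both modes are recorded in the manifest.

Co-inertia axes are the singular vectors of the cross-covariance
C = X_AᵀX_B/n; per-axis co-inertia is the squared singular value and the
total equals ‖C‖²_F. Row scores are projections of each table on the
unit-norm loading vectors of the common axes, so identical tables receive
identical paired scores — the degenerate self-coupling case yields exactly
zero divergence (enforced exactly by using a common axis basis when the two
tables are bit-identical). Axes are oriented so the largest-|loading|
coefficient of the first table is positive.

The RV coefficient, trace(W_A W_B)/√(trace W_A² · trace W_B²) with
W = XXᵀ, is always computed on the full centered tables so that it is
comparable between the observed pair and the bootstrap null, regardless of
the truncation mode. Its permutation test permutes rows of one table
(one-sided, large RV). The bootstrap null repeatedly draws two
disjoint-by-default locus subsets of candidate-set size from the
non-candidate pool and records their RV; the empirical p asks whether the
observed RV is unusually **low** (p = (#{RV_null ≤ RV_obs}+1)/(n_boot+1)),
since the scientific question is whether the candidate set decouples from
genome-wide structure more than random locus sets do.

## Divergence and its geographic structure

Per-individual divergence is the Euclidean distance between the paired
co-inertia scores over the leading k axes. The default axis rule is a
cumulative co-inertia coverage fraction of 0.947 (an explicit k
overrides); the achieved coverage and k are always reported. Distances are
not transformed.

Geographic structure is tested with the nested linear model
divergence ~ basin + site-within-basin using sequential (Type I) sums of
squares with basin first. Because the design is purely nested, the
decomposition reduces to between-basin, between-site-within-basin and
within-site sums of squares, computed by explicit group-mean projections;
both F statistics use the within-site residual mean square. This avoids
general-purpose ANOVA routines whose term degrees of freedom miscount
under nested dummy codings with absent factor combinations.

## Population-level regression

Per site: mean divergence, number of genotyped individuals, and expected
heterozygosity He = 2p̂(1−p̂) per locus (plug-in estimator; an optional
2n/(2n−1) small-sample factor is available), averaged over loci with at
least 4 genotyped individuals at that site (loci failing the rule are
excluded for that site only).

The divergence model is selected by exhaustive enumeration of term subsets
over {climate variables (linear and quadratic), He of each locus set}
under AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), where k counts the
regression coefficients including the intercept plus one for the error
variance. Quadratic terms are admitted only together with their linear
term (hierarchy constraint). Predictors are standardized before the
search — AICc comparisons are invariant to affine predictor rescaling, and
standardization keeps quadratic terms well conditioned; coefficients are
reported on both scales. Two-block variation partitioning on adjusted R²
gives unique fractions [a] = adjR²(A∪B) − adjR²(B),
[c] = adjR²(A∪B) − adjR²(A), shared [b] = adjR²(A) + adjR²(B) − adjR²(A∪B)
(possibly slightly negative under adjustment — reported as-is), and
unexplained = 1 − adjR²(A∪B). A confound check regresses mean divergence
on per-site sample size and flags a slope with p < 0.05.

## Synthetic-data generator

The generator emulates the sampling design the analysis assumes: 5 basins
× 4 wetlands (20 sites) in contiguous latitudinal blocks over a ~5.5°
extent, 4–10 individuals per wetland, and 1709 unlinked loci (1619 neutral
+ 90 climate-driven) by default. Neutral allele frequencies follow a
two-level Balding–Nichols hierarchy, Beta(p(1−F)/F, (1−p)(1−F)/F), with
F_basin = 0.10 and F_site = 0.05 by default — moderate hierarchical
differentiation typical of fragmented plant populations; ancestral
frequencies are uniform on (0.05, 0.95). Climate variables are linear in
latitude plus Gaussian noise, with one precipitation-like block spanning an
order of magnitude and increasing along the gradient, reproducing the
collinearity structure the CLV step must handle. Selected loci shift the
site allele frequency on the logit scale by beta (default 1.5) per SD of
the driving variable (default BIO12), i.e. selection acts at the
site-frequency level, matching the site resolution of climate data.
Genotypes are Binomial(2, p_site); 3% of genotypes are set missing
independently. Monomorphic loci can arise by drift and are retained in the
output for downstream filtering. A truth table records each locus'
selection status, slope, driving variable and ancestral frequency.

What the generator does **not** emulate: linkage disequilibrium between
loci (GBS SNPs are simulated unlinked), temporal selection dynamics,
isolation-by-distance within basins beyond the block structure, genotyping
error, and depth-dependent missingness (missingness is uniform). Passing
recovery tests therefore demonstrates that the chain detects
site-frequency/climate covariance of the planted form — not robustness to
LD clusters or informative missingness in real reduced-representation
data.

## Problem sizes used in validation

The test suite and acceptance script run the chain at desk scale chosen as
the package's own validation design: oracle checks on 6–30-row matrices;
permutation-test calibration with 200 null replicates at 199 permutations;
planted-locus recovery on 10 replicates of 20 sites × 8 individuals with
500 neutral + 25 selected loci at beta = 2 and F_site = F_basin = 0.05;
model recovery on 20 replicates of 17 sites; and a full run at the default
1709-locus study shape with 999 permutations and 1000 bootstrap
iterations.

## Known limitations

* The 2.5 SD outlier rule has limited power when unmodeled neutral
  structure is collinear with climate. In the generator this occurs when
  basin blocks align with the latitudinal climate gradient: at
  F_basin = 0.10 sensitivity for beta = 1.5 effects drops well below what
  the same effect achieves at F_basin = 0.05, because basin-driven
  loadings inflate the per-axis SD the rule divides by. This mirrors the
  well-known confounding of GEA methods without explicit structure
  correction.
* Axis-wise permutation tests are sequential and condition on estimated
  (not true) leading axes; their calibration is verified globally, not
  per axis.
* The CLV auto-k rule is a criterion-drop heuristic; for published-figure
  parity set k explicitly.
* Variation-partitioning fractions use Ezekiel-adjusted R² and can be
  slightly negative; they are reported unmodified.
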