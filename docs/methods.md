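# Methods

This note documents the models, estimators and numerical choices behind
`lineagescape`, and what the synthetic landscape does and does not emulate.

## The synthetic landscape

The generator is the package's study system: all defaults together define
one reproducible scenario (12 demes in 2 lineages, 20 diploid individuals
per deme, 2000 neutral + 20 adaptive biallelic SNPs, a 50 × 50 grid of
0.5° cells). Everything is a pure function of the config seed
(`numpy.random.default_rng` with spawned child generators per component).

**Climate.** Each of the 19 bioclim layers is a planar gradient plus a
smooth Gaussian random field (white noise smoothed with a Gaussian kernel,
σ = 10 % of the grid side). BIO1 anchors a temperature latent and BIO12 a
precipitation latent; the other variables load on their block latent at
0.9 plus independent smooth noise. The raw precipitation field is
orthogonalized against the temperature latent before mixing, so the sample
correlation between the two anchors equals the configured `block_corr`
(default 0.3) exactly. Both block gradients run south–north. Units are
nominal (°C-like for BIO1–BIO11, mm-like for BIO12–BIO19): the analyses
only ever use standardized values.

**Genotypes.** Neutral loci follow a two-level Balding–Nichols hierarchy:
ancestral frequency p ~ U(0.05, 0.95); lineage frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `f_lineage` (default 0.04); deme
frequency drawn the same way around the lineage frequency with
F = `f_deme` (default 0.02). These defaults put between-lineage pairwise
Φ<sub>ST</sub> near 0.05–0.07 and within-lineage values near 0.02–0.03 —
weak, gene-flow-dominated structure. Adaptive loci are deterministic
logistic clines, deme frequency = logistic(α + s·z), with z the deme's
standardized BIO1, s = ±`cline_slope` (default 3, alternating sign over
loci) and α solved by root-finding so the mean frequency over demes is
0.5. The slope is chosen for detectability at desk scale — real
climate-associated loci are likely far weaker. Genotypes are
Binomial(2, deme frequency) per individual and locus; missingness, when
enabled, is uniform (no genotyping-error model: the pipeline consumes hard
calls).

**Geometry of confounding.** The lineages split the grid west/east while
the climate gradients run south–north. This deliberate near-orthogonality
of climate and ancestry means (i) the first constrained RDA axis carries
the adaptive cline, (ii) the structure-confound filter can be tested
against a genuinely distinct structure axis, and (iii) adaptive units
delineate blocks along the climate gradient rather than the lineage
boundary. In empirical systems the two often coincide; the synthetic
default separates them so that each filter's behaviour is identifiable.
Passing tests on this landscape show the estimators work when climate and
structure are separable — they say nothing about the (harder) collinear
case, where the confounder filter is expected to sacrifice true positives
(it demonstrably does at seeds where climate and longitude align by
chance).

**Occurrences, land cover, futures.** Cell suitability for a lineage is
exp(−½ · Mahalanobis²) around lineage-specific (BIO1, BIO12) optima;
occurrences sample cells with probability proportional to suitability and
jitter uniformly within the cell. Land cover draws one of 7 categories per
cell from lineage-half-specific weights. Future scenarios add per-variable
deltas (default: +3 to every temperature variable, −100 to every
precipitation variable), optionally scaled linearly with latitude
(`future_lat_factor`) to create lineage-asymmetric exposure.

## Estimators and tests

**Φ<sub>ST</sub>.** Implemented as the Weir–Cockerham (1984) a/(a+b+c)
variance-component ratio for unphased biallelic SNPs, summed over loci
before the ratio is taken (ratio of sums). This is an approximation to
AMOVA-based Φ<sub>ST</sub> that is exact for unlinked SNPs without a
haplotype distance. Pairwise estimates are clipped at 0 before the
linearization Φ/(1−Φ) (the linearization diverges as Φ → 1; fixed
differences produce infinities deliberately). Demes under 3 individuals
are excluded (configurable).

**PCA.** Missing calls are mean-imputed per site; columns centred and (by
default) scaled by √(p(1−p)). Axis signs are fixed by making the
largest-|loading| element positive. LD pruning (window 50, step 5,
r² > 0.2) is available but is a pass-through on the unlinked synthetic
data.

**Distances.** Great-circle distances use the haversine formula on a
sphere of radius 6371.0088 km. Climatic distance is the Euclidean distance
on z-scored bioclim variables; because a full PCA is a rotation, the
all-PCs route is identical, and both are computed and cross-checked at
1e−8 on every call. Constant columns are dropped (they carry no
information and have no z-score).

**Permutation tests.** Mantel and MRM permute rows and columns of one
matrix simultaneously; RDA significance permutes predictor rows (global
test) or residualized response rows (sequential axis tests, conditioning
on previous canonical axes — a calibrated approximation, not a port of
vegan's marginal test); the niche equivalency test re-splits pooled
occurrences at the original sample sizes (lower tail). All p-values use
(count + 1)/(n_perm + 1) and are exact (possibly conservative) by
construction; type-I error at α = 0.05 is verified by simulation in the
acceptance tests. Default permutation count is 9999; calibration
simulations use 99 permutations per replicate, which is sufficient for a
0.05-level decision.

**Candidate cascade.** RDA responses are deme × frequency matrices (not
individual genotypes). Candidates load beyond ±`sd_mult` (default 3)
s.d. of the mean on a significant axis; the implied two-tailed normal tail
mass is ≈ 0.0027. The confounder filter computes |Spearman ρ| of each
candidate's deme frequencies against (i) the RDA1 site score, (ii) PC1 of
the *non-candidate* SNPs and (iii) longitude, and keeps the SNP only when
(i) is the strict maximum; ties are filtered conservatively. Using only
non-candidate SNPs for (ii) matters: with weak structure, a PC1 computed
on all SNPs is captured by the adaptive cline itself and the filter then
removes true positives. The differentiation scans are simplified analogues
of published tools: per-SNP Weir–Cockerham θ against a scaled χ² null
(df = demes − 1, scale matched to the 5 %-trimmed mean) and PC-regression
coefficient z-scores combined into a robust (MinCovDet) Mahalanobis
distance against χ²(K); both use Benjamini–Hochberg q < 0.05, and only
their intersection counts. The final set is (filtered RDA candidates ∪
scan intersection) ∩ in-gene SNPs; the in-gene restriction is applied
after merging, and counts at every stage are logged.

**Niche overlap.** The environmental space is a PCA of the pooled
background climate (cells within the 1500-km buffer of both groups, "PCA-
env" style joint calibration; a per-group flag exists). Occupancy
densities are binned kernel densities on an R × R grid (R = 100 default)
smoothed with a per-axis normal-reference bandwidth computed from the
*background* scores — the same kernel must smooth the occurrence and
background surfaces, otherwise their ratio is biased at the margins.
Occupancy = occurrence density ÷ background density where the background
is positive, else 0, renormalized. Schoener's D is computed as
Σ min(z₁, z₂), algebraically equal to 1 − ½Σ|z₁ − z₂| for normalized
surfaces and exactly 0/1 at the disjoint/identical boundaries; values are
clipped to [0, 1] against floating-point residue.

**Habitat selection.** The sign statistic f is the fraction of B bootstrap
resamples of the used-cell set (with replacement, same size) in which the
used proportion of a category strictly exceeds its availability; verdicts
preferred/avoided at f ≥ 0.975 / ≤ 0.025. Under exact proportionality f
concentrates near 0.5 (slightly below, because exact ties count against
exceedance); under a *sampled* proportional use f is approximately uniform
— a single draw is a noisy estimate of the 0.5 convention, which is why
summary reports average f over replicate draws.

**Genetic offset.** The enriched RDA uses the final candidates and five
predictors chosen greedily by marginal importance (constrained-variance
share in single-predictor RDAs — a stand-in for gradient-forest ranking,
which is out of scope) subject to pairwise |r| < 0.7. The adaptive index
projects each cell's climate, standardized by the calibration demes' mean
and s.d., onto the RDA axes; a cell with a deme's exact climate receives
that deme's linear-combination site score, and future layers use the same
calibration-deme standardization so scenarios are comparable. Index axes
are on the site-score scale and therefore already carry their eigenvalue
weight; the offset is the per-cell Euclidean distance between index
vectors (axes = 1 by default, so |Δindex|), which is a metric and is
invariant to axis sign.

**Ranges.** Binary ranges use a strict suitability threshold (the
concordance-maximizing threshold selection of empirical studies is out of
scope; thresholds are config inputs). Cell areas are d² R² cos(latitude)
with d the cell size in radians — for a 2.5′ cell at the equator this is
21.47 km². Centroids are area-weighted means of cell-centre unit vectors
on the sphere, renormalized; migration distance is the great-circle
distance between the breeding and non-breeding centroids. The buffer mask
tests cell-centre-to-occurrence distances, so a zero radius reproduces
exactly the occupied cells when occurrences are pooled to cell centres.

## Problem sizes

Simulation-based checks run at sizes chosen to keep the full suite fast
while leaving comfortable statistical margins: null-calibration tests use
1000 replicates of 99 permutations each (12-deme matrices, 30-SNP
responses, 40 × 40 density grids); parameter recovery uses 2000 loci; the
cascade check runs the full default landscape. The pipeline itself takes a
few seconds at default sizes.

## Known limitations

No linkage disequilibrium, coalescent noise, selection dynamics or
genotyping error in the generator; the logistic clines are noise-free at
the deme level. The differentiation scans are calibrated simplifications,
not ports of OutFLANK/PCAdapt. Individual-level RDA, gradient forests,
ancestry/coancestry models and SDM fitting are out of scope; suitability
grids are consumed as inputs (the generator provides them). Spherical
(not ellipsoidal) Earth throughout. The confounder-filter rule
(strict-maximum |Spearman ρ|) is a documented stand-in for a procedure
whose published description is incomplete, and it is conservative: under
chance collinearity between climate and geography it removes true
candidates, which the scan-intersection route then has to recover.
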