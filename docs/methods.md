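# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, what the synthetic
data do and do not emulate, and the numerical conventions.

## Study design being modelled

A diversity panel of n inbred lines (default 180) is phenotyped for
seedling height under two light-quality treatments: *unshaded*
(high R:FR, ≈7) and *shaded* (far-red enriched, R:FR ≈0.3), at equal
PAR so only light quality differs. Each genotype has `n_reps` plants
(default 4) per treatment, randomized over `n_batches` growth batches
(default 6). Initial height H_i (coleoptile length at transfer) is a
covariate; final height H_f is the response. Genotypes are biallelic
marker dosages (copies of the most frequent, "reference", allele) on
14 chromosomes (allotetraploid: 7 pairs in each of the A and B
genomes).

## Genotype QC and kinship

Markers are discarded if nonpolymorphic or if the minor allele count
(over non-missing integer calls; a heterozygote contributes one copy
to each allele) is below `min_mac` = 10. Missing calls are then
imputed with the marker's mean observed dosage 2p. *Convention:*
"impute with the allele frequency" is implemented on the dosage scale
(2p, not p), because imputing p would place imputed entries on half
the scale of observed dosages and attenuate per-copy regression
slopes. Filtering precedes imputation so MAC reflects real calls.

Kinship is the VanRaden genomic relationship matrix
K = VVᵗ / (2Σᵢpᵢ(1−pᵢ)) with V the column-centered dosage matrix.
Frequencies are recomputed on the post-QC, post-imputation matrix —
the matrix actually analysed. For fully inbred lines diag(K) ≈ 1 + F
≈ 2; variance components on the K scale must be read accordingly
(a line expresses ≈ 2σ²_u of polygenic variance). K is stored exactly
as estimated; any ridge (1e-8) used for numerical safety lives inside
linear solves only.

## Phenotype model

H_f is fitted by OLS with all effects fixed —
`H_i + batch + genotype + light + light:genotype` — matching a design
with many replicates and few batches where all terms are to be
compared on one footing. Incremental (Type-I) F-tests are reported in
that fixed entry order; with unbalanced data Type-I sums of squares
are order dependent, so the order is part of the method. η² is
SS_effect/SS_total in percent and, together with the residual row,
sums to 100 by construction. Degrees of freedom are always derived
from the data, never hard-coded. (A published table of this layout
can report η² columns that do not sum to 100 and a batch df that
disagrees with the stated batch count; this implementation reports
only the internally consistent decomposition.)

BLUEs are model predictions per genotype × light cell at the
grand-mean H_i with batch levels averaged with equal weight — the
adjustment point is a convention; BLUEs are invariant to factor
reference-level coding, and cells with no data are flagged NaN rather
than silently extrapolated.

H² per light level uses the one-way genotype ANOVA moment estimator:
σ²_e = MS_error, σ²_g = max(0, (MS_genotype − MS_error)/n̄) with n̄
the harmonic-mean replicate count (exact when balanced). Negative
moment estimates truncate to 0. A REML alternative
(`method="reml"`, random-genotype intercept) is available; the two
agree closely on balanced data. CV = σ_g/μ with μ the mean observed
H_f in that light level.

## Mixed-model scan

The response is the stacked BLUE vector (length 2n, environment-major,
genotypes in kinship order). Fixed effects: intercept, light, marker
dosage, marker × light. Random structure: polygenic u with Var = Kσ²_u
shared across environments, polygenic×light u_e with
Var = (Z₁KZ₁ᵗ ∘ Z_EZ_Eᵗ)σ²_ue — equivalently, independent per-
environment polygenic deviations each with covariance Kσ²_ue — and
iid residuals. Without u_e, genome-wide marker×environment tests are
strongly inflated; with it, the joint test is calibrated (verified by
simulation: empirical size ≈ 5%, genomic-control λ ≈ 1).

*Computation.* With identical genotype order in both environment
blocks, Z₁KZ₁ᵗ = J₂⊗K and the u_e term is I₂⊗K, so the rotation
(Q⊗U) — Q the 2×2 sum/difference rotation, U the eigenvectors of K —
diagonalizes all covariance terms simultaneously. REML reduces to
diagonally weighted least squares: the residual variance is profiled
out and the restricted likelihood is maximized over the variance
ratios (γ_u, γ_ue) by bounded L-BFGS-B restarted from a coarse grid
(boundary estimates at exactly 0 are reachable); tolerance 1e-8 on
the log-likelihood. Each marker test is then a 4-column weighted
regression.

*Testing.* The "genetic effect" is the 2-df Wald F of
{marker, marker×light} jointly, referenced to F(2, n_obs − rank(X)) —
a small-sample convention; at n_obs = 360 the df rule is immaterial.
BH step-up FDR at q = 0.05 is applied to the joint p-values across
all markers. For significant markers, a sequential Type-I split tests
the marker after {intercept, light} and the interaction last, each at
a fixed 5% level. By default variance components are estimated once
under the no-marker null and reused for all markers (EMMAX-style);
`per_marker_reml` refits them per marker — the two agree to first
order, and the reuse mode makes a 46k-marker scan a few seconds.

*Effect coding.* The scan covariate counts copies of the **least
frequent** allele, so β_marker is the unshaded height change per
minor-allele copy relative to a two-reference-copy genotype, and
β_inter the additional per-copy change under shade; the predicted
contrast is `copies × (β_marker + β_inter·1[shaded])`. When the
synthetic generator injects effects per reference-dosage copy at a
marker whose reference allele is the major one, the estimated signs
are therefore flipped relative to the injected values; magnitudes and
tests are unaffected.

## QTL clustering

LD between dosage vectors is the squared Pearson correlation R².
Significant markers are clustered per chromosome by average-linkage
agglomeration on d = 1 − √R², with the tree cut at 1 − √R²c. The √
transform (|r| being closer to normal than r²) is applied to both the
distance and the cutoff for internal consistency; a
`sqrt_transform=False` switch gives the untransformed reading
(d = 1 − R², cut 1 − R²c). This transform-vs-cutoff pairing is the
module's main interpretive choice and both variants are exposed.

R²c is the 99th percentile of R² over `n_pairs` (default 10,000)
randomly sampled cross-chromosome pairs — sampled rather than
exhaustive, with a fixed seed recorded per run. Background relatedness
legitimately inflates R²c above the iid χ²₁/n scale. Markers are
sorted lexicographically before clustering so ties resolve
independently of input order. Note the cut direction: a *larger* R²c
lowers the cut height and can only split blocks further (never merge
more). Blocks are named by chromosome with a position-ordered ordinal
when a chromosome carries more than one ("4B1", "4B2"); boundaries
are the min/max member map positions; the lead marker minimizes the
joint-test p-value.

## Synthetic data

Genotypes are founder-haplotype mosaics: founder alleles are drawn at
frequency Uniform(maf_min, 1 − maf_min) per marker; each line copies
one founder per `block_length`-marker segment (segments never span
chromosomes), giving LD that decays with marker separation. Each line
draws founder ancestry proportions from a symmetric
Dirichlet(`founder_concentration`); segments genome-wide follow those
proportions, creating genuine background relatedness and mildly
elevated unlinked LD. The default concentration (30) reflects a panel
whose founders were homogenized by many generations of intercrossing
before line extraction — weak structure, weak LD. Residual
heterozygosity (dosage 1) is injected per call at 2% by default (two
selfing generations leave a little; the exact rate is a parameter, as
is the missing-call rate). Columns are recoded so dosage counts the
panel-major allele.

Phenotypes follow the same mixed model the scan fits, plus the design
terms: H_f = μ + light + batch + β_hi·H_i + Σ_qtl dosage·(β_marker +
β_inter·1[shaded]) + u + u_e + ε, with u ~ N(0, Kσ²_u), u_e drawn
independently per environment with covariance Kσ²_ue, and iid ε.
H_i is lognormal with mean 15 mm and CV 0.1 (a positive, mildly
skewed distribution for coleoptile length; the exact law is a
modelling choice). Plants are assigned to batches uniformly at
random. Defaults (μ = 193 mm, light effect +7 mm ≈ +3.4%, σ²_u = 300,
σ²_ue = 30, σ²_e = 900 mm², on the diag(K) ≈ 2 scale) give unshaded
means near 208 mm and realized within-environment H² ≈ 0.36–0.49 with
genetic CV ≈ 11–13% — the regime of the emulated trial. Injected QTLs
add variance on top of these, so runs with large simulated QTLs show
higher H² and larger treatment contrasts than the QTL-free defaults.

Light spectra are non-negative mixtures of three bands (blue/white
450 nm, red 665 nm, far-red 730 nm) whose red and far-red amplitudes
solve a 2×2 linear system so that the spectrum's PAR and R:FR — as
computed by the package's own radiometry — hit their targets exactly.

*What the generator does not emulate:* genotyping-array intensity
artefacts, presence/absence variants, pedigree-explicit descent
(mosaic blocks stand in for recombination history), non-Gaussian
residuals, spatial/edge effects within phytotrons, and selection or
drift in the source population. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the
stated generative model, not robustness to those artefacts.

## Radiometry conventions

PPFD(λ) = Irr·λ/(N_A·h·c) with CODATA exact constants; band
integrals use the trapezoid rule on the wavelength grid so results
are stable under grid refinement (`literal_sum=True` reproduces a
plain sum of sampled bins). Band endpoints are inclusive. PAR is the
400–700 nm integral; red 660–670 nm; far-red 725–735 nm.

## Problem sizes and numerical choices

The test suite exercises the pipeline at panel sizes chosen for quick,
stable Monte-Carlo checks: calibration on ≈2,000 null markers at
n = 180, REML recovery at n = 300 over 50 replicates, QTL
detection/classification over 20 replicates of 180 × 2,000 panels.
These sizes keep Monte-Carlo error well below the tested tolerances;
the implementation itself handles tens of thousands of markers (the
scan is O(markers · n²) after a single n × n eigendecomposition).
Degenerate inputs are handled explicitly: constant markers are
skipped with a reason, single-batch designs drop the batch term with
a warning, empty significant sets yield empty QTL lists, all-missing
markers are an error, and negative variance estimates are truncated
at zero (H²) or prevented by bounds (REML).

## Known limitations

- The scan supports exactly two environments; the eigen-rotation
  trick and the u_e construction rely on disjoint environment blocks.
- BLUEs are treated as exact responses in stage two; their estimation
  error is absorbed into σ²_e rather than propagated.
- Sequential main/interaction decomposition is only meaningful for
  markers that pass the joint-test FDR; p-values for the split are
  not further multiplicity-corrected (fixed 5%, by design).
- Mean-dosage imputation ignores LD; with material missingness a
  model-based imputer would be preferable.
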