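# Methods

This note documents the statistical models, the synthetic-herd generator,
the numerical choices, and the limits of what the test suite can show.

## Study design being emulated

A single-herd study: several hundred Holstein cows, each with (i) a panel
of blood metabolites measured once, in a handful of sampling-date batches;
(ii) in-line milk spectra — ~70 sub-observations per milking on 32
visible/NIR channels (400–1,000 nm), each weighted by the milk quantity it
represents; (iii) dense SNP genotypes; (iv) herd covariates: days in milk
banded into six classes (<60, 60–120, 121–180, 181–240, 241–300, >300 d)
and parity in three classes (1, 2, ≥3). The farm data themselves are
proprietary, so the package ships a generator that reproduces their
statistical structure and the pipeline is validated on that.

## Synthetic herds (`milkpred.simulate`)

Genotypes: per-SNP alternate-allele frequencies q ~ U(0.05, 0.5), genotypes
Binomial(2, q) i.i.d. per cow (Hardy–Weinberg, no LD). Independence keeps
every downstream expectation analytically checkable; an optional
Gaussian-copula block mode (`ld_block_size`, `ld_block_rho`) adds
within-block correlation for experiments that need LD. Markers are laid
out in position order along the 29 bovine autosomes.

Phenotypes: for each metabolite, y = DIM effect + parity effect + batch +
a + e on a unit-variance scale for the random part: Var(a) = h²,
Var(batch) = the configured batch fraction (default 0.1), Var(e) the
remainder. The additive value a comes from `n_qtl` loci (default 50) with
N(0, 1) effects rescaled so the realised Var(a) equals h² exactly. Fixed
effects default to 0–0.8 SD across DIM bands and 0–0.3 SD across parities,
the magnitude of lactation-stage effects on energy metabolites. Metabolites
are simulated independently of each other; the pipeline is single-trait
throughout, so cross-metabolite covariance would exercise nothing.

Spectra: two latent milk-composition traits (fat, protein) are built from
the standardised metabolites with symmetric mixing weights (every
metabolite loads with magnitude 1/√t on both latents, alternating sign on
the second) so no trait is privileged; each latent is
√r² · (metabolite combo) + √(1−r²) · noise with r² = `spectra_signal_r2`
(default 0.3, giving spectra-only predictive r around 0.4–0.5). Channel
responses are smooth Gaussian absorption-like curves over 400–1,000 nm
loaded on the latents, on a sinusoidal baseline. Each cow receives
k ~ Poisson(70) sub-observations (≥1) with within-cow noise
(`subobs_sd`, default 0.1 — the within-cow spread of the ~70 readings is
not documented anywhere, so it is an explicit parameter) plus channel
noise (default 0.05), and a milk weight ~ U(0.20, 0.33).

What the generator does *not* emulate: kinship (real herds are networks of
half-sibs; unrelated genotypes make the effective marker dimension maximal,
which materially lowers GWAS power and genomic prediction accuracy at a
given n), linkage disequilibrium (by default), non-linear
spectra–metabolite links, and metabolite-specific scales. Passing tests
therefore demonstrate correctness of the machinery and the *direction* of
the information gains, not the effect sizes attainable on real herds.

## Spectral preprocessing (`milkpred.spectra`)

Order of operations: weighted aggregation → first derivative → SNV → QC.
Aggregation first matches the fact that the ~70 readings are reported as
one record per cow. The SNV divisor is the population SD over the
spectrum's own 31 derivative channels: SNV is by construction a
per-spectrum (row) operation, and each retained row has mean 0 and SD 1 to
1e-12 by design. A constant (zero-variance) spectrum has no SNV transform;
the cow is flagged `degenerate spectrum` and excluded from modelling.

QC: PCA retains the fewest components explaining ≥95% of variance
(configurable); squared Mahalanobis distances of the score vectors are
referred to a chi-square with df = retained components, and cows below the
`alpha_qc` tail threshold (default 0.05) are flagged. Two caveats are
worth knowing. First, with a non-robust covariance a single gross outlier
has D² bounded near n, so flagging requires the herd to be larger than the
chi-square cutoff at the retained df — the planted-outlier tests use herds
of 30–60 cows for this reason. Second, on generated herds the flagged
fraction runs above the nominal level (≈15% at α = 0.05): cow-mean noise
scales with 1/√k and k varies Poisson-fashion between cows, so the D²
distribution is a scale mixture with a heavier-than-chi-square tail. Real
instruments show the same heterogeneity; users wanting removal rates near
1% (typical of production QC) should set `alpha_qc` around 1e-3.

## Genotype QC and the GRM (`milkpred.genomics`)

Filter order: non-autosomal → MAF < 0.05 → HWE p ≤ 1e-5 (1-df chi-square
goodness of fit; adequate at n ≈ 400 with common alleles, and monomorphic
SNPs return p = 1) → SNP call rate < 0.95 → sample call rate < 0.95.
Remaining missing calls are imputed to the column mean 2pⱼ. Every
exclusion is recorded with its reason and the counts reconcile exactly.

G = MM′/c with column j of M centred by 2pⱼ and c = 2Σpⱼ(1−pⱼ). When the
frequencies are computed from the analysed cows themselves, the centred
columns sum to zero, so G annihilates the all-ones vector and is singular
*by construction*. `Grm.blend()` (0.99 G + 0.01 I) restores invertibility;
the pipeline applies it per training fold (where frequencies are
fold-internal), while the low-level GRM op leaves G untouched so the exact
algebraic identities remain testable with externally supplied frequencies.

## GBLUP, REML and GWAS (`milkpred.gblup`)

`GBLUP(y, X, batch, grm).fit()` solves Henderson's mixed-model equations,
scaled so that the inverse coefficient matrix is the prediction-error
variance matrix; the a-block C^{aa} is retained. Solutions match the
direct GLS/BLUP computed by explicit inversion of
V = Gσ²ₐ + WW′σ²_batch + Iσ²ₑ to 1e-8 on every fixture.

Variance components: EM-REML in the eigenbasis of G, where the animal
block of the coefficient matrix is diagonal and each iteration costs
O(n·m²) for m fixed+batch effects. Plain EM crawls when an estimate
approaches a boundary, so each step is extrapolated on the log scale
(step lengths 2, 4, 8) keeping the candidate with the best restricted
likelihood — convergence (relative log-likelihood change < 1e-8) typically
takes ~20 iterations instead of hundreds. Non-convergence within the
iteration cap yields a warning and the last iterate, flagged.

Backsolving and p-values: u = M′G⁻¹â/c, which satisfies Mu = â exactly
whenever G = MM′/c is invertible. The default standardisation uses the
per-SNP sampling variance Var(uᵢ) = mᵢ′G⁻¹(Gσ²ₐ − C^{aa})G⁻¹mᵢ/c²; tiny
negative values of this difference (below 1e-10 of the maximum) are
numerical zeros and are floored rather than treated as errors. The
`empirical-sd` variant (one constant scale = SD of the u vector) is kept
because the phrase "standard deviation of the SNP effects" admits both
readings. Under non-genetic responses the per-SNP method's p-values are
uniform (mean KS ≈ 0.03 at n = 200, p = 1,000) and the −log₁₀(p) > 2 tail
holds its nominal ~1% size. Selection at a threshold is strict (>), and
selections at 3.0 ⊆ 2.5 ⊆ 2.0 by construction.

## Elastic net (`milkpred.enet`)

The solver minimises the unscaled objective
RSS + λ[(1−α)‖β‖² + α‖β‖₁] by cyclic coordinate descent
(βⱼ ← S(2zⱼ, λα)/(2(dⱼ + λ(1−α)))), on internally standardised columns
with the intercept handled analytically; coefficients are returned on the
original scale. Stopping: max coefficient change < `tol` (default 1e-7) or
`max_iter` (default 10,000). KKT residuals certify optimality; λ = 0
reproduces OLS and α = 0 the closed-form ridge to 1e-8 (at `tol` = 1e-12).
The inner loop is numba-compiled; warm starts across the tuning grid make
repeated fits nearly free.

Parameterization: a λ of at most 1 is a vanishingly weak penalty for this
unscaled objective (soft-thresholds of ≤0.5 against gradients that grow
with n), so the 0–1 grid is only a meaningful search space in glmnet's
1/(2N)-scaled convention. `tune_random_grid` therefore supports both: the
default interprets grid pairs literally in the unscaled objective, while
`parameterization="glmnet"` — the pipeline's default, since glmnet+caret
is the stack this kind of analysis is actually run with — converts each
grid pair exactly onto the unscaled objective
(λ ← Nλ_g(1+α_g), α ← 2α_g/(1+α_g)) before fitting. Tuning uses one
seeded 80:20 split of the training rows; the winner has the lowest tuning
MSE with ties broken by higher Pearson correlation, then smaller λ, then
smaller α, and is refit on the full training set (warm-started from its
80% solution, which does not change the optimum — zero-start and
warm-start agree to 1e-9 in objective).

## Cross-validation pipeline (`milkpred.pipeline`)

5-fold random partition (sizes within 1), each fold validated exactly
once. Per fold and metabolite, *training cows only* determine: allele
frequencies, the (blended) GRM, REML variance components, GWAS p-values,
marker selections, elastic-net standardisation constants and tuned (α, λ).
Tuning seeds derive deterministically from the master seed and the
fold/trait/model indices, so permuting a validation fold's responses
leaves that fold's selections and coefficients bit-identical — asserted by
a permutation-guard test. An empty marker selection falls back to the
all-marker M3 with a warning. DIM and parity enter the elastic-net design
as full one-hot blocks (6 + 3 columns; redundant columns are harmless
under penalisation and are dropped automatically if constant), giving
M1/M2/M3 widths of 31 / 40 / 40 + markers. Batch is a random effect in
the GWAS model but not an elastic-net feature. Fold metrics are aggregated
as mean ± SD; RD is computed from mean r against M1. The slope diagnostic
is the regression coefficient of ŷ on y, which for shrunken predictions
sits well below 1 — regressing y on ŷ instead would give the near-unity
values familiar from calibration plots.

## Problem sizes in the shipped checks

The directional-replication study runs 400 cows × 5,000 SNPs × 3
metabolites (h² = 0.1/0.4/0.7, 50 QTL) × 5 folds × 10 herd replicates,
with an 8-candidate random search per model fit and a relaxed coordinate-
descent tolerance (3e-5, iteration cap 2,000) for the all-marker design;
GWAS calibration uses 20 replicates of 200 × 1,000 under h² = 0; REML
recovery 10 replicates at n = 1,000. These sizes were chosen so the whole
suite runs on a laptop core in minutes while keeping Monte-Carlo error
small relative to the effects being asserted.

A note on power at this scale: with unrelated genotypes the GWAS
noncentrality per QTL is √(n_train · h²/n_qtl) ≈ 1.56 at h² = 0.4 —
below the 2.576 needed for −log₁₀(p) > 2 — so marker selection recovers
only ~15% of the QTL against ~1% false positives, and the genomic models
cannot beat the on-farm model for the medium-heritability trait at this
design; at h² = 0.7 the ordering M3 > M2 > M1 is clear. Real herds, with
kinship and LD, reach useful power at far smaller effective dimension.

## Known limitations

- Single record per cow (Z = I); repeated measures are out of scope.
- No pedigree information, single-step matrices, or multi-trait models.
- The Mahalanobis QC uses a non-robust covariance (see above).
- The coordinate-descent iteration cap can truncate the all-marker fits in
  the near-interpolation regime; predictions are stable well before the
  coefficient-change criterion is met, and the convergence flag is
  recorded on every fit.
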