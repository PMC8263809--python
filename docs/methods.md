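# Methods

This note records the models the package implements, the defaults it
ships, the numerical choices made where the design was open, and what the
simulation-based validation does and does not demonstrate.

## Model

All genotype columns X_j and the phenotype Y are standardized to mean 0
and population variance 1 (denominator n), so X_jᵀX_j = n exactly, the
marginal correlation is r_j = X_jᵀY/n, and the single-SNP χ² statistic is
S_j = n r_j²/(1 − r_j²). The trait model is linear, E[Y] = Xβ with
Gaussian residuals of variance σ²_e; on this scale the heritability
contributed by SNP j is h²_j = β_j².

### Heritability models

E[h²_j] = Σ_k a_jk τ_k with pre-specified annotations a_jk. Shipped
annotation builders:

* **constant** (`gcta`): a single all-ones column.
* **MAF-dependent** (`ldak-thin`): one column w_j·[2p_j(1−p_j)]^0.75,
  where w_j ∈ {0,1} marks survivors of duplicate thinning. Thinning is
  greedy in position order: a SNP is dropped if an already-kept SNP within
  100 kb has c² > 0.98. The thinning window/threshold and the 0.75
  exponent are configuration parameters; the defaults follow the
  established convention for this model family.
* **custom**: any finite m × K table with at least one positive entry.

τ is estimated by ordinary least squares (no intercept) of S_j − 1 on
n_j·ℓ_jk, where ℓ_jk = a_jk + Σ_l c²_jl a_lk are annotation-weighted LD
scores from the sparse LD panel. No inflation/confounding parameter is
fitted. A per-SNP weight hook exists for users who want weighted
regression; the default is unweighted. Collinear annotation columns are
rejected with the offending pairs named.

Fitted per-SNP expectations e_j = Σ_k a_jk τ̂_k are floored at
1e−10 × mean positive e (at least 1e−16) so every prior variance stays
positive; the residual variance σ²_e = 1 − Σ_j e_j is clamped to ≥ 0.05
with a warning when Σe_j ≥ 0.95, since sampling noise can push the sum
past 1.

### Priors and the conditional posterior

Four families, each parameterised by e_j:

| tool   | prior on β_j | implied prior variance |
|--------|--------------|------------------------|
| lasso  | DE(λ/√e_j)   | 2e_j/λ² |
| ridge  | N(0, v·e_j)  | v·e_j |
| bolt   | p·N(0,(1−f₂)/p·e_j) + (1−p)·N(0,f₂/(1−p)·e_j) | e_j |
| bayesr | π₁δ₀ + π₂N(0,se_j/100) + π₃N(0,se_j/10) + π₄N(0,se_j), s=(π₂/100+π₃/10+π₄)⁻¹ | e_j |

Given t_j = X_jᵀ(residual + X_jβ_j), the conditional posterior under a
Gaussian mixture is itself a mixture with component moments
μ_c = t_j/(X_jᵀX_j + σ²_e/σ²_c), v_c = σ²_e/(X_jᵀX_j + σ²_e/σ²_c).
Component responsibilities are the exact marginal likelihoods,
∝ w_c·√(v_c/σ²_c)·exp(μ_c²/2v_c) (point mass: ∝ w_c) — note the square
root on the variance ratio, which is what the exact derivation gives; the
implementation is verified against numerical quadrature rather than any
transcribed formula. All responsibility arithmetic runs in log space with
max-subtraction, so extreme signals cannot overflow.

Under the double-exponential prior the posterior is a two-piece truncated
Gaussian; the posterior mean and second moment use the closed form with
log-space piece weights and a stable Mills-ratio evaluation (direct erfc
down to z = −35, an asymptotic tail series beyond). The posterior mode is
the soft-threshold rule sign(t)(|t| − λσ²_e)/XᵀX; the individual-level
lasso uses the mode (coordinate descent), the summary-statistic lasso uses
the posterior mean for consistency with the variational scheme. Both are
exposed.

## Summary-statistic fitting

* **LD panel**: pairs within 3 cM (default) whose likelihood-ratio test of
  c_jl = 0 is significant at P < 0.01. The LRT statistic is
  −n′·ln(1 − c²) ~ χ²₁, the exact LRT for a bivariate-normal correlation —
  chosen because the test itself is standard while its statistic's form
  was an open design choice. Pairs are stored once (j < l) with symmetric
  query access; the binary file is a self-describing header (panel size,
  window, threshold, per-SNP counts) plus exactly 8 bytes per pair
  (int32 partner, float32 correlation).
* **Sliding windows**: effects start at zero; each 1 cM window is iterated
  (cyclic conditional-mean updates, σ²_e = 1 within a window, since a
  single window's expected heritability is near zero) until the estimated
  variance explained by its SNPs, β_wᵀC_wβ_w with stored sparse LD and
  unit diagonal, changes by < 1e−5. The window then slides 1/8 cM. A
  window that fails to converge within 50 iterations is rolled back to its
  pre-window effects and counted. The convergence metric's exact formula
  was an open choice; β_wᵀC_wβ_w is the natural "proportion of variance
  explained" under the stored LD. Windows start at the chromosome start
  and every SNP is revisited by ~8 overlapping windows; the final pass
  over a SNP is the one whose window has moved past it.
* **Pseudo summary statistics**: X_AᵀY_A/n_A is drawn about XᵀY/n with
  covariance (n_B/(n_A·n))·C, realised as
  (n_B/(n_A·n))^½ · X′ᵀg/√n′ with g standard normal over the reference
  panel; X_BᵀY_B = XᵀY − X_AᵀY_A exactly. This scaling makes
  Var(r_A) = 1/n_A and Var(r_B) = 1/n_B — the training/test statistics
  behave exactly like GWAS results from n_A and n_B samples. Scoring uses
  a reference panel distinct from the one used for construction, because
  reusing the panel biases the estimated model–phenotype correlation R.
  An optional long-range-LD region list zeroes effects inside the regions
  before scoring.
* **Grids**: ridge and lasso tune a global prior-variance scale over
  {0.05, 0.1, …, 0.9, 1.0} (11 settings; for the lasso the scale applies
  to λ⁻²); bolt tunes p ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.5} ×
  f₂ ∈ {0.1, 0.3, 0.5} (18); bayesr tunes the ridge configuration
  (0,0,0,1) plus (π₂,π₃,π₄) over {0, 0.01, 0.05, 0.1, 0.2} with
  π₄ ≤ π₃ ≤ π₂ and a positive sum (35 total; 125 triplets without the
  ordering restriction). All grids are overridable.

## Individual-level fitting

The variational fit maintains an exact residual vector; each sweep updates
every β_j once with t_j = X_jᵀresidual + n·β_j. Convergence is declared
when both the total posterior second moment (estimated genetic variance)
and the residual variance move by less than the tolerance — a surrogate
for the variational objective, chosen because the objective itself is not
needed anywhere else. Update order is cyclic, not randomized. σ²_e
defaults to 1 − Σe_j (clamped ≥ 0.05). Prior parameters are chosen on a
seeded random 90/10 split by validation MSE (ties to the earliest grid
entry) and the winner is refitted on all samples.

The penalized lasso solves min 1/(2n)‖Y − Xβ‖² + λ·Σ pf_j|β_j| with
pf_j ∝ 1/√e_j normalised to mean 1, starting at the smallest λ giving an
all-zero solution and descending geometrically (50 steps to λ₀/100 by
default) with warm starts. A sequential-strong-rule screen
(|gradient| ≥ pf·(2λ_new − λ_old)) restricts each solve, followed by a
full KKT check that re-admits violators, so solutions are identical to
no-screening coordinate descent. Ten-fold cross-validation tracks the
path; exploration stops after the CV error has risen for three
consecutive steps, and the reported solution minimises CV error over the
explored path.

## Classical baseline and evaluation

Clumping is greedy by significance: keep the most significant remaining
SNP (p from S_j via the χ²₁ survival function), remove stored neighbours
with c² above the threshold, repeat down to the p-value cutoff. The grid
is 6 p thresholds {5e−8, 1e−4, 1e−3, 0.01, 0.1, 1} × 4 clumping
thresholds {0.2, 0.5, 0.8, none} (all 24 candidates are fitted); kept
SNPs get their marginal correlation r_j as the effect size — the
standardized scale keeps classical and model-based scores directly
comparable. Candidates are ranked by validation R² (individual data) or
pseudo-test R (summary data), and the winning thresholds are re-applied
to the full statistics.

R² is the squared observed/predicted correlation; its standard deviation
comes from a delete-one-block jackknife over 200 contiguous blocks
(calibrated in the test suite against the spread across independent
replicates). MAE is computed after standardizing both vectors; AUC is the
Mann–Whitney statistic.

## Simulation design

Haplotypes follow a first-order copying process: an allele is copied from
the previous SNP with probability ρ, else drawn fresh at that SNP's
frequency; runs of copies are sampled as geometric run lengths (identical
in distribution, far fewer random draws). Two haplotypes sum to a dosage;
SNPs are equally spaced in cM (default 100 SNPs per cM, so a 3 cM LD
window spans ±300 SNPs and a 1 cM solver window ~100 SNPs). Adjacent-SNP
correlation ≈ ρ (default 0.9) with geometric decay, giving LD support
comparable to the window sizes. Target frequencies are uniform on the MAF
range; the copying process smooths realised frequencies toward the range
centre, so studies that need wide MAF spread use a lower ρ. Effects are
drawn from the requested prior family with variance ∝ the heritability
profile, then rescaled so Σβ_j² equals the target h² exactly — parameter
recovery studies then carry no h²-sampling noise. Monomorphic columns
(possible at small n) are re-drawn independently, which breaks LD for
those rare columns only.

What the simulations do not emulate: realistic recombination maps,
population structure and relatedness, case/control ascertainment,
imputation dosage error, and strand/allele-coding heterogeneity between
cohorts. Passing the validation suite therefore demonstrates internal
correctness of the estimators and the expected ordering of methods under
the assumed model, not performance on any particular real cohort.

## Validation problem sizes

The statistical-recovery studies use sizes chosen to keep Monte-Carlo
error well below the effects being measured on a single CPU: τ recovery
at m = 5,000 SNPs, n = 10,000 GWAS samples, 50 replicates (relative bias
threshold 10%, empirical standard error ~1%); the pipeline-vs-classical
comparison at n = 20,000, m = 5,000, h² = 0.5, 20 replicates with a
2,000-sample holdout and two 1,000-sample reference panels; the
matched-vs-constant heritability-model comparison at n = 10,000,
m = 2,000 with MAF-dependent effects, ρ = 0.5 and MAF range 0.01–0.5 to
retain frequency spread, 20 paired replicates. Reference panels of 1,000
are proportionate at these scales and satisfy the n′ ≥ 30 precondition of
the LD estimator.

## Known limitations

* Multi-allelic SNPs, VCF/BGEN input and non-integer dosages are out of
  scope; PLINK 1 hard calls only, with mean imputation of missingness
  before standardization (this keeps X_jᵀX_j = n exact; hard-call
  thresholds for imputed dosages are not applicable to this input).
* Pseudo summary statistics require a single GWAS sample size across SNPs.
* The individual-level tools hold the standardized genotype matrix in
  memory; biobank-scale out-of-core fitting is not attempted.
* The summary-statistic solver trusts the LD panel; with a mismatched
  reference population the usual caveats about external LD apply.
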