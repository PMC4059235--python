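# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limits of `gblupsim`. Notation: n animals, M SNPs,
W the n × M allelic-dosage matrix in [0, 2], p the per-SNP allele
frequencies, h² heritability, λ = (1 − h²)/h².

## De-regression of EBVs

EBVs are shrunken predictors and contain parental information; regressing
markers on raw EBVs both double-counts families and under-disperses the
response. We back-solve the two-effect mixed-model equations in
(parent average, individual), whose coefficient matrix is
Z'Z + [[4, −2], [−2, 2]]λ with the diagonal information contents recovered
in closed form from the input reliabilities (r²_i, r²_PA):

    α = 1/(0.5 − r²_PA),  δ = (0.5 − r²_PA)/(1 − r²_i)
    Z'Z_PA = λ(0.5α − 4) + 0.5λ√(α² + 16/δ)
    Z'Z_i  = δ·Z'Z_PA + 2λ(2δ − 1)

dEBV = [−2λ·EBV_PA + (Z'Z_i + 2λ)·EBV_i]/Z'Z_i, with reliability
r²* = Z'Z_i/(Z'Z_i + λ) and weight
w = (1 − h²)/[(c + (1 − r²*)/r²*)h²]. The algebra is verified two ways in
the test suite: a numeric root-finder reconstructs (Z'Z_PA, Z'Z_i) from the
MME inverse independently of the closed form, and the implied reliabilities
round-trip the inputs to ~1e−15. PA reliability is expressed on the
animal's breeding-value scale (r²_PA = 0.5 − PEV_PA/σ²_a), which is why it
is bounded by 0.5.

Two properties of this parameterisation are worth knowing:

* Records with Z'Z_i ≤ 0 (young animals whose EBV is essentially all
  parent average) carry no individual information and are *dropped*, not
  errors. Exactly-zero weights are treated as drops too.
* For founders (r²_PA = 0) the procedure does **not** reduce to the
  single-animal 1×1 de-regression EBV/r²: the PA effect remains in the
  system with zero information, and its −2λ coupling makes the implied own
  information larger (e.g. dEBV = 1.606·EBV rather than 1.351·EBV at
  r² = 0.74, h² = 0.5). This is a property of the parent-average-retaining
  back-solve, not a bug; the founder tests therefore use the 2×2 MME as
  the oracle.

`c` is the fraction of genetic variance not captured by markers; it
defaults to 0.5 and is configurable. In purely synthetic cohorts where all
genetic variance is marker-borne, c = 0 is the truth and is what the
calibration experiments use.

## Genomic relationship matrix

G = ZZ'/(2Σp_j(1−p_j)), Z = W − 2p. Frequencies are computed once on the
full animal set and reused across CV folds (a flag switches to
training-only frequencies). G is never blended with a pedigree matrix;
numerical rank deficiency is handled at factorisation time by escalating
diagonal jitter (starting at 1e−8 × mean diagonal, ×10 per retry, logged).
`rel10` summarises connectedness as the mean of an animal's 10 largest
relationships, diagonal excluded. Dense storage: the design regime is a
few thousand animals at most.

## GBLUP: two equivalent forms

Model (2) y = 1μ + a + e with a ~ N(0, Gσ²_a) and model (3)
y = 1μ + Ca* + e with G = CC', a* ~ N(0, Iσ²_a*) have identical
likelihoods; (3) is a Bayesian ridge on the columns of the Cholesky factor
and is what the Gibbs sampler fits. Record weights enter as
R = diag(1/w); row-scaling by √w reduces the model to a homoscedastic
ridge.

Priors: σ² ~ scaled-inv-χ²(df, S) with density ∝ (σ²)^(−df/2−1)e^(−S/2σ²),
prior mean S/(df − 2); df = 3 is the smallest df with a finite mean.
Elicitation from (h² = 0.5, Ve = 0.4): Va = Ve·h²/(1−h²),
Se = Ve(df+2), Sa = Va(df+2)/Ā with Ā the mean self-relationship
(1 without inbreeding), giving Se = Sa = 2.0 at the defaults. μ has a flat
prior.

Sampler mechanics: the whole a* vector is drawn jointly from its
multivariate-normal full conditional using a one-off eigendecomposition of
C̃'C̃ (O(n³) once, O(n²) per sweep), which removes the element-wise-sweep
autocorrelation; σ²_e and σ²_a* are scaled-inv-χ² draws with df + n degrees
of freedom. Chains reproduce bit-identically under a fixed seed. Default
chain in the library and tests is 20 000 iterations with 5 000 burn-in,
which recovers a simulated h² = 0.5 to within ±0.01–0.03 at n = 500;
production configs can raise this. Thinned draws (every 10th) are stored;
posterior means use every post-burn-in draw. Geweke z-scores and effective
sample sizes of the variance chains are reported, not enforced. Batch
means of a* are stored so Monte-Carlo standard errors of the GEBVs can be
formed; the model-equivalence test uses them with a multiplicity allowance
(98% of animals within 3 MCSE, all within 5) since the maximum of a few
hundred z-scores routinely exceeds 3.

With variances fixed, the closed form solves
(G_T + R_Tλ)x = y − 1μ̂, â_T = G_T x, with μ̂ by GLS against
V = G_Tσ²_a + R_Tσ²_e, and equals the Gibbs posterior mean up to MC error
and the G⁻¹-form mixed-model equations to 1e−8.

## Validation prediction and individual reliability

â_V = G_TV (G_T + R_Tλ)⁻¹ (y_T − 1μ̂), algebraically equal to
G_TV G_T⁻¹ â_T; one Cholesky factorisation of (G_T + R_Tλ) is shared with
the reliability computation
rel_i = [G_TV (G_T + R_Tλ)⁻¹ G_TV']_ii/[G_V]_ii. The ratio is a
*reliability* (a variance ratio); the reported *accuracy* is its square
root, and both are returned explicitly because the two are easy to
conflate. μ̂ is always the training-fold estimate. A validation animal
with non-positive [G_V]_ii gets NaN with a warning rather than an abort —
that regime is produced by aggressive shrinkage of imputed genotypes and
is part of what the package is built to surface.

## Synthetic cohorts

The generator emulates the features of a sire-family genomic-evaluation
dataset that the pipeline is sensitive to, and nothing more:

* **Founder haplotypes.** Per-SNP base frequencies U(0.05, 0.5)
  (minor-allele coding, MAF ≥ 0.05 as after QC); adjacent-locus LD via a
  first-order copying chain (allele copied from the previous locus with
  probability ρ, else drawn fresh), which keeps marginal frequencies inside
  [0.05, 0.5] and gives adjacent allele correlation ≈ ρ. Chromosomes are
  index-based integer labels; no physical map, no coalescent realism.
* **Families.** Founder sires and dams drawn from the haplotype panel;
  offspring receive one recombinant gamete per parent with
  Poisson(recomb_per_chrom) crossovers at uniform positions. Multiple dams
  per sire give paternal half sibs; litters give full sibs. Realised
  genomic relationships average 0.5 (parent–offspring), 0.5 (full sibs),
  0.25 (half sibs).
* **Breeding values.** Marker effects i.i.d. normal on a chosen QTL set,
  rescaled so the cohort variance of TBV equals σ²_a exactly; TBV = Zu
  with the same centring as G, so a ~ N(0, Gσ²_a) holds by construction.
* **EBVs.** EBV = r²·TBV + e with Var(e) = r²(1−r²)σ²_a, giving
  corr(EBV, TBV) = r and unit regression of TBV on EBV — the unbiasedness
  BLUP evaluations have. Parent-average EBVs are built analogously from
  (TBV_s + TBV_d)/2 with reliability r²_PA < 0.5. Default own
  reliabilities are drawn U(0.6, 0.85) (a realistic sire-evaluation range,
  mean ≈ 0.73) and offspring PA reliability is 0.3.
* **Imputation error.** LD imputation recovers haplotypes shared with the
  reference population and loses individual-specific detail, so its error
  is *not* independent noise: cross-animal relationships survive largely
  intact while self-relationships deflate. The emulator reproduces this
  with ŵ = a + s(w − a) + e, anchoring a at the parent-average dosage when
  both parents are genotyped and at twice the reference-panel frequency
  otherwise (panel frequencies are Binomial(H, p)/H draws, so a small
  panel pulls all anchored-to-panel animals toward the same point).
  Noise is drawn as 2·Beta with exactly the target mean and variance —
  a clamped Gaussian loses substantial variance at the dosage boundaries
  and overshoots the accuracy target by ~0.02. (s, θ) are calibrated per
  call from the cohort's empirical moments so that (1) the per-animal
  across-SNP R² between true and imputed dosage equals r2_target and
  (2) the centred dosage variance deflates by the same factor; the
  calibration accounts for the feasibility cap on bounded-scale noise.
  Measured at L = 5000: R² = 0.880/0.950 at targets 0.88/0.95, variance
  and G-diagonal deflation ratios within 1% of target. An optional MAF
  penalty degrades SNPs below MAF 0.1, emulating harder rare-allele
  imputation; positional (chromosome-end) penalties are not implemented.

What passing tests on these cohorts do *not* show: behaviour under real
LD decay and haplotype structure, selection, non-additive variation,
pedigree errors, or imputation-software-specific error patterns. The
emulator matches the two moments of imputation error that the downstream
claims depend on (per-animal R² and the diagonal-versus-off-diagonal
deflation asymmetry), not the full error process.

## Cross-validation study

k = 10 folds by random permutation (fold sizes differ by at most one; 983
animals split as seven 98s and three 99s). Scenarios: REFERENCE (observed
genotypes), VAL_IMPUTED_HIGH (validation imputed, R² = 0.95, H = 1800),
VAL_IMPUTED_LOW (validation imputed, R² = 0.88, H = 128), ALL_IMPUTED_LOW
(everyone imputed, R² = 0.88, H = 128). Explicit names are used instead of
scenario numbers to avoid ambiguity. Per fold: de-regress, impute per
scenario (fresh panel draw per fold for validation-only scenarios; one
imputed dataset per scenario when everyone is imputed), recompute allele
frequencies from the scenario's genotypes, rebuild G, fit on training,
predict validation, accumulate r(GEBV, EBV), the adjusted accuracy
r/mean(√r²_EBV), fold-mean rel10 and per-animal reliabilities.

Pooled accuracy is the fold-size-weighted mean of per-fold correlations
(fold size is the natural weight; an unweighted option exists). Scenario
comparison: two-way fixed-effects ANOVA (scenario + fold block; with one
observation per cell the fixed-block model is the estimable equivalent of
a random-block analysis) and Tukey HSD on scenario means using the blocked
residual mean square, with a compact letter display. Covariate screens
regress per-fold accuracy on fold-mean EBV accuracy and fold-mean rel10.
Top-fraction ranking overlap uses deterministic id-based tie-breaking and
a per-trait ranking-direction flag.

The default model in `run_study` is the closed-form BLUP at the
λ = (1 − h²)/h² implied by the de-regression h² (only the variance ratio
matters for prediction and reliability); `method: "gibbs"` re-estimates
variance components per fold as a full analysis would. Default study size
(25 sires × 5 dams × 4 offspring = 650 animals, 3000 SNPs on 5
chromosomes) runs the four-scenario study in a few seconds on one CPU —
chosen as the smallest design in which the scenario contrasts and the
diagonal-deflation artifact are clearly resolved.

Randomness policy: one master seed; every stage derives its own seed as
SHA-256(master:stage) mod 2³¹, so runs reproduce bit-identically and
stages are independently perturbable.

## The imputation artifact

With everyone imputed from a small panel, diag(G_V) deflates by ≈ R² while
cross-animal relationships are better preserved; since diag(G_V) is the
denominator of the individual reliability, reported accuracies rise while
realized accuracy falls. In the replicated experiments
(20 × 400-train/50-validation, true variances) the reference scenario's
mean √reliability tracks realized corr(â_V, TBV) within ±0.03, while the
all-imputed scenario shows a positive estimated-minus-realized margin and
a validation-diagonal ratio of ≈ 0.86–0.88. Uniform rescaling of G alone
would cancel through re-estimated variance components; it is precisely the
diagonal-versus-off-diagonal asymmetry that survives and biases the
reliability ratio.

## Numerical choices and degenerate inputs

* Cholesky-with-jitter escalation: 1e−8 × mean diagonal, ×10 per retry,
  6 retries, applied jitter logged and returned; indefinite matrices fail.
* Constant responses: closed-form BLUP returns zero effects; the Gibbs
  sampler shrinks σ²_a toward its prior scale without diverging; ANOVA on
  a constant table reports F = 0 rather than 0/0 noise.
* A SNP with zero non-missing calls, frequencies outside (0, 1), a zero
  G normaliser, non-positive weights and overlapping train/validation
  sets are hard errors with specific messages.
* Residual missingness after QC is mean-imputed with 2p before G.
* QC order is fixed: autosome → animal call rate → SNP call rate → MAF
  (recomputed on surviving animals); the report accounts for every removal.

## Known limitations

* The imputation emulator is parametric; it cannot express error patterns
  that depend on local haplotype structure (e.g. chromosome-end effects).
* De-regression is single-trait and takes input reliabilities as given; no
  full-pedigree reliability computation.
* No marker-effect (SNP-BLUP/Bayesian alphabet) parameterisation and no
  REML; the animal-centric form is the point of the design.
* Reliability theory is applied to validation animals only; training-side
  prediction-error variances from the full MME inverse are out of scope.
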