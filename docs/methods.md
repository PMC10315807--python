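# Methods

Statistical model, estimator conventions, generator scope and numerical
choices for `mrscreen`. Notation: J instruments, per-SNP exposure association
(bx_j, sx_j), outcome association (by_j, sy_j), weights w_j = 1/sy_j².

## Data model and harmonization

A `VariantAssociation` is one SNP–trait summary record (alleles, beta, se,
p, n, optional chrom/pos/eaf) with validated invariants (se > 0, p ∈ (0, 1],
eaf ∈ (0, 1), distinct single-letter alleles). Harmonization aligns the
outcome record to the exposure's effect allele by rsID: identical allele
pairs pass through; swapped pairs negate the outcome beta and complement its
eaf; palindromic pairs (A/T, C/G), whose strand cannot be resolved from
summary data alone, are dropped; incompatible allele pairs are dropped.
Every drop is recorded with its reason.

## Instrument selection

Candidates are exposure associations with p < 1e-5. Greedy LD clumping keeps
the best (lowest p, ties broken by position then rsID) SNP and removes
neighbours with r² > 0.1 within 500 kb, iterating on the remainder. Per-SNP
instrument strength uses R² = β²/(β² + n·se²) — the exact transform of the
squared t statistic, requiring no allele frequency — and
F = (n − k − 1)/k · R²/(1 − R²); SNPs with F < 10 are removed. After
harmonization, instruments associated with the outcome at p < 1e-5 are
excluded (guarding against reverse causation and correlated pleiotropy), as
are instruments associated with known confounders when a lookup table is
supplied. An exposure with fewer than 3 surviving instruments is not
analyzed. All removals are audited by stage.

## Estimators

**Wald ratio.** by/bx with first-order delta SE sy/|bx|.

**IVW.** Weighted least squares of by on bx through the origin with weights
w_j: β̂ = Σ w_j bx_j by_j / Σ w_j bx_j². Fixed-effects SE is
(Σ w_j bx_j²)^{-1/2}; the multiplicative random-effects SE multiplies it by
√(max(1, Q/(J−1))), so underdispersion never shrinks the SE below the
fixed-effects value. Inference is normal.

**MR-Egger.** Instruments are oriented so bx_j ≥ 0 (the estimate is invariant
to allele orientation only under this convention), then weighted regression
of by on bx *with* intercept. Both coefficient SEs are scaled by
√(Q_egger/(J−2)) with **no floor at 1**: flooring the residual scale would
make the intercept test (the directional-pleiotropy test, t with J−2 df)
conservative in exactly the homogeneous samples where it is used as a gate.
This is a deliberate deviation from the IVW convention, chosen for
calibration of the intercept test and verified by simulation in the test
suite.

**Weighted median.** Order the Wald ratios, form cumulative weight midpoints
S_j = (Σ_{i≤j} w'_i − w'_j/2)/Σ w'_i with inverse-variance ratio weights
w'_j = bx_j²/sy_j², and interpolate to S = 0.5. Consistent when ≥ 50% of the
weight comes from valid instruments. The SE is a seeded parametric bootstrap
(resample per-SNP summary statistics from their sampling distributions,
recompute the median).

Binary-outcome effects are log odds ratios; `to_or` maps (β, se) to OR with
normal (or t, for Egger) confidence limits.

## Heterogeneity, outliers, and the screen

**Cochran's Q.** Q = Σ w_j bx_j² (by_j/bx_j − β̂)², chi-square on J−1 df
(J−2 around an Egger fit).

**Radial MR.** The IVW fit re-expressed on radial coordinates; per-SNP
contributions q_j partition Q exactly and are chi-square(1) under
homogeneity. SNPs with q_j-p < 0.05 are removed and the fit repeated until
no outlier remains or only 3 SNPs would survive.

**MR-PRESSO.** Observed residual sum of squares uses leave-one-out expected
values; the null distribution is simulated parametrically with a caller-
supplied seed. The global p has the add-one lower bound 1/(n_sim+1). Per-SNP
outlier p-values are Bonferroni-adjusted; the distortion test bootstraps the
difference between raw and outlier-corrected estimates. Requires J ≥ 4.

**Candidate screen.** An exposure is retained when all hold: IVW p < 0.05;
Egger and weighted-median point estimates agree in sign with IVW; no
heterogeneity (Q p > 0.05); no directional pleiotropy (Egger intercept
p > 0.05); and no leave-one-out sign flip. Retained exposures are re-estimated
in a replication cohort; a final candidate must be direction-consistent there
and significant in a DerSimonian–Laird random-effects meta-analysis of the
two log-OR estimates. Bonferroni and Benjamini–Hochberg adjusted p-values are
reported across the screened set.

## Direction, power, LDSC

**Steiger.** Compare summed instrument R² on exposure vs outcome via Fisher's
z: z = (atanh√R²x − atanh√R²y)/√(1/(n_x−3) + 1/(n_y−3)); the causal direction
is "forward" when R²x > R²y.

**Power.** For a binary outcome with case fraction K, sample size n,
instrument strength R², and alternative odds ratio OR:
power = Φ(|ln OR|·√(n·R²·K(1−K)) − z_{0.975}), the standard non-centrality
approximation for the two-stage estimator.

**Lean LDSC.** Regression of χ² on LD scores ℓ: E[χ²_j] = a + n·h²·ℓ_j/M,
fit by two-pass WLS (second-pass weights from first-pass fitted values,
1/(2·E[χ²]²)), with a free intercept absorbing confounding inflation.
SEs come from a delete-block jackknife computed by sufficient-statistic
subtraction (O(M), not O(M·blocks)); block count auto-reduces with a warning
on short panels. Genetic covariance uses the analogous z₁z₂ regression; the
genetic correlation rg = gencov/√(h²₁h²₂) is jackknifed jointly (ratio per
delete-block replicate) and clamped to [−1, 1], with the unclamped value
reported alongside. Intended for validating synthetic panels — it assumes
the panel's SNPs are representative and handles no annotation stratification.

## Colocalization

Per SNP, the Wakefield log approximate Bayes factor:
lABF = ½ln(V/(V+W)) + z²W/(2(V+W)), with V the squared SE and prior effect
variance W = sd², sd = 0.2 for quantitative and 0.15 for binary traits.
Hypothesis weights for H0–H4 are accumulated in log space (logsumexp); the
H3 sum over distinct causal pairs is computed as a log-difference
(Σ_i Σ_j − Σ_i=j) with a clamp at zero when cancellation makes it vanish
numerically (a warning is emitted). Priors p1 = p2 = 1e-4, p12 = 1e-5.
PP.H4 > 0.8 is the shared-variant decision. Only single-causal-variant
configurations are modeled (the standard ABF approximation); traits are
joined on rsID.

## Multivariable MR

Given a row-complete J×m matrix of exposure associations BX and outcome
vector by, multivariable IVW solves the no-intercept WLS by = BX·θ with
weights w_j, scaling SEs by √(max(1, Q/(J−m))) and using t(J−m) inference.
Joint instruments are the union of the per-exposure selected instruments,
re-clumped jointly, restricted to SNPs present in every exposure table
(incomplete SNPs audited). Near-singular design matrices raise a
`CollinearityError` rather than returning unstable estimates. Multivariable
PRESSO mirrors the univariable algorithm with leave-one-out refits computed
by batched rank-one downdates.

## Pipeline determinism

`run_pipeline` derives per-exposure child seeds from the root seed with
`numpy.random.SeedSequence` (reduced mod 2³¹−1), so results are independent
of exposure iteration order. Reports serialize to canonical JSON and are
hashed with SHA-256; identical configurations reproduce byte-identical
reports. Per-exposure failures are recorded as statuses, never raised.

## Synthetic-data generators (scope)

All generators produce *summary statistics* directly under the standard
two-sample asymptotics — no individual-level data is simulated.

**Two-sample panels.** True SNP effects γ_j are half-normal (sd 0.15,
truncated below at 0.075), oriented so the effect allele raises the exposure.
Sampling SEs follow 1/√(2n·eaf(1−eaf)) for the quantitative exposure and
1/√(2n·eaf(1−eaf)·K(1−K)) for the binary outcome (log-OR scale). Outcome
effects are θγ_j + α_j plus sampling noise, with four pleiotropy regimes:
`none` (α = 0), `balanced` (α ~ N(0, s²)), `directional` (α ~ N(s, (s/2)²) on
a fraction of SNPs), and `inside_violating` (α correlated ~0.7 with γ,
violating the InSIDE assumption that Egger requires). Default sample sizes
(7 824 exposure; 32 072 primary outcome with case fraction 0.622; 8 554
replication with case fraction 0.519) mirror a realistic metabolite screen.

**LD regions.** AR(1) correlation (parameter ρ) among m SNPs; z-vectors drawn
from N(√n·R·a, R) where a places a single causal variant (shared, distinct,
trait1-only, or null), so marginal z's are exactly standard normal at the
null.

**LDSC panels.** LD scores ℓ = 1 + Gamma(3, 30); per-SNP standardized effects
drawn with variance h²ℓ_j/M and cross-trait correlation rg, then z = √n·β + e,
matching the LDSC generative expectation E[χ²] = 1 + n h² ℓ/M exactly.

**Universes.** A dictionary of exposures (a few of them causal with common
θ), two outcome cohorts sharing a SNP panel, an identity-block LD matrix, and
full ground truth. Every exposure table reports the full panel so
multivariable MR has complete cases.

## Known limitations

- Instrument clumping and MVMR assume the supplied LD matrix is complete for
  the candidate SNPs; missing pairs raise rather than being assumed null.
- The outcome-overlap exclusion (p < 1e-5), faithful to common screening
  practice, removes exactly the instruments of a *strongly* causal exposure
  and truncates the surviving outcome effects; simulations in the test suite
  show strongly causal exposures can self-censor below the minimum instrument
  count or fail the Egger-intercept gate for this reason. At metabolite-scale
  effect sizes this is the intended conservative behavior.
- Weighted-median SEs are bootstrap-based and therefore seed-dependent;
  all callers must pass explicit seeds.
- The colocalization model assumes at most one causal variant per trait per
  region and ignores LD between test SNPs (standard ABF framework).
- Lean LDSC is a validation tool: two-pass WLS on simulated panels, no
  sample-overlap intercept modeling beyond a free intercept, no partitioned
  heritability.
- Steiger's test uses the Fisher-z approximation with summed per-SNP R²,
  which assumes independent instruments.
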