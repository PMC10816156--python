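# Methods

This package implements two-sample Mendelian randomization (TSMR) from GWAS
summary statistics: using genetic variants as instrumental variables, it
estimates the causal effect of an exposure (here motivated by angina
liability) on a binary outcome (hepatic failure) from two non-overlapping
study populations. This note records the statistical model, the estimators
and their conventions, the synthetic-data generator that stands in for real
GWAS extracts, and the design choices made where the design was genuinely
open.

## Model and notation

For SNP *j*, let γⱼ (SE σ_γⱼ) be its per-allele association with the
exposure and Γⱼ (SE σ_Γⱼ) its association with the outcome, both on the
log-odds scale and expressed per copy of the same effect allele. Under the
instrumental-variable assumptions (relevance, independence from confounders,
and exclusion restriction), each valid instrument satisfies

    Γⱼ = β γⱼ,

where β is the causal log-odds effect. Horizontal pleiotropy adds a direct
effect αⱼ, giving Γⱼ = β γⱼ + αⱼ; pleiotropy is *balanced* when E[αⱼ] = 0
and *directional* otherwise. MR-Egger is consistent for β under the InSIDE
condition (instrument strength independent of direct effects,
corr(γⱼ, αⱼ) = 0).

## Instrument selection

Five screening stages run in a fixed order, each a contraction on the
exposure table, with per-stage counts and drop reasons recorded in an audit:

1. **Genome-wide significance** — keep p < 5×10⁻⁸ (strict inequality).
2. **LD clumping** — greedy: repeatedly take the remaining SNP with the
   smallest p as an index and drop every other remaining SNP on the same
   chromosome within ±10,000 kb whose r² with the index is ≥ 0.01. Ties in
   p break by position, then SNP id, so results are platform-independent.
   The LD matrix is an input (square or long-format triples); computing LD
   from genotype panels is out of scope.
3. **Weak-instrument filter** — per-SNP F ≥ 10 with
   F = (N−K−1)/K · R²/(1−R²), K = 1. The default R² estimator is
   R² = z²/(z²+N−2) with z = β/SE, which needs no allele frequency; a
   frequency-based mode (R² = 2·EAF·(1−EAF)·β²) is available when EAF is
   present. Note an algebraic identity: with K = 1 and the z-score R²,
   F = z² exactly, so genome-wide-significant SNPs (|z| > 5.45) always pass
   F ≥ 10 — the stage matters only for relaxed significance thresholds or
   externally supplied R² values. Published instrument tables report F
   values close to, but not exactly, z² (they were computed from richer
   inputs); per-SNP F agreement with such tables is approximate by nature.
4. **Palindrome exclusion** — A/T and C/G variants are dropped outright,
   with no frequency-based rescue: their strand is ambiguous and the
   upstream studies' strand conventions are unknown.
5. **Confounder exclusion** — any SNP with a confounder association
   p < 1×10⁻⁵ in a user-supplied table (exact id match) is removed. The
   confounder vocabulary (viral hepatitides, alcohol, metabolic and
   autoimmune liver disease, lipid traits, …) ships as data, not code.

Palindromic variants are also dropped during harmonization, so the pipeline
is safe in either order; the audit records which stage removed each SNP.

## Harmonization

Outcome records are aligned onto the exposure's effect-allele frame: a
swapped allele pair negates the outcome beta (and reflects EAF); a pair that
matches only after complementing to the opposite strand is complemented
first; anything else is dropped with a logged reason. Strand complement is
attempted only after direct and swapped matches both fail, minimizing silent
mis-alignment. Harmonization is idempotent and sign-flip–involutive (both
property-tested).

## Estimators

All five estimators operate on the harmonized per-SNP effects; weights are
always the inverse outcome variance wⱼ = σ_Γⱼ⁻². Estimates are kept on the
log-odds scale internally; odds ratios and 95% CIs (exp(β̂ ∓ 1.96·SE)) are
attached at reporting time.

**IVW** — weighted least squares of Γ on γ through the origin:
β̂ = Σwγ Γ / Σwγ², SE_fixed = (Σwγ²)^(−1/2). Cochran's
Q = Σw(Γ−β̂γ)² is referred to χ²(J−1); if its p < 0.05 the SE is inflated
multiplicatively to SE_fixed·√(Q/(J−1)) (never below SE_fixed) — a
multiplicative random-effects model, applied automatically by the pipeline
while both SEs are always retained. P-values are two-sided normal. With one
SNP the estimate reduces to the Wald ratio and Q is flagged undefined.

**MR-Egger** — SNPs are oriented so γⱼ ≥ 0, then Γ is regressed on γ with a
free intercept (weights w). The slope estimates β; the intercept estimates
average directional pleiotropy. SEs carry the overdispersion factor
max(1, √(Q_E/(J−2))) and inference uses t with J−2 df — the two-parameter
fit at small J is the one place where normal inference would be noticeably
anticonservative.

**Weighted median** — per-SNP Wald ratios βⱼ = Γⱼ/γⱼ (first-order SE
σ_Γⱼ/|γⱼ|) are sorted; with normalized weights w′ the estimator
interpolates the cumulative weight midpoints sⱼ = Σ_{k≤j} w′_k − w′_j/2 at
0.5. Consistent while valid instruments hold > 50% of the weight.

**Mode-based (weighted and simple)** — the kernel-smoothed mode of the Wald
ratios with bandwidth h = φ·0.9·min(sd, 1.4826·MAD)·J^(−1/5) (φ = 1 by
default; if the MAD is zero the SD alone is used, and a fully degenerate
ratio set returns the common value). The density is evaluated on a fixed
512-point grid spanning [min β − h, max β + h] so the argmax is
deterministic across platforms; the weighted variant weights each ratio by
its inverse variance.

Median and mode SEs come from a parametric bootstrap (default 1000
replicates, explicit seed): γ̂ⱼ and Γ̂ⱼ are resampled from
Normal(γ̂ⱼ, σ_γⱼ) and Normal(Γ̂ⱼ, σ_Γⱼ) and the estimator recomputed; the SE
is the standard deviation of the replicate estimates. Inside the bootstrap
the density is accumulated in float32 — the grid argmax and the resulting
SE are insensitive to that precision, and it roughly halves the cost.
No published convention fixes the bootstrap count, bandwidth multiplier, or
kernel for these methods; the defaults above are declared, not inferred.

The five estimators are exposed as scikit-learn-style classes
(`fit(X, y, se_exposure=, se_outcome=)`, fitted attributes `beta_`, `se_`,
`pvalue_`, `get_params`/`set_params`, `predict` of the fitted line) with
thin functional wrappers; reporting order is IVW, weighted median, weighted
mode, simple mode, MR-Egger.

## Sensitivity suite

* **Cochran's Q** about the IVW fit (df J−1) and about the Egger fit
  (df J−2), upper-tail χ² p-values.
* **Egger intercept test** — t(J−2) on the intercept; the decision rule
  reports "no directional pleiotropy" at p ≥ 0.05.
* **Monte-Carlo outlier test (MR-PRESSO-style)** — the observed statistic is
  RSS = Σⱼ wⱼ (Γⱼ − β̂₋ⱼ γⱼ)² with β̂₋ⱼ the leave-one-out IVW slope. Each of
  n_sim (default 1000) replicates redraws γ*ⱼ ~ N(γⱼ, σ_γⱼ) and
  Γ*ⱼ ~ N(β̂₋ⱼ γⱼ, σ_Γⱼ) and recomputes the statistic. The global p is the
  add-one Monte-Carlo tail (1 + #{RSS* ≥ RSS})/(n_sim + 1), so it can never
  fall below 1/(n_sim+1). Per-SNP outlier p-values compare each SNP's
  observed weighted residual with its own simulated distribution (add-one),
  Bonferroni-adjusted across the J SNPs; adjusted p < 0.05 flags an
  outlier. When outliers exist the IVW slope is recomputed without them,
  and a distortion test compares the raw-vs-corrected shift against slopes
  from 1000 random same-size subsets. The simulation count, significance
  threshold, and Bonferroni correction are configuration with these
  defaults; published analyses rarely state them, so externally reported
  global p-values are not regenerable exactly.
* **Leave-one-out** — the IVW estimate (the primary method) excluding each
  SNP in turn.

## Synthetic two-sample studies

The generator emulates the structure of a biobank-scale exposure GWAS paired
with a rare-outcome register GWAS, at desk scale (default 500-SNP panel, not
tens of millions — panel scale is emulated in structure, not cardinality):

* **Effects.** Instrument effects γⱼ are half-normal(τ²) with τ = 0.15 —
  risk-allele coding, matching how published instrument lists orient
  effects — and are rejection-sampled jointly with their observed values
  until the observed exposure association passes 5×10⁻⁸, so the selection
  stage retains them by construction. The residual winner's-curse
  attenuation of downstream slopes is ≈1% of β at these settings (measured
  0.705–0.710 recovered at β = 0.72). Invalid instruments receive
  αⱼ ~ N(μ_α, σ_α²); the invalid set is chosen by count, or — with
  `pleiotropy_by_weight` — accumulated in random order until the invalid
  share of the inverse-variance ratio weight matches the requested
  fraction, which is the quantity the weighted median's breakdown point
  actually cares about.
* **InSIDE.** α is drawn independently of γ, and with ≥3 invalid
  instruments the draw is repeated until the sample correlation is below
  0.2, so generated datasets satisfy the assumption and not just its
  expectation; an `inside_violation` switch couples α to γ for negative
  tests.
* **Standard errors.** Binary-trait SEs use the case-fraction
  approximation σ² = 1/(N·v·2·MAF·(1−MAF)), v = cf·(1−cf), rather than
  simulating individual-level logistic data — the right SE structure at
  desk-scale cost. Defaults mirror a 9,481-case/446,987-control exposure
  study and a 464-case/213,592-control outcome study; MAF is uniform on
  (0.1, 0.5). These SEs reproduce the order of magnitude of published
  per-SNP SEs (0.01–0.04 exposure-side, ~0.07 outcome-side) but not their
  exact values, which reflect imputation and covariate adjustment not
  modelled here.
* **Panel structure.** SNPs sit in LD blocks of 5 consecutive SNPs assigned
  round-robin to chromosomes 1–22 (within-block r² = 0.7^distance, blocks
  independent, 20 Mb between same-chromosome blocks); each instrument leads
  its own block so clumping keeps it as the index SNP. 15% of variants are
  palindromic; 30% of outcome rows are re-expressed on swapped alleles and
  10% on the opposite strand, so harmonization has real work to undo (all
  recorded in a truth file). A single seed drives named substreams
  (effects, alleles, frames, confounders), making every component
  reproducible bit-for-bit.

What passing tests on these data do **not** show: robustness to panel-scale
multiple testing, sample overlap between the two studies, population
structure, LD reference-panel mismatch, or real imputation noise — none of
which the generator models.

## Validation scenarios and problem sizes

The acceptance computations (also runnable via `scripts/acceptance.py`) use:
oracle equivalence on 200 random instances (J ≤ 50) against statsmodels WLS;
parameter recovery over 500 replicates (β = 0.72, J = 30); IVW type-I error
over 2000 null replicates and Egger-intercept type-I error over 500
balanced-pleiotropy replicates (J = 50, σ_α = 0.07); outlier detection over
200 null and 200 single-outlier (+10σ) replicates at J = 20, n_sim = 1000;
and 100 random clumping instances (J ≤ 20) against a brute-force oracle.

The robustness demonstration pins 40% of the inverse-variance weight on
directionally pleiotropic instruments (J = 15, μ_α = 0.2, σ_α = 0.05, a 10×
larger outcome study so ratios are precise). Scenario rationale: under
one-sided contamination the weighted median's weighted-quantile shift and
its bootstrap SE both scale with the ratio noise, and their ratio grows
like √J — mirroring the √(J−1) growth of the heterogeneity-inflated IVW
detection ratio — so a moderate J with precise ratios is where the contrast
is cleanest: the weighted median stays within 3 of its own SE of the truth
(≥ 95% of replicates) while the fixed-effects ("all instruments valid")
IVW is biased by > 3 SE in essentially all replicates. Keeping the invalid
*weight* share at 0.40 matters: assigning 40% of instruments by count lets
the weight share wander past the 50% breakdown point in roughly a quarter
of replicates.

The Egger-intercept *power* illustration (μ_α = 0.02, J = 50) uses strong
instruments and a 10× outcome study because at the rare-outcome default the
intercept SE (≈0.016) is comparable to the effect being detected, capping
power near 20% for any σ_α.

## Numerical and degenerate-input conventions

Zero exposure effects make Wald ratios undefined and raise; an all-zero γ
vector is rejected. Bootstrap SEs of exactly degenerate replicate sets are
floored at the smallest positive float so p-values stay defined. Mode grid
ties resolve to the lowest grid point. The pipeline is a pure function of
(input files, config, seed): reports serialize with sorted keys and are
byte-identical across re-runs; the output directory does not enter the
config hash. Empty instrument sets abort with a stage-named diagnostic
rather than a partial report.

## Known limitations

No Steiger directionality filtering, multivariable MR, contamination-mixture
estimators, Rucker model selection, or I² for Egger regression; no reverse-
direction analyses; no proxy-SNP lookup, liftover, or VCF ingestion.
Confounder screening matches exact SNP ids only. Figures are deliberately
left to the user: the tested contract is the set of plot-ready tables
(scatter with fitted lines, per-SNP and per-method forests, leave-one-out).
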