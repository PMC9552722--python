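# Methods

## Setting and assumptions

`tsmr` performs two-sample Mendelian randomization: the effect of an
exposure X on an outcome Y is estimated from per-variant summary
statistics taken from two non-overlapping GWAS.  A variant j is a valid
instrument if it (i) associates with X, (ii) is independent of
confounders of X–Y, and (iii) affects Y only through X (exclusion
restriction).  Under these assumptions and approximate linearity, the
per-variant Wald ratio θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ (on
the log-odds scale when Y is binary).  The estimators differ in how they
behave when (iii) fails for some variants:

* **IVW** assumes all instruments valid; it is the inverse-variance
  weighted mean of the ratios, equivalently the zero-intercept weighted
  regression of β̂ᵧ on β̂ₓ with weights seᵧ⁻².
* **Weighted median** is consistent while instruments carrying at least
  half the total weight are valid.
* **MR-Egger** allows all instruments to be (directionally)
  pleiotropic provided instrument strength is independent of the direct
  effects (InSIDE); its intercept estimates the average direct effect
  and its slope the causal effect.

## Estimation details

**Ratio SEs.** The default `first_order` SE, seᵧⱼ/|β̂ₓⱼ|, ignores
exposure-side noise; it is accurate when seᵧ dominates |θ|·seₓ, which
holds for the packaged study data (seᵧ ≈ 0.013–0.023 vs |θ|seₓ ≈ 0.003).
A `second_order` option adds the exposure-noise term.

**IVW.** Fixed-effect SE (Σw)^(−1/2); the default multiplicative
random-effects model multiplies it by max(1, √(Q/(J−1))) so that
heterogeneity can widen but never narrow the interval.  p-values use the
standard normal.  On the packaged data the random-effects SE is 0.219
(fixed: 0.203); the published analysis reports 0.213, consistent with
random effects on unrounded inputs, which is why random effects is the
default.

**Weighted median.** Ratios are sorted; with normalized weights pⱼ the
standardized cumulative weight is sⱼ = Σ_{k≤j}p_k − pⱼ/2 and the
estimate interpolates θ̂ against s at s = 0.5 (the extreme ratio is
returned, with a warning, if the curve never crosses 0.5 — only possible
with a single variant).  The SE is the standard deviation of the
estimate over a parametric bootstrap (default 1,000 iterations, default
seed 20220, both recorded in the result metadata) that redraws each
(β̂ₓⱼ, β̂ᵧⱼ) from normal distributions with the reported SEs.

**MR-Egger.** Variants are first re-oriented so every β̂ₓⱼ ≥ 0 (flipping
the effect allele, negating both betas and complementing both
frequencies; Wald ratios are invariant).  Weighted least squares with a
free intercept and weights seᵧ⁻² is solved by the normal equations;
coefficient SEs are inflated by max(1, √(RSSw/(J−2))) and p-values use
t(J−2).  The same max(1,·) convention keeps under-dispersed data from
shrinking the SEs.

**Odds ratios.** OR = exp(β) with 95% CI exp(β ∓ 1.96·se).  The
multiplier is fixed at 1.96 (not a configurable quantile) to match
conventional reporting.

## Diagnostics

**Cochran's Q.** About the fixed-effect IVW estimate, Q = Σwⱼ(θ̂ⱼ−θ̂)²
with df J−1 (algebraically the weighted RSS of the zero-intercept
regression); about the Egger fit, the weighted RSS with df J−2.  Upper
chi-square tail; p > 0.05 is reported as "no significant heterogeneity".

**Egger intercept test.** p > 0.05 on the intercept is reported as "no
significant pleiotropy"; the 0.05 threshold is the field's reporting
convention and is surfaced in configuration.

**PRESSO-style RSS test.** The observed statistic is
RSS = Σⱼ (β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)²/seᵧⱼ², with θ̂₍₋ⱼ₎ the IVW estimate
excluding j.  Each of `n_sim` (default 1,000) parametric replicates
redraws β̂ₓⱼ* ~ N(β̂ₓⱼ, seₓⱼ) and β̂ᵧⱼ* ~ N(θ̂₍₋ⱼ₎β̂ₓⱼ, seᵧⱼ) and
recomputes the statistic identically; the global p-value is
(1 + #{RSS* ≥ RSS})/(n_sim + 1).  Only when the global test is
significant (α = 0.05) are per-variant residuals referred to their
simulated distributions (Bonferroni-adjusted over J) to flag outliers;
when outliers exist, an outlier-removed IVW estimate is reported
together with a distortion p-value that compares the estimate shift
against removing random same-sized subsets of non-outlier variants.
The test needs ≥ 4 variants (leave-one-out fitting must retain ≥ 3).
Because the replicates redraw the exposure betas as well, and the
p-value is discrete, the global test is slightly conservative (empirical
type-I error ≈ 0.033 at α = 0.05 over 1,000 null datasets in the test
suite).

**Sensitivity tables.** Leave-one-out IVW (one row per removed variant)
and per-variant Wald ratios with IVW/weighted-median summary rows,
emitted as plain DataFrames ready for forest plotting; simple matplotlib
renderings are provided in `tsmr.plots` but carry no analysis content.

## Instrument selection and strength

Selection applies, in order: the genome-wide significance threshold
(default p < 5×10⁻⁸), a user-supplied confounder exclusion list (the
screening of instruments against traits such as BMI, smoking and blood
pressure has no algorithmic form, so it is an explicit input), and
greedy LD clumping — candidates sorted by ascending p (ties broken
lexicographically by ID for determinism) are accepted iff their r² with
every already-accepted variant is below the threshold (default 0.001).
LD is consumed as a user-supplied pairwise table; a missing pair is an
error, never assumed zero, and `LDTable.independent()` covers published
pre-clumped instrument sets.  No LD is computed from genotypes and no
web service is queried.

R² per variant is estimated either as z²/(z² + N − 2) (`z_based`,
default — needs only beta/SE/N) or as 2·EAF(1−EAF)β² (`af_beta`, assumes
a unit-variance phenotype).  Published R² columns computed from
unrounded data rarely match either recipe at printed precision, so
F = R²(N−2)/(1−R²) also accepts externally supplied R² values; with
`z_based` R², F reduces algebraically to z².  F < 10 flags a weak
instrument.

## Harmonization

Outcome records are matched by variant ID (optionally substituting a
user-supplied LD proxy with r² ≥ 0.8, adopting the proxy's outcome
statistics verbatim and recording the action).  Allele alignment
recognises identical, swapped, strand-complemented and
swapped-complemented configurations; swaps negate the outcome beta and
complement its EAF; anything else (e.g. A/C vs A/G) drops the variant
with the reason logged.  Palindromic variants (A/T, C/G) are governed by
`palindromic_policy`; the default `keep_if_eaf_informative` (band
0.5 ± 0.08) keeps them only when both frequencies are known, both are
away from 0.5, and they are concordant.  When a frequency is missing the
check degrades gracefully: a palindromic variant whose printed alleles
already match the exposure orientation exactly is treated as
pre-oriented and kept — published harmonized tables (including the
packaged study data, whose outcome betas are printed against the
exposure-raising allele and without EAF) follow this convention —
while one that would need a strand inference is dropped.  Harmonization
is idempotent, and kept + dropped always partitions the instrument set.

## Synthetic-data generator

`simulate(SimConfig)` draws, per variant: an allele frequency
(uniform on `eaf_bounds`), a true exposure effect γⱼ (normal or a fixed
list), a direct effect αⱼ (zero / balanced / directional), analytic SEs
seₓⱼ = (2p(1−p)·n_exp)^(−1/2) (outcome analogous), observed betas
normal around the truth (β̂ᵧⱼ around θγⱼ + αⱼ), normal two-sided
p-values, and allele pairs with a configurable palindromic fraction.
An optional outlier shifts one variant's outcome beta by a stated
multiple of its SE.  Everything is deterministic given the seed, and
αⱼ ⊥ γⱼ, so InSIDE holds by construction.

Defaults are chosen to emulate the packaged study data.  Because
published trait scalings are rarely unit-variance and binary-outcome
precision is governed by the effective size 4·ncase·ncontrol/(ncase+ncontrol),
`n_exp` and `n_out` are *effective* precision parameters: the defaults
(145,000 and 12,000) are back-computed from the printed SEs of the
packaged exposure (≈ 0.004) and outcome (≈ 0.013–0.023) tables, and
γ ~ N(0.04, 0.012²) matches the printed exposure effects, giving
instrument F-statistics in the study's 34–108 range and the
outcome-noise-dominated regime that first-order ratio SEs assume.
What the generator does **not** emulate: LD between instruments,
winner's-curse selection of instruments, sample overlap between the two
GWAS, and non-normal summary noise — so passing calibration tests
support the estimators under the clean two-sample model, not robustness
to those real-data complications.

`scenario_battery()` fixes five named configurations — null,
causal-no-pleiotropy, balanced-pleiotropy (α sd 0.01), directional
pleiotropy (α mean 0.02), and single-outlier (one variant shifted by 10
outcome-SEs among 20) — that between them exercise every estimator and
diagnostic.  The test suite uses them at modest replicate counts
(200–1,000) chosen to keep Monte-Carlo error well inside the asserted
tolerance bands.

## Known limitations and deliberate scope

* Diagnostics are advisory: significant pleiotropy or heterogeneity is
  prominently flagged but does not abort a run (a `strict` mode exists),
  mirroring check-then-report practice.
* One calibration property sits at an analytic ceiling: after removing a
  single outlier carrying ~1/J of the weight, the corrected and
  uncorrected IVW estimates share the remaining instruments' noise, so
  the probability that correction moves the estimate strictly closer to
  the truth is ≈ Φ(shift/(2·SE·√J)) ≈ 0.87 for a 10-SE outlier among 20
  instruments — outlier *detection* is essentially certain, but
  correction cannot beat that bound.
* No mode-based estimators, multivariable MR, Steiger filtering, I²/
  Rücker model selection, LD estimation from genotypes, or remote data
  access; multi-allelic variants are out of scope.
* The weighted-median p-value is normal-approximation based on the
  bootstrap SE, the standard reporting convention.
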