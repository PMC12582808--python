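# Methods

## Scope and model

`medmr` analyses three GWAS summary-statistic tables — exposure, mediator,
outcome — joined per SNP by rsID. The causal chain of interest is

    exposure --α--> mediator --β2--> outcome,    exposure --β1--> outcome,

so the total exposure→outcome effect is β = β1 + α·β2. Effects for binary
traits are log odds ratios; the reporting layer exponentiates.

## Harmonization

Outcome (and mediator) effects are aligned to the exposure's effect
allele: swapped labels flip the beta sign and complement the frequency;
strand flips are resolved by base complement. Palindromic (A/T, C/G)
variants carry no strand information in their labels, so they are kept
only when both effect-allele frequencies are available, both sit outside
0.5 ± w (default w = 0.08, i.e. drop when the frequency is in
[0.42, 0.58]), and both agree on the minor allele after label alignment;
anything else — including a frequency missing on either side, or a
disagreement that a frequency flip could "rescue" — is dropped as
ambiguous rather than flipped. Joining is by rsID only; indels, liftover
and proxy lookups are out of scope. Every dropped SNP is logged with one
of four reasons (allele_mismatch, palindromic_ambiguous,
missing_in_outcome, duplicate), and retained + dropped always accounts for
every exposure SNP.

## Instrument selection

Candidates need exposure p strictly below 1e-5. Clumping is greedy in
ascending p-value (ties broken on rsID so results are order-independent):
a candidate survives if, against every already-accepted SNP on the same
chromosome within 10,000 kb, r² is below 0.001. A user-supplied LD matrix
(square TSV) provides r²; without one, any same-chromosome pair inside the
window is treated as linked (distance-only pruning). This fallback is
deliberately conservative and is *not* equivalent to clumping against a
population reference panel — supply an LD matrix when one is available.
Instrument strength uses the per-SNP F = (β/se)², the squared Wald z; F of
exactly 10 is retained ("below 10" excluded). An r²-and-n based F is
available as an option but is not the default, because the per-SNP
medians/minima/maxima of order 20 that the workflow reports are the
z²-based quantity.

## Estimators and inference conventions

- IVW fixed: weighted regression through the origin, w = 1/se_out²;
  se = (Σ w β_x²)^(−1/2). Random effects multiply the se by
  max(1, √(Q/(n−1))) — multiplicative overdispersion, floored so it can
  never be anti-conservative relative to fixed effects. Normal p-values.
- MR-Egger: exposure effects oriented non-negative (flipping paired
  outcome effects), weighted regression with intercept; the residual
  variance estimate is floored at 1 before scaling the coefficient
  covariance; t inference on n−2 df for slope and intercept.
- Weighted median: inverse-variance weights β_x²/se_out² on the ordered
  Wald ratios; the estimate interpolates linearly between cumulative
  weight midpoints at 0.5. Standard errors by parametric bootstrap
  (default 1000 replicates) perturbing both β_x and β_y; the seed is a
  required argument — there is no hidden global random state.
- Modes: Gaussian-kernel density of the Wald ratios with bandwidth
  φ·1.06·s·n^(−1/5), s the scaled median absolute deviation; the weighted
  variant weights ratios by inverse variance. The argmax is taken on a
  512-point grid spanning mean ± 4s, widened where necessary to cover the
  data range (a pure mean ± 4s span can exclude an outlying cluster when
  the MAD is small, which would corrupt the argmax). If s = 0 the discrete
  weighted mode is returned (ties → smallest ratio).
- OR reporting: exp(β) with exp(β ± z·se). At the conventional 95% level
  the multiplier is the fixed value 1.96 used throughout standard MR
  reporting; other levels use the exact normal quantile, and the
  multiplier can be overridden.
- Cochran's Q uses ratio weights β_x²/se_out² around the fixed-effects
  IVW estimate (where Q is minimal); I² = max(0, (Q−df)/Q)·100 by default.
  An alternative convention, 100·df/Q when Q > df, is available behind
  `i2_convention="paper"` to reproduce tables published under it; it is
  not the default because the standard definition is the interpretable
  one.
- Steiger: per-SNP variance explained recovered from the Wald z,
  r² = z²/(z²+n−2), summed over instruments per trait; direction is
  correct when the exposure sum strictly exceeds the outcome sum, and the
  p-value is a two-sample Fisher-z comparison of the implied correlations
  at the two sample sizes. Liability-scale refinements for binary traits
  are out of scope. Note the z-based r² has a noise floor: under no signal
  E[z²] = 1, so the outcome r² cannot average below ≈ nsnp/n.
- MVMR-IVW: weighted multivariable regression without intercept,
  w = 1/se_out²; coefficient covariance from the weighted normal equations
  with residual inflation floored at 1 (this reduces exactly to
  random-effects IVW when there is a single exposure). The instrument set
  is the union of the exposures' selected instruments, restricted to SNPs
  present in every exposure's full summary statistics and the outcome,
  harmonized pairwise to the first exposure. No re-clumping across the
  union by default, preserving each exposure's selected set.
- Mediation: point estimates by the product-of-coefficients algebra
  above; indirect se by the delta method √(α²se₂² + β2²se_α²); the
  proportion's interval propagates the ratio treating numerator and
  denominator as independent (two-sample setting), and a seeded
  parametric bootstrap is available instead. Proportions outside [0,100]%
  are reported verbatim with a warning, never clamped — inconsistent
  signs legitimately produce them. A sign-consistency flag (indirect vs
  direct) is reported, not asserted. Decomposition is only interpreted
  (gated) when the total effect and the exposure→mediator effect are both
  significant at the working level (default .05).
- The screening policy reports random-effects IVW as the primary estimate
  (it equals fixed-effects when heterogeneity is absent), flags traits
  whose Egger intercept is significant so the Egger slope can be preferred
  there, and applies no multiple-testing correction by default (raw
  p < .05 across taxa); Benjamini–Hochberg is available behind a flag.

## Synthetic study conditions

The generator emulates the summary-level statistical structure the
analysis assumes. Per SNP j: γ_j ~ N(0, gamma_sd²) is the exposure
effect; the mediator adds an independent genetic component
δ_j ~ N(0, med_gamma_sd²) (required for MVMR identifiability — without it
the mediator column is a multiple of the exposure column); the outcome
effect is β1·γ_j + β2·(α·γ_j + δ_j) plus, for the invalid fraction, a
pleiotropic term (balanced: mean zero; directional: nonzero mean) oriented
to the exposure-increasing allele — the scale on which the Egger intercept
is defined. Standard errors follow 1/√(2·n·maf·(1−maf)); observed betas
add N(0, se²) noise; p-values are two-sided Wald; allele pairs include a
configurable palindromic fraction; an optional block-diagonal LD matrix is
emitted with SNPs of a block placed adjacently.

Default sample sizes mirror the motivating study: exposure n = 18,340 (a
16S microbiome GWAS); outcome and mediator are FinnGen-style binary traits
entered as effective sample sizes, 4/(1/ncase + 1/nctrl): ≈ 160,845 for
constipation (44,590 cases / 409,143 controls) and 16,700 for a Parkinson
trait of a few thousand cases. Default gamma_sd = 0.04 puts the p < 1e-5
screen at roughly 8–12 instruments per trait with F ≈ 19–30, the regime
the real taxa show. Default chain truth is α = 0.4, β2 = 0.3, β1 = 0.08
(total 0.2, proportion mediated 60%).

Named presets fix the conditions used by the validation studies:

- `null_config` — all causal effects zero (instruments still predict the
  exposure): IVW type-I error.
- `balanced_pleiotropy_null_config` — zero-mean pleiotropy on every
  instrument with InSIDE intact: Egger-intercept type-I error.
- `strong_chain_config` — the chain truth with strong instruments
  (gamma_sd = 0.15): interval coverage and mediation recovery. Strong
  instruments are used here deliberately so these checks measure the
  estimators rather than weak-instrument/winner's-curse attenuation,
  which is a known, separate phenomenon at threshold-grazing instrument
  strength.
- `paper_scale_effect_config` — a small total effect (0.03) at
  study-scale strength with a weak mediator→outcome path, reproducing the
  real screen's variance-explained pattern (exposure r² ~ 1e-2, outcome
  r² orders of magnitude smaller, near the z² noise floor).

The mediation-recovery study averages the proportions of replicates that
pass the significance gate — exactly the set of models the pipeline
interprets. The ungated per-replicate proportion is a ratio whose
denominator occasionally lands near zero, and its heavy tails make the
ungated mean a poor summary of what the method reports.

What the generator does *not* emulate: real LD from reference panels,
taxon-abundance distributions and their transformation, sample overlap
between GWAS, population stratification, and liability-scale subtleties of
binary traits (effects are drawn directly on the log-odds scale). Passing
tests therefore demonstrate correctness of the estimators and workflow
under the stated statistical model, not robustness to those features of
real data.

## Numerical choices and degenerate inputs

Weighted regressions are solved by normal equations (designs are tiny);
rank deficiency or condition numbers above 1e12 abort with "collinear".
The Egger fit refuses designs whose oriented exposure effects are
constant. Bootstrap standard errors are floored at the smallest positive
float to preserve the se > 0 invariant. The mediation identity
direct + indirect = total is asserted on every call to within 4 ulp.
Zero total effect yields a missing proportion with a warning rather than
an error. Simulated p-values are floored at the smallest positive float.
Files are written with fixed formatting so identical seeds produce
byte-identical outputs.

## Problem sizes

Validation runs use 60-SNP panels per replicate with 500 replicates for
rejection/coverage rates and 300 for mediation and directionality — sizes
chosen so the whole validation suite completes in seconds while leaving
Monte-Carlo error well inside the tolerance bands (rate se ≈ 0.01 at 500
replicates; proportion se ≈ 0.4 pp at ~250 gated replicates).

## Known limitations

- Distance-only clumping (no LD matrix) over-prunes dense loci and keeps
  only the lead signal per window.
- No MR-PRESSO/robust IVW/contamination-mixture estimators, no MVMR-Egger,
  no conditional F-statistics, no multi-mediator decomposition.
- The Steiger r² from z-statistics ignores case-control ascertainment;
  with very unbalanced designs the implied correlations are approximate.
- Two-sample independence is assumed throughout (no overlap correction).
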