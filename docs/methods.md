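# Methods

## Structural model and estimands

The package targets the standard two-sample MR mediation setting: an
exposure `X` instrumented by variants `G_i` with per-allele effects `γ_i`,
mediators `M_k = α_k X + Σ_i δ_ik G_i + e_k`, and an outcome
`Y = θ_dir X + Σ_k β_k M_k + Σ_i p_i G_i + e_y`. Univariable MR with
exposure instruments estimates the total effect
`θ_total = θ_dir + Σ_k α_k β_k`; multivariable MR conditioning on the
mediators estimates the direct effect `θ_dir`; the proportion mediated is
the difference-method statistic `PM = 1 − θ_dir/θ_total`. For binary
traits every quantity lives on the log-odds scale, where total and direct
effects are linear in the summary estimates; odds ratios are derived for
reporting only, and PM is always a ratio of log-odds (or gram) effects,
never of ORs.

The `δ_ik` term — mediator-specific variant effects — deserves emphasis.
Without it, every variant–mediator association is exactly proportional to
the variant–exposure association, the multivariable design matrix is
singular in truth, and the direct effect is unidentified. Real mediators
(BMI, lipids, blood pressure) have their own genome-wide-significant loci,
which is precisely what makes multivariable MR work; the generator therefore
includes mediator-specific effects by default. In the univariable analysis
these same effects act as balanced horizontal pleiotropy: they inflate
Cochran's Q (absorbed by the multiplicative random-effects SE) without
biasing the total effect, because they are independent of `γ`.

## Synthetic summary statistics

Simulation happens at the summary level: each trait's estimated per-variant
effect is the true marginal effect plus `Normal(0, SE)` noise with an
independent stream per trait (the two-sample, non-overlapping-cohorts
design), and the SE in closed form —
`σ/√(2 n f(1−f))` for a continuous trait with SD `σ`, and
`1/√(2 n c(1−c) f(1−f))` for a case-control trait with case fraction `c`
analysed on the log-odds scale. Binary traits are simulated directly on the
log-odds scale rather than through a liability threshold so the ground
truth is exact on the analysis scale. A small-n individual-level mode
(binomial genotypes, traits built from the structural equations,
per-variant OLS/logistic fits) exists purely to validate those closed
forms, and the test suite does so.

Instrument strengths are parameterized by the per-variant F statistic at a
reference exposure-GWAS size of 3,037,499 (a large educational-attainment
GWAS): `F ~ F_min + Exponential(F_mean − F_min)` with defaults
`F_min = 28`, `F_mean = 57`, chosen to reproduce the instrument-strength
profile such a study reports (minimum F ≈ 28, median ≈ 49; with ~4000
variants, ≈7.5% of exposure variance). Effect alleles are defined as the
exposure-increasing allele (`γ ≥ 0`), which is how published instrument
lists are oriented; allele pairs are drawn with a configurable palindromic
fraction (default 0.15), and files can be written with per-variant
allele-swap and strand-complement corruption to exercise harmonization.
Pleiotropy is `p_i ~ Normal(pleio_mean, pleio_sd)` independent of `γ`
(InSIDE holds), optionally confined to a random `invalid_fraction` of
variants; `pleio_mean = 0` is balanced, `≠ 0` directional.

The built-in multi-outcome demo study emulates the scale of a large
education → pregnancy-outcomes analysis: five mediators (one binary, on
log-odds; four continuous, in SD units) with their own genetics, five
case-control outcomes at 141k–233k samples with realistic case fractions,
and one continuous outcome in grams (SD 500, n = 270k). Outcome blocks
state the true total effect and proportion mediated; mediator→outcome
coefficients are solved so those targets hold exactly, including a
birth-weight configuration whose mediators act in competing directions with
zero net mediation.

What the generator does **not** emulate: LD between the *estimates* (noise
is independent per variant; the block reference matrix exists to exercise
pruning, not to correlate errors), sample overlap between exposure and
outcome GWAS, allele-frequency differences between cohorts, population
stratification, and non-collapsibility of odds ratios. Passing tests
therefore demonstrate estimator correctness under the stated sampling
model, not robustness to those real-data complications.

## Estimators and numerical choices

* Wald-ratio SEs are first order (`se_y/|β̂_x|`), ignoring exposure-side
  noise; a second-order option exists. This is accurate for strongly
  instrumented designs — the neglected term biases ratio estimators by
  O(1/F) per variant, so at the median-strength profile (mean F ≈ 57) a
  ≈2% attenuation of MR estimates is expected and visible in large
  replicate studies, while at the strong end of the realistic range
  (F of a few hundred, used by the recovery simulations in the test suite)
  it is below Monte-Carlo resolution.
* IVW/Egger/MVMR SEs use multiplicative random effects by default:
  the fixed-effect SE scaled by `√max(1, Q/df)` (df = L−1, L−2, L−K−1).
  Fixed effects are available by flag. CIs are normal approximations at
  ±1.96 SE throughout, matching two-sided tests at P < .05.
* MR-Egger first orients all variants to non-negative exposure effects, so
  results are invariant to arbitrary allele orientation.
* Weighted median: ratios ordered, cumulative-weight midpoints
  `(S_i − w_i/2)/S`, linear interpolation at 0.5; weights `(β̂_x/se_y)²`.
* Weighted mode: argmax over a 1024-point grid of the weight-scaled
  Gaussian-kernel density of the ratios; bandwidth =
  `bandwidth_factor × 1.4826·MAD` (falling back to the SD when the MAD
  degenerates because a majority of ratios tie); identical ratios short-
  circuit to the common value.
* Weighted median/mode SEs come from a seeded parametric bootstrap of the
  summary estimates (default 1000 replicates).
* Greedy LD pruning: candidates below the p-threshold ranked by p-value
  (ties broken lexicographically by variant id for determinism); keep the
  best remaining, discard everything with r² ≥ threshold against any kept
  variant. Pairs absent from the reference matrix count as independent,
  with a logged warning.
* MVMR guards: a rank-deficient variant-effect matrix (e.g. a mediator with
  identically zero associations) and L ≤ K+1 are hard errors; a
  per-trait minimum marginal F accompanies results as a descriptive
  instrument-strength note.
* PM is undefined (NaN, with a warning) when |θ_total| falls below a floor
  (default 1e-6); bootstrap replicates below the floor are dropped and
  counted, and the CI is flagged unstable when more than 10% drop.

## Harmonization policy

All traits are oriented to the exposure's effect allele. Non-palindromic
variants are resolved from the allele letters (swap → negate beta and
mirror the frequency; strand complement → relabel; both → negate);
incompatible allele pairs are dropped, never silently retained, as are
variants missing from any trait. Palindromic variants (A/T, G/C) cannot be
resolved from letters, so orientation is inferred from the effect-allele
frequency: retained only when both traits' frequencies are outside
[0.42, 0.58], kept as-is when they fall on the same side of 0.5 and
sign-flipped when on opposite sides. The frequency window is a common
convention and configurable. Two stricter policies are available:
`same-side` (retain only frequency-concordant variants, never infer a
flip) and `drop-all`. Frequency inference is the default because it makes
the pipeline exactly invariant to how variants happen to be written on
disk — an allele-swapped palindromic row moves its frequency to the other
side of 0.5, and a policy that cannot flip would drop it, changing the
instrument set; the test suite asserts this invariance to 1e-12 through
written files. The trade-off, documented rather than hidden: inference
assumes both GWAS draw from similar allele-frequency distributions, and a
drop-all policy is safer when they do not.

## Bootstrap for the proportion mediated

Per replicate the IVW total and MVMR direct effects are re-fitted on the
same harmonized dataset and PM recomputed; the point estimate always comes
from the original data, the SE is the replicate SD, the CI the 2.5/97.5
percentiles; everything is seeded. The default resampling unit is the
**variant** (instruments drawn with replacement). The alternative
parametric scheme — redraw every harmonized beta from
`Normal(estimate, SE)` — propagates only the nominal GWAS sampling noise,
and when per-variant outcome associations are overdispersed relative to
their SEs (exactly what mediator-specific genetics produce) it understates
the spread of the total effect and undercovers badly; in the package's own
calibration simulations variant resampling attains ≈95–97% coverage of the
true PM where the parametric scheme falls below 70%. Variant resampling is
therefore the default, with `mode="parametric"` retained for homogeneous
panels.

For multivariable models the default instrument set is the union of each
trait's genome-wide-significant, LD-pruned variants (ranked by the best
p-value across traits and pruned as a single set); `exposure`-only
instruments are available by config. The union is the default because
conditional identification of the mediator coefficients comes from
mediator-specific loci, which exposure-only selection discards.

## Recovery-simulation design choices

The test suite's recovery studies fix the instrument panel to the
generator's known instruments rather than re-discovering them at p < 5e-8
inside each replicate. Threshold re-discovery conditions on noisy exposure
estimates and adds winner's-curse attenuation — a property of instrument
discovery, not of the estimators under test; it is exercised separately
(selection correctness against a literal re-implementation, type-I-error
calibration through the full selection pipeline, and the demo study, whose
headline estimates carry the expected few-percent attenuation). Replicate
counts and problem sizes (200–1000 replicates of 300–500-variant studies;
500 datasets with 1000 bootstrap replicates for PM coverage) were chosen so
every Monte-Carlo SE is several times smaller than the effects being
checked while the whole suite runs in a few minutes on one CPU.

## Known limitations

First-order Wald weighting makes all estimators attenuate by O(1/F̄); no
weak-instrument-robust or winner's-curse-corrected variants are provided.
No conditional F statistics (beyond the descriptive minimum), no
MR-PRESSO/Steiger-style outlier filtering, no correlated (InSIDE-violating)
pleiotropy estimation — correlated pleiotropy can be *generated* only via
custom per-variant configuration, and none of the estimators is consistent
under it except the weighted median/mode within their breakdown limits.
Proxy-variant lookup, multi-allelic variants, indels and build liftover are
out of scope; variants missing from any trait are simply dropped.
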