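# Methods

## Model and estimators

mrscan estimates the causal effect of an exposure on an outcome from
two independent sets of GWAS summary statistics under the instrumental
variable assumptions: each instrument is (1) associated with the
exposure, (2) independent of confounders of the exposure–outcome
relationship, and (3) affects the outcome only through the exposure.
Assumption 1 is enforced by the p ≤ 5e-8 selection and the F-statistic
diagnostic; assumptions 2–3 cannot be verified from summary data and
are mitigated by the outcome-association exclusion (p ≤ 5e-5 removed)
and the cross-trait pleiotropy screen.

Per-instrument Wald ratios use first-order delta-method standard
errors, `s_j = se_out_j / |beta_exp_j|`, ignoring exposure-side
uncertainty — the standard two-sample convention, adequate when
instruments are strong (F ≫ 20); second-order weights are out of scope.
The IVW point estimate is the inverse-variance weighted mean of the
ratios, equivalently a weighted least-squares regression of outcome on
exposure betas through the origin. The multiplicative random-effects
variant keeps the fixed-effects point estimate and multiplies the
standard error by `sqrt(Q/(k−1))`, floored at 1: heterogeneity can only
widen the interval, never narrow it. Under homogeneous instruments the
floor makes the random-effects interval conservative (coverage above
the nominal 95%, about 97% in our simulations) while the plain IVW
interval is calibrated (about 95%); that conservatism is the intended
behaviour of the multiplicative model, not an error. p-values are
two-sided normal with no small-sample t correction (GWAS sample sizes);
the 95% CI uses z = 1.959964 internally and reported tables round to
3 decimals.

Model selection by instrument count — k = 1 Wald ratio, k = 2
fixed-effects IVW, k ≥ 3 multiplicative random-effects IVW — follows
the convention that heterogeneity is only estimable with enough
instruments. The k = 3 boundary is configurable (`random_min_k`).

## Instrument selection

Clumping is greedy: take the smallest-p remaining SNP as an index,
remove every remaining SNP on the same chromosome within 100 kb of it
*or* in LD with it at r² > 0.001, repeat. Ties in p break by genomic
coordinate, making the output deterministic. Both removal rules apply
jointly, matching standard clumping semantics. The retained set
therefore contains no pair that is simultaneously close and correlated,
verified exhaustively against an independent reference implementation
on small instances.

Per-SNP explained variance uses `r² = 2·eaf·(1−eaf)·beta²`
(standardized-trait approximation) with the fallback
`r² = z²/(z²+n−2)` when eaf is missing; summed r² enters
`F = R²(n−1−k)/((1−R²)k)`. F ≤ 20 is a reported flag, not a hard
filter, since weak-but-valid instruments still carry information.

The outcome-association exclusion deserves a caution: when the
exposure genuinely affects the outcome, instruments with the largest
exposure effects also carry the strongest outcome signal, so removing
outcome-associated SNPs preferentially deletes the best instruments
and biases the pooled estimate toward the null (in our simulations at
true beta = 0.2 it shifts the mean estimate by about −0.02 and drops
CI coverage to ~89%). The filter is kept in the scan pipeline as
specified, but the estimator-calibration checks bypass it, and users
screening strong effects should consider raising or disabling
`p_outcome_exclude`.

The cross-trait screen drops SNPs genome-wide significant in ≥ 5 of
the other exposure datasets in the run; with no other exposures it is
the identity.

## Harmonization

Outcome records are re-expressed on the exposure's effect allele:
swapped allele labels flip the outcome beta's sign (and eaf),
complementary alleles are treated as opposite-strand reports, and both
together flip sign as well. Palindromic SNPs (A/T, C/G) are resolved
by allele frequency: both studies must report eaf outside the
ambiguity band 0.42–0.58 (half-width configurable), concordant
frequencies confirm the strand, discordant ones imply one extra flip;
anything else is dropped as `palindromic_ambiguous`, and a strict mode
drops all palindromes. Indels and multi-allelic records are dropped as
`non_snp`; instruments absent from the outcome as `missing_in_outcome`.
Every instrument appears exactly once in the audit, kept or with a
drop reason.

## Synthetic data

The simulator emulates two-sample summary statistics directly at the
summary level. Per locus, one index SNP receives a true exposure effect
γ ~ N(0, gamma_sd²) (for the causal fraction of loci); the other SNPs
in the locus inherit the attenuated marginal effect ρ·γ under an
exchangeable within-locus correlation ρ — the same ρ fills the locus's
LD matrix, keeping clumping behaviour analytically transparent. The
true outcome effect is Γ = causal_beta·γ + α, with α a direct
(pleiotropic) effect drawn for a configurable fraction of loci.
Observed betas are Normal(truth, se²) with
`se = 1/sqrt(2·n·maf·(1−maf))`, the standardized-trait GWAS standard
error; two-sided p-values follow from the normal z. Binary outcomes
are approximated on the log-odds scale with the same machinery.
Generation is a pure function of the seed: one substream per locus is
spawned deterministically, so adding loci never perturbs earlier ones.

Defaults model a well-powered design: 50 single-SNP loci, both samples
at n = 100 000, causal_beta = 0.2, gamma_sd = 0.05, maf uniform on
(0.05, 0.5), no pleiotropy. With these values roughly half the loci
pass genome-wide selection (expected per-SNP F ≈ z² well above 20).
Default allele pairs are non-palindromic so harmonization is exercised
separately from frequency-based palindrome inference (a `palindromic`
switch enables the stress case).

What the simulator does *not* model: individual-level genotypes and
case-control ascertainment, realistic human LD maps (exchangeable
blocks only), allele-frequency differences between the two studies,
sample overlap between exposure and outcome GWAS, and winner's-curse
correction. Passing tests therefore demonstrate the statistical
machinery is correct under the stated generative model, not that real
GWAS pairs satisfy the IV assumptions.

## Numerical choices and edge cases

- p-values printed as 0 are clamped to the smallest positive double and
  flagged rather than rejected; computed p-values are clamped into
  (0, 1].
- Duplicate records at one (chrom, pos) keep the lowest p, logged.
- All p-threshold comparisons are inclusive (≤).
- An instrument with beta_exp = 0 raises a degenerate-instrument error
  rather than producing an infinite ratio.
- Pairs with zero surviving instruments yield a `no_instruments` row;
  unreadable datasets fail only their own pairs, and the CLI exits 2 on
  partial failure.
- Scan results are written with `%.6g` formatting; summary tables are
  written with full `repr` precision so write→read round-trips exactly.

## Problem sizes

Monte Carlo checks use 200 replicates for bias and 500 for coverage
and null calibration of the 50-instrument design (a few seconds each);
clumping correctness enumerates 48 small instances of up to 8 SNPs
against the brute-force reference. These sizes give Monte Carlo
standard errors well inside the asserted bands (e.g. ±1% on a 95%
coverage proportion at 500 replicates).

## Known limitations

- No MR-Egger, weighted median/mode, MR-PRESSO, Steiger or
  leave-one-out sensitivity analyses; the scan reports IVW-family
  estimates only.
- No proxy-SNP lookup for instruments missing in the outcome, and no
  LD computation from reference panels — LD is supplied by the caller
  (pairwise r² table or the simulator's exchangeable blocks).
- Binary-trait effects are treated as log-odds throughout; the
  continuous/binary distinction affects interpretation, not arithmetic.
- Nominal p < 0.05 is the default significance rule across a scan;
  Benjamini-Hochberg q-values are available but off by default.
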