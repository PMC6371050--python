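# Methods

This note documents the statistical procedures implemented in `mateperm`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real questionnaire data.

## Data model

The unit of analysis is a long-format partner table: one row per
(respondent, partner) with a father flag, a listing ordinal, and up to 21
trait values. Traits are registered with explicit scales — e.g. eye colour
1–5 in the order gray, blue, green, brown, black; hair colour 1–9 light to
dark; TIPI Big Five domains 2–14 — and values outside a trait's scale are
load-time errors. Respondents must list at least two partners (the
inclusion rule of the cohort design this emulates). Missing cells stay
missing; a partner lacking trait X is excluded only from analyses of X,
and a respondent left with fewer than two X-values drops from X's
"informative set". Age difference is stored in months, negative when the
woman is older. TIPI domains are scored as direct item + (8 − reverse-keyed
item), range 2–14; summing rather than averaging the two items affects only
the scale constant of the personality traits, never a test decision.

## Consistency index and permutation test

Per respondent, consistency on a trait is the mean absolute difference over
all unordered partner pairs (sum of |differences| divided by
p(p−1)/2); the population index Δ̄ averages these per-respondent means with
equal weight, so a woman with ten partners counts exactly as much as one
with two. The null distribution permutes the informative partners' trait
values across all informative slots, which is equivalent to reassigning
partners to respondents at random while preserving every respondent's
partner count; each trait is permuted independently. The one-tailed p is
the fraction of null draws *strictly* below the observed Δ̄ — no +1
smoothing, so exact 0 and exact 1 can occur and are formatted as "<0.001"
and "1.000" only at the presentation layer. A zero-variance null (constant
trait) carries no evidence of consistency and returns p = 1. Default
10,000 permutations; the analysis scripts use 2,000, which resolves p to
5·10⁻⁴ and leaves all reported conclusions unchanged.

## Relocation effect size

The effect size is the percentage of partners that must switch respondents
before Δ̄ first reaches the null mean. A relocation step is a swap of two
partners between different respondents — the only single move that
preserves partner counts — and counts as two relocated partners; the
balanced two-colour toy (every respondent two same-coloured partners,
colours split 50/50) fixes this counting: its Δ̄-maximal configuration is
reached by exactly N/2 swaps of its 2N partners, i.e. 50%.

Candidate swaps are drawn uniformly at random, but a candidate is kept
**only if it strictly raises Δ̄** and is reverted otherwise; only kept
swaps count. This elevate-only rule is forced by the measure's own 0–50%
range: an unconditional random walk approaches the null mean only in the
limit of near-total randomization (its expected Δ̄ relaxes asymptotically
to the null mean from below), and empirically needs well over 100%
relocations on strongly clustered cohorts, which would break both the
bound and the magnitudes the measure is meant to produce. When the
observed Δ̄ already sits at or above the target the run returns exactly 0.
Runs are repeated (default 10,000; tests and analysis scripts use 30–200)
and summarised by the mean and the 2.5–97.5% quantile interval. Δ̄ is
updated incrementally after each swap (only the two affected respondents'
means are recomputed), which matches full recomputation to float precision.

## Shared and cumulative effects

For a trait pair (A, B) the analysis restricts to pairwise-complete
partners (both traits present, respondents with ≥ 2 such partners). Each
directed run randomizes the configuration by whole-partner swaps until
Δ̄(A) reaches its null mean on that subset, then continues against B's null
mean; the second leg's relocation percentage is the residual effect
resid(B|A) (default 1,000 runs per direction). Whole partners move, so both
traits travel together — this is what makes the residual meaningful. The
union of the two effects is the arithmetic mean of the two directed
estimates E_A + resid(B|A) and E_B + resid(A|B) (the defining identity
gives no combiner when the directions disagree by Monte-Carlo noise; the
mean is the symmetric choice), and the shared effect E_A + E_B − union is
clamped into [0, min(E_A, E_B)] — no negative relationship between
consistencies is modelled.

Higher-order intersections are not resampled. For a third trait C against
the union of A and B, the segments (A∩C)¬B, (B∩C)¬A and A∩B∩C are assumed
proportional to the union's own segments A¬B : B¬A : A∩B and scaled so
that their sum, counting A∩B∩C twice, equals shared(A,C) + shared(B,C).
This apportionment generalizes to a running union of any size in closed
form: tracking the union's full region decomposition collapses to two
scalars — the running total W and the sum M of included simple effects —
with overlap(C | union) = (Σ_X shared(X,C) / M) · W. The test suite
verifies this identity against an explicit region-list implementation.

Accumulation starts from the largest simple effect and repeatedly adds the
trait with the largest unique contribution (simple effect minus overlap
with the running union, floored at 0; ties broken by trait name). A
candidate's contribution computed at any step caps its contribution at all
later steps: an apparent *growth* in unique contribution as the union
expands can only reflect apportionment error, so the minimum over steps is
the safe estimate. The maximal cumulative effect size is the sum of the
included contributions; it is bounded below by the largest simple effect
and above by the sum of simple effects. On the bundled 21-trait reference
table this yields 49.31%. A fixed inclusion order can be supplied instead
of the greedy selection; with the order (A, B, C) the three-variable
illustration (simple 20/15/10%, shared 10/4/3%) reproduces the exact
segments 2/1/2%, unique contribution 5% and total 30%, while the greedy
rule itself prefers C (unique 6%) over B (5%) after A and totals 29.73% —
the greedy order and the fixed-order total cannot both hold on this input.

## Correlational measures and equivalence

The respondent-attributable variance share is estimated by a
random-intercept linear mixed model (respondent identity the sole random
factor, REML) as 100·var(respondent)/(var(respondent) + var(residual)),
with benchmarks 10/20/30% for meaningful/medium/large consistency;
singular fits return the boundary 0. The double-entry pairwise r enters
every unordered within-respondent partner pair in both orientations,
making the coefficient symmetric by construction; respondents with more
partners contribute more pairs, deliberately unreweighted. Double entry is
the only orientation-free choice; a single-entry variant would depend on
arbitrary partner ordering. Cross-measure equivalence is summarised by the
three pairwise Pearson correlations across traits and the OLS fit of ICC%
on relocation% with 95% CIs. Partner-level correlations between all 210
trait pairs use pairwise-complete partners, two-sided p-values, and
Benjamini–Hochberg adjustment applied jointly across the 210 pairs
(contrast: the per-trait p-vectors of the main analyses are adjusted
separately per 21-trait family).

## Father contrasts

The exclusion test removes all father-flagged partners and recomputes Δ̄
over respondents still holding ≥ 2 informative partners; the change
(restricted − full) is compared against permutations that relabel, within
every respondent's informative set, the same number of partners as fathers
uniformly at random and apply the identical restriction rule, keeping
observed and null comparable. The two-tailed p doubles the smaller tail
(fraction ≤ and fraction ≥ the observed change), capped at 1. A change
below expectation means fathers are exceptional within their sets; above,
especially typical. Mean contrasts fit trait ~ father-indicator with a
random respondent intercept (REML); variance contrasts fit the same model
to |value − its father/non-father group mean| (Levene's idea in
mixed-model form). Group means are global per group, not per respondent:
the contrast concerns the father/non-father grouping, and within-respondent
centring would conflate it with the consistency structure itself.
Inestimable traits (constant values, single-group data) are reported as
missing rather than fabricated, and sit out the BH adjustment.

## Synthetic cohorts

The generator emulates the shape of a questionnaire cohort of mothers:
537 respondents by default; partner counts on {2..10} from a discretized
normal whose underlying (μ, σ) are calibrated so the *realized* law has
mean 2.98 and SD 1.32 (naive truncation of N(2.98, 1.32) would inflate the
mean to ~3.3; the calibrated law is decreasing with median 3). Trait
values are midpoint + u_i + e_ij with Gaussian respondent effects and
partner noise mixed to the configured ICC; the marginal SD defaults to
one sixth of the trait's scale range. Partner-level noise can be
correlated across traits through a supplied PSD matrix. Each respondent's
last-listed partner is flagged as the father (configurable extra fathers),
with optional mean shift and SD ratio applied to father rows. Ordinal
traits are rounded then clipped to their scale; rounding and clipping
attenuate the realized ICC slightly (immaterial at the default SDs — the
recovery tests bound the bias well under the ±5-point criterion).
Missingness is completely at random per cell, default 5%.

What passing tests on these cohorts show: correct calibration of both
permutation tests under the null, power under clustering, and unbiased
recovery of ICC and father effects *under the generative model*. What they
do not show: robustness to informative missingness (women skipping items
they remember poorly), memory or social-desirability bias in retrospective
partner ratings, fashion-driven secular trends in traits such as
beardedness, or ordinal measurement distortions beyond rounding — all of
which exist in real questionnaire data.

## Numerical choices and limitations

* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage and per-run seeds from one master seed via seed
  sequences, so a fixed (input, config, seed) reproduces outputs
  byte-for-byte.
* Permutation nulls are vectorised (value matrix × pair-index reduceat) and
  chunked at 2,000 permutations to bound memory.
* The elevate-only swap search raises an error if the target Δ̄ is not
  reached within a generous proposal budget (degenerate targets above the
  achievable maximum); targets taken from permutation-null means are
  always reachable in practice.
* Analysis-script scales (2,000 permutations, 200 effect runs, 50 residual
  runs per direction on a six-trait subset) are the package's own choice of
  resolution for the simulated re-analysis; all defaults remain at the
  full 10,000/10,000/1,000.
* The greedy accumulation order is a heuristic; only the cumulative total
  is designed to be stable under apportionment error (the min-rule
  redistributes, not removes, contributions). Reported per-trait unique
  contributions should be read with that caveat.
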