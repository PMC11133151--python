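# Methods

## The estimand and the base cleaning

The quantity of interest is the group-level Stroop interference effect: the
arithmetic mean over participants of per-participant interference scores,
where a score is the centre (mean, or median for the no-exclusion/median
pipeline) of alcohol-trial RTs minus the centre of neutral-trial RTs, in
milliseconds. Inference per pipeline is the one-sample t test of the scores
against zero, with the t-based 95% CI — equivalent to a paired t test on the
condition means.

Every pipeline starts from the same cleaned base dataset, built once:

1. practice-phase trials are dropped;
2. RTs from incorrect trials are excluded from every RT computation (means,
   SDs, medians, MADs, cutoff screens for trial removal), surviving only as
   error counts;
3. a trial that hit the 3000-ms response window is an error with no recorded
   RT; it contributes to error denominators but to no RT statistic;
4. error rates use all critical trials (correct + incorrect + timed out) as
   the denominator;
5. the fast-guess participant screen ("> 25% of RTs < 200 ms") operates on
   all critical trials with a recorded RT regardless of correctness, because
   fast guesses are usually errors and a correct-only screen would
   under-detect them.

Participants left without a correct RT in one or both conditions are
retained in the base but flagged; estimation drops them pairwise and the
removal bookkeeping records it.

## The registry of 27 specifications

Six categories, 2 + 6 + 8 + 7 + 2 + 2 = 27 rules, each applied in isolation
(never chained). Conventions that the individual rules share:

* **Strict comparisons.** "remove RTs > 2000 ms" keeps a 2000-ms trial.
* **Pooled per-participant statistics.** SD- and MAD-based trial rules
  compute the participant's centre and spread on alcohol and neutral RTs
  pooled into one distribution, in a single pass (no iterative
  re-estimation after removal). This mirrors how these rules are used in
  practice, and it is exactly why they interact with a true condition
  shift: if alcohol RTs really are slower, a pooled upper bound clips more
  of the alcohol distribution than the neutral one.
* **Sample SD** (n−1 denominator); **MAD** with the normal-consistency
  factor 1.4826.
* **Degenerate dispersion removes nothing.** If a participant's SD or MAD
  is 0, or a sample-level screening SD is 0, the bounds collapse onto the
  centre; rather than deleting everything, the rule is treated as vacuous.
  Emitted once per affected participant in the removal log.
* **Winsorizing is single-pass**: the bound is computed on the original
  pooled RTs, then out-of-bound values are substituted (participant mean,
  or mean + k·SD); trial counts are conserved.
* **Participant screens** are upper-tail ("more errors / slower than the
  sample") except the interference screen, which is two-sided (± 4 SD).
  The "mean RT > k SD" screens compare participant mean RTs with the mean
  and SD of those participant means.
* **Trimmed means** act at participant level: scores sorted, floor(n ·
  proportion / 2) participants removed from each tail (the proportion is
  the total trimmed fraction), ordinary mean/CI/t on the remainder. With
  n = 10 and 10% trimming, floor(10 · 0.05) = 0 — nobody is removed; the
  floor rule is symmetric by construction and never trims one tail only.
  The retained scores enter the ordinary t machinery (no Yuen-style
  adjusted standard error): trimming is modelled as participant removal,
  which is the simplest reading of a participant-level trim and keeps all
  27 pipelines on one inferential footing. A Yuen variant would widen the
  trimmed pipelines' CIs; the point estimates would not move.

Dispatch is pure in (base dataset, specification): registry order, or
running other specifications first, cannot change any result.

## Variance decomposition

The category ICC treats the 27 estimates as an unbalanced one-way layout
grouped by decision category and uses the method-of-moments ANOVA
estimator: ICC = σ²_between / (σ²_between + σ²_within) with σ²_within =
MSW, σ²_between = (MSB − MSW)/n0 truncated at zero, and n0 = (N −
Σn_i²/N)/(k − 1). Method-of-moments is deterministic, closed-form, and is
the variance-partition definition itself; REML would differ only slightly
at 27 observations and is left to external cross-checks. When every
estimate is identical the ICC is reported as 0 (there is no variance to
partition). Ranking ties in the curve are broken lexicographically by
spec id so figures and tables are reproducible.

## Stability correlations

Per non-reference pipeline, the Pearson correlation between its
per-participant interference scores and those of the no-exclusion (median)
reference, with pairwise-complete deletion per comparison (participants
missing under either pipeline are dropped for that comparison only, never
listwise across all 26). Fewer than 3 complete pairs, or a zero-variance
margin, flags the correlation as undefined rather than fabricating a
value. The outcome multiverse replaces the reference scores with a
participant covariate (craving by default). Pearson rather than rank
correlation: the interference score is the quantity of applied interest on
its own scale, and the r-distribution summary (mean, SD, histogram) is the
standard way these agreement analyses are reported.

## Power solver

`required_sample_size(dz, alpha, power, tails)` returns the smallest
integer n at which the paired/one-sample t test achieves the target power,
computed exactly from the noncentral t distribution (noncentrality dz·√n,
df n−1) with integer bisection. `tails` is always explicit. The solver
floors at n = 2 (df ≥ 1); note that at df = 1 the t tails are so heavy
that even dz = 3 still needs n = 4 — the floor binds only for enormous
effects.

## The synthetic-data generator

What it emulates: per-participant ex-Gaussian RTs (Normal(μ_i +
alcohol·δ_i, σ) + Exp(τ)) with random location μ_i ~ N(μ_base, σ_μ) and
random shift δ_i ~ N(δ, σ_δ); fast-guess (U(100, 250) ms) and lapse
(U(1500, 3000) ms) contaminants; an RT-independent trial error process;
the 3000-ms timeout coded as an incorrect, RT-less trial; both task
layouts (mobile: 66 critical trials in two randomized single-condition
blocks, three colours, no recorded practice; web: 24 practice trials then
168 fully randomized critical trials, four colours); and a craving
covariate coupled to δ_i through a Gaussian-copula-style mix with target
correlation r_craving, rescaled to [0, 100]. Lapses can be concentrated in
the slower condition via `lapse_bias` (share of the lapse probability on
alcohol trials; 0.5 = symmetric) — attention captured by alcohol words is
a condition-dependent process, and the asymmetric setting is what makes
SD-based removal systematically shrink the estimate, the directional
pattern the stricter pipelines show.

Defaults (ms): μ_base 650, σ_μ 80, σ 100, τ 200, δ 25, σ_δ 30, p_fast
0.02, p_lapse 0.02, ε 0.05, r_craving 0.3. These are field-realistic
values for online/mobile colour-naming RTs (overall means ~850 ms, right
skew, a few percent contaminants); no RT distribution summaries exist for
the original datasets, so the presets are plausible defaults, not
calibrated fits. `paper_like_novel` fixes n = 156 participants (166
recruited minus 10 failing the practice gate) on the web layout with δ =
25; `paper_like_published` uses the mobile layout, n = 60, δ = 35; `null`
has no effect and no contaminants; `heavy_contamination` stresses the
filters. Identical configs (including the seed) produce byte-identical
CSVs.

What it does not emulate — and hence what passing tests do not show about
real data: word-level stimulus effects (lexical frequency, arousal,
word-specific difficulty), sequential effects (post-error slowing,
practice/fatigue drifts within a session), response-key or colour biases,
block-order carryover in the mobile design, device heterogeneity in timing
precision, and any dependence of the error process on RT or condition.
The generator shows the pipeline machinery is correct and calibrated under
a known ground truth; it cannot certify distributional claims about any
particular empirical dataset.

## Problem sizes and numerical choices

Simulation-based checks run at the web-study scale (156 participants × 192
trials). Parameter recovery averages the no-exclusion/mean estimate over
200 seeds of the clean path (contaminants disabled — symmetric
contaminants carry no condition shift and dilute the estimand by exactly
their mixing proportion, so unbiasedness is a property of the clean
generative path) and requires agreement with δ = 25 within 3 Monte-Carlo
standard errors. The directional contamination effect uses 14 seeds with
p_lapse = 0.03 and lapse_bias = 2/3 and a one-sided sign test at p < .01.
Operator implementations are cross-checked against independent
plain-Python brute-force versions on 1000 randomized multisets of ≤ 20
RTs per operator family.

Curve CSVs write floats with 17 significant digits, so an IEEE round-trip
parse recovers estimates bit-for-bit. Degenerate inference (zero-variance
scores) reports p = 1 for an all-zero score vector and p = 0 for a
constant nonzero one, with a warning, rather than propagating NaNs.

## Known limitations

* The trimmed-mean pipelines use the plain t on retained participants, not
  Yuen's adjusted test (see above); their CIs are therefore anti-
  conservative relative to the Yuen variant.
* The ICC is a point estimate with 27 observations in 6 groups; it is
  reported without a CI and is sensitive to single extreme pipelines.
* The craving coupling targets a population correlation with the *true*
  shift δ_i; measurement noise attenuates the observable correlation with
  estimated interference by roughly σ_δ / √(σ_δ² + 2(σ²+τ²)/n_trials).
* The registry is the closed set of 27 rules; user-defined additive chains
  of operators are deliberately unsupported (isolation is the design), but
  the operator functions are public for reuse.
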