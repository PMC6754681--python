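# Methods

## Scoring model

The screening statistic is an occurrence count: a categorized lexicon maps
normalized surface forms (single words, phrases, emoticons) to exactly one
of 14 categories (13 depressive-symptom categories plus first-person
pronouns), and every token of a participant's text whose normalized form is
in the lexicon adds one point to the total and to its category tally.
Three choices fix the semantics:

* **One category per surface form.** "One point per typed word" is
  ambiguous if a word could belong to several categories, so the loader
  rejects cross-category duplicates rather than double-counting or picking
  arbitrarily.
* **Occurrence counting, not unique-word counting.** Repeating a keyword
  repeats the point; EMA total scores in the hundreds over two weeks are
  only reachable under occurrence counting.
* **Exact matching on normalized tokens.** The lexicon enumerates
  derivatives, spelling variants and shortenings explicitly, so the matcher
  does no stemming or substring search. Normalization lower-cases
  (Unicode-aware), strips surrounding punctuation, keeps internal
  apostrophes, and leaves pure-symbol tokens (emoticons) intact. Phrase and
  emoticon surfaces are extracted first by greedy longest-match, left to
  right, non-overlapping — plain punctuation splitting would destroy them —
  and the remainder splits on whitespace/punctuation.

First-person-pronoun matches are included in the total by default (the
total is defined over all matched words regardless of category);
`include_pronouns=False` excludes them entirely so the
total-equals-category-sum invariant always holds.

Events are bucketed into *local calendar days* in a configurable timezone
(default UTC; the simulator stamps events at UTC+8). Window totals sum
daily totals over a closed calendar window ending at a chosen date — 7 and
14 days by convention, matching the CES-D's one-week and BDI-II's two-week
recall frames; missing days contribute zero. Participants with no text get
total 0 rather than being dropped: exclusion is a study-level decision, not
a scoring rule.

## Norms

Interpretation cut points are the 25th/50th/75th percentiles of a reference
cohort's totals under the linear-interpolation quantile definition, rounded
half-up to integers; levels are [0,q1], (q1,q2], (q2,q3], (q3,max]. The
rounding rule is a documented choice — published integer cuts imply integer
boundaries but not a quantile dialect. Reference samples smaller than 8,
all-equal, or whose rounded quartiles collapse are rejected as unnormable.
A built-in table ships the published cuts (19/38/65, max 164) so
classification works without a reference cohort; scores above the observed
maximum still classify as critical.

## Instruments

BDI-II (21 items, 0–3; bands 0–13/14–19/20–28/29–63) and SWLS (5 items,
1–7; 5–9 extreme dissatisfaction, 30–35 high satisfaction) are plain sums.
CES-D (20 items, 0–3; cutoff 16) reverse-codes the instrument's standard
positive-affect items at positions 4/8/12/16 — the source instrument names
the factor, not positions, so the standard positions are used. The Affect
Balance Scale takes 10 binary items, by file convention 5 positive-affect
then 5 negative-affect, and reports balance = positive − negative + 5
(range 0–10). Band classification accepts fractional totals (cohort means)
by comparing against the printed integer cut points with open upper bounds
(e.g. BDI-II "mild" is 14 ≤ t < 20).

## Validation statistics

Pearson r is tested two-tailed via t = r·√(n−2)/√(1−r²) with df = n−2.
Magnitude labels follow lower-inclusive/upper-exclusive bands on |r|
(negligible < 0.30 ≤ low < 0.50 ≤ moderate < 0.70 ≤ high < 0.90 ≤ very
high); effect sizes read |r| directly against 0.10/0.30/0.50 because this
validation tradition reports d numerically equal to r, and a
non-significant correlation gets no effect-size label. Constant input
vectors are rejected (undefined correlation) rather than returned as NaN.

The five pairings are fixed: CES-D with the 7-day total and BDI-II with
the 14-day total (congruent, +), ABS-negative with both windows
(convergent, +), ABS-positive and SWLS with both windows (divergent, −).
A pairing is *supported* when any of its windows shows a significant
correlation of the expected sign. Pairings with a missing instrument or
fewer than 3 complete cases are skipped with a recorded warning. The
rendered report flags significant coefficients with 0.25 ≤ |r| < 0.30 as
borderline, since conventions that label such values "medium" conflict
with the 0.30 threshold.

Bland–Altman: differences d = a − b, sample SD (ddof 1), limits of
agreement mean ± z·SD with fixed z (default 1.96), confidence intervals by
Student t with df n−1 — SE(mean) = SD/√n and SE(LoA) = SD·√(1/n +
z²/(2(n−1))). This combination of a fixed-z limit with t-based intervals,
and this LoA variance (rather than the cruder 3·SD²/n), is the one that
reproduces published interval bounds computed by standard agreement
software. Outliers are differences strictly outside the limits. The
summary-level constructor recovers SD = (LoA⁺ − LoA⁻)/(2z), keeps the
printed limits verbatim (they may be asymmetric after rounding), validates
that the mean lies inside them, and cannot recover an outlier count. A
zero-variance difference vector yields a degenerate result (limits collapse
onto the mean, no intervals) rather than an error.

## Synthetic cohorts

Each participant draws a latent severity θ ~ N(0, 1). Per day and category,
keyword counts are Poisson with mean exp(a + b·θ), optionally multiplied by
a Gamma(1/φ, φ) factor (φ = 0.3 by default) for extra overdispersion;
keywords are drawn from a built-in 35-entry demonstration lexicon covering
all 14 categories in English and Tagalog and are scattered across a
Poisson number of daily events among filler words. Questionnaire items
discretize loading·θ + N(0, σ²) noise through equal-probability normal
thresholds into each instrument's range; loadings are signed (+0.9 BDI-II
and CES-D, +0.6 ABS-negative, −0.6 ABS-positive, −0.8 SWLS), CES-D's
reverse-coded positions are stored inverted so the scorer recovers
severity, and the two ABS halves use their own signed loadings. Attrition
drops each participant's responses (never their text) independently with a
configured probability, mirroring completers-only analysis.

Defaults — 53 participants, 14 days, a = log 0.39, b = 0.75, 3 events/day,
8 filler words/event — were calibrated analytically so the 14-day total has
mean near 100 with SD comparable to the mean (the heavy between-person
dispersion this kind of free-text tallying shows), and so the five pairings
reproduce the qualitative sign structure of the validation design. No
published effect-size anchor links text rates to severity, so the defaults
do not target specific r values; under them the congruent correlations come
out higher (~0.8) than a real cohort's, because simulated text has no
topic drift, code-switching or behavioral noise.

What the simulator does *not* emulate: realistic Tagalog/Taglish text,
day-of-week or academic-calendar effects on typing, severity-dependent
dropout (available as an explicit option only), and range restriction from
recruitment. Passing tests therefore demonstrate that the pipeline
recovers planted structure — signs, monotone signal, null behavior — not
that any particular real-world correlation magnitude is expected.

## Numerical and testing notes

* Quantiles: `numpy.percentile(..., method="linear")`; rounding half-up via
  floor(x + 0.5).
* p-values: scipy's Student-t survival function; |r| = 1 maps to p = 0.
* The t-based two-sided p agrees with the exhaustive-permutation p (all 720
  orderings at n = 6) to within ~0.12, tightest for moderate |r|; the test
  suite freezes enumeration results to document the scale of agreement.
* Monotone signal recovery in the severity-text coupling b is asserted on
  *rank* correlation: the log link skews totals as b grows, which
  attenuates Pearson r (it peaks and then declines) while the monotone
  association keeps strengthening.
* The null-coupling type-I check runs 500 replicated studies (40
  participants each, reduced event/filler rates to keep the run short) and
  expects the per-correlation false-positive rate in 0.03–0.07 at
  α = 0.05, a band widened beyond binomial error because the eight tests
  within a study share score vectors.
* Seed determinism is byte-level: identical config and seed reproduce
  identical event streams, responses and reports. Attrition uses a seed
  sequence derived from the config seed so it never perturbs the base
  cohort draw.

## Known limitations

Published cohort-level correlations cannot be reproduced exactly from a
simulator (no raw data exists to replay), and two printed summary numbers
are mutually inconsistent in the source material (the mean paired
difference versus the difference of the printed means; the reference
cohort's usage-day statistics versus its total input count) — the
summary-level Bland–Altman entry point takes the printed values as given
and does not attempt to reconcile them. Matching is exact by design:
misspellings outside the lexicon's enumerated variants are missed.
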