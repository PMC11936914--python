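# Methods

This note documents the statistical procedure `emostroop` implements, the
synthetic-data model used to test it, the defaults and the design choices
that were genuinely open.

## 1. Latency preprocessing

For each participant and word the task yields (at most) two latencies, one
red and one blue presentation. The pipeline is fixed and auditable:

1. **Fast-trial filter.** Raw trials with latency strictly below `min_ms`
   (default 100 ms) are dropped as anticipatory responses. The rule reads
   "smaller than", so a trial at exactly 100 ms is kept.
2. **Colour averaging.** Surviving presentations are averaged per word:
   `(lat_red + lat_blue) / 2`. If one colour was removed by the fast filter,
   the word keeps its single observation (`n_colors_used = 1`) rather than
   being discarded — dropping it would silently shrink a participant's
   issue inventory; the condition is flagged in the output table.
3. **Slow-word filter.** Word *means* strictly above `max_ms` (default
   2000 ms) are removed as lapses. Applying the fast rule to raw trials and
   the slow rule to averaged means follows the order in which the two rules
   operate on the data ("observations" versus "average latencies"); both
   thresholds are configuration options.
4. **Within-participant z-scoring.** Word means are standardised per
   participant with the sample SD (n−1). Scope defaults to `per_section`
   (each Stroop round separately) because rounds differ in difficulty and
   fatigue; `all_sections` is available for sensitivity analysis. Groups
   need ≥ 3 words and nonzero variance; violations raise typed errors naming
   the participant.

The direction of standardisation deserves a note: the procedure description
this implements ("per word across participant") is grammatically ambiguous,
but its stated rationale — mean response latency varies a lot *between
participants* — only holds when each participant's own distribution is the
reference, so the default standardises within participant across words.

Each stage reports counts in/out (`PreprocessAudit`), so removed-outlier
totals can be audited against ground truth in simulations.

## 2. Words of interest

A word is *of interest* when its z-score is strictly above the cut-off
(default 1.5). "Above" is read strictly: a z exactly at the threshold is not
flagged. The four conventional cut-offs 0.5/1.0/1.5/2.0 are first-class and
the threshold is exposed to the practitioner, since its choice is explicitly
a clinical dial, not a statistical constant.

The **percentage of interest** of a (section, category) cell divides the
flagged count by the number of words *in the configured word list* for that
cell, not the post-filter observed words. This keeps percentages comparable
across participants with different outlier counts: a word removed by the
slow filter still counts in the denominator.

The per-participant profile ranks flagged words z-descending (ties broken by
word text so reports are bit-for-bit reproducible). The headline "issues"
count covers all flagged words of the five daily-life domains (50 words by
default); an option restricts it to related-category words only. Profiles
are produced for *every* participant, including those excluded from group
models for suspected undiagnosed ADHD — the individual report is the
instrument's purpose; the exclusion applies to inference, not to people.

## 3. Group models

* **ANOVA.** Percentage of interest ~ diagnosis × category (2 × 3), type-II
  sums of squares (each participant contributes every category, so imbalance
  exists only between diagnosis groups, where type II is conventional);
  partial η² = SS_term / (SS_term + SS_error). Run per threshold to mirror
  the sweep.
* **Moderated regression.** OLS of word-mean latency on valence, diagnosis
  (control = 0, ADHD = 1) and their product, at the word-observation level.
  Valence is the participant's *own* −3…+3 rating, consumed as a real
  number. Only rated emotion words (positive/neutral/negative) enter;
  emotion-round distraction words carry no rating-based hypothesis and are
  left out. Per-term partial η² uses t²/(t² + df_resid).
* **Logistic classifier.** Diagnosis ~ personality-related percentage + the
  five daily-life domain percentages (each domain's flagged share of its
  full 10-word inventory), optionally + screener total. Percentages are
  rescaled to 0–1 proportions before fitting, so each odds ratio is per
  full-scale change — the only scale on which odds ratios of order 10³ are
  meaningful. Reported: coefficients, odds ratios, Wald z, LR χ² against the
  intercept-only model, McFadden pseudo-R², and sensitivity / specificity /
  percent correct at classification threshold 0.5 (configurable). Perfect
  separation degrades Newton's method; the model then refits by quasi-Newton,
  warns, sets `converged=False`, and still reports metrics from the achieved
  predictions.

The fits delegate to statsmodels; the package's own contribution is the data
derivation feeding them, and independent brute-force oracles (explicit
sums-of-squares decomposition, filter-and-sort flagging, permutation nulls,
exhaustive confusion tables) cross-check every model in the test suite.

## 4. Synthetic cohort model

The study's participant data are not shareable, so testing rests on a
generator that emulates the design: seven rounds (personality, emotion, five
daily-life domains), every word shown once in red and once in blue in
pseudo-random order, per-participant valence ratings for emotion words.

Expected latency per participant *p* and word *w* (ms):

```
E[lat] = mu + baseline_p
       + related_shift · 1[ADHD, related word]
       + b_v·v + b_d·d + b_vd·v·d        (rated emotion words)
       + planted_shift · 1[planted issue word]
```

with trial noise `N(0, sigma) + Exp(tau)` — the ex-Gaussian, the standard
right-skewed reaction-time model, mean μ + τ.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| mu, sigma, tau | 500, 60, 100 ms | conventional adult colour-naming RT magnitudes (no RT summaries were reported to calibrate against) |
| baseline SD | 80 ms | typical between-subject spread, and the stated motivation for within-participant z-scoring |
| b_v, b_d, b_vd | 2.68, 20.89, −8.36 ms | the reported moderated-regression coefficients, used as generating values |
| related shift | 25 ms | a modest group-level slowing on related words, matching the direction of the reported category × diagnosis interaction |
| planted issues k | 3 per ADHD participant | the instrument's target regime of "two to five" issues |
| planted shift | 3.0 within-participant SDs (≈ 247 ms at defaults) | a personally salient topic should dominate that participant's own distribution |
| contamination | 0.2% slow (4–8 s), 0.05% fast (10–90 ms) | rare lapses/anticipations, sized to trip the outlier rules |
| rating noise SD | 0.5 | raters mostly agree with the norm within one scale point |
| screener | N(14, 3) vs N(8, 3), clipped ≥ 0 | two overlapping normals; item responses are out of scope |

The valence effect is generated from the participant's *recorded* integer
rating, not the continuous word norm, because the regression consumes the
rating and the scientific claim concerns subjective valence; this also makes
noise-free coefficient recovery exact, which the tests rely on.

Planted issues are assigned to **distinct** daily-life domains (a
related-category word per domain, cycling if k exceeds five): issues are
distinct life areas, and clustering several planted words in one 10-word
round would inflate that round's SD and mask the words from their own
z-scores. Ratings are integer-rounded and clipped to −3…+3 like the survey
instrument. A single global seed drives per-participant substreams
(`SeedSequence([seed, index])`), so enlarging a cohort never reshuffles
existing participants. Ground truth (planted words, expected latencies,
injected contamination) is emitted alongside and never consumed by the
pipeline under test.

What the generator does **not** emulate: sequential/learning and fatigue
effects, colour-naming errors, word-specific frequency/length effects,
comorbidity structure, or any distributional feature of the real cohort
beyond the assumed model. Passing tests therefore demonstrate that the
pipeline recovers what this model plants — not that the instrument is
clinically valid.

## 5. Calibration of the null flagged-word count

A structural observation, computed by the test suite and the acceptance
script rather than asserted: with *no* planted effects, the mean number of
flagged daily-life words per participant at z > 1.5 out of 50 is ≈ 4.0
under the default ex-Gaussian noise (e.g. 4.004 over 500 participants at
one seed). The Gaussian-tail intuition 50 · P(z > 1.5) ≈ 3.3 undershoots
for two opposing reasons that do not cancel: sample z-scores over n = 10
words per round compress the tail (a pure-Gaussian simulation gives ≈ 2.9),
while the ex-Gaussian's residual right skew (≈ 0.89 after averaging two
trials) fattens it more strongly. The observed study mean of 3.38 sits
between the two regimes, consistent with real reaction times being less
skewed after averaging than the conventional τ = 100 ms assumption. The
flagged count at a fixed cut-off is, in other words, sensitive to the shape
of the latency distribution, not only to planted effects — worth remembering
when comparing issue counts across populations or task versions.

## 6. Numerical and scale choices

* Sample SD (n−1) everywhere a z-score is formed; the oracles match this.
* Strict inequalities at both outlier boundaries and at the flag threshold.
* Flag ties broken by word text ascending; reports are byte-reproducible.
* Problem sizes in tests and the acceptance script (200 replicate cohorts of
  120 participants; 500 null participants; 200-case oracle sweeps) were
  chosen to pin Monte-Carlo error well below the tolerances being checked
  while keeping a full run under a minute.
* Degenerate inputs raise typed errors (`ValidationError` subclasses) naming
  the offending row, word or participant; nothing is silently dropped.

## 7. Known limitations

* The ANOVA treats the category factor as between-cell despite being
  within-participant; no repeated-measures or mixed-effects extension is
  provided (deliberately matching the target procedure).
* No multiple-testing correction across the four-threshold sweep.
* The logistic model's odds ratios are fit on proportions; comparing them to
  per-percentage-point odds ratios requires exponent rescaling.
* Longitudinal tracking of issue profiles across therapy sessions is out of
  scope, as is anything about stimulus construction or task delivery.
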