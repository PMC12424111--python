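# Methods

## Task model

The six conditions share one stimulus space — four directions crossed
with two display modalities (arrow glyph, lowercase word) — and differ
in the allowed modalities and the stimulus→key rule (match, opposite,
or the boxed-override switch rule). The correct-response map is total
and deterministic over each condition's legal stimuli (at most 16), and
is asserted exhaustively in the tests.

Stimulus streams are i.i.d.: direction uniform over four, modality
uniform over the condition's allowed set, boxed flag Bernoulli.
Immediate repeats are allowed — the administration procedure specifies
randomization but not a no-repeat constraint, and independent draws are
the simplest reading. The boxed fraction in K6 is 0.25 by default: the
instructions present boxed items as the minority case ("for many of the
trials" the prepotent opposite rule applies), and one quarter keeps the
switch demand real without inverting the prepotency; it is exposed in
the condition spec. Mixed-modality conditions draw arrow/word 50/50 (no
split is specified).

## Session engine

Timing decisions where the procedure is silent, all configurable:

* inter-stimulus interval 0 ms and no per-item deadline — the next item
  appears the moment a response lands;
* an item whose response would land past the 60 000 ms boundary is not
  counted as attempted (and not logged): only completed answers score.
  Hence the closed-form oracle: at constant latency L the attempted
  count is exactly ⌊60000/L⌋;
* practice continues until five consecutive correct answers, capped at
  100 items by default so that degenerate (always-wrong) responders
  terminate; a cap failure is flagged on the result and the session
  continues to the next condition;
* feedback (check mark / verbatim retry message) is given during
  practice only; latencies are recorded as integer milliseconds.

One master seed per session spawns independent per-condition,
per-phase substreams (numpy `SeedSequence`), so any single trial is
reproducible in isolation and two sessions with the same seed and a
deterministic responder produce byte-identical JSONL logs. Replay
rescores persisted events through the same scoring function the engine
uses; equality is exact, not approximate.

## Respondent simulator

Per-item latency for respondent *r* in condition *c* is lognormal with
log-median

    log m(r,c) = log(1000/base_rate) + log cost_c
               + age_slope·(age − 54.09) − trait_sd·z_r
               + [c ∈ K3..K6] log inh_r + [c = K6] log sw_r
               + cond_noise_sd·w_{r,c}

and item-level dispersion `item_sd` (0.35, a typical speeded-RT
coefficient of variation). `z_r` is standard normal (general speed),
`inh_r`/`sw_r` are folded-lognormal multipliers ≥ 1 (person-specific
inhibition and switching costs), and `w_{r,c}` is an idiosyncratic
person-by-condition term. Errors occur per item with probability
`base_error_c × proneness_r` (capped at .3) and press a uniformly
random wrong key.

### Calibration

The defaults target the validation study's correlation structure: all
pairwise subtest correlations ≳ .72 (mean ≈ .8) and age correlations
≈ −.5. On the log-score scale the variance decomposes as
A + T + I + S + C where A = (age_slope·σ_age)² is the age component,
T = trait_sd² the shared speed trait, I and S the inhibition/switching
cost components, and C = cond_noise_sd² the per-condition residual.
Targeting corr(age, k) ≈ −.55 and corr(k_i, k_j) ≈ .82 with a total
log-score SD ≈ .25 gives age_slope = .0085/yr, trait_sd = .18,
cond_noise_sd = .106, with small I (σ = .11) and S (σ = .08); the
condition cost multipliers 1.00/1.08/1.15/1.25/1.30/1.45 keep the
difficulty ordering speeded < inhibition < switching and a K1 rate of
1.7 items/s (≈ 96 items per timed minute at the cohort mean). At
n = 5000 the realized minimum pairwise correlation is ≈ .72–.73 and all
six age correlations are ≈ −.50.

Demographics: age truncated-normal(54.09, 16.24) on [18, 85] (the
truncation shrinks the realized SD to ≈ 14.6); education a mixture on
12–20 years (no one below 12, mode at 12/16); gender 49:38
female:male; ethnicity from the study's category frequencies. Ethnicity
and gender are independent of the latent traits — no mechanism linking
them to performance is modelled, which is why the demographic
correlation table requires an explicit, user-chosen numeric coding
before it will correlate ethnicity at all.

Scores are produced mechanistically — every respondent sits the full
session through the engine — so the calibration is falsifiable against
the engine's actual behaviour. An analytic mode replaces the event loop
with the expected item count ⌊60000 / (m·exp(item_sd²/2))⌋ and a
binomial draw for correctness; it matches the engine's score
distribution up to within-trial timing noise (≈ 1% of variance) and is
used where only score-level structure matters.

Surrogate external measures are linear in the standardized
speed-and-age composite with independent noise: positive loadings
(.21–.67) for the attention/processing-speed/interference measures,
negative (−.26 to −.61) for the timed trail-making and pegboard
measures (raw time: lower is better), zero for the depression and
anxiety inventories (discriminant measures). They reproduce sign
patterns and rough magnitudes, not the real instruments — no clinical
subgroup structure, practice effects, or non-speed variance is
modelled, so passing tests say nothing about real clinical cohorts.
Optional missingness is completely at random with per-measure rates
derived from the reference complete-pair counts (e.g. 44/87 for the
interference subtests).

## Psychometrics

* Correlations: pairwise deletion (each cell on all cases complete for
  that pair, reproducing heterogeneous degrees of freedom); regressions:
  listwise within each model. Stated in output metadata; SD uses n−1.
* Significance flags at .05 and .01 two-tailed, no multiple-testing
  correction (matching the analysis being mirrored); report tables
  round r and α to two decimals, full precision retained internally.
* Both alpha forms are computed — raw from item variances, standardized
  from the mean pairwise correlation — because only the standardized
  form is checkable from a printed correlation matrix; the two-path
  identity (raw data vs its correlation matrix) is a tested property.
* Degenerate inputs: a constant outcome defines F = R² = 0; constant
  items, fewer than three pairs, or collinear predictors raise an
  explicit undefined-result error rather than returning NaN.

## Power analysis

Exact method: the sampling density of the correlation coefficient under
bivariate normality (hypergeometric form), integrated by adaptive
quadrature (tolerance 1e−10) over |r| > r_crit, with r_crit from the
null t test at n−2 df. Required-n searches bracket from the Fisher-z
closed form and bisect; a 1e−8 guard keeps integer thresholds stable.
The exact method is the default because the required-n integers it
produces (29/84/782 at ρ = .5/.3/.1, power .80, α = .05) match standard
statistical-package output, whereas Fisher-z gives 30/85/783; both are
exposed and their achieved powers agree within .02 for n ≥ 30,
|ρ| ≤ .6. The method is validated against a Monte-Carlo rejection-rate
oracle in the tests. One quoted effect size ("large r = .05") is an
evident typo for r = .5 and is treated as such.

## Problem sizes

The shared test fixtures use 400 analytic-mode and 60 engine-mode
respondents; calibration-at-scale checks use 5000 (engine mode runs
~4 ms per respondent-session, so a 5000-cohort takes ~20 s). The
Monte-Carlo power oracle uses 30 000–40 000 replicate samples of n = 87,
giving a standard error ≈ .003 on the rejection rate. The exhaustive
permutation oracle enumerates all 8! = 40 320 permutations.

## Known limitations

* The interactive front-end measures latency around a blocking terminal
  read; no keyboard-hardware calibration is attempted, and non-arrow
  keys during timed trials are ignored rather than logged (a divergence
  risk against live administrations that record them).
* The simulator has no diagnostic-group structure, no practice effects
  across repeat administrations, and no process-level RT theory; it is
  a measurement-structure emulator, not a cognitive model.
* Test–retest reliability, factor structure, and norming are out of
  scope.
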