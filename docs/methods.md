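# Methods

`keysleep` estimates nocturnal rest-activity patterns from two modalities —
smartphone keyboard event streams and morning sleep diaries — and quantifies
how well they agree, where they diverge, and which person-level traits
moderate the mapping between them. This note documents the models, the
synthetic cohort that stands in for real data, and the numerical and design
choices a maintainer would want to know about.

## The night axis

All night-level times are decimal hours since **noon of the evening anchor
date**: 7 PM is 7.0, midnight 12.0, 3 AM 15.0, 3 PM the next day 27.0. The
axis is monotone across midnight, which removes every wraparound special
case from the arithmetic. Clock strings ("HH:MM") and absolute timestamps
are converted only at I/O boundaries; clock times at or before 15:00 on a
morning report belong to the report date, later times to the previous
calendar date, because the nightly analysis window ends at 3 PM.

## Keyboard-derived estimates

For each participant-night the extractor considers all keystrokes between
7 PM and 3 PM the next day (bounds inclusive) and finds the **longest
interval without keyboard activity (the keystroke-absence period, KAP)**.
The keystrokes bracketing that gap are the last-keystroke (rest-onset proxy)
and first-keystroke (activity-onset proxy) estimates; their midpoint proxies
midsleep, and the gap length proxies rest duration.

Decisions where the definition is silent:

- **Ties** for the longest gap resolve to the earliest-starting gap
  (deterministic, and favors the nocturnal gap over a late-afternoon tie).
- Gaps running into the **window edges are not candidates**: both endpoints
  of the KAP must be keystrokes. Nights whose true rest extends past 3 PM
  are therefore mis-estimated and left to the outlier rule.
- Fewer than two in-window events make the night invalid (`valid=False`,
  estimates missing) — never an exception.
- No minimum KAP duration is imposed; the pooled 4-SD outlier rule is the
  only filter.
- `hours_with_activity` counts distinct clock-hour bins (00–23) containing
  at least one keystroke per calendar day; under bin counting the
  restriction to the first-to-last-keystroke span is vacuous and is not
  separately enforced.

## Diary-derived estimates

Eight metrics per night, all exact arithmetic: bedtime, try-to-sleep, sleep
onset (try-to-sleep + latency), midsleep (midpoint of onset and offset),
sleep offset, out-of-bed, total sleep period (offset − onset) and total bed
period (out-of-bed − bedtime). Midsleep is computed from derived onset and
offset because the core consensus-diary item set has no midsleep question.
Invalid raw values (unparseable clock strings, negative latencies) are coded
missing at read time with the row retained; ordering violations after axis
mapping (negative durations, out-of-bed before sleep offset, bedtime after
try-to-sleep) null only the affected derived fields.

**Outlier rule.** Before any modeling, each metric is masked at |z| > 4
against the pooled (all participants × nights) mean and SD, in a single
pass. Per-person standardization and iteration were considered and
rejected: the pooled single pass is the simplest defensible reading, and
the rule's statistics are frozen at fit time so repeated application is
idempotent.

## Agreement and equivalence

Eight metric pairs are compared (last keystroke ↔ bedtime / try-to-sleep /
onset; midpoint KAP ↔ midsleep; first keystroke ↔ offset / out-of-bed;
KAP ↔ total sleep / total bed period), with differences signed keyboard −
diary (negative = keyboard earlier or shorter).

- **ICC** per metric comes from a random-intercept-only (unconditional)
  model: ICC = σ²_between / (σ²_between + σ²_within). A singular fit
  reports ICC 0 with a flag rather than raising.
- **Mean differences** are tested on stacked long data (both modalities of
  a night as rows) with modality as a fixed factor and a participant random
  intercept only — deliberately no night-level random effect, so the
  modality coefficient equals the raw mean difference in balanced data.
  α = .01 throughout (99% CIs); p between .01 and .05 is labeled a trend.
- **Equivalence (TOST)** is implemented as the 98%-CI-inclusion criterion —
  equivalent at Δ when the (1 − 2α) CI lies strictly inside (−Δ, +Δ) — at
  Δ = 0.5 h and 1.0 h, using the mixed-model SE for internal consistency
  with the significance test.
- **Repeated-measures Bland-Altman**: bias is the intercept of a
  random-intercept model on the differences; limits of agreement are
  bias ± 1.96·√(σ²_between + σ²_within) of the differences, so they
  describe single new nights, not participant means.

## Multilevel association and moderation models

All association models regress the grand-standardized diary metric on the
grand-standardized keyboard metric with a participant random intercept, so
slopes are standardized βs. Explained variance is reported two ways
(fixed-effects/marginal and fixed-plus-random/conditional, Nakagawa-style);
the marginal version is the headline number.

- **Cluster-mean centering** uses empirical-Bayes person means: fixed
  intercept plus the predicted random intercept of the metric's
  unconditional model. The decomposition (person mean + deviation)
  reconstructs each observation exactly; shrinkage vanishes as nights per
  person grow.
- **First-level moderation** adds the day-level moderators
  (hours-with-activity, also EB-centered, and a weekend indicator) with
  main effects and centered-metric × moderator interactions. Evening-
  anchored pairs use the previous day's keyboard hours; morning and
  duration pairs the next day's.
- **Random slopes**: the random-intercept model is compared with a model
  adding a random slope (plus intercept-slope covariance) for the centered
  keyboard metric. Both are REML fits with identical fixed effects, so the
  restricted likelihoods are comparable; the LRT has 2 df. The boundary
  null makes this test conservative, which is acknowledged rather than
  corrected. Boundary fits report slope SD 0.
- **Cross-level moderation** adds grand-mean-centered traits (chronotype
  MSFsc, PSQI, trait self-control) with main effects and trait ×
  centered-metric interactions to the random-slope model, after a
  collinearity screen (pairwise trait correlations plus VIFs on the fixed
  design; VIF above 10 warns but the fit proceeds).

**Degrees of freedom.** A Satterthwaite approximation would be preferable
for fixed-effect t tests, but the mixed-model backend exposes no machinery
for it, so all models use a residual-style df (n_obs − n_groups − n_fixed),
flagged as `df_method="residual"` in every result. For the designs used
here (≈1,000 observations, ≈150 groups) the difference from Satterthwaite
df is immaterial at α = .01.

**Optimizers.** Mixed models try BFGS, then Powell, then CG (maxiter 200);
the first fit without convergence or singularity warnings wins, otherwise
the best-likelihood candidate is returned flagged as non-converged.
Degenerate data (zero residual variance) falls back to the closed-form
summary (equivalence test: paired t-test form) with a fallback flag.

## The synthetic cohort

The generator emulates a one-week student cohort (157 participants × 7
nights by default) with known ground truth, so every downstream stage is
testable without any data download.

Per participant: a chronotype offset (SD 0.75 h), a habitual
sleep-duration offset (SD 0.45 h), a lognormal personal keystroke rate
(median 60/h, log-SD 0.4), an in-bed-phone-use propensity (Beta around
0.25), an integer PSQI (mean 5.16, SD 2.27, clipped 0–21) and a trait
self-control score (mean 2.98, SD 0.56, clipped 1–5). Per night: try-to-
sleep time N(00:30, 1.25 h) plus the chronotype offset and a weekend delay
(0.5 h on nights whose morning is Saturday/Sunday); bedtime an exponential
gap (mean 0.5 h) earlier; onset after an exponential latency (mean 16 min);
duration N(7.75, 1.1 h); out-of-bed an exponential rise lag (mean 0.5 h)
after offset. Degenerate draws (duration < 2 h, out-of-bed past ~2:30 PM)
are redrawn with bounded retries.

The keystroke stream is a homogeneous Poisson process during wake. Phone
behavior does not track the diary anchors exactly: the evening stream ends
at bedtime plus an independent N(0, 0.6 h) offset (capped at try-to-sleep),
or continues until try-to-sleep on in-bed-use nights; the morning stream
resumes at out-of-bed plus an independent N(0, 0.6 h) offset (floored at
sleep offset). This independent behavioral jitter is what makes the
duration pairs agree less well than the timing pairs — endpoint errors add
in a duration but average out in a midpoint — matching the qualitative
pattern seen in real keyboard-vs-diary comparisons. Nocturnal awakenings
are Poisson with mean 0.05 × PSQI per night; each, with probability 0.2,
emits a burst of 1–5 keystrokes within 10 minutes at a uniform time in the
sleep period. This is the mechanism by which poorer general sleep quality
degrades the keyboard proxy. Diaries report truth plus N(0, 15 min) per
field, rounded to the 5-minute grid, with orderings clamped to be internally
consistent (diarists do not report out-of-bed before wake-up); latency is
reported directly with the same noise. Alarm use is Bernoulli (60%
weekdays, 46% weekend mornings).

Seeding: one master seed spawns per-participant substreams, so outputs are
byte-identical across runs and any participant can be regenerated in
isolation.

What the generator does **not** emulate: bursty within-day usage (real
streams concentrate thousands of keystrokes into ~12 active hours; a
homogeneous wake-rate process of comparable density is active in nearly
every wake hour, so the hours-with-activity covariate is compressed toward
the wake duration), typing content and inter-key latencies, daytime naps,
app downtime, and any circadian structure beyond a per-person offset.
Passing tests therefore demonstrate correctness of the estimators under
this generative model, not performance on real keyboard streams.

## Validation harnesses and problem sizes

Monte-Carlo recovery checks run at sizes chosen to keep the default suite
fast while leaving no ambiguity about the verdicts: ICC recovery (20
replicates of 200 × 7, between 1 / within 3); standardized-slope recovery
and 99%-CI coverage (20 replicates of 150 × 7, β = 0.75); TOST size at the
bound (200 replicates) and power at zero difference (40 replicates);
random-slope detection at slope SD 0.35 and null calibration at 0 (20/40
replicates); cross-level moderation with PSQI-dependent slope attenuation
(γ = −0.04 per PSQI point, i.e. standardized slopes spanning roughly
0.9–0.55 across the observed PSQI range; 20 replicates at 157 × 7). The
full default cohort is run end to end once to check the qualitative
pattern: timing βs exceed duration βs, KAP exceeds the diary sleep period
by roughly an hour, small-offset timing pairs are equivalent within ±1 h,
and the weekend delay appears in both modalities.

## Known limitations

- The residual-df approximation is anti-conservative relative to
  Satterthwaite for small clusters; irrelevant at the default sizes but
  worth revisiting for cohorts with few participants.
- The stacked equivalence model ignores the night-level pairing, so its SE
  is conservative when difference variance is small relative to night
  variance; this mirrors the specification of the analysis rather than an
  oversight.
- The 4-SD rule is a blunt instrument for app-downtime artifacts: a phone
  switched off across a whole window surfaces as a spuriously long KAP and
  is only caught if it exceeds 4 pooled SDs.
- Generator weekend contrasts are a free calibration knob (default 0.5 h,
  a deliberately mild contrast); weekday/weekend moderation results should
  be read relative to that choice.
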