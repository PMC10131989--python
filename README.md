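# keysleep

Rest-activity estimation from smartphone keyboard interaction streams, and
multilevel agreement analysis against morning sleep diaries.

Smartphones offer an unobtrusive way to approximate when people rest and
when they are active: the timing of keyboard activity and inactivity across
the 24-hour day. `keysleep` is for researchers in digital phenotyping,
sleep epidemiology and ambulatory assessment who want to (a) turn raw
keystroke event logs into nightly rest-activity estimates, (b) derive the
matching self-reported estimates from consensus-style sleep diaries, and
(c) quantify — with the field's standard multilevel toolkit — how well the
two modalities agree, whether they are statistically *equivalent*, and how
the mapping varies between people.

## The estimators at the core

For each participant-night, among keystrokes in the window from 7 PM to
3 PM the next day, the **keystroke-absence period (KAP)** is the longest
interval without keyboard activity:

- last keystroke before the KAP → rest-onset proxy (vs diary bedtime,
  try-to-sleep, sleep onset),
- first keystroke after the KAP → activity-onset proxy (vs sleep offset,
  out-of-bed),
- midpoint KAP → midsleep proxy,
- KAP length → rest-duration proxy (vs total sleep / total bed period).

Agreement between modalities is assessed per metric pair with:

- **ICCs** from unconditional (intercept-only) multilevel models:
  ICC = σ²_between / (σ²_between + σ²_within);
- mean differences from stacked multilevel models (modality fixed factor,
  participant random intercept), with NHST at α = .01 (99% CI) and
  **TOST equivalence** at Δ = 0.5 h and 1 h (equivalent when the 98% CI
  lies inside ±Δ);
- repeated-measures **Bland-Altman** bias and limits of agreement;
- standardized-β association models *y*ᵢⱼ = β·*x*ᵢⱼ + *u*ᵢ + εᵢⱼ, extended
  with empirical-Bayes cluster-mean centering, day-level moderators
  (hours with keyboard activity, type of day), **random slopes** (LRT with
  2 df), and cross-level trait moderators (chronotype MSFsc, PSQI, trait
  self-control).

A bundled synthetic cohort generator produces keystroke streams, diaries
and trait tables from a ground-truth circadian sleep model (with
PSQI-dependent nocturnal phone-use bursts and weekday/weekend timing
shifts), so the whole pipeline is exercisable and testable without any
data download. See `docs/methods.md` for the model details and the
generator's scope.

## Worked example

The whole pipeline — simulate a 157 × 7 cohort, extract keyboard nights,
derive diary nights, apply the pooled 4-SD outlier rule, and fit the
agreement and association models — runs from the shell:

```bash
keysleep run --seed 7 --out-dir demo_out
```

which ends by printing (abridged):

```
pair | mean diff (h) | 98% CI | equiv@0.5h | equiv@1h
last_keystroke~bedtime | +0.13 | [-0.01, +0.27] | True | True
last_keystroke~sleep_onset | -0.71 | [-0.85, -0.57] | False | True
midpoint_kap~midsleep | -0.09 | [-0.23, +0.05] | True | True
first_keystroke~out_of_bed | -0.01 | [-0.18, +0.16] | True | True
kap~total_sleep_period | +1.22 | [+1.09, +1.35] | False | False
kap~total_bed_period | -0.15 | [-0.29, -0.02] | True | True

pair | beta | 99% CI | slope SD | LRT p
last_keystroke~bedtime | 0.86 | [0.82, 0.90] | 0.21 | 2.1e-23
midpoint_kap~midsleep | 0.92 | [0.89, 0.95] | 0.10 | 0.00011
kap~total_sleep_period | 0.65 | [0.59, 0.71] | 0.25 | 2.9e-06
kap~total_bed_period | 0.75 | [0.70, 0.81] | 0.23 | 1.2e-10
```

Read: the keyboard proxies track the *bed-related* diary times closely
(last keystroke is within ~8 min of reported bedtime on average, and
equivalent within ±30 min), sit farther from the *sleep-related* times
(sleep onset differs by −0.71 h: people stop typing before they fall
asleep), and the inactivity period overshoots the reported sleep period by
about 1.2 h — so it is not equivalent to total sleep even within ±1 h,
while every timing pair is. Timing associations (β .83–.93) are stronger
than duration associations (β .65/.75), and the significant random-slope
SDs (0.10–0.25) say the strength of that mapping genuinely differs between
people.

The same stages are available as subcommands (`simulate`, `extract`,
`derive`, `agree`, `model`, `report`) with a YAML config, and as a library:

```python
import keysleep as ks

cohort = ks.simulate_cohort(ks.SimConfig(seed=7))
nights, day = ks.extract_all_nights(cohort.events)
paired = ks.pair_nights(nights, diary_nights, day)
result = ks.test_difference(paired["midpoint_kap~midsleep"])
model = ks.AssociationModel().fit(paired["midpoint_kap~midsleep"])
```

Outputs land in `--out-dir` as CSV/JSON (`agreement_report.json`,
`model_report.json`, per-pair paired-night tables) plus a `manifest.json`
with SHA-256 digests: identical seeds reproduce identical files.

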