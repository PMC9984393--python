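# somnokit

Sleep scoring and circadian summarization for rodent opioid studies.

Chronic opioid exposure disrupts sleep in mice, most prominently as
elevated wakefulness during the dark (active) phase. Quantifying that
phenotype takes a chain of small, error-prone steps: staging raw EEG/EMG
into vigilance states, or inferring sleep from passive-infrared (PIR)
activity sensors; collapsing the stage sequence into per-hour and 12-h
light/dark minutes; and comparing treatment groups over time.
`somnokit` implements that chain as a tested library with a thin CLI,
plus a synthetic-data generator so every stage can be exercised and
validated without any recordings.

## What it computes

**EEG/EMG staging** (`somnokit.staging`). Each 4-s epoch is labeled from
band-dominance fractions — the share of 0.5-s sub-windows whose spectral
peak falls in a band — and an EMG amplitude flag calibrated per recording
(2-means on log RMS). With `f_band` the dominance fraction:

- WAKE: `f_>12Hz > 0.10` and high EMG
- NREM: `f_0.5-4Hz > 0.30` and `f_>12Hz < 0.10` and low EMG
- REM:  `f_5-10Hz > 0.20` and low EMG
- otherwise a configurable fallback (WAKE)

**PIR sleep scoring** (`somnokit.compass`). Activity is a 0–100 score
per 10-s bin; a maximal run of zero-score bins lasting ≥ 40 s is scored
as sleep. Bouts (maximal scored-sleep runs) are summarized by count,
mean, and maximum duration, and sleep calls can be validated against a
ground-truth vector by per-bin Pearson correlation.

**Circadian summaries** (`somnokit.metrics`). Minutes per stage per
clock hour, 12-h light/dark totals under a configurable light cycle
(default lights on 07:00–19:00), and drinking-water dose arithmetic
(volume × concentration / body weight).

**Group statistics** (`somnokit.stats`). Pooled-variance unpaired
t-test; classical split-plot two-way ANOVA (between-subject group ×
within-subject hour, `F = MS_effect / MS_error` with subjects-within-group
and subject×time error strata); and an animal-level label-permutation
test (exact under exchangeability, exhaustive when feasible) with an
optional max-T statistic for family-wise per-hour contrasts.

**Synthetic data** (`somnokit.simulate`). Vigilance states follow a
first-order Markov chain with a transition matrix per (light phase,
condition); chronic morphine raises dark-phase wake persistence, and an
optional intervention window emulates a transient chemogenetic
inhibition. EEG/EMG are tonal-plus-noise with stage-appropriate bands
and EMG atonia in sleep; PIR traces are zero in sleep bins except for a
small false-movement probability.

## Worked example

```python
import numpy as np
from somnokit import (
    CONTROL, MORPHINE, HypnogramParams, PirParams, LightCycle,
    simulate_hypnogram, simulate_activity_trace, true_sleep_bins,
    score_sleep, detect_bouts, bout_statistics, validate_against_truth,
    minutes_per_hour, aggregate_light_dark,
)

lc = LightCycle()  # lights on 07:00-19:00
for cond in (CONTROL, MORPHINE):
    hyp = simulate_hypnogram(HypnogramParams(duration_h=24.0, seed=1), condition=cond)
    ld = aggregate_light_dark(minutes_per_hour(hyp, lc), lc).table
    print(cond, "dark wake:", round(ld.loc["dark", "wake_min"], 1), "min")

hyp = simulate_hypnogram(HypnogramParams(duration_h=24.0, seed=1), condition=MORPHINE)
trace = simulate_activity_trace(hyp, PirParams(seed=2))
sleep = score_sleep(trace)
stats = bout_statistics(detect_bouts(sleep, trace.bin_s))
r = validate_against_truth(sleep, true_sleep_bins(hyp))
print(f"bouts={stats.bout_count} mean={stats.mean_bout_s:.0f}s "
      f"max={stats.max_bout_s:.0f}s total={stats.total_sleep_min:.0f}min r={r:.3f}")
```

Output:

```
control dark wake: 512.1 min
morphine dark wake: 643.3 min
bouts=177 mean=192s max=1010s total=566min r=0.978
```

The control animal is awake ~512 of the 720 dark minutes while the
chronic-morphine animal is awake ~643 — the dark-cycle wake elevation the
package is built to quantify. The PIR sleep call agrees with the
generating hypnogram at r ≈ 0.98 per bin.

The same pipeline from the shell:

```sh
somnokit simulate hypnogram --condition morphine --duration-h 24 --seed 1 --out hyp.tsv
somnokit simulate pir --hypnogram hyp.tsv --seed 2 --out pir.csv
somnokit compass score --csv pir.csv --out sleep.csv
somnokit summarize --sleep sleep.csv --out summary.csv
somnokit compare --csv tidy.csv --value minutes --between condition --within hour
```

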