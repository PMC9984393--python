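# Methods

## Vigilance-state model and the synthetic generator

States (WAKE, NREM, REM) evolve as a first-order Markov chain on a 4-s
epoch grid. The chain is time-inhomogeneous through matrix switching
only: at each epoch the active 3×3 row-stochastic matrix is selected by
clock time — light phase (default 12:12, lights on 07:00–19:00),
experimental condition, and an optional intervention window that swaps
in a replacement matrix while the clock is inside it. The first state is
drawn from the stationary distribution of the matrix active at the start
of the recording. A single uniform stream drives the whole simulation,
so two runs with the same seed are bit-identical, and two runs differing
only in a late intervention window share their entire pre-window
trajectory.

A Markov chain is the simplest generative mechanism that produces the
two structures the downstream analysis must detect: circadian
organization (phase-switched matrices) and condition effects on wake
architecture (persistence changes). It deliberately omits homeostatic
drift within a phase, ultradian REM cycling beyond first-order
transitions, and inter-animal heterogeneity; passing tests therefore
show the pipeline recovers what the chain encodes, not that real mouse
sleep is first-order Markov.

### Default transition matrices

No quantitative stage proportions were available to calibrate against,
so the defaults were fixed once from standard mouse sleep architecture:

| regime | wake fraction | mean NREM bout | notes |
|---|---|---|---|
| light (both conditions) | 0.29 | ≈ 2.5 min | sleep-dominant rest phase; REM ≈ 12% of time, entered only from NREM |
| dark, control | 0.70 | ≈ 1.6 min | active phase |
| dark, chronic morphine | 0.87 | ≈ 1.2 min | higher wake self-transition (0.993 vs 0.985) and faster sleep exit |

The chronic-morphine light matrix equals the control's: the drug's wake
phenotype is dark-phase specific. Direct WAKE→REM transitions are
rejected at validation unless explicitly enabled (`allow_wake_rem`),
reflecting rodent physiology; REM→NREM is allowed but rare (0.01).
The default intervention window starts at clock hour 20 (one hour into
the dark phase, matching an injection given then) and lasts 4 h — the
typical effective window of the agonist — during which the chain runs
under the *control* dark matrix: inhibition cancels the drug-specific
wake elevation without abolishing normal dark-phase wake.

### Signals

EEG per epoch is a single stage-characteristic sinusoid — frequency
jittered uniformly in the stage's band (NREM 2.25 ± 1 Hz, REM 7.5 ± 1.5
Hz, WAKE 18 ± 3 Hz), random phase — plus white noise (default amplitude
0.1 against tone amplitudes 1–1.5). EMG is zero-mean Gaussian at a
stage RMS (WAKE 3.0, NREM 0.3, REM 0.2 — atonia in sleep); construction
requires wake EMG to exceed both sleep stages'. This tonal model is
*not* 1/f-realistic EEG: it contains no spindles, no broadband slope,
no mixed-band epochs. It is sufficient exactly because the staging
features are band-dominance fractions, which the tones control directly;
staging accuracy on these signals is an upper bound, not an estimate of
accuracy on real recordings.

### PIR traces

Each 10-s bin takes the majority stage of its overlapping epochs,
weighted by overlap; ties go to WAKE so binning never invents sleep.
Sleep bins score 0 except with a small false-movement probability
(default 0.005, e.g. twitches crossing the sensor), in which case a
small positive score (uniform 1–10) is drawn; wake bins score uniform
20–100. Wake scores are bounded away from zero: the sensor registers
some movement in any bin the animal is predominantly awake — so scored
sleep can only be lost (short bouts, false movements), never invented,
which mirrors the directional bias reported for inactivity-based scoring.

## Staging rules

"Dominated by a band X% of the time" is operationalized as the fraction
of 0.5-s sub-windows whose spectral peak (mean-removed, Hann-tapered,
DC excluded) lies in the band. Raw 0.5-s spectra have 2 Hz resolution —
too coarse for a 0.5–4 Hz band — so sub-window spectra are zero-padded
to 2 s, interpolating the peak on a 0.5 Hz grid. Consequently a tone
within a quarter-bin (0.25 Hz) of a band edge can quantize onto the
edge; the fast band is strictly `> 12 Hz` while delta and theta are
edge-inclusive. A silent sub-window has no dominant frequency and counts
toward no band, so all-zero EEG yields all-zero fractions (defined, not
an error).

The EMG high/low threshold is calibrated per recording: exact 1-D
2-means on log RMS (optimal split of the sorted values by within-cluster
SSE), threshold at the midpoint of the two cluster centers in log space.
Log-domain clustering makes staging invariant to rescaling all EMG
epochs by a common factor. If all values fall within a 1% relative range
the split is meaningless and the threshold is +inf (everything low) —
with the fixed rule order this biases degenerate recordings toward NREM/
REM rather than fabricating wake from noise in the EMG gain.

Rules are applied in fixed precedence WAKE → NREM → REM; the first rule
whose conditions hold wins, so every epoch gets exactly one label. When
no rule fires the fallback stage (default WAKE, configurable) is
assigned; in the source workflow such epochs went to manual re-scoring,
which is out of scope here. The 5–10 Hz REM band is theta-range activity
and is named `theta_band` accordingly. No temporal smoothing or
transition constraints are applied by default; a 3-epoch majority filter
is available (`smooth=True`).

## PIR sleep scoring

A maximal run of consecutive exactly-zero bins lasting **≥ 40 s** (four
10-s bins) is sleep. Two readings of the rule coexist in its source
description ("greater than 40 s" vs "convert 40 s of inactivity into
sleep"); the inclusive reading is the default because the conversion
statement names 40 s itself as sleep, and a `strict` flag gives the
exclusive one (> 40 s, five bins). Only exact zeros count as inactivity —
no epsilon — and bouts are never merged across a single active bin.
Bout statistics are count, arithmetic mean, maximum, and total minutes;
an empty bout list reports zeros. Validation against a truth vector is
the plain Pearson product-moment correlation of the per-bin 0/1 vectors;
a constant vector makes r undefined and raises.

## Summaries

Hour buckets are clock hours; a 4-s epoch cannot straddle an hour
boundary because 4 divides 3600 and recordings must start on the epoch
grid (asserted). Partial first/last hours are reported with their actual
coverage and flagged incomplete, never rescaled. Light/dark totals sum
hourly minutes over hours whose midpoint falls in the phase; light +
dark equals the 24-h total exactly. Zeitgeber time (ZT0 = lights-on) is
carried alongside clock hours so post-hoc windows can be expressed in
either convention. Dose arithmetic:
`mg/kg/day = mL/day × mg/mL / (g/1000)`.

## Statistics

The unpaired t-test is the pooled-variance Student form
(df = n1 + n2 − 2), two-sided by default, with Welch and one-sided
options. One reported bout-length comparison in the motivating study
(t = 1.720, df = 17, P = 0.0418) is consistent only with a one-sided
test; the default here stays two-sided.

The mixed ANOVA is the classical split-plot decomposition: group is
tested against subjects-within-group; time and group×time against the
subject×time residual. With a complete time grid the decomposition is
exact even for unequal group sizes (the study's own groups are unequal),
so "balanced" is enforced as *no missing cells*, not equal n. Sphericity
is not corrected by default; Greenhouse–Geisser adjusted degrees of
freedom are available (`correction="gg"`). Tukey post-hoc comparisons
are not implemented; per-hour contrasts use the permutation test with
the max-T statistic for family-wise control. The permutation test
relabels whole animals (time courses intact); with two groups and few
animals it enumerates all label assignments exhaustively and reports the
exact proportion of relabelings at least as extreme, otherwise it draws
`n_perm` random permutations and uses the add-one estimate
(1 + #{≥ obs}) / (1 + n_perm).

## Problem sizes and numerical choices

Test and validation runs use 24-h single-animal days (21 600 epochs,
8 640 bins), 8-animal cohorts for the pooled PIR validity figure,
100-seed Monte Carlo for scenario contrasts, 500 replicates for type-I
calibration of the group F-test, and 200 replicates for permutation-p
uniformity — sizes at which Monte-Carlo error is small against the
margins being tested. Stationary distributions are obtained by
least-squares solution of the balance equations with the normalization
row appended. Row-stochasticity is validated to 1e-12; ANOVA oracle
agreement is asserted at 1e-8 relative; EDF round trips are exact up to
16-bit quantization.

## Known limitations

- The generator's matrices reproduce qualitative circadian/condition
  structure, not any particular animal's stage proportions.
- Tonal EEG means staging accuracy here does not transfer to real
  recordings with mixed-band epochs and artifacts; no artifact rejection
  is implemented.
- Spectral band *power* analysis is deliberately absent (out of scope in
  the motivating workflow).
- The PIR 0–100 score construction from raw sensor events is
  hardware-side and consumed as given.
- The EDF writer covers the minimal two-channel, 1-s-record case used
  here; it is not a general EDF+ implementation.
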