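# Methods

`burstlapse` implements an analysis pipeline linking bursts of EEG
oscillations to behavioural lapses in a sustained-attention reaction-time
task, together with a ground-truthed synthetic-data generator that makes
every stage testable without access to real recordings. This note records
the models, the parameter choices that matter, and the places where the
design was genuinely open.

## The task and trial outcomes

The behavioural model is a lateralised attention task: a stimulus appears
every 2–10 s (uniform inter-stimulus interval) and shrinks away within
0.5 s. Responses are classified from the reaction time *rt*:

* *false alarm*: rt < 0.1 s,
* *fast*: 0.1 s ≤ rt < 0.5 s,
* *slow*: 0.5 s ≤ rt < 1 s,
* *lapse*: no response or rt ≥ 1 s.

All intervals in the package are half-open `[start, end)`; times are
seconds from recording start; voltages are microvolts.

## Cycle-by-cycle burst detection

A burst is a run of consecutive oscillation cycles that is both rhythmic
and larger than the aperiodic background. The detector:

1. band-pass filters the preprocessed signal in narrow overlapping bands,
   4 Hz wide from 2 to 16 Hz in 1 Hz steps (zero-phase 4th-order
   Butterworth). The 1 Hz step guarantees every frequency of interest sits
   within half a bandwidth of some band centre;
2. finds signed zero-crossings of each narrowband signal (sub-sample,
   linearly interpolated);
3. between crossings, locates positive peaks and troughs as voltage
   extrema of a *scoring* signal — the input low-passed at 20 Hz
   (zero-phase). Scoring on the raw 0.5–40 Hz signal was tried first and
   rejected: under a 1/f background the beta/gamma-range jitter flips the
   sample-to-sample signs so often that even bursts four times larger than
   background fail any useful monotonicity threshold. 20 Hz is above every
   filter band, so theta/alpha morphology is essentially intact
   (zero-phase attenuation < 6 % at 14 Hz). Trough times are refined to
   sub-sample precision by parabolic interpolation;
4. defines cycle *i* from positive peak *i* to positive peak *i + 1*, with
   one trough inside. Cycle period is trough-to-trough
   (negative-peak-to-negative-peak); amplitude is the mean peak-to-trough
   excursion of the two flanks; per-cycle properties are
   * *monotonicity*: fraction of sample-to-sample differences with the
     expected sign over the descending and ascending flanks,
   * *period consistency* and *amplitude consistency*: the worse
     neighbour ratio `min/max` (boundary cycles use their single
     neighbour),
   * *narrowband amplitude*: the cycle's peak-to-trough range in the
     filter band that produced the crossings;
5. marks a cycle as qualifying when monotonicity ≥ 0.6, period
   consistency ≥ 0.5, amplitude consistency ≥ 0.2, and narrowband
   amplitude ≥ 1.4 × the median narrowband cycle amplitude of its
   channel/band; a maximal run of ≥ 4 consecutive qualifying cycles whose
   largest cycle reaches 4 × that median becomes a burst;
6. merges, per channel, overlapping detections whose mean frequencies are
   within a factor 1.5 of each other — these are the same event seen by
   adjacent filter bands. Genuinely co-occurring theta and alpha rhythms
   (frequency ratio > 1.5) are kept as separate bursts. The merged burst
   inherits cycles, period and amplitude from the constituent with the
   largest *background-relative* in-band amplitude (raw in-band energy
   would be biased toward low bands under a 1/f spectrum);
7. labels each burst theta (4–8 Hz) or alpha (8–14 Hz), half-open edges,
   from a robust period estimate: the median pairwise slope (Theil–Sen) of
   trough time against cycle index. Long trough baselines average out the
   localisation jitter of individual troughs; the plain mean
   negative-peak-to-negative-peak period is also reported on each burst.

The two amplitude criteria assume bursts occupy a minority of the
recording, so the channel/band median cycle amplitude reflects background;
a recording that is one continuous oscillation would defeat them. The
rhythmicity thresholds deliberately sit low: because the crossings come
from narrow bands, background cycles look fairly rhythmic too, and on
simulated data these properties separate burst from background far less
than amplitude does. All thresholds were calibrated once on simulated
1/f-plus-burst recordings (sensitivity and precision both ≥ 0.93, band
accuracy ≈ 0.96, near-zero detections on pure background) and are
config-exposed.

## Event-locked statistics

*Occupancy* is the boolean channel × sample indicator of being inside a
burst (or an eye closure). The pipeline:

* removes artifact samples and (for burst analyses) eye-closure samples;
* epochs occupancy around stimulus onsets over [−2, +4] s, dropping
  false-alarm trials, eye-closure trials, and trials with > 50 % missing
  data;
* per participant and outcome, averages the proportion of non-missing
  channels with a burst across trials, interpolates time points with
  fewer than 15 clean trials (linear; an outcome is dropped when such
  gaps exceed 20 % of the window or fewer than 15 trials survive), and
  z-scores by the mean/SD of the channel proportion over the entire
  pooled session block;
* tests each time point against zero across participants (two-sided
  one-sample t), with Benjamini–Hochberg FDR across all time points and
  outcomes of the analysis, plus Hedge's g
  (`g = d·(1 − 3/(4·df − 1))`);
* for topographies, averages per-channel occupancy within the windows
  Pre [−2, 0), Stimulus [0, 0.3), Response [0.3, 1), Post [2, 4) s,
  subtracts the session-block channel mean, and corrects per topography.
  Window membership uses a half-sample tolerance so that the sample at a
  boundary lands on the correct side despite floating-point time axes.

Display smoothing is lowess (tricube-weighted local linear fit, no
robustness iterations) over 0.2 s.

## Amplitude quantiles

Every burst overlapping [−1, 0) s before an (eyes-open, non-false-alarm)
trial contributes one record with the mean amplitude of its cycles inside
that window and the trial's outcome; a config flag collapses to one
record per trial (its largest burst). Records are sorted into 10
equal-count amplitude quantiles within the session block (ties broken by
stable order; bin sizes differ by at most one); the per-quantile lapse
proportion is z-scored across the 10 values per participant; all 45
quantile pairs are compared with paired t-tests under BH-FDR. A
participant with fewer than 10 records is excluded.

## Time–frequency control analysis

Morlet wavelets on 1–35 Hz (1 Hz grid) with 3–15 cycles logarithmically
spaced across the grid; reflection padding of one maximal wavelet length;
power floored at 1e−12 of the recording median before log10. The
session-block mean per channel × frequency (over unmasked samples) is
subtracted from every time point — no other baseline correction. Epoching
follows the occupancy rules and is run both with and without eye-closure
exclusion. Group maps are one-sample t per (frequency, time) cell with
FDR over the map; band summaries use delta 1–4, theta 4–8, alpha 8–14,
beta 15–25, gamma 25–30 Hz (half-open) with FDR per topography.

## Statistics layer

Two-sided tests throughout. FDR families are always passed explicitly by
the calling analysis. `detectable_effect_size(alpha, power, n)` solves
for the smallest standardized effect whose two-sided one-sample t-test at
`df = n − 1` and noncentrality `d·√n` reaches the requested power, by
Brent root finding on the noncentral-t distribution; at α = 0.05 and
power 0.8 this gives d ≈ 0.70 for n = 18 and d ≈ 1.00 for n = 10 (the
package reports both the d and the small-sample-corrected g scale).

## The synthetic-data generator

One simulated run contains:

* **background**: independent per channel, spectrally shaped white noise
  with power ∝ f^−χ (default χ = 1.5), held flat below 0.5 Hz so slow
  drift does not dominate; total RMS scaled to 10 µV;
* **bursts**: Poisson events (default 2/min/channel per band), frequency
  uniform within theta [4, 8) or alpha [8, 14) Hz, 4–12 cycles, waveform
  = sinusoid × Hann envelope, peak-to-trough amplitude at envelope
  maximum log-normal (median 40 µV, σ = 0.4), optionally copied to k
  adjacent channels;
* **eye closures**: Poisson intervals (1/min, log-normal ~2 s) rendered
  as a pupil-confidence trace (≈ 0.9 open, ≈ 0.1 closed, Gaussian jitter,
  120 samples/s) — thresholding at 0.5 recovers them;
* **artifacts**: all-channel Poisson intervals (0.5/min, ~1 s);
* **trials**: ISIs uniform in [2, 10] s; lapse probability
  `logistic(β₀ + β_amp·A + β_ec·EC + β_dist·dist)` with `A` the largest
  injected-burst amplitude overlapping [−1, 0) s (0 if none, optionally
  restricted to one band or replaced by a top-decile indicator), `EC`
  eyes closed > 50 % of the stimulus window, and distance coupling off by
  default; non-lapses draw a shifted log-normal rt in [0.1, 1) s. The
  default β₀ = −1.5 and β_amp = 0.012/µV put the lapse probability near
  0.18 with no pre-stimulus burst and raise it to ≈ 0.33 across the burst
  amplitude range, in line with the lapse rates the task produces under
  sleep pressure.

All randomness derives from one seed through fixed named substreams, so
reruns are bit-identical and each stage can be re-drawn in isolation;
per-participant/run seeds derive deterministically from the master seed.

What the generator does **not** emulate: volume conduction and leadfield
mixing (events are copied, not mixed, across channels), non-stationary
background, ECG/EMG artifact morphology, circadian drift, and any
stimulus-evoked response or event-related desynchronisation. Passing
recovery tests on these simulations therefore demonstrates the internal
correctness and calibration of the pipeline, not detector performance on
real EEG.

## Validation problem sizes

The test suite runs everything end to end at desk scale, chosen to keep
the full run in the tens of minutes on one core:

* detector recovery: 20 recordings × 8 channels × 5 min, 1/f^1.5
  background, ≥ 6-cycle bursts (the log-normal amplitude distribution
  puts essentially all events at SNR ≥ 2, defined as envelope peak over
  background in-band RMS);
* FDR null calibration: 100 datasets × 12 participants × 2 pooled runs
  of 12 min, all couplings zero, occupancy taken from ground-truth events
  (the detector has its own dedicated recovery test; the calibration
  question concerns everything downstream of it);
* effect recovery: (a) a negative alpha-amplitude coupling
  (β_amp = −0.03, β₀ = logit 0.35) recovered as an FDR-significant
  negative pre-stimulus lapse segment, 12 participants × 2 runs, 25
  seeds; (b) the default positive coupling recovered as a significant
  Q1-vs-Q10 quantile difference, 14 participants × 3 runs × 16 channels,
  25 seeds (16 channels rather than the realistic 123 because with very
  many channels the per-trial *maximum* amplitude saturates and the
  simulated coupling flattens — a property of the outcome model, not of
  the analysis); (c) the spectral/occupancy dissociation, where coupling
  confined to the top theta-amplitude decile (heavy tail σ = 0.8, rate
  4/min, spatial extent 4, β_top = 1.0) yields a significant pre-stimulus
  theta power elevation with no significant occupancy effect — 12
  participants × 2 runs, theta-restricted Morlet grid, 25 seeds.

## Known limitations

* The burst criteria were calibrated against this generator's waveform
  model (Hann-enveloped sinusoids); asymmetric or sawtooth-like real
  oscillations will score differently on monotonicity.
* Bursts co-occurring in the same band on the same channel merge into one
  event; the channel-proportion measure cannot distinguish one global
  burst from several local ones.
* The EDF writer quantises to 16 bits per channel full range; round-trips
  are exact only to that resolution.
* `detectable_effect_size` addresses the one-sample/paired design only.
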