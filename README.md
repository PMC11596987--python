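# burstlapse

Cycle-by-cycle detection of EEG oscillation bursts and event-locked
burst/behaviour statistics for sustained-attention tasks — with a fully
ground-truthed synthetic-data generator, so the whole pipeline is testable
end to end without access to real recordings.

## The problem

During drowsiness, people produce *behavioural lapses* — stimuli that go
unanswered. Bursts of theta (4–8 Hz) and alpha (8–14 Hz) oscillations in
the EEG are candidate neural markers of the underlying vigilance state,
but spectral power conflates how *often* oscillations occur with how
*large* they are. This package implements the waveform-level alternative:
detect individual oscillatory bursts cycle by cycle, then relate their
timing, topography and amplitude to trial outcomes (fast / slow / lapse)
in a reaction-time task, with eye closures measured by pupillometry and
excluded as a confound.

The pipeline covers:

* **burst detection** — narrow overlapping band-pass filters (2–16 Hz),
  zero-crossing-delimited cycles scored for monotonicity, period/amplitude
  consistency and prominence over the 1/f background; runs of qualifying
  cycles become bursts, merged across bands and sorted into theta/alpha by
  a robust negative-peak-to-negative-peak period;
* **event-locked statistics** — burst *occupancy* (proportion of channels
  in a burst) epoched around stimuli, z-scored against the session block,
  tested per time point and per channel/window with one-sample t-tests
  under Benjamini–Hochberg FDR, with Hedge's g effect sizes;
* **amplitude quantiles** — pre-stimulus burst amplitudes binned into 10
  quantiles; lapse proportion per quantile, paired t-tests between all
  quantile pairs;
* **time–frequency control** — Morlet-wavelet log power (1–35 Hz, 3–15
  cycles), session-normalised, as outcome-resolved maps and band/window
  topographies;
* **synthetic data** — 1/f^χ background, Hann-enveloped sinusoidal bursts
  with log-normal amplitudes, eye-closure/pupil-confidence traces, and a
  trial process whose lapse probability follows
  `logistic(β₀ + β_amp·A + β_ec·EC)` on the pre-stimulus burst amplitude
  `A` and eye closure `EC` — every injected event recorded as ground
  truth.

See `docs/methods.md` for the full model description, parameter defaults
and validation problem sizes.

## Worked example

Simulate a small three-participant dataset, detect bursts, and run the
amplitude-quantile analysis (the default configuration couples lapse
probability to pre-stimulus burst amplitude):

```bash
burstlapse simulate --out demo --participants 3 --runs 2 --seed 7
burstlapse detect --data demo
burstlapse quantiles --data demo --out demo/grp --band alpha --use-detected
```

or from Python:

```python
>>> from burstlapse.synth import SimConfig, simulate_run
>>> from burstlapse.bursts import detect_recording
>>> run = simulate_run(SimConfig(duration=300.0, seed=7))
>>> bursts = detect_recording(run.recording)
>>> len(run.ground_truth.bursts), len(bursts)
(163, 145)
>>> bursts[0].band, round(bursts[0].frequency, 1), round(bursts[0].mean_amplitude, 1)
('alpha', 10.3, 19.8)
```

163 events were injected and 145 detected (short or small events fail
the four-qualifying-cycle rule; recovery on events of six or more cycles
runs at about 94 % sensitivity and 96 % precision). The statistics layer answers the
power question directly:

```python
>>> from burstlapse.stats import detectable_effect_size
>>> round(detectable_effect_size(alpha=0.05, power=0.8, n=18)["d"], 3)
0.701
>>> round(detectable_effect_size(alpha=0.05, power=0.8, n=10)["d"], 3)
0.996
```

i.e. with 18 participants a two-sided paired/one-sample t-test at
α = 0.05 has 80 % power only for standardized effects of roughly 0.7 and
above (1.0 and above for 10 participants).

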