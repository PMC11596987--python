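"""Synthetic EEG with ground-truth bursts, eye closures and coupled trial outcomes.

The generator emulates the ingredients of a soporific sustained-attention
session: a 1/f aperiodic background, theta/alpha oscillation bursts
(sinusoid under a Hann envelope, log-normal amplitudes), prolonged eye
closures visible as low pupil confidence, and a trial schedule whose lapse
probability follows a logistic model of pre-stimulus burst amplitude and
eye closure.  Everything injected is recorded in a :class:`GroundTruth`
object so downstream analyses can be validated without real data.

All randomness flows from ``SimConfig.seed``; each stage draws from its own
deterministic substream, so reruns are bit-identical and stages can be run
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import Mask, Recording, SessionBlock

_STREAMS = {"background": 1, "bursts": 2, "closures": 3, "trials": 4, "artifacts": 5}


def _rng(config: "SimConfig", stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stage]])


@dataclass
class SimConfig:
    """Parameters of one simulated task recording.

    Defaults describe one 12-min task run: 8 channels at 250 samples/s, a
    1/f^1.5 background of ~10 uV RMS, two burst bands (theta 4-8 Hz, alpha
    8-14 Hz) at 2 events/min/channel each, log-normal peak-to-trough
    amplitudes (median 40 uV), ~1 eye closure per minute, stimuli every
    2-10 s, and a logistic outcome model calibrated so lapse probability
    rises from ~0.23 to ~0.33 across the burst-amplitude range (with no
    pre-stimulus burst it sits near 0.18).
    """

    n_channels: int = 8
    duration: float = 720.0          # s
    rate: float = 250.0              # samples/s
    aperiodic_exponent: float = 1.5  # power-law slope of background spectrum
    background_rms: float = 10.0     # uV, total RMS of the shaped background
    burst_rate: float = 2.0          # events/min/channel, per band
    burst_bands: dict = field(default_factory=lambda: {"theta": (4.0, 8.0),
                                                       "alpha": (8.0, 14.0)})
    burst_cycles: tuple = (4, 12)    # inclusive integer range
    burst_amp_median: float = 40.0   # uV peak-to-trough at envelope maximum
    burst_amp_sigma: float = 0.4     # log-normal sigma
    spatial_extent: int = 1          # co-active adjacent channels per event
    closure_rate: float = 1.0        # events/min
    closure_dur_median: float = 2.0  # s (log-normal)
    closure_dur_sigma: float = 0.5
    artifact_rate: float = 0.5       # events/min, all-channel artifact spans
    artifact_dur: float = 1.0        # s, mean (exponential)
    isi: tuple = (2.0, 10.0)         # s, uniform inter-stimulus interval
    stimulus_dur: float = 0.5        # s, stimulus visibility window
    pupil_rate: float = 120.0        # samples/s of the confidence trace
    # outcome model: p(lapse) = logistic(beta0 + beta_amp*A + beta_ec*EC
    #                                    + beta_dist*distance)
    beta0: float = -1.5
    beta_amp: float = 0.012          # per uV of max pre-stimulus burst amplitude
    beta_ec: float = 4.0             # eyes closed > half the stimulus window
    beta_dist: float = 0.0           # radial stimulus distance in [0, 1]
    coupling_band: str | None = None   # restrict amplitude coupling to one band
    top_decile_only: bool = False    # couple only on A >= 90th pct of amplitudes
    beta_top: float = 1.3            # logit shift used in top-decile mode
    force_ec_lapse: bool = False     # beta_ec = infinity flag
    fa_rate: float = 0.02            # false-alarm probability on non-lapses
    rt_shift: float = 0.1            # s, shifted log-normal reaction times
    rt_median: float = 0.25          # s, median of the log-normal part
    rt_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.n_channels < 1 or self.duration <= 0:
            raise ValueError("rate, n_channels and duration must be positive")
        for name in ("burst_rate", "closure_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        nyq = self.rate / 2.0
        for lo, hi in self.burst_bands.values():
            if not (0 < lo < hi < nyq):
                raise ValueError("burst frequency ranges must lie inside (0, rate/2)")
        if self.isi[0] < self.stimulus_dur:
            raise ValueError("minimum ISI must cover the stimulus window")
        if self.burst_cycles[0] < 2:
            raise ValueError("bursts need at least 2 cycles")

    @property
    def amp_q90(self) -> float:
        """Analytic 90th percentile of the burst-amplitude distribution."""
        return float(self.burst_amp_median * np.exp(1.2815515655446004 * self.burst_amp_sigma))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["burst_bands"] = {k: list(v) for k, v in self.burst_bands.items()}
        d["burst_cycles"] = list(self.burst_cycles)
        d["isi"] = list(self.isi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "burst_bands" in d:
            d["burst_bands"] = {k: tuple(v) for k, v in d["burst_bands"].items()}
        for key in ("burst_cycles", "isi"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """The simulator's record of everything it injected.

    ``bursts`` has one row per event: first/last co-active channel index,
    start/end s, frequency Hz, cycle count, peak-to-trough amplitude uV and
    band label.  ``closures`` and ``artifacts`` are (start, end) interval
    arrays; ``trial_latent`` carries the per-trial lapse probability and its
    covariates.
    """

    bursts: pd.DataFrame
    closures: np.ndarray
    artifacts: np.ndarray
    trial_latent: pd.DataFrame | None = None

    def burst_occupancy(self, n_channels: int, n_samples: int, rate: float,
                        band: str | None = None) -> np.ndarray:
        """Boolean channel x sample matrix of injected-burst presence."""
        occ = np.zeros((n_channels, n_samples), bool)
        sel = self.bursts if band is None else self.bursts[self.bursts["band"] == band]
        for row in sel.itertuples():
            i0 = int(np.ceil(row.start * rate))
            i1 = min(int(np.ceil(row.end * rate)), n_samples)
            occ[int(row.ch_lo):int(row.ch_hi) + 1, i0:i1] = True
        return occ

    def closure_indicator(self, n_samples: int, rate: float) -> np.ndarray:
        ind = np.zeros(n_samples, bool)
        for s, e in self.closures:
            ind[int(np.ceil(s * rate)):min(int(np.ceil(e * rate)), n_samples)] = True
        return ind


# ---------------------------------------------------------------------------
# background


def simulate_background(config: SimConfig) -> Recording:
    """Aperiodic 1/f^exponent background via spectrally shaped white noise.

    Channels are independent.  The power-law shaping is held constant below
    0.5 Hz (the high-pass corner) so slow drift does not dominate the
    variance; the total RMS is scaled to ``background_rms``.
    """
    rng = _rng(config, "background")
    n = int(round(config.duration * config.rate))
    freqs = np.fft.rfftfreq(n, 1.0 / config.rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    f_eff = np.maximum(freqs[nz], 0.5)
    shape[nz] = f_eff ** (-config.aperiodic_exponent / 2.0)
    shape[0] = 0.0
    data = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        spec = np.fft.rfft(rng.standard_normal(n))
        x = np.fft.irfft(spec * shape, n)
        data[ch] = x / max(x.std(), 1e-12) * config.background_rms
    return Recording(data, config.rate, [f"CH{c + 1}" for c in range(config.n_channels)])


# ---------------------------------------------------------------------------
# bursts


def draw_burst_events(config: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw burst events (no waveforms): Poisson counts per channel and band,
    uniform frequency within band, integer cycle count, log-normal amplitude."""
    rng = rng if rng is not None else _rng(config, "bursts")
    rows = []
    for band, (flo, fhi) in sorted(config.burst_bands.items()):
        for ch in range(config.n_channels):
            n_ev = rng.poisson(config.burst_rate * config.duration / 60.0)
            for _ in range(n_ev):
                f = rng.uniform(flo, fhi)
                n_cyc = int(rng.integers(config.burst_cycles[0], config.burst_cycles[1] + 1))
                dur = n_cyc / f
                if dur >= config.duration:
                    continue
                start = rng.uniform(0.0, config.duration - dur)
                amp = config.burst_amp_median * np.exp(rng.normal(0.0, config.burst_amp_sigma))
                ch_hi = min(ch + config.spatial_extent - 1, config.n_channels - 1)
                rows.append((ch, ch_hi, start, start + dur, f, n_cyc, amp, band))
    events = pd.DataFrame(rows, columns=["ch_lo", "ch_hi", "start", "end",
                                         "freq", "n_cycles", "amplitude", "band"])
    return events.sort_values("start", kind="stable").reset_index(drop=True)


def _burst_waveform(times: np.ndarray, start: float, dur: float, freq: float,
                    amp: float, phase: float) -> np.ndarray:
    env = np.zeros_like(times)
    inside = (times >= start) & (times < start + dur)
    u = (times[inside] - start) / dur
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))  # Hann over the event
    return env * (amp / 2.0) * np.sin(2.0 * np.pi * freq * (times - start) + phase)


def inject_bursts(recording: Recording, config: SimConfig,
                  events: pd.DataFrame | None = None) -> tuple[Recording, GroundTruth]:
    """Add burst waveforms to a recording; returns the modified copy and
    ground truth.  Outside every event interval the signal is untouched."""
    rng = _rng(config, "bursts")
    if events is None:
        events = draw_burst_events(config, rng)
    out = recording.copy()
    t = out.times
    rate = out.rate
    for row in events.itertuples():
        phase = rng.uniform(0.0, 2.0 * np.pi)
        i0 = max(int(np.floor(row.start * rate)), 0)
        i1 = min(int(np.ceil(row.end * rate)) + 1, out.n_samples)
        seg = _burst_waveform(t[i0:i1], row.start, row.end - row.start,
                              row.freq, row.amplitude, phase)
        for ch in range(int(row.ch_lo), int(row.ch_hi) + 1):
            out.data[ch, i0:i1] += seg
    gt = GroundTruth(bursts=events, closures=np.empty((0, 2)), artifacts=np.empty((0, 2)))
    return out, gt


# ---------------------------------------------------------------------------
# eye closures and artifacts


def _draw_intervals(rng: np.random.Generator, rate_per_min: float, duration: float,
                    dur_sampler) -> np.ndarray:
    n = rng.poisson(rate_per_min * duration / 60.0)
    rows = []
    for _ in range(n):
        d = float(dur_sampler(rng))
        if d >= duration:
            continue
        s = rng.uniform(0.0, duration - d)
        rows.append((s, s + d))
    if not rows:
        return np.empty((0, 2))
    return np.array(sorted(rows))


def simulate_closures(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Pupil-confidence trace plus the true closure intervals.

    Confidence sits near 0.9 with eyes open and near 0.1 during closures,
    with Gaussian jitter, sampled at ``pupil_rate`` and clipped to [0, 1].
    """
    rng = _rng(config, "closures")
    intervals = _draw_intervals(
        rng, config.closure_rate, config.duration,
        lambda r: config.closure_dur_median * np.exp(r.normal(0.0, config.closure_dur_sigma)))
    n = int(round(config.duration * config.pupil_rate))
    ts = np.arange(n) / config.pupil_rate
    conf = 0.9 + rng.normal(0.0, 0.03, n)
    closed = np.zeros(n, bool)
    for s, e in intervals:
        closed |= (ts >= s) & (ts < e)
    conf[closed] = 0.1 + rng.normal(0.0, 0.03, closed.sum())
    trace = pd.DataFrame({"timestamp": ts, "confidence": np.clip(conf, 0.0, 1.0)})
    return trace, intervals


def simulate_artifacts(config: SimConfig) -> np.ndarray:
    """All-channel artifact intervals (start, end) drawn as a Poisson process."""
    rng = _rng(config, "artifacts")
    return _draw_intervals(rng, config.artifact_rate, config.duration,
                           lambda r: r.exponential(config.artifact_dur))


# ---------------------------------------------------------------------------
# trial outcomes


def _interval_overlap(starts, ends, lo, hi):
    return np.minimum(ends, hi) - np.maximum(starts, lo)


def simulate_trials(ground_truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Trial schedule and outcomes coupled to the injected signals.

    Onsets follow uniform ISIs in ``config.isi``.  Lapse probability is
    ``logistic(beta0 + beta_amp * A + beta_ec * EC + beta_dist * dist)``
    where ``A`` is the largest peak-to-trough amplitude of any injected burst
    overlapping [-1, 0) s before onset (0 if none; restricted to
    ``coupling_band`` when set; replaced by ``beta_top * 1[A >= q90]`` in
    top-decile mode) and ``EC`` indicates eyes closed for more than half of
    the stimulus window.  Non-lapse trials draw a shifted log-normal reaction
    time in [0.1, 1) s, split fast/slow at 0.5 s.
    """
    rng = _rng(config, "trials")
    epoch_pre, epoch_post = 2.0, 4.0  # keep trials epochable
    onsets = []
    t = epoch_pre + rng.uniform(*config.isi)
    while t < config.duration - epoch_post:
        onsets.append(t)
        t += rng.uniform(*config.isi)
    if not onsets:
        raise ValueError("duration too short for a single trial")
    onsets = np.asarray(onsets)
    n = onsets.size

    bursts = ground_truth.bursts
    if config.coupling_band is not None:
        bursts = bursts[bursts["band"] == config.coupling_band]
    bstart = bursts["start"].to_numpy(float)
    bend = bursts["end"].to_numpy(float)
    bamp = bursts["amplitude"].to_numpy(float)

    pre_amp = np.zeros(n)
    for i, onset in enumerate(onsets):
        ov = _interval_overlap(bstart, bend, onset - 1.0, onset)
        if np.any(ov > 0):
            pre_amp[i] = bamp[ov > 0].max()

    ec = np.zeros(n, bool)
    for i, onset in enumerate(onsets):
        ov = _interval_overlap(ground_truth.closures[:, 0], ground_truth.closures[:, 1],
                               onset, onset + config.stimulus_dur) if len(ground_truth.closures) else np.array([])
        closed = float(np.clip(ov, 0.0, None).sum()) if ov.size else 0.0
        ec[i] = closed > 0.5 * config.stimulus_dur

    distance = np.sqrt(rng.uniform(0.0, 1.0, n))  # uniform over the hemifield disc
    if config.top_decile_only:
        amp_term = config.beta_top * (pre_amp >= config.amp_q90)
    else:
        amp_term = config.beta_amp * pre_amp
    logit = config.beta0 + amp_term + config.beta_ec * ec + config.beta_dist * distance
    p_lapse = 1.0 / (1.0 + np.exp(-logit))
    if config.force_ec_lapse:
        p_lapse = np.where(ec, 1.0, p_lapse)
    lapse = rng.uniform(size=n) < p_lapse

    rt = np.full(n, np.nan)
    for i in np.flatnonzero(~lapse):
        if rng.uniform() < config.fa_rate:
            rt[i] = rng.uniform(0.02, 0.1)
            continue
        x = config.rt_shift + config.rt_median * np.exp(rng.normal(0.0, config.rt_sigma))
        while x >= 1.0:
            x = config.rt_shift + config.rt_median * np.exp(rng.normal(0.0, config.rt_sigma))
        rt[i] = x

    from .events import classify_outcome

    hemifield = np.where((onsets // 120).astype(int) % 2 == 0, "left", "right")
    trials = pd.DataFrame({
        "onset": onsets,
        "rt": rt,
        "outcome": [classify_outcome(r) for r in rt],
        "hemifield": hemifield,
        "distance": distance,
        "ec_stimulus": ec,
    })
    ground_truth.trial_latent = pd.DataFrame(
        {"p_lapse": p_lapse, "pre_amp": pre_amp, "ec": ec, "distance": distance})
    return trials


# ---------------------------------------------------------------------------
# whole sessions and datasets


@dataclass
class SimulatedRun:
    """One simulated task run with every artefact the pipeline consumes."""

    recording: Recording
    trials: pd.DataFrame
    pupil: pd.DataFrame
    mask: Mask
    ground_truth: GroundTruth
    config: SimConfig


def simulate_run(config: SimConfig, waveforms: bool = True) -> SimulatedRun:
    """Simulate one full run (EEG + bursts + closures + artifacts + trials).

    With ``waveforms=False`` the EEG array is left at zero and only the
    event-level ground truth is produced — orders of magnitude faster, and
    sufficient for analyses that operate on occupancy rather than voltages.
    """
    if waveforms:
        rec = simulate_background(config)
        rec, gt = inject_bursts(rec, config)
    else:
        n = int(round(config.duration * config.rate))
        rec = Recording(np.zeros((config.n_channels, n)), config.rate,
                        [f"CH{c + 1}" for c in range(config.n_channels)])
        gt = GroundTruth(bursts=draw_burst_events(config),
                         closures=np.empty((0, 2)), artifacts=np.empty((0, 2)))
    pupil, closures = simulate_closures(config)
    gt.closures = closures
    gt.artifacts = simulate_artifacts(config)
    trials = simulate_trials(gt, config)

    artifact = np.zeros((rec.n_channels, rec.n_samples), bool)
    for s, e in gt.artifacts:
        artifact[:, int(np.ceil(s * rec.rate)):int(np.ceil(e * rec.rate))] = True
    mask = Mask(artifact, gt.closure_indicator(rec.n_samples, rec.rate))
    return SimulatedRun(rec, trials, pupil, mask, gt, config)


def participant_seed(master_seed: int, participant: int, run: int = 0) -> int:
    """Deterministic sub-seed (< 2**31) for one participant/run."""
    ss = np.random.SeedSequence([int(master_seed), int(participant), int(run)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_dataset(config: SimConfig, n_participants: int, n_runs: int = 3,
                 condition: str = "BL", waveforms: bool = True,
                 ) -> list[tuple[SessionBlock, list[GroundTruth]]]:
    """Simulate a multi-participant dataset of pooled session blocks.

    Each participant gets ``n_runs`` independent runs sharing the layout of
    ``config`` but with per-participant/run seeds derived from
    ``config.seed``; everything is deterministic given that master seed.
    """
    from dataclasses import replace

    dataset = []
    for p in range(n_participants):
        runs = [simulate_run(replace(config, seed=participant_seed(config.seed, p, r)),
                             waveforms=waveforms)
                for r in range(n_runs)]
        block = SessionBlock(condition, [r.recording for r in runs],
                             [r.trials for r in runs], [r.mask for r in runs])
        dataset.append((block, [r.ground_truth for r in runs]))
    return dataset
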