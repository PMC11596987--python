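"""In-memory containers for multichannel EEG, trial tables, masks and session blocks.

Conventions used throughout the package:

* voltages are microvolts, times are seconds, 0-based from recording start;
* all trial/analysis windows are half-open ``[start, end)``;
* channels are identified by label string whenever recordings are combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns a trial table must carry (``outcome`` / ``ec_stimulus`` are derived
#: but always materialised so tables round-trip through TSV unchanged).
TRIAL_COLUMNS = ("onset", "rt", "outcome", "hemifield", "distance", "ec_stimulus")

OUTCOMES = ("falsealarm", "fast", "slow", "lapse")


@dataclass
class Recording:
    """A multichannel voltage signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in samples/s.
    channels : list of str
        Ordered, unique channel labels.
    t0 : float
        Time of the first sample in seconds (0 for a fresh recording).
    """

    data: np.ndarray
    rate: float
    channels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.channels = list(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel count does not match data rows")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.rate, list(self.channels), self.t0)


@dataclass
class Mask:
    """Boolean exclusion masks aligned to one :class:`Recording`.

    ``artifact`` is channel x sample; ``closure`` is a single row shared by all
    channels (eyes closed).  True means "excluded".
    """

    artifact: np.ndarray
    closure: np.ndarray

    def __post_init__(self) -> None:
        self.artifact = np.asarray(self.artifact, dtype=bool)
        self.closure = np.asarray(self.closure, dtype=bool).ravel()
        if self.artifact.ndim != 2:
            raise ValueError("artifact mask must be channels x samples")
        if self.artifact.shape[1] != self.closure.shape[0]:
            raise ValueError("artifact and closure masks disagree on sample count")

    @classmethod
    def empty(cls, n_channels: int, n_samples: int) -> "Mask":
        return cls(np.zeros((n_channels, n_samples), bool), np.zeros(n_samples, bool))

    @property
    def n_samples(self) -> int:
        return self.closure.shape[0]


def validate_trials(trials: pd.DataFrame, isi_bounds: tuple[float, float] | None = None) -> pd.DataFrame:
    """Validate a trial table; returns the (unmodified) table.

    Checks column presence, strictly increasing onsets, the rt<->lapse
    correspondence, and optionally that inter-onset intervals respect the
    configured ISI bounds (simulated data only).
    """
    for col in ("onset", "rt"):
        if col not in trials.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    onsets = trials["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("trial onsets must be strictly increasing")
    if "outcome" in trials.columns:
        rt_absent = trials["rt"].isna().to_numpy()
        is_lapse = (trials["outcome"] == "lapse").to_numpy()
        if np.any(rt_absent & ~is_lapse):
            raise ValueError("trials without an rt must be lapses")
    if isi_bounds is not None and len(onsets) > 1:
        isi = np.diff(onsets)
        lo, hi = isi_bounds
        if isi.min() < lo - 1e-9 or isi.max() > hi + 1e-9:
            raise ValueError("inter-onset interval outside configured ISI bounds")
    return trials


@dataclass
class SessionBlock:
    """All recordings of one condition (e.g. pooled baseline task runs).

    Every group-level normalisation (session mean/SD of burst occupancy,
    session-average spectral power) is taken over the whole block, so the
    members must share sampling rate and channel set.
    """

    condition: str
    recordings: list[Recording]
    trials: list[pd.DataFrame]
    masks: list[Mask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ValueError("a session block needs at least one recording")
        if len(self.recordings) != len(self.trials):
            raise ValueError("one trial table per recording is required")
        rate = self.recordings[0].rate
        chans = self.recordings[0].channels
        for rec in self.recordings[1:]:
            if rec.rate != rate:
                raise ValueError("all recordings in a block must share the sampling rate")
            if rec.channels != chans:
                raise ValueError("all recordings in a block must share the channel set")
        if not self.masks:
            self.masks = [Mask.empty(r.n_channels, r.n_samples) for r in self.recordings]
        for rec, mask in zip(self.recordings, self.masks):
            if mask.n_samples != rec.n_samples:
                raise ValueError("mask sample count does not match its recording")

    @property
    def rate(self) -> float:
        return self.recordings[0].rate

    @property
    def channels(self) -> list[str]:
        return self.recordings[0].channels

    @property
    def n_trials(self) -> int:
        return sum(len(t) for t in self.trials)
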