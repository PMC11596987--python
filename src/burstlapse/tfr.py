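"""Morlet-wavelet spectral control analysis.

Complements the binary burst statistics with amplitude-weighted evidence:
log spectral power 1-35 Hz (3-15 wavelet cycles, logarithmically spaced),
normalised by subtracting the session-block average per channel and
frequency, epoched with the same rules as occupancy, and summarised as
outcome-resolved frequency x time t-maps and band x window topographies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import stats as bstats
from .containers import Recording
from .events import OccupancyEpochs, WINDOWS, epoch_tensor, window_mask

#: frequency bands of the band/topography summaries (half-open edges)
TFR_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (15.0, 25.0),
    "gamma": (25.0, 30.0),
}


@dataclass
class TFRTensor:
    """Channel x frequency x time log10 power with its grids."""

    power: np.ndarray
    freqs: np.ndarray
    n_cycles: np.ndarray
    rate: float          # effective rate of the time axis (after decimation)

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]


def default_freq_grid(fmin: float = 1.0, fmax: float = 35.0,
                      fstep: float = 1.0) -> np.ndarray:
    return np.arange(fmin, fmax + fstep / 2.0, fstep)


def cycles_for_freqs(freqs: np.ndarray, cmin: float = 3.0, cmax: float = 15.0) -> np.ndarray:
    """Cycles per frequency, logarithmically spaced from cmin to cmax."""
    n = len(freqs)
    if n == 1:
        return np.array([cmin])
    return np.logspace(np.log10(cmin), np.log10(cmax), n)


def morlet_tfr(recording: Recording, freqs: np.ndarray | None = None,
               n_cycles: np.ndarray | None = None, decim: int = 1) -> TFRTensor:
    """Morlet-wavelet log power of a whole recording.

    Edges are handled by reflection padding of one maximal wavelet length;
    power is floored at 1e-12 of the recording's median power before the
    base-10 log so silent synthetic segments stay finite.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = freqs if freqs is not None else default_freq_grid()
    if freqs.max() >= recording.rate / 2.0:
        raise ValueError("maximum frequency must be below Nyquist")
    n_cycles = n_cycles if n_cycles is not None else cycles_for_freqs(freqs)

    pad = int(np.ceil(np.max(n_cycles / freqs) * recording.rate))
    data = np.pad(recording.data, ((0, 0), (pad, pad)), mode="reflect")
    power = tfr_array_morlet(data[None], recording.rate, freqs, n_cycles=n_cycles,
                             output="power", decim=decim, verbose="error")[0]
    lo = pad // decim
    power = power[:, :, lo:lo + int(np.ceil(recording.n_samples / decim))]
    floor = 1e-12 * np.median(power)
    logp = np.log10(np.maximum(power, max(floor, 1e-300))).astype(float)
    return TFRTensor(logp, freqs, np.asarray(n_cycles, float), recording.rate / decim)


def session_tfr_mean(tensors: list[TFRTensor],
                     masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Session-block mean log power per channel x frequency (unmasked samples)."""
    num = cnt = None
    for i, t in enumerate(tensors):
        p = t.power
        if masks is not None:
            p = np.where(masks[i][:, None, :], np.nan, p)
        s = np.nansum(p, axis=2)
        c = np.sum(~np.isnan(p), axis=2)
        num = s if num is None else num + s
        cnt = c if cnt is None else cnt + c
    return num / cnt


def session_normalise(tensor: TFRTensor, session_mean: np.ndarray) -> TFRTensor:
    """Subtract the session-block mean from every time point (no other
    baseline correction is applied)."""
    return replace(tensor, power=tensor.power - session_mean[:, :, None])


def decimate_mask(mask: np.ndarray, decim: int, n_time: int) -> np.ndarray:
    """A decimated sample is excluded if any source sample was excluded."""
    if decim == 1:
        return mask[:, :n_time]
    n_ch, n_samp = mask.shape
    padded = np.zeros((n_ch, n_time * decim), bool)
    padded[:, :n_samp] = mask[:, :n_time * decim]
    return padded.reshape(n_ch, n_time, decim).any(axis=2)


def epoch_tfr(tensor: TFRTensor, trials: pd.DataFrame,
              window: tuple[float, float] = (-2.0, 4.0),
              mask: np.ndarray | None = None, max_missing_frac: float = 0.5,
              exclude_ec: bool = True) -> OccupancyEpochs:
    """Epoch a normalised TFR with the occupancy epoching rules.

    Returns epochs whose row axis is the flattened channel x frequency grid
    (``data.shape[1] == n_channels * n_freqs``).
    """
    n_ch, n_freq, n_time = tensor.power.shape
    flat = tensor.power.reshape(n_ch * n_freq, n_time)
    m = None
    if mask is not None:
        decim = max(1, int(round(mask.shape[1] / n_time)))
        m = np.repeat(decimate_mask(mask, decim, n_time), n_freq, axis=0)
    return epoch_tensor(flat, trials, tensor.rate, window, m, max_missing_frac,
                        exclude_ec)


def participant_tfr_map(epochs: OccupancyEpochs, n_channels: int, n_freqs: int,
                        outcome: str, min_trials: int = 15) -> np.ndarray | None:
    """Frequency x time mean map for one outcome (averaged over trials and
    channels), or None when too few trials."""
    sub = epochs.for_outcome(outcome)
    if sub.shape[0] < min_trials:
        return None
    n_time = sub.shape[2]
    maps = sub.reshape(sub.shape[0], n_channels, n_freqs, n_time)
    with np.errstate(invalid="ignore"):
        return np.nanmean(maps, axis=(0, 1))


def tfr_by_outcome(maps: list[np.ndarray], q_fdr: float = 0.05,
                   min_n: int = 3) -> dict[str, np.ndarray]:
    """Group stats over participant frequency x time maps for one outcome.

    One-sample t against 0 per cell; BH-FDR across the whole map (one
    figure panel).  Cells with undefined variance are masked, not counted
    significant.
    """
    stack = np.stack(maps)  # participants x freq x time
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    ok = (n >= min_n) & (sd > 0)
    t = np.full(mean.shape, np.nan)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
    from scipy import stats as sps
    p = np.full(mean.shape, np.nan)
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), n[ok] - 1)
    sig_flat, p_adj_flat = bstats.fdr_bh(p.ravel(), q_fdr)
    return {"t": t, "p": p, "p_fdr": p_adj_flat.reshape(p.shape),
            "significant": sig_flat.reshape(p.shape), "n": n}


def participant_band_windows(epochs: OccupancyEpochs, freqs: np.ndarray,
                             n_channels: int, outcome: str,
                             bands: dict[str, tuple[float, float]] | None = None,
                             windows: dict[str, tuple[float, float]] | None = None,
                             min_trials: int = 15) -> dict[tuple[str, str], np.ndarray]:
    """Per (band, window): channel-wise mean normalised power for one outcome."""
    bands = bands if bands is not None else TFR_BANDS
    windows = windows if windows is not None else {k: WINDOWS[k] for k in ("Pre", "Stimulus")}
    sub = epochs.for_outcome(outcome)
    if sub.shape[0] < min_trials:
        return {}
    n_freq = freqs.size
    n_time = sub.shape[2]
    cube = sub.reshape(sub.shape[0], n_channels, n_freq, n_time)
    times = epochs.times
    out = {}
    for bname, (flo, fhi) in bands.items():
        fsel = (freqs >= flo) & (freqs < fhi)
        if not fsel.any():
            continue
        for wname, (lo, hi) in windows.items():
            tsel = window_mask(times, lo, hi, epochs.rate)
            with np.errstate(invalid="ignore"):
                out[(bname, wname)] = np.nanmean(cube[:, :, fsel][..., tsel],
                                                 axis=(0, 2, 3))
    return out


def band_topography(per_participant: list[dict[tuple[str, str], np.ndarray]],
                    q_fdr: float = 0.05, min_n: int = 3) -> pd.DataFrame:
    """Group t per channel for each band x window; FDR per topography."""
    from .events import group_topography

    return group_topography(per_participant, q_fdr=q_fdr, min_n=min_n)
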