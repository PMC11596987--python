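"""Filter chain, eye-closure masking and mask combination.

The chain reproduces a conventional task-EEG preparation: 40 Hz low-pass,
decimation to 250 samples/s, 0.5 Hz high-pass.  All filtering is zero-phase
so event-locked timing is preserved.  The low-pass is a windowed-design FIR
(one second of taps, applied forward-backward) — an IIR of moderate order
rolls off too slowly to serve as the anti-alias filter for the decimation —
while the high-pass is a forward-backward 4th-order Butterworth.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import Mask, Recording


def standard_filter_chain(recording: Recording, lowpass_hz: float = 40.0,
                          target_rate: float = 250.0,
                          highpass_hz: float = 0.5) -> Recording:
    """Low-pass, decimate to ``target_rate``, high-pass.

    The input rate must be an integer multiple of ``target_rate`` (plain
    decimation after the anti-alias low-pass); rates below 100 samples/s
    cannot honour the 40 Hz low-pass and raise.
    """
    if recording.rate < 100:
        raise ValueError("sampling rate too low to honour the 40 Hz low-pass")
    factor = recording.rate / target_rate
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("input rate must be an integer multiple of the target rate")
    factor = int(round(factor))

    numtaps = int(recording.rate) | 1  # ~1 s of taps; sharp yet stable
    taps = signal.firwin(numtaps, lowpass_hz, fs=recording.rate)
    data = signal.filtfilt(taps, 1.0, recording.data, axis=1)
    data = data[:, ::factor]
    sos_hp = signal.butter(4, highpass_hz, btype="high", fs=target_rate, output="sos")
    data = signal.sosfiltfilt(sos_hp, data, axis=1)
    return Recording(np.ascontiguousarray(data), target_rate,
                     list(recording.channels), recording.t0)


def closure_mask(confidence: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Eyes-closed indicator: confidence strictly below ``threshold``."""
    return np.asarray(confidence, float) < threshold


def flag_ec_trials(trials, closure: np.ndarray, rate: float,
                   stim_window: float = 0.5, fraction: float = 0.5):
    """Set ``ec_stimulus`` true where eyes were closed for more than
    ``fraction`` of the half-open stimulus window [onset, onset+stim_window).
    """
    closure = np.asarray(closure, bool)
    out = trials.copy()
    flags = []
    for onset in out["onset"].to_numpy(float):
        i0 = int(np.ceil(onset * rate))
        i1 = int(np.ceil((onset + stim_window) * rate))
        if i1 > closure.size:
            raise ValueError("closure mask does not cover all trial windows")
        win = closure[i0:i1]
        flags.append(win.mean() > fraction if win.size else False)
    out["ec_stimulus"] = np.asarray(flags, bool)
    return out


def combine_masks(mask: Mask, mode: str = "without_ec") -> np.ndarray:
    """Channel x sample exclusion mask.

    ``without_ec``: artifact OR eye closure (closures treated like artifacts,
    the default for burst analyses).  ``with_ec``: artifact only (the
    spectral control analysis is additionally run this way).
    """
    if mode == "without_ec":
        return mask.artifact | mask.closure[None, :]
    if mode == "with_ec":
        return mask.artifact.copy()
    raise ValueError(f"unknown mask mode {mode!r}")
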