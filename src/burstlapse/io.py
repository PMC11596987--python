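"""Readers/writers: EDF for raw EEG, TSV trial tables, CSV pupil traces,
npz+JSON result containers, YAML pipeline configuration.

EDF files are written with a small built-in writer (16-bit quantisation, one
data record, fixed header date so output is byte-reproducible) and read back
through :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Mask, Recording, validate_trials

# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as a minimal EDF file.

    Data are scaled per channel to the full signed 16-bit range; the header
    start date/time is fixed (files depend only on the data).
    """
    path = Path(path)
    n_ch, n_samp = recording.data.shape
    duration = n_samp / recording.rate

    phys_max_strs, scales = [], []
    for ch in range(n_ch):
        amax = float(np.max(np.abs(recording.data[ch])))
        amax = max(amax, 1e-6)
        pm = f"{amax * 1.01:.6g}"[:8]
        phys_max_strs.append(pm)
        scales.append(float(pm) / 32767.0)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(1, 8),
        _edf_field(f"{duration:.6g}"[:8], 8),
        _edf_field(n_ch, 4),
    ])
    sig = b""
    for fmt, vals in [
        ("label", recording.channels),
        ("transducer", [""] * n_ch),
        ("dim", ["uV"] * n_ch),
        ("pmin", ["-" + pm for pm in phys_max_strs]),
        ("pmax", phys_max_strs),
        ("dmin", ["-32767"] * n_ch),
        ("dmax", ["32767"] * n_ch),
        ("prefilter", [""] * n_ch),
        ("spr", [n_samp] * n_ch),
        ("reserved", [""] * n_ch),
    ]:
        width = {"label": 16, "transducer": 80, "dim": 8, "pmin": 8, "pmax": 8,
                 "dmin": 8, "dmax": 8, "prefilter": 80, "spr": 8, "reserved": 32}[fmt]
        sig += b"".join(_edf_field(v, width) for v in vals)

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for ch in range(n_ch):
            dig = np.round(recording.data[ch] / scales[ch]).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (data in microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 256:
        raise ValueError(f"{path} is not a valid EDF file (truncated header)")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as one format error
        raise ValueError(f"{path} is not a valid EDF file: {exc}") from exc
    data = raw.get_data() * 1e6  # mne loads Volts
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


# ---------------------------------------------------------------------------
# Trial tables (TSV)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6f")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated trial table and validate it.

    Outcomes are recomputed from ``rt`` and must agree with any stored
    ``outcome`` column; onsets must be strictly increasing.
    """
    from .events import classify_outcome

    trials = pd.read_csv(path, sep="\t")
    computed = np.array([classify_outcome(rt) for rt in trials["rt"]])
    if "outcome" in trials.columns:
        stored = trials["outcome"].to_numpy(str)
        if np.any(stored != computed):
            raise ValueError("stored outcome labels disagree with rt classification")
    trials["outcome"] = computed
    if "ec_stimulus" in trials.columns:
        trials["ec_stimulus"] = trials["ec_stimulus"].astype(bool)
    validate_trials(trials)
    return trials


# ---------------------------------------------------------------------------
# Pupil confidence traces (CSV)


def write_pupil(trace: pd.DataFrame, path: str | Path) -> None:
    trace[["timestamp", "confidence"]].to_csv(path, index=False, float_format="%.6f")


def read_pupil(path: str | Path) -> pd.DataFrame:
    """Read a timestamp/confidence CSV; confidence clipped into [0, 1]."""
    trace = pd.read_csv(path)
    if not {"timestamp", "confidence"}.issubset(trace.columns):
        raise ValueError("pupil CSV needs 'timestamp' and 'confidence' columns")
    trace = trace.copy()
    trace["confidence"] = trace["confidence"].clip(0.0, 1.0)
    return trace


def resample_confidence(trace: pd.DataFrame, rate: float, n_samples: int,
                        t0: float = 0.0) -> np.ndarray:
    """Align a (possibly irregular) confidence trace to EEG sample times.

    Each EEG sample takes the confidence of the nearest trace timestamp.
    Raises if the trace does not overlap the recording at all.
    """
    ts = trace["timestamp"].to_numpy(float)
    conf = trace["confidence"].to_numpy(float)
    order = np.argsort(ts)
    ts, conf = ts[order], conf[order]
    t = t0 + np.arange(n_samples) / rate
    if ts[-1] < t[0] or ts[0] > t[-1]:
        raise ValueError("pupil trace does not overlap the recording")
    idx = np.searchsorted(ts, t)
    idx = np.clip(idx, 1, len(ts) - 1)
    left, right = ts[idx - 1], ts[idx]
    use_left = (t - left) <= (right - t)
    return np.where(use_left, conf[idx - 1], conf[idx])


# ---------------------------------------------------------------------------
# Result containers: named arrays in one .npz + JSON metadata sidecar


def save_container(path: str | Path, arrays: dict[str, np.ndarray],
                   meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta or {}, fh, indent=1, sort_keys=True)


def load_container(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    path = Path(path)
    with np.load(path, allow_pickle=False) as npz:
        arrays = {k: npz[k] for k in npz.files}
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arrays, meta


# ---------------------------------------------------------------------------
# ground truth (JSON)


def write_truth(ground_truth, path: str | Path) -> None:
    """Serialise simulator ground truth (events, closures, artifacts) to JSON."""
    payload = {
        "bursts": ground_truth.bursts.to_dict(orient="list"),
        "closures": np.asarray(ground_truth.closures, float).tolist(),
        "artifacts": np.asarray(ground_truth.artifacts, float).tolist(),
    }
    if ground_truth.trial_latent is not None:
        latent = ground_truth.trial_latent.copy()
        latent["ec"] = latent["ec"].astype(int)
        payload["trial_latent"] = latent.to_dict(orient="list")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path):
    from .synth import GroundTruth

    payload = json.loads(Path(path).read_text())
    latent = None
    if "trial_latent" in payload:
        latent = pd.DataFrame(payload["trial_latent"])
        latent["ec"] = latent["ec"].astype(bool)
    return GroundTruth(
        bursts=pd.DataFrame(payload["bursts"]),
        closures=np.asarray(payload["closures"], float).reshape(-1, 2),
        artifacts=np.asarray(payload["artifacts"], float).reshape(-1, 2),
        trial_latent=latent,
    )


# ---------------------------------------------------------------------------
# YAML configuration


def default_config() -> dict:
    """Full default parameter set for the pipeline (YAML-overridable)."""
    from .synth import SimConfig

    return {
        "simulate": SimConfig().to_dict(),
        "preprocess": {
            "lowpass_hz": 40.0,
            "target_rate": 250.0,
            "highpass_hz": 0.5,
            "ec_confidence_threshold": 0.5,
            "ec_trial_fraction": 0.5,
            "stim_window": 0.5,
        },
        "bursts": {
            "min_cycles": 4,
            "monotonicity": 0.6,
            "period_consistency": 0.5,
            "amplitude_consistency": 0.2,
            "amp_factor": 1.4,
            "amp_peak_factor": 4.0,
            "band_low": 2.0,
            "band_high": 16.0,
            "band_width": 4.0,
            "band_step": 1.0,
        },
        "epochs": {
            "window": [-2.0, 4.0],
            "max_missing_frac": 0.5,
            "min_clean_trials": 15,
            "max_gap_frac": 0.2,
            "min_trials": 15,
            "smooth_span_s": 0.2,
        },
        "quantiles": {"k": 10, "window": [-1.0, 0.0], "per_trial_max": False},
        "tfr": {"fmin": 1.0, "fmax": 35.0, "fstep": 1.0,
                "cycles_min": 3.0, "cycles_max": 15.0},
        "stats": {"q_fdr": 0.05},
    }


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, merged (section-wise) over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section in cfg and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg
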