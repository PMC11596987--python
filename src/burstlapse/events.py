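"""Trial outcomes, event-locked epoching and group-level burst statistics.

The central quantity is *occupancy*: at each sample, which channels are
inside a burst (or an eye closure).  Occupancy is epoched around stimulus
onsets into a trial x channel x time tensor with explicit missingness
(artifact/closure samples), reduced per participant into z-scored,
outcome-resolved time courses or window topographies, and tested at the
group level with one-sample t-tests and BH-FDR within the analysis family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as bstats


def _nanmean(a: np.ndarray, axis) -> np.ndarray:
    """nanmean that returns NaN for all-NaN slices without warnings."""
    cnt = np.sum(~np.isnan(a), axis=axis)
    tot = np.nansum(a, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tot / cnt
    return np.where(cnt > 0, out, np.nan)

#: analysis windows in seconds relative to stimulus onset (half-open)
WINDOWS: dict[str, tuple[float, float]] = {
    "Pre": (-2.0, 0.0),
    "Stimulus": (0.0, 0.3),
    "Response": (0.3, 1.0),
    "Post": (2.0, 4.0),
}

EPOCH_WINDOW = (-2.0, 4.0)


def window_mask(times: np.ndarray, lo: float, hi: float, rate: float) -> np.ndarray:
    """Half-open window [lo, hi) on a sampled time axis.

    A half-sample tolerance guards the boundary sample against the
    floating-point drift of ``t0 + k / rate`` time axes.
    """
    tol = 0.5 / rate
    return (times >= lo - tol) & (times < hi - tol)


def classify_outcome(rt: float | None) -> str:
    """Trial outcome from the reaction time.

    <0.1 s: false alarm; [0.1, 0.5) s: fast; [0.5, 1) s: slow; absent or
    >=1 s: lapse.
    """
    if rt is None or (isinstance(rt, float) and np.isnan(rt)):
        return "lapse"
    if rt < 0:
        raise ValueError("reaction time cannot be negative")
    if rt < 0.1:
        return "falsealarm"
    if rt < 0.5:
        return "fast"
    if rt < 1.0:
        return "slow"
    return "lapse"


@dataclass
class OccupancyEpochs:
    """Event-locked tensor (trial x row x time) with NaN as missingness.

    Rows are channels for occupancy data (or a single row for the closure
    indicator); values are 0/1 occupancy or arbitrary floats (spectral
    power).  ``outcomes`` aligns with the first axis.
    """

    data: np.ndarray
    outcomes: np.ndarray
    rate: float
    window: tuple[float, float] = EPOCH_WINDOW
    trial_index: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[2]) / self.rate

    def for_outcome(self, outcome: str) -> np.ndarray:
        return self.data[self.outcomes == outcome]


def epoch_tensor(values: np.ndarray, trials: pd.DataFrame, rate: float,
                 window: tuple[float, float] = EPOCH_WINDOW,
                 mask: np.ndarray | None = None,
                 max_missing_frac: float = 0.5,
                 exclude_ec: bool = True) -> OccupancyEpochs:
    """Epoch a row x sample array around stimulus onsets.

    Masked samples become NaN; trials with more than ``max_missing_frac``
    missing data are dropped, as are false-alarm trials, trials whose window
    exceeds the recording, and (for burst analyses) eye-closure trials.
    """
    values = np.asarray(values, float)
    if values.ndim != 2:
        raise ValueError("values must be rows x samples")
    n_rows, n_samp = values.shape
    n_time = int(round((window[1] - window[0]) * rate))

    keep_rows, outcomes, kept_idx = [], [], []
    for ti, row in enumerate(trials.itertuples()):
        if row.outcome == "falsealarm":
            continue
        if exclude_ec and bool(getattr(row, "ec_stimulus", False)):
            continue
        i0 = int(round((row.onset + window[0]) * rate))
        if i0 < 0 or i0 + n_time > n_samp:
            continue
        seg = values[:, i0:i0 + n_time].copy()
        if mask is not None:
            m = mask[:, i0:i0 + n_time]
            seg[m] = np.nan
        if np.isnan(seg).mean() > max_missing_frac:
            continue
        keep_rows.append(seg)
        outcomes.append(row.outcome)
        kept_idx.append(ti)

    data = np.stack(keep_rows) if keep_rows else np.empty((0, n_rows, n_time))
    return OccupancyEpochs(data, np.asarray(outcomes, dtype=object), rate, window,
                           np.asarray(kept_idx, int))


def concatenate_epochs(parts: list[OccupancyEpochs]) -> OccupancyEpochs:
    """Pool epochs across the recordings of one session block."""
    parts = [p for p in parts if p.data.shape[0] > 0]
    if not parts:
        raise ValueError("no epochs to concatenate")
    ref = parts[0]
    data = np.concatenate([p.data for p in parts], axis=0)
    outcomes = np.concatenate([p.outcomes for p in parts])
    return OccupancyEpochs(data, outcomes, ref.rate, ref.window, None)


# ---------------------------------------------------------------------------
# session normalisation statistics


def channel_proportion(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-sample proportion of (unmasked) rows that are inside a burst."""
    v = np.asarray(values, float)
    if mask is not None:
        v = np.where(mask, np.nan, v)
    return _nanmean(v, axis=0)


def session_proportion_stats(values_per_run: list[np.ndarray],
                             masks: list[np.ndarray] | None = None) -> tuple[float, float]:
    """Mean and SD of the channel proportion over an entire session block."""
    series = []
    for i, v in enumerate(values_per_run):
        m = masks[i] if masks is not None else None
        series.append(channel_proportion(v, m))
    pooled = np.concatenate(series)
    return float(np.nanmean(pooled)), float(np.nanstd(pooled))


def session_channel_means(values_per_run: list[np.ndarray],
                          masks: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-channel mean occupancy over the session block (topography reference)."""
    num = None
    for i, v in enumerate(values_per_run):
        v = np.asarray(v, float)
        if masks is not None:
            v = np.where(masks[i], np.nan, v)
        s = np.nansum(v, axis=1)
        c = np.sum(~np.isnan(v), axis=1)
        if num is None:
            num, cnt = s, c
        else:
            num, cnt = num + s, cnt + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / cnt


# ---------------------------------------------------------------------------
# participant-level reductions


def participant_timecourse(epochs: OccupancyEpochs, session_mean: float,
                           session_sd: float, min_clean_trials: int = 15,
                           max_gap_frac: float = 0.2,
                           min_trials: int = 15) -> dict[str, np.ndarray | None]:
    """Outcome-resolved z time courses for one participant.

    Per time point: the trial average of the proportion of non-missing
    channels with a burst, z-scored by the session-block mean/SD.  Time
    points with fewer than ``min_clean_trials`` clean trials are linearly
    interpolated from their neighbours; an outcome is dropped (None) when
    such gaps exceed ``max_gap_frac`` of the window or when fewer than
    ``min_trials`` trials survive epoching.
    """
    if session_sd <= 0:
        raise ValueError("session SD must be positive for z-scoring")
    out: dict[str, np.ndarray | None] = {}
    for outcome in ("fast", "slow", "lapse"):
        sub = epochs.for_outcome(outcome)
        if sub.shape[0] < min_trials:
            out[outcome] = None
            continue
        prop = _nanmean(sub, axis=1)               # trial x time
        clean = np.sum(~np.isnan(prop), axis=0)
        series = _nanmean(prop, axis=0)
        low = clean < min_clean_trials
        if low.mean() > max_gap_frac:
            out[outcome] = None
            continue
        if low.any():
            good = np.flatnonzero(~low)
            if good.size == 0:
                out[outcome] = None
                continue
            series[low] = np.interp(np.flatnonzero(low), good, series[good])
        out[outcome] = (series - session_mean) / session_sd
    return out


def smooth_timecourse(series: np.ndarray, rate: float, span: float = 0.2) -> np.ndarray:
    """Lowess smoothing over a ``span``-second window (display convention)."""
    if span <= 0:
        raise ValueError("span must be positive")
    return bstats.lowess(series, x_span=span * rate)


def group_timecourse_stats(z_by_outcome: dict[str, np.ndarray], rate: float,
                           window: tuple[float, float] = EPOCH_WINDOW,
                           q_fdr: float = 0.05, min_n: int = 3) -> pd.DataFrame:
    """Group one-sample t-tests of the z time courses against 0.

    ``z_by_outcome`` maps outcome -> participants x time array (excluded
    participants simply absent from the rows).  The BH-FDR family is all
    time points of all outcomes passed in together (one figure).
    """
    from scipy import stats as sps

    frames = []
    for outcome, z in z_by_outcome.items():
        z = np.asarray(z, float)
        if z.ndim != 2:
            raise ValueError("z time courses must be participants x time")
        times = window[0] + np.arange(z.shape[1]) / rate
        n = np.sum(~np.isnan(z), axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(z, axis=0)
            sd = np.nanstd(z, axis=0, ddof=1)
        ok = (n >= min_n) & (sd > 0)
        t = np.full(z.shape[1], np.nan)
        p = np.full(z.shape[1], np.nan)
        g = np.full(z.shape[1], np.nan)
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(n[ok]))
        p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), n[ok] - 1)
        j = 1.0 - 3.0 / (4.0 * (n[ok] - 1) - 1.0)
        g[ok] = mean[ok] / sd[ok] * j
        frames.append(pd.DataFrame({"outcome": outcome, "time": times, "t": t,
                                    "p": p, "g": g, "n": n}))
    df = pd.concat(frames, ignore_index=True)
    sig, p_adj = bstats.fdr_bh(df["p"].to_numpy(), q_fdr)
    df["p_fdr"] = p_adj
    df["significant"] = sig
    return df


def participant_topography(epochs: OccupancyEpochs, session_channel_mean: np.ndarray,
                           windows: dict[str, tuple[float, float]] | None = None,
                           min_trials: int = 15) -> dict[tuple[str, str], np.ndarray]:
    """Per (window, outcome): channel-wise burst proportion minus the session
    channel average, for one participant.  Outcomes with fewer than
    ``min_trials`` epochs are omitted."""
    windows = windows if windows is not None else WINDOWS
    t = epochs.times
    out = {}
    for outcome in ("fast", "slow", "lapse"):
        sub = epochs.for_outcome(outcome)
        if sub.shape[0] < min_trials:
            continue
        for wname, (lo, hi) in windows.items():
            cols = window_mask(t, lo, hi, epochs.rate)
            prop = _nanmean(sub[:, :, cols], axis=(0, 2))
            out[(wname, outcome)] = prop - session_channel_mean
    return out


def group_topography(per_participant: list[dict[tuple[str, str], np.ndarray]],
                     q_fdr: float = 0.05, min_n: int = 3) -> pd.DataFrame:
    """Group t-test per channel; FDR applied within each topography
    (window x outcome) separately, as each is its own display."""
    keys = sorted({k for d in per_participant for k in d})
    records = []
    for key in keys:
        rows = np.stack([d[key] for d in per_participant if key in d])
        n_ch = rows.shape[1]
        tvals = np.full(n_ch, np.nan)
        pvals = np.full(n_ch, np.nan)
        gvals = np.full(n_ch, np.nan)
        ns = np.zeros(n_ch, int)
        for ch in range(n_ch):
            col = rows[:, ch]
            col = col[~np.isnan(col)]
            ns[ch] = col.size
            if col.size < min_n or col.std(ddof=1) == 0:
                continue
            r = bstats.one_sample_t(col)
            tvals[ch], pvals[ch], gvals[ch] = r.t, r.p, r.g
        sig, p_adj = bstats.fdr_bh(pvals, q_fdr)
        for ch in range(n_ch):
            records.append((key[0], key[1], ch, tvals[ch], pvals[ch], p_adj[ch],
                            bool(sig[ch]), gvals[ch], ns[ch]))
    return pd.DataFrame(records, columns=["window", "outcome", "channel", "t", "p",
                                          "p_fdr", "significant", "g", "n"])


# ---------------------------------------------------------------------------
# behaviour tabulations


def ec_lapse_fraction_by_threshold(trials: pd.DataFrame,
                                   thresholds: np.ndarray) -> np.ndarray:
    """Fraction of lapses that are eye-closure lapses, as the reaction-time
    threshold defining a lapse varies (PVT-style: lapse = rt > threshold or
    no response)."""
    thresholds = np.asarray(thresholds, float)
    if thresholds.size > 1 and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    rt = trials["rt"].to_numpy(float)
    ec = trials["ec_stimulus"].to_numpy(bool)
    out = np.full(thresholds.size, np.nan)
    for i, th in enumerate(thresholds):
        is_lapse = np.isnan(rt) | (rt > th)
        if is_lapse.any():
            out[i] = ec[is_lapse].mean()
    return out


def lapse_by_distance_quantiles(trials: pd.DataFrame, k: int = 6,
                                eo_only: bool = True) -> pd.DataFrame:
    """Lapse percentage per stimulus-distance quantile (1 = closest).

    Equal-count bins by radial distance; ties broken by stable input order.
    """
    from .quantiles import equal_count_bins

    sub = trials[trials["outcome"] != "falsealarm"]
    if eo_only:
        sub = sub[~sub["ec_stimulus"].astype(bool)]
    if len(sub) < k:
        raise ValueError(f"need at least {k} trials for {k} quantiles")
    dist = sub["distance"].to_numpy(float)
    lapse = (sub["outcome"] == "lapse").to_numpy()
    bins = equal_count_bins(dist, k)
    records = []
    for b in range(k):
        sel = bins == b
        records.append((b + 1, int(sel.sum()), 100.0 * lapse[sel].mean(),
                        float(dist[sel].mean())))
    return pd.DataFrame(records, columns=["quantile", "n", "lapse_pct", "mean_distance"])
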