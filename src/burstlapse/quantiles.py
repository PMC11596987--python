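"""Pre-stimulus burst-amplitude quantiles vs lapse probability.

For each trial, every burst overlapping the second before stimulus onset is
one record carrying the mean amplitude of its cycles inside that window and
the trial's outcome.  Records are binned into equal-count amplitude
quantiles within the session block; the per-quantile lapse proportion is
z-scored per participant and all quantile pairs are compared with paired
t-tests under BH-FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as bstats
from .bursts import Burst

PRESTIM_WINDOW = (-1.0, 0.0)


def equal_count_bins(values: np.ndarray, k: int) -> np.ndarray:
    """Assign values to k equal-count bins (0..k-1) by ascending value.

    Bin sizes differ by at most one; ties are broken by stable input order.
    """
    values = np.asarray(values, float)
    n = values.size
    if n < k:
        raise ValueError(f"need at least {k} values for {k} bins")
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, int)
    bins[order] = (np.arange(n) * k) // n
    return bins


def prestim_burst_amplitudes(bursts: list[Burst], trials: pd.DataFrame,
                             window: tuple[float, float] = PRESTIM_WINDOW,
                             ) -> pd.DataFrame:
    """One record per (burst x trial window) intersection.

    A burst contributes when its span overlaps [onset+window0, onset+window1);
    its amplitude is the mean over cycles whose (trough) peak lies inside the
    window — when cycle times are unavailable the burst mean amplitude is
    used.  Eye-closure and false-alarm trials are excluded.
    """
    rows = []
    sub = trials[(trials["outcome"] != "falsealarm")
                 & (~trials["ec_stimulus"].astype(bool))]
    starts = np.array([b.start for b in bursts])
    ends = np.array([b.end for b in bursts])
    for ti, row in zip(sub.index, sub.itertuples()):
        lo, hi = row.onset + window[0], row.onset + window[1]
        hits = np.flatnonzero((starts < hi) & (ends > lo)) if len(bursts) else []
        for bi in hits:
            b = bursts[bi]
            if b.cycle_times.size:
                inside = (b.cycle_times >= lo) & (b.cycle_times < hi)
                if not inside.any():
                    continue
                amp = float(b.cycle_amps[inside].mean())
            else:
                amp = b.mean_amplitude
            rows.append((ti, bi, b.band, amp, row.outcome == "lapse"))
    return pd.DataFrame(rows, columns=["trial", "burst", "band", "amplitude", "lapse"])


def prestim_records_from_events(events: pd.DataFrame, trials: pd.DataFrame,
                                window: tuple[float, float] = PRESTIM_WINDOW,
                                ) -> pd.DataFrame:
    """Same record table built from simulator ground-truth events."""
    rows = []
    sub = trials[(trials["outcome"] != "falsealarm")
                 & (~trials["ec_stimulus"].astype(bool))]
    starts = events["start"].to_numpy(float)
    ends = events["end"].to_numpy(float)
    for ti, row in zip(sub.index, sub.itertuples()):
        lo, hi = row.onset + window[0], row.onset + window[1]
        for bi in np.flatnonzero((starts < hi) & (ends > lo)):
            rows.append((ti, bi, events["band"].iat[bi],
                         float(events["amplitude"].iat[bi]), row.outcome == "lapse"))
    return pd.DataFrame(rows, columns=["trial", "burst", "band", "amplitude", "lapse"])


def quantile_lapse_curve(records: pd.DataFrame, k: int = 10,
                         per_trial_max: bool = False) -> pd.DataFrame:
    """Per-quantile lapse proportion for one participant's session block.

    Records are sorted into ``k`` equal-count amplitude quantiles; each
    quantile's lapse proportion is the fraction of its records whose trial
    lapsed; the k values are then z-scored for the participant.  With
    ``per_trial_max`` a trial contributes only its largest-amplitude burst.

    Raises ValueError with fewer than ``k`` records (participant excluded).
    """
    if per_trial_max and len(records):
        idx = records.groupby("trial")["amplitude"].idxmax()
        records = records.loc[idx]
    if len(records) < k:
        raise ValueError(f"fewer than {k} burst records; participant excluded")
    amps = records["amplitude"].to_numpy(float)
    lapse = records["lapse"].to_numpy(bool)
    bins = equal_count_bins(amps, k)
    prop = np.array([lapse[bins == b].mean() for b in range(k)])
    mean_amp = np.array([amps[bins == b].mean() for b in range(k)])
    sd = prop.std()
    z = (prop - prop.mean()) / sd if sd > 0 else np.zeros(k)
    return pd.DataFrame({"quantile": np.arange(1, k + 1), "mean_amplitude": mean_amp,
                         "lapse_proportion": prop, "z": z,
                         "n_records": np.bincount(bins, minlength=k)})


def quantile_pair_tests(curves: list[pd.DataFrame], q_fdr: float = 0.05,
                        value: str = "z") -> pd.DataFrame:
    """Paired t-tests between all quantile pairs across participants.

    ``curves`` holds one quantile curve per participant; the BH-FDR family is
    the k(k-1)/2 pairs of one panel (band x condition).
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 participants")
    mat = np.stack([c[value].to_numpy(float) for c in curves])  # part x k
    k = mat.shape[1]
    records = []
    for i in range(k):
        for j in range(i + 1, k):
            r = bstats.paired_t(mat[:, j], mat[:, i])
            records.append((i + 1, j + 1, r.t, r.p, r.g, r.n))
    df = pd.DataFrame(records, columns=["q_low", "q_high", "t", "p", "g", "n"])
    sig, p_adj = bstats.fdr_bh(df["p"].to_numpy(), q_fdr)
    df["p_fdr"] = p_adj
    df["significant"] = sig
    return df
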