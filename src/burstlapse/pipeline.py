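"""Per-participant and group-level drivers composing the analysis stages.

These functions wire together masking, epoching, session normalisation and
the group statistics for one session block (one participant/condition) and
across participants.  They accept occupancy matrices from either the burst
detector or simulator ground truth, so every stage downstream of detection
can be exercised independently of it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import events, quantiles as qmod
from .containers import SessionBlock
from .preprocess import combine_masks


def participant_timecourse_analysis(block: SessionBlock, occs: list[np.ndarray],
                                    window: tuple[float, float] = events.EPOCH_WINDOW,
                                    min_clean_trials: int = 15,
                                    max_gap_frac: float = 0.2,
                                    min_trials: int = 15,
                                    max_missing_frac: float = 0.5,
                                    ) -> dict[str, np.ndarray | None]:
    """Outcome-resolved z time courses of burst occupancy for one block.

    ``occs`` holds one boolean channel x sample matrix per recording of the
    block.  Eye-closure samples are excluded like artifacts, eye-closure
    trials are dropped, and the z reference is the session-block mean/SD of
    the channel proportion.
    """
    masks = [combine_masks(m, "without_ec") for m in block.masks]
    mean, sd = events.session_proportion_stats(occs, masks)
    if sd <= 0:
        return {o: None for o in ("fast", "slow", "lapse")}
    parts = [events.epoch_tensor(occ.astype(float), tr, block.rate, window, m,
                                 max_missing_frac, exclude_ec=True)
             for occ, tr, m in zip(occs, block.trials, masks)]
    epochs = events.concatenate_epochs(parts)
    return events.participant_timecourse(epochs, mean, sd, min_clean_trials,
                                         max_gap_frac, min_trials)


def participant_topography_analysis(block: SessionBlock, occs: list[np.ndarray],
                                    window: tuple[float, float] = events.EPOCH_WINDOW,
                                    min_trials: int = 15,
                                    ) -> dict[tuple[str, str], np.ndarray]:
    """Per (window, outcome) channel-wise occupancy deviations for one block."""
    masks = [combine_masks(m, "without_ec") for m in block.masks]
    chan_mean = events.session_channel_means(occs, masks)
    parts = [events.epoch_tensor(occ.astype(float), tr, block.rate, window, m,
                                 exclude_ec=True)
             for occ, tr, m in zip(occs, block.trials, masks)]
    epochs = events.concatenate_epochs(parts)
    return events.participant_topography(epochs, chan_mean, min_trials=min_trials)


def participant_quantile_curve(records: pd.DataFrame, band: str | None = None,
                               k: int = 10, per_trial_max: bool = False,
                               ) -> pd.DataFrame | None:
    """Quantile curve for one participant, or None when under-populated."""
    if band is not None:
        records = records[records["band"] == band]
    try:
        return qmod.quantile_lapse_curve(records, k=k, per_trial_max=per_trial_max)
    except ValueError:
        return None


def stack_timecourses(per_participant: list[dict[str, np.ndarray | None]],
                      ) -> dict[str, np.ndarray]:
    """Collect per-outcome z matrices (participants x time), dropping excluded
    participants per outcome."""
    out: dict[str, np.ndarray] = {}
    for outcome in ("fast", "slow", "lapse"):
        rows = [d[outcome] for d in per_participant if d.get(outcome) is not None]
        if rows:
            out[outcome] = np.stack(rows)
    return out


def group_timecourse(per_participant: list[dict[str, np.ndarray | None]],
                     rate: float, window: tuple[float, float] = events.EPOCH_WINDOW,
                     q_fdr: float = 0.05) -> pd.DataFrame:
    z_by_outcome = stack_timecourses(per_participant)
    if not z_by_outcome:
        raise ValueError("no participant time courses survive the inclusion rules")
    return events.group_timecourse_stats(z_by_outcome, rate, window, q_fdr)
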