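import numpy as np
import pandas as pd
import pytest

from burstlapse import events
from burstlapse.events import (OccupancyEpochs, classify_outcome,
                               ec_lapse_fraction_by_threshold, epoch_tensor,
                               group_timecourse_stats, group_topography,
                               lapse_by_distance_quantiles,
                               participant_timecourse, participant_topography,
                               session_proportion_stats, smooth_timecourse)


class TestClassifyOutcome:
    @pytest.mark.parametrize("rt,expected", [
        (0.3, "fast"), (0.7, "slow"), (None, "lapse"), (np.nan, "lapse"),
        (0.05, "falsealarm"), (0.1, "fast"), (0.5, "slow"), (1.0, "lapse"),
        (1.7, "lapse"), (0.0, "falsealarm"),
    ])
    def test_boundaries(self, rt, expected):
        assert classify_outcome(rt) == expected

    def test_negative_rt_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(-0.1)


def _trials(onsets, rts, ec=None):
    n = len(onsets)
    return pd.DataFrame({
        "onset": onsets, "rt": rts,
        "outcome": [classify_outcome(r) for r in rts],
        "ec_stimulus": ec if ec is not None else [False] * n,
        "distance": np.linspace(0.1, 0.9, n),
    })


class TestEpochTensor:
    RATE = 250.0

    def _values(self, rng, n_ch=3, dur=60.0):
        return (rng.uniform(size=(n_ch, int(dur * self.RATE))) < 0.2)

    def test_trial_inside_artifact_dropped(self, rng):
        values = self._values(rng)
        mask = np.zeros_like(values, dtype=bool)
        mask[:, int(8 * self.RATE):int(25 * self.RATE)] = True
        ep = epoch_tensor(values, _trials([12.0, 40.0], [0.3, 0.4]), self.RATE,
                          mask=mask)
        assert ep.data.shape[0] == 1  # only the clean trial survives

    def test_partial_missingness_retained(self, rng):
        values = self._values(rng)
        mask = np.zeros_like(values, dtype=bool)
        # 40 % of the [-2, 4] window of a trial at 20 s: 2.4 s
        mask[:, int(18.0 * self.RATE):int(20.4 * self.RATE)] = True
        ep = epoch_tensor(values, _trials([20.0], [0.3]), self.RATE, mask=mask)
        assert ep.data.shape[0] == 1
        assert np.isnan(ep.data).mean() == pytest.approx(0.4, abs=0.01)

    def test_falsealarm_and_ec_excluded(self, rng):
        values = self._values(rng)
        trials = _trials([10.0, 20.0, 30.0], [0.05, 0.3, 0.4],
                         ec=[False, False, True])
        ep = epoch_tensor(values, trials, self.RATE)
        assert list(ep.outcomes) == ["fast"]

    def test_window_outside_recording_dropped(self, rng):
        values = self._values(rng, dur=20.0)
        ep = epoch_tensor(values, _trials([1.0, 10.0, 19.0], [0.3] * 3), self.RATE)
        assert ep.data.shape[0] == 1

    def test_retention_matches_brute_force(self, rng):
        rate = 50.0
        values = rng.uniform(size=(2, int(60 * rate))) < 0.3
        for _ in range(100):
            mask = rng.uniform(size=values.shape) < rng.uniform(0.2, 0.7)
            onset = float(rng.uniform(3.0, 55.0))
            ep = epoch_tensor(values, _trials([onset], [0.3]), rate, mask=mask)
            i0 = int(round((onset - 2.0) * rate))
            frac = mask[:, i0:i0 + int(6 * rate)].mean()
            assert (ep.data.shape[0] == 1) == (frac <= 0.5)


class TestParticipantTimecourse:
    def _epochs(self, data, outcomes, rate=250.0):
        return OccupancyEpochs(data, np.asarray(outcomes, dtype=object), rate)

    def test_session_mean_occupancy_gives_zero_z(self):
        data = np.full((20, 3, 1500), 0.3)
        ep = self._epochs(data, ["fast"] * 20)
        out = participant_timecourse(ep, session_mean=0.3, session_sd=0.1)
        assert out["fast"] == pytest.approx(np.zeros(1500))

    def test_toy_hand_computation(self):
        # 2 channels, 16 trials, 4 time points; one trial has channel 0 bursting
        data = np.zeros((16, 2, 4))
        data[0, 0, :] = 1.0  # proportion 0.5 at every time for that trial
        ep = OccupancyEpochs(data, np.asarray(["lapse"] * 16, dtype=object), 250.0,
                             window=(0.0, 4 / 250.0))
        out = participant_timecourse(ep, session_mean=0.1, session_sd=0.2,
                                     min_clean_trials=1, min_trials=10)
        expected = (0.5 / 16 - 0.1) / 0.2
        assert out["lapse"] == pytest.approx(np.full(4, expected))

    def test_low_trial_count_excluded(self):
        data = np.zeros((5, 2, 10))
        ep = self._epochs(data, ["fast"] * 5)
        out = participant_timecourse(ep, 0.1, 0.2, min_trials=15)
        assert out["fast"] is None

    def test_gap_rule_excludes_outcome(self, rng):
        # 21 % of time points have < 15 clean trials -> outcome dropped
        data = np.zeros((20, 2, 100))
        data[:10, :, :21] = np.nan  # 21 points have only 10 clean trials
        ep = self._epochs(data, ["slow"] * 20)
        out = participant_timecourse(ep, 0.1, 0.2, min_clean_trials=15,
                                     max_gap_frac=0.2)
        assert out["slow"] is None

    def test_gap_interpolated_when_small(self):
        data = np.zeros((20, 2, 100))
        data[:10, :, 50:60] = np.nan  # 10 % of points low-n
        data[:, :, :] += 0.2
        ep = self._epochs(data, ["slow"] * 20)
        out = participant_timecourse(ep, 0.0, 1.0, min_clean_trials=15,
                                     max_gap_frac=0.2)
        assert out["slow"] is not None
        assert np.isfinite(out["slow"]).all()


def test_session_stats_z_invariant(rng):
    """z-scoring the session's own proportion series gives mean 0, SD 1."""
    occ = rng.uniform(size=(8, 5000)) < 0.15
    mean, sd = session_proportion_stats([occ])
    series = occ.mean(axis=0)
    z = (series - mean) / sd
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0, abs=1e-12)


class TestSmoothTimecourse:
    def test_constant_unchanged(self):
        y = np.full(200, 1.5)
        assert smooth_timecourse(y, 250.0, span=0.2) == pytest.approx(y)

    def test_linear_interior_unchanged(self):
        y = np.linspace(0, 1, 500)
        sm = smooth_timecourse(y, 250.0, span=0.2)
        assert sm[60:-60] == pytest.approx(y[60:-60], abs=1e-6)

    def test_step_becomes_monotone(self):
        y = np.concatenate([np.zeros(100), np.ones(100)])
        sm = smooth_timecourse(y, 250.0, span=0.2)
        assert np.all(np.diff(sm) >= -1e-9)
        assert sm[0] == pytest.approx(0, abs=1e-6)
        assert sm[-1] == pytest.approx(1, abs=1e-6)


class TestGroupTimecourse:
    def test_null_input_nothing_significant(self):
        z = {"fast": np.zeros((6, 50))}
        df = group_timecourse_stats(z, 250.0)
        assert not df["significant"].any()

    def test_consistent_offset_everywhere_significant(self, rng):
        z = {"fast": 1.0 + 0.01 * rng.standard_normal((8, 50))}
        df = group_timecourse_stats(z, 250.0)
        assert df["significant"].all()

    def test_fdr_at_least_raw_p(self, rng):
        z = {"fast": rng.standard_normal((8, 100))}
        df = group_timecourse_stats(z, 250.0)
        ok = df["p"].notna()
        assert (df.loc[ok, "p_fdr"] >= df.loc[ok, "p"] - 1e-12).all()


class TestTopography:
    def _epochs(self, data, outcomes):
        return OccupancyEpochs(data, np.asarray(outcomes, dtype=object), 250.0)

    def test_session_average_occupancy_near_zero_t(self, rng):
        per_part = []
        for _ in range(8):
            data = (rng.uniform(size=(20, 4, 1500)) < 0.2).astype(float)
            ep = self._epochs(data, ["fast"] * 20)
            per_part.append(participant_topography(ep, np.full(4, 0.2)))
        df = group_topography(per_part)
        assert not df["significant"].any()

    def test_single_channel_surplus_flagged(self, rng):
        per_part = []
        for _ in range(8):
            data = (rng.uniform(size=(20, 4, 1500)) < 0.2).astype(float)
            data[:, 2, :] = (rng.uniform(size=(20, 1500)) < 0.5).astype(float)
            ep = self._epochs(data, ["fast"] * 20)
            per_part.append(participant_topography(ep, np.full(4, 0.2)))
        df = group_topography(per_part)
        pre = df[(df["window"] == "Pre") & (df["outcome"] == "fast")]
        assert pre.set_index("channel")["significant"][2]
        assert pre[pre.channel != 2]["significant"].mean() <= 0.34

    def test_window_boundary_half_open(self):
        # occupancy only at exactly t = 0.3 s -> belongs to Response, not Stimulus
        data = np.zeros((16, 1, 1500))
        idx = int(round((0.3 - (-2.0)) * 250))
        data[:, 0, idx] = 1.0
        ep = self._epochs(data, ["fast"] * 16)
        topo = participant_topography(ep, np.zeros(1))
        assert topo[("Response", "fast")][0] > 0
        assert topo[("Stimulus", "fast")][0] == pytest.approx(0.0)


class TestBehaviourOps:
    def test_ec_fraction_extremes(self):
        t = _trials([1.0, 2.0, 3.0], [np.nan, 0.8, 0.3])
        assert ec_lapse_fraction_by_threshold(t, np.array([0.5]))[0] == 0.0
        t_ec = _trials([1.0, 2.0], [np.nan, np.nan], ec=[True, True])
        assert ec_lapse_fraction_by_threshold(t_ec, np.array([0.5]))[0] == 1.0

    def test_matches_brute_force(self, rng):
        n = 200
        rts = np.where(rng.uniform(size=n) < 0.3, np.nan, rng.uniform(0.1, 1.2, n))
        t = _trials(np.arange(n) * 5.0 + 2.0, rts,
                    ec=list(rng.uniform(size=n) < 0.4))
        thresholds = np.array([0.3, 0.5, 0.7, 0.9])
        out = ec_lapse_fraction_by_threshold(t, thresholds)
        for th, got in zip(thresholds, out):
            lapse = np.isnan(rts) | (rts > th)
            assert got == pytest.approx(t.loc[lapse, "ec_stimulus"].mean())

    def test_thresholds_must_ascend(self):
        t = _trials([1.0], [0.3])
        with pytest.raises(ValueError):
            ec_lapse_fraction_by_threshold(t, np.array([0.5, 0.4]))

    def test_distance_quantiles_twelve_trials(self):
        t = _trials(np.arange(12) * 5.0 + 2.0, [0.3] * 12)
        df = lapse_by_distance_quantiles(t, k=6)
        assert df["n"].tolist() == [2] * 6
        assert df["lapse_pct"].tolist() == [0.0] * 6

    def test_distance_coupling_monotone_in_expectation(self):
        from burstlapse.synth import SimConfig, simulate_run
        cfg = SimConfig(duration=4000.0, n_channels=2, burst_rate=0.0,
                        closure_rate=0.0, beta_dist=2.5, beta0=-2.5, seed=21)
        run = simulate_run(cfg, waveforms=False)
        df = lapse_by_distance_quantiles(run.trials, k=6)
        from scipy.stats import spearmanr
        rho = spearmanr(df["quantile"], df["lapse_pct"]).statistic
        assert rho > 0.5
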