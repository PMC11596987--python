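import numpy as np
import pytest

from burstlapse.containers import Recording
from burstlapse.bursts import (Burst, BurstCriteria, Cycles, band_grid,
                               build_cycles, classify_band, cycle_properties,
                               detect_bursts, detect_recording, filter_bank,
                               merge_bursts, occupancy, zero_crossings)


def make_cycles(qualify, rate=250.0, freq=10.0):
    """Synthetic Cycles whose criteria pass/fail exactly follows `qualify`."""
    n = len(qualify)
    period = 1.0 / freq
    peak_idx = (np.arange(n + 1) * period * rate).astype(int)
    trough_idx = peak_idx[:-1] + int(period * rate / 2)
    c = Cycles(peak_idx, trough_idx, np.full(n, period), np.full(n, 40.0), rate,
               trough_t=trough_idx / rate)
    q = np.asarray(qualify, float)
    c.monotonicity = q  # 1 passes the 0.6 default, 0 fails
    c.period_consistency = np.ones(n)
    c.amplitude_consistency = np.ones(n)
    return c


class TestFilterBank:
    def test_default_band_count(self):
        assert len(band_grid()) == 11
        assert band_grid()[0] == (2.0, 6.0)
        assert band_grid()[-1] == (12.0, 16.0)

    def test_sine_peaks_in_matching_band(self, sine_recording):
        out = filter_bank(sine_recording)
        rms = {band: np.sqrt((x[0] ** 2).mean()) for band, x in out.items()}
        assert max(rms, key=rms.get) == (8.0, 12.0)

    def test_dc_suppressed(self):
        rec = Recording(np.full((1, 2500), 30.0), 250.0, ["c"])
        for x in filter_bank(rec).values():
            assert np.abs(x).max() < 1.0

    def test_low_rate_rejected(self, rng):
        rec = Recording(rng.normal(size=(1, 500)), 50.0, ["c"])
        with pytest.raises(ValueError):
            filter_bank(rec)


class TestZeroCrossings:
    def test_sine_count_and_alternation(self):
        rate = 250.0
        t = np.arange(0, 1, 1 / rate)
        times, signs = zero_crossings(np.sin(2 * np.pi * 10 * t), rate)
        assert len(times) == 20
        assert np.all(np.abs(np.diff(signs)) == 2)  # strict alternation

    def test_constant_has_none(self):
        times, _ = zero_crossings(np.full(100, 3.0), 250.0)
        assert times.size == 0

    def test_negation_flips_signs(self, rng):
        x = rng.normal(size=1000)
        t1, s1 = zero_crossings(x, 250.0)
        t2, s2 = zero_crossings(-x, 250.0)
        assert t1 == pytest.approx(t2)
        assert np.array_equal(s1, -s2)


class TestBuildCycles:
    def test_pure_sine_periods(self):
        rate = 250.0
        x = 40.0 * np.sin(2 * np.pi * 10.0 * np.arange(0, 1, 1 / rate))
        cycles = build_cycles(x, rate, zero_crossings(x, rate))
        assert len(cycles) == 9  # 10 positive peaks in 1 s
        assert cycles.period == pytest.approx(0.100, abs=0.004)

    def test_six_hz_periods(self):
        rate = 250.0
        t = np.arange(0, 2, 1 / rate)
        x = np.sin(2 * np.pi * 6 * t)
        cycles = build_cycles(x, rate, zero_crossings(x, rate))
        assert cycles.period.mean() == pytest.approx(1 / 6, abs=0.004)

    def test_peaks_equal_argmax_between_crossings(self, rng):
        rate = 250.0
        t = np.arange(0, 4, 1 / rate)
        x = np.sin(2 * np.pi * 8 * t) + 0.3 * rng.normal(size=t.size)
        times, signs = zero_crossings(np.sin(2 * np.pi * 8 * t), rate)
        cycles = build_cycles(x, rate, (times, signs))
        # brute force: max of x strictly between consecutive rising/falling crossings
        bounds = np.floor(times * rate).astype(int) + 1
        k = 0
        for j in range(len(times) - 1):
            if signs[j] != 1:
                continue
            seg = slice(bounds[j], max(bounds[j + 1], bounds[j] + 1))
            expect = seg.start + int(np.argmax(x[seg]))
            if k < cycles.peak_idx.size:
                assert cycles.peak_idx[k] == expect
                k += 1

    def test_too_few_crossings(self):
        assert build_cycles(np.zeros(100), 250.0, (np.empty(0), np.empty(0, int))) is None


class TestCycleProperties:
    def test_pure_sine_is_perfect(self, sine_recording):
        x = sine_recording.data[0]
        cycles = build_cycles(x, 250.0, zero_crossings(x, 250.0))
        cycle_properties(cycles, x)
        assert cycles.monotonicity == pytest.approx(1.0)
        assert cycles.period_consistency == pytest.approx(1.0)
        assert cycles.amplitude_consistency == pytest.approx(1.0)

    def test_period_ratio_formula(self):
        c = make_cycles([1, 1])
        c.period = np.array([0.100, 0.125])
        cycle_properties(c, np.sin(2 * np.pi * 10 * np.arange(0, 1, 1 / 250)))
        # both cycles have a single neighbour -> ratio 0.100/0.125 = 0.8
        assert c.period_consistency == pytest.approx([0.8, 0.8])

    def test_white_noise_monotonicity_low(self, rng):
        medians = []
        for _ in range(5):
            x = rng.normal(size=5000)
            nb = filter_bank(Recording(x[None], 250.0, ["c"]))[(8.0, 12.0)][0]
            cycles = build_cycles(x, 250.0, zero_crossings(nb, 250.0))
            cycle_properties(cycles, x)
            medians.append(np.median(cycles.monotonicity))
        assert np.median(medians) < 0.8


class TestDetectBursts:
    CRIT = BurstCriteria(min_cycles=3, monotonicity=0.5, period_consistency=0.5,
                         amplitude_consistency=0.2, amp_factor=0.0,
                         amp_peak_factor=0.0)

    def test_five_qualifying_cycles_one_burst(self):
        bursts = detect_bursts(make_cycles([1] * 5), self.CRIT, "c", (8.0, 12.0))
        assert len(bursts) == 1
        assert bursts[0].n_cycles == 5

    def test_interrupted_run_no_burst(self):
        bursts = detect_bursts(make_cycles([1, 1, 0, 1, 1]), self.CRIT, "c", (8.0, 12.0))
        assert bursts == []

    def test_matches_brute_force_runs(self, rng):
        for _ in range(200):
            q = (rng.uniform(size=rng.integers(5, 40)) < 0.5).astype(int)
            mc = int(rng.integers(2, 5))
            crit = BurstCriteria(min_cycles=mc, monotonicity=0.5,
                                 period_consistency=0.5, amplitude_consistency=0.2,
                                 amp_factor=0.0, amp_peak_factor=0.0)
            got = [(b.n_cycles) for b in detect_bursts(make_cycles(q), crit, "c", (8.0, 12.0))]
            # brute force run-length scan
            runs, cur = [], 0
            for v in list(q) + [0]:
                if v:
                    cur += 1
                else:
                    if cur >= mc:
                        runs.append(cur)
                    cur = 0
            assert got == runs


class TestClassifyBand:
    @pytest.mark.parametrize("freq,band", [(6.0, "theta"), (10.0, "alpha"),
                                           (8.0, "alpha"), (4.0, "theta"),
                                           (14.0, "other"), (3.0, "other"),
                                           (20.0, "other")])
    def test_half_open_edges(self, freq, band):
        assert classify_band(1.0 / freq) == band


def _mk_burst(channel, start, end, n_cycles=5, freq=10.0):
    return Burst(channel=channel, start=start, end=end, n_cycles=n_cycles,
                 mean_period=1 / freq, robust_period=1 / freq,
                 mean_amplitude=30.0, band=classify_band(1 / freq),
                 filter_band=(8.0, 12.0))


class TestMergeBursts:
    def test_identical_duplicates_collapse(self):
        bursts = [_mk_burst("c", 1.0, 2.0), _mk_burst("c", 1.0, 2.0)]
        assert len(merge_bursts(bursts)) == 1

    def test_disjoint_kept(self):
        bursts = [_mk_burst("c", 1.0, 2.0), _mk_burst("c", 3.0, 4.0)]
        assert len(merge_bursts(bursts)) == 2

    def test_different_channels_never_merge(self):
        bursts = [_mk_burst("a", 1.0, 2.0), _mk_burst("b", 1.0, 2.0)]
        assert len(merge_bursts(bursts)) == 2

    def test_concurrent_other_rhythm_kept_separate(self):
        bursts = [_mk_burst("c", 1.0, 2.0, freq=6.0), _mk_burst("c", 1.2, 1.8, freq=11.0)]
        merged = merge_bursts(bursts)
        assert sorted(b.band for b in merged) == ["alpha", "theta"]

    def test_merged_spans_equal_interval_union(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            starts = rng.uniform(0, 30, n)
            ends = starts + rng.uniform(0.2, 3.0, n)
            bursts = [_mk_burst("c", float(s), float(e)) for s, e in zip(starts, ends)]
            merged = sorted((b.start, b.end) for b in merge_bursts(bursts))
            # brute-force interval union of same-frequency bursts
            ivs = sorted(zip(starts, ends))
            union = []
            for s, e in ivs:
                if union and s < union[-1][1]:
                    union[-1] = (union[-1][0], max(union[-1][1], e))
                else:
                    union.append((s, e))
            assert merged == pytest.approx(union)


class TestOccupancy:
    def test_empty(self):
        occ = occupancy([], ["a", "b"], 100, 250.0)
        assert not occ.any()

    def test_span_arithmetic(self):
        occ = occupancy([_mk_burst("b", 1.0, 2.0)], ["a", "b"], 1000, 250.0)
        assert occ[1].sum() == 250
        assert occ[0].sum() == 0
        assert occ[1, int(1.0 * 250)] and not occ[1, int(2.0 * 250)]

    def test_merged_equals_union_of_parts(self):
        parts = [_mk_burst("a", 1.0, 2.0), _mk_burst("a", 1.5, 2.5)]
        occ_parts = occupancy(parts, ["a"], 1000, 250.0)
        occ_merged = occupancy(merge_bursts(parts), ["a"], 1000, 250.0)
        assert np.array_equal(occ_parts, occ_merged)


class TestDetectRecording:
    def test_clean_burst_recovered(self):
        rate = 250.0
        t = np.arange(0, 20, 1 / rate)
        x = 3.0 * np.random.default_rng(0).standard_normal(t.size)
        env = np.zeros_like(t)
        inside = (t >= 8.0) & (t < 9.0)
        u = (t[inside] - 8.0) / 1.0
        env[inside] = 0.5 * (1 - np.cos(2 * np.pi * u))
        x = x + env * 25.0 * np.sin(2 * np.pi * 10 * (t - 8.0))
        bursts = detect_recording(Recording(x[None], rate, ["c"]))
        alpha = [b for b in bursts if b.band == "alpha"
                 and min(b.end, 9.0) - max(b.start, 8.0) > 0.5]
        assert len(alpha) >= 1

    def test_deterministic(self, rng):
        rec = Recording(rng.normal(0, 10, (2, 10000)), 250.0, ["a", "b"])
        a = detect_recording(rec)
        b = detect_recording(rec)
        assert [(x.channel, x.start, x.end, x.band) for x in a] == \
               [(x.channel, x.start, x.end, x.band) for x in b]
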