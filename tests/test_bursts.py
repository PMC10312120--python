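"""Burst-detector tests: thresholding, one-cycle filter, clustering,
parameter extraction and recovery scoring."""

import numpy as np
import pytest

from betadyn.bursts import (BurstEvent, burst_mask, burst_parameters,
                            cluster_events, recover_injected,
                            trial_burst_params)
from betadyn.containers import EpochSet
from betadyn.spectral import normalize_tfr, tfr
from betadyn.synthetic import SyntheticGroundTruth, generate_noise, inject_bursts

from conftest import FS

FREQS = np.arange(13.0, 30.5, 0.5)
TIMES = np.arange(-0.75, 0.251, 0.02)


def flood_fill_components(mask):
    """Brute-force 4-connectivity component oracle."""
    mask = mask.copy()
    comps = []
    while mask.any():
        seed = tuple(np.argwhere(mask)[0])
        stack, comp = [seed], set()
        while stack:
            f, t = stack.pop()
            if not (0 <= f < mask.shape[0] and 0 <= t < mask.shape[1]):
                continue
            if not mask[f, t]:
                continue
            mask[f, t] = False
            comp.add((f, t))
            stack += [(f + 1, t), (f - 1, t), (f, t + 1), (f, t - 1)]
        comps.append(comp)
    return comps


class TestBurstMask:
    def test_constant_power_yields_empty_mask(self):
        grid = np.full((len(FREQS), len(TIMES)), 4.2)
        assert not burst_mask(grid, FREQS, TIMES).any()

    def test_hand_threshold(self):
        """17 bins at 1 and 3 contiguous bins at 10: row mean 2.35 and
        sample SD 3.297 give a threshold of 8.94, so only the 10s mark
        (and they span 60 ms >= one 20 Hz cycle of 50 ms)."""
        row = np.ones(20)
        row[8:11] = 10.0
        grid = np.tile(row, (len(FREQS), 1))
        times = TIMES[: 20]
        mask = burst_mask(grid, FREQS, times)
        i20 = list(FREQS).index(20.0)
        expected = np.zeros(20, dtype=bool)
        expected[8:11] = True
        np.testing.assert_array_equal(mask[i20], expected)

    def test_run_shorter_than_one_cycle_cleared(self):
        """At 20 Hz one cycle is 50 ms = 3 bins of 20 ms; a 2-bin run is
        cleared while a 3-bin run survives."""
        base = np.ones(20)
        short = base.copy()
        short[5:7] = 10.0  # 2 bins = 40 ms < 50 ms
        grid = np.tile(base, (len(FREQS), 1))
        i20 = list(FREQS).index(20.0)
        grid[i20] = short
        mask = burst_mask(grid, FREQS, TIMES[:20])
        assert not mask[i20].any()

    def test_threshold_shift_equivariance(self):
        rng = np.random.default_rng(4)
        grid = rng.exponential(size=(len(FREQS), len(TIMES)))
        shifted = grid.copy()
        shifted[10] += 100.0  # adding a constant shifts mean, not SD
        np.testing.assert_array_equal(burst_mask(grid, FREQS, TIMES),
                                      burst_mask(shifted, FREQS, TIMES))

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            burst_mask(np.ones((3, 1)), FREQS[:3], TIMES[:1])


class TestClusterEvents:
    def test_empty_mask(self):
        grid = np.ones((len(FREQS), len(TIMES)))
        mask = np.zeros_like(grid, dtype=bool)
        assert cluster_events(mask, grid, FREQS, TIMES) == []

    def test_separated_blobs(self):
        mask = np.zeros((len(FREQS), len(TIMES)), dtype=bool)
        mask[2:5, 3:8] = True
        mask[10:12, 20:26] = True
        grid = np.where(mask, 5.0, 1.0)
        events = cluster_events(mask, grid, FREQS, TIMES)
        assert len(events) == 2

    def test_diagonal_touch_stays_separate(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        grid = np.where(mask, 5.0, 1.0)
        events = cluster_events(mask, grid, FREQS[:6], TIMES[:6])
        assert len(events) == 2

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            mask = rng.random((len(FREQS), len(TIMES))) < 0.25
            grid = rng.exponential(size=mask.shape)
            events = cluster_events(mask, grid, FREQS, TIMES)
            oracle = flood_fill_components(mask)
            assert len(events) == len(oracle)
            got = sorted(frozenset(e.points) for e in events)
            want = sorted(frozenset(c) for c in oracle)
            assert got == want

    def test_partition_property(self):
        rng = np.random.default_rng(12)
        mask = rng.random((len(FREQS), len(TIMES))) < 0.3
        grid = rng.exponential(size=mask.shape)
        events = cluster_events(mask, grid, FREQS, TIMES)
        pts = [p for e in events for p in e.points]
        assert len(pts) == mask.sum()
        assert len(set(pts)) == len(pts)


class TestBurstParameters:
    def test_no_events(self):
        p = burst_parameters([], window=(-0.7, 0.0))
        assert p.n_events == 0
        assert np.isnan(p.peak_power)

    def test_hand_event(self):
        """Single event spanning 18-22 Hz and -310..-110 ms, maximum power
        10 at (20 Hz, -210 ms) -> (1, 10, -0.21 s, 20 Hz, 4 Hz, 0.2 s)."""
        mask = np.zeros((len(FREQS), len(TIMES)), dtype=bool)
        fsel = (FREQS >= 18) & (FREQS <= 22)
        tsel = (TIMES >= -0.31 - 1e-9) & (TIMES <= -0.11 + 1e-9)
        mask[np.ix_(fsel, tsel)] = True
        grid = np.where(mask, 5.0, 1.0)
        grid[list(FREQS).index(20.0), np.argmin(np.abs(TIMES + 0.21))] = 10.0
        events = cluster_events(mask, grid, FREQS, TIMES)
        p = burst_parameters(events, window=(-0.7, 0.0))
        assert p.n_events == 1
        assert p.peak_power == 10.0
        assert p.peak_time == pytest.approx(-0.21, abs=1e-9)
        assert p.peak_freq == 20.0
        assert p.freq_range == pytest.approx(4.0)
        assert p.time_range == pytest.approx(0.2, abs=1e-9)

    def test_tie_break_earliest_time_then_lowest_freq(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        grid = np.ones((5, 5))
        grid[2, 3] = grid[3, 1] = grid[1, 1] = 7.0  # three-way tie
        events = cluster_events(mask, grid, FREQS[:5], TIMES[:5])
        assert len(events) == 1
        assert events[0].peak_point == (1, 1)

    def test_window_restriction_counts_by_peak(self):
        mask = np.zeros((len(FREQS), len(TIMES)), dtype=bool)
        mask[3, 2:6] = True   # peak well before -0.7 s
        mask[8, 30:34] = True  # peak inside the pretarget window
        grid = np.where(mask, 5.0, 1.0)
        events = cluster_events(mask, grid, FREQS, TIMES)
        p = burst_parameters(events, window=(-0.7, 0.0))
        assert p.n_events == 1


class TestRecovery:
    def _one_event(self, f, t):
        return BurstEvent(points=[(0, 0)], peak_power=5.0, peak_freq=f,
                          peak_time=t, freq_range=0.0, time_range=0.0,
                          peak_point=(0, 0))

    def test_exact_match_scores_one(self):
        from betadyn.synthetic import BurstRecord

        gt = SyntheticGroundTruth(
            [BurstRecord(0, "motor", -0.3, 20.0, 0.2, 5.0)], {}, (0,) * 4, 0)
        events = [[self._one_event(20.0, -0.3)]]
        recall, precision = recover_injected(events, gt, "motor")
        assert recall == 1.0 and precision == 1.0

    def test_no_events_zero_recall(self):
        from betadyn.synthetic import BurstRecord

        gt = SyntheticGroundTruth(
            [BurstRecord(0, "motor", -0.3, 20.0, 0.2, 5.0)], {}, (0,) * 4, 0)
        recall, precision = recover_injected([[]], gt, "motor")
        assert recall == 0.0

    def test_empty_ground_truth_recall_undefined(self):
        gt = SyntheticGroundTruth([], {}, (0,) * 4, 0)
        recall, precision = recover_injected([[self._one_event(20.0, -0.3)]],
                                             gt, "motor")
        assert recall is None
        assert precision == 0.0


class TestParamsTable:
    def test_csv_columns_and_units(self, tmp_path):
        from betadyn.bursts import BurstParams, params_table

        params = [BurstParams(n_events=0),
                  BurstParams(2, 10.0, -0.2, 20.0, 4.0, 0.2)]
        tab = params_table(params, window="pretarget")
        assert list(tab.columns) == ["trial", "window", "n_events",
                                     "peak_power", "peak_time_ms",
                                     "peak_freq_hz", "freq_range_hz",
                                     "time_range_ms"]
        assert tab.loc[1, "peak_time_ms"] == pytest.approx(-200.0)
        assert tab.loc[1, "time_range_ms"] == pytest.approx(200.0)
        tab.to_csv(tmp_path / "bursts.csv", index=False)
        assert (tmp_path / "bursts.csv").exists()


class TestAmplitudeMonotonicity:
    def test_recall_increases_with_amplitude(self):
        """Raising the injected amplitude never lowers the expected fraction
        of injected bursts the detector recovers.

        The raw per-trial event count is *not* monotone in amplitude: the
        threshold is within-trial mean + 2 SD per frequency row, so stronger
        bursts inflate the row SD and suppress weak noise events, which can
        lower the total count even as burst detectability rises. Recovery of
        the injected events is the monotone quantity.
        """
        recalls = {3.0: [], 8.0: []}
        for seed in range(30):
            noise = generate_noise(6, 420, FS, 1.0, seed=500 + seed)
            ep = EpochSet(noise, FS, -1.0, ("motor",), window="pretarget")
            for amp in recalls:
                injected, recs = inject_bursts(ep, rate=1.0, amp=amp,
                                               seed=900 + seed,
                                               center_span=(-0.7, 0.2))
                T = normalize_tfr(tfr(injected))
                _, events = trial_burst_params(T, "motor",
                                               window=(-0.75, 0.25))
                gt = SyntheticGroundTruth(recs, {}, (0,) * 4, 0)
                r, _ = recover_injected(events, gt, "motor")
                if r is not None:
                    recalls[amp].append(r)
        assert np.mean(recalls[8.0]) >= np.mean(recalls[3.0])
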