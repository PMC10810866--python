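import numpy as np
import pytest

from neoripple import events as ev
from neoripple.io import TimeSeries, make_events
from neoripple.synth import (
    make_aperiodic_noise,
    make_recording,
    make_ripple_waveform,
    make_spw_waveform,
)

FS = 1000.0


def overlaps_any(table, start, stop):
    return any((r.start_s < stop) and (start < r.stop_s) for r in table.itertuples())


def inject(x, wave, t0_s, fs=FS):
    c = int(round(t0_s * fs))
    x[c: c + wave.size] += wave
    return x


# ---------------------------------------------------------------------------
# active periods


class TestActivePeriods:
    def test_zero_signal_empty(self):
        assert ev.detect_active_periods(np.zeros(int(30 * FS)), FS).empty

    @staticmethod
    def theta_burst(dur_s, amp):
        t = np.arange(int(dur_s * FS)) / FS
        return amp * np.sin(2 * np.pi * 8.0 * t) * np.hanning(t.size)

    def test_large_burst_detected_small_rejected(self, rng):
        x = rng.normal(0, 2.0, int(60 * FS))
        x = inject(x, self.theta_burst(0.8, 150.0), 20.0)
        x = inject(x, self.theta_burst(0.2, 150.0), 40.0)
        table = ev.detect_active_periods(x, FS)
        assert overlaps_any(table, 20.0, 20.8)
        # a 200 ms burst fails the 300 ms duration rule
        assert not overlaps_any(table, 39.9, 40.4)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            ev.detect_active_periods(np.zeros(100), 20.0)


# ---------------------------------------------------------------------------
# radial difference & SPWs


class TestRadialDifference:
    def test_identical_channels_cancel(self, rng):
        x = rng.normal(0, 10, int(10 * FS))
        ts = TimeSeries(np.stack([x, x], axis=1), fs=FS)
        diff, fs_d = ev.radial_difference(ts, 0, 1)
        assert fs_d == 250.0
        assert np.max(np.abs(diff)) < 1e-6

    def test_synthetic_reversal_doubles(self):
        w = np.zeros(int(10 * FS))
        inject(w, make_spw_waveform(300.0, 60.0, FS), 5.0)
        ts = TimeSeries(np.stack([w, -w], axis=1), fs=FS)
        diff, fs_d = ev.radial_difference(ts, 0, 1)
        # linearity: (+A above, -A below) gives exactly twice the processed
        # single-channel deflection
        single = TimeSeries(np.stack([w, np.zeros_like(w)], axis=1), fs=FS)
        diff_single, _ = ev.radial_difference(single, 0, 1)
        np.testing.assert_allclose(diff, 2.0 * diff_single, atol=1e-9)
        assert diff.max() == pytest.approx(600.0, rel=0.2)

    def test_band_pass_removes_200hz(self):
        t = np.arange(int(10 * FS)) / FS
        x = 100 * np.sin(2 * np.pi * 200.0 * t)
        ts = TimeSeries(np.stack([x, np.zeros_like(x)], axis=1), fs=FS)
        diff, fs_d = ev.radial_difference(ts, 0, 1)
        interior = diff[int(fs_d): -int(fs_d)]  # skip filter edge transients
        assert np.max(np.abs(interior)) < 0.05 * 100

    def test_missing_channel_rejected(self):
        ts = TimeSeries(np.zeros((1000, 2)), fs=FS)
        with pytest.raises(ValueError, match="channel"):
            ev.radial_difference(ts, 0, 2)


class TestAdaptiveMultiplier:
    @pytest.mark.parametrize(
        "sd,expected", [(5.0, 5.0), (150.0, 3.0), (60.0, 4.0)]
    )
    def test_linear_clamped_map(self, sd, expected):
        assert ev.adaptive_spw_multiplier(sd, 20.0, 100.0) == pytest.approx(expected)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ev.adaptive_spw_multiplier(-1.0)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            ev.adaptive_spw_multiplier(10.0, 50.0, 50.0)


class TestDetectSpw:
    def test_zero_signal_empty(self):
        assert ev.detect_spw(np.zeros(5000), 250.0).empty

    def test_gaussian_deflection_recovered(self, rng):
        fs = 250.0
        x = rng.normal(0, 10.0, int(60 * fs))
        w = make_spw_waveform(4.5 * 10.0 * 2.0, 60.0, fs)  # 9 SD peak
        c = int(30 * fs) - w.size // 2
        x[c: c + w.size] += w
        table = ev.detect_spw(x, fs, multiplier=4.0)
        assert len(table) >= 1
        best = table.iloc[np.argmin(np.abs(table["peak_s"] - 30.0))]
        assert best["peak_s"] == pytest.approx(30.0, abs=0.004)
        assert best["halfwidth_s"] == pytest.approx(0.06, abs=0.015)

    def test_wide_deflection_rejected(self, rng):
        fs = 250.0
        x = rng.normal(0, 10.0, int(60 * fs))
        w = make_spw_waveform(90.0, 150.0, fs)  # FWHM 150 ms > 100 ms cap
        c = int(30 * fs) - w.size // 2
        x[c: c + w.size] += w
        table = ev.detect_spw(x, fs, multiplier=4.0)
        assert not overlaps_any(table, 29.8, 30.2)


# ---------------------------------------------------------------------------
# ripples: power method


class TestRipplesPower:
    def test_noise_floor_false_positive_rate(self):
        minutes = 0
        n_fp = 0
        for seed in range(100):
            ts = make_aperiodic_noise(30.0, FS, 2.0, 2.0, seed=seed)
            n_fp += len(ev.detect_ripples_power(ts.channel(0), FS))
            minutes += 0.5
        assert n_fp / minutes < 1.0

    def test_injected_burst_boundaries(self, rng):
        x = rng.normal(0, 1.0, int(30 * FS))
        w = make_ripple_waveform(150.0, 7.5, 30.0, FS)  # 50 ms at 8x SD+
        inject(x, w, 15.0)
        table = ev.detect_ripples_power(x, FS)
        assert len(table) == 1
        assert table.loc[0, "start_s"] == pytest.approx(15.0, abs=0.010)
        assert table.loc[0, "stop_s"] == pytest.approx(15.05, abs=0.010)

    def test_nearby_bursts_merged(self, rng):
        x = rng.normal(0, 1.0, int(30 * FS))
        w = make_ripple_waveform(150.0, 4.5, 30.0, FS)  # 30 ms bursts
        inject(x, w, 15.0)
        inject(x, w, 15.05)  # 20 ms gap < 30 ms merge rule
        table = ev.detect_ripples_power(x, FS)
        hits = table[(table["start_s"] < 15.08) & (table["stop_s"] > 15.0)]
        assert len(hits) == 1

    def test_event_frequency_estimate(self, rng):
        x = rng.normal(0, 1.0, int(30 * FS))
        inject(x, make_ripple_waveform(150.0, 7.5, 30.0, FS), 15.0)
        table = ev.detect_ripples_power(x, FS)
        assert table.loc[0, "peak_freq_hz"] == pytest.approx(150.0, rel=0.15)


# ---------------------------------------------------------------------------
# ripples: by-cycle method


class TestRipplesBycycle:
    def test_stationary_sine_one_event_all_burst(self):
        t = np.arange(int(20 * FS)) / FS
        table, feats = ev.detect_ripples_bycycle(
            50 * np.sin(2 * np.pi * 120.0 * t), FS
        )
        assert len(table) == 1
        assert feats.is_burst.mean() > 0.99
        assert table.loc[0, "stop_s"] - table.loc[0, "start_s"] > 19.0

    def test_white_noise_burst_fraction_low(self, rng):
        _, feats = ev.detect_ripples_bycycle(rng.normal(0, 2, int(60 * FS)), FS)
        assert feats.is_burst.mean() < 0.05

    def test_alternating_period_chirp_rejected(self):
        # adjacent measured cycle periods alternate at a ratio below the
        # period-consistency threshold -> no oscillatory period
        seg = []
        for k in range(150):
            fr = 70.0 if k % 2 else 200.0
            n = int(round(FS / fr))
            seg.append(50 * np.sin(2 * np.pi * fr * np.arange(n) / FS))
        table, _ = ev.detect_ripples_bycycle(
            np.concatenate(seg), FS, locate_band=(50.0, 250.0)
        )
        assert table.empty

    def test_ripple_on_spw_background_found(self):
        hits = 0
        for seed in range(10):
            bg = make_aperiodic_noise(3.0, FS, 2.0, 2.0, seed=seed).channel(0)
            x = bg.copy()
            s = make_spw_waveform(-300.0, 60.0, FS)
            x[1500 - s.size // 2: 1500 - s.size // 2 + s.size] += s
            w = make_ripple_waveform(140.0, 6, 50.0, FS)
            x[1500 - w.size // 2: 1500 - w.size // 2 + w.size] += w
            table, _ = ev.detect_ripples_bycycle(x, FS)
            hits += overlaps_any(table, 1.475, 1.525)
        assert hits >= 9

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            ev.detect_ripples_bycycle(
                np.zeros(5000), FS, thresholds={"monotonicity": 1.5}
            )
        with pytest.raises(ValueError, match="unknown"):
            ev.detect_ripples_bycycle(
                np.zeros(5000), FS, thresholds={"wibble": 0.5}
            )

    def test_raising_thresholds_never_increases_bursts(self, rng):
        x = rng.normal(0, 2, int(30 * FS))
        inject(x, make_ripple_waveform(140.0, 8, 50.0, FS), 15.0)
        fracs = []
        for thr in (0.3, 0.6, 0.9):
            _, feats = ev.detect_ripples_bycycle(
                x, FS, thresholds={k: thr for k in
                                   ("amplitude_consistency",
                                    "period_consistency", "monotonicity")}
            )
            fracs.append(feats.is_burst.sum())
        assert fracs[0] >= fracs[1] >= fracs[2]


# ---------------------------------------------------------------------------
# consensus / coupling / classes


def table_from(intervals, kind="ripple", freq=140.0):
    rows = []
    for a, b in intervals:
        rows.append(
            dict(kind=kind, start_s=a, stop_s=b, peak_s=(a + b) / 2,
                 peak_amp=50.0, n_cycles=(b - a) * freq, peak_freq_hz=freq)
        )
    return make_events(rows)


class TestConsensus:
    def test_identical_tables_identity(self):
        t = table_from([(1.0, 1.05), (2.0, 2.04)])
        out = ev.consensus_ripples(t, t)
        assert len(out) == 2

    def test_disjoint_tables_empty(self):
        a = table_from([(1.0, 1.05)])
        b = table_from([(2.0, 2.05)])
        assert ev.consensus_ripples(a, b).empty

    def test_single_overlap_retained_with_power_bounds(self):
        power = table_from([(1.0, 1.05), (2.0, 2.04), (3.0, 3.04)])
        cycle = table_from([(2.03, 2.08)])
        out = ev.consensus_ripples(power, cycle)
        assert len(out) == 1
        assert out.loc[0, "start_s"] == 2.0 and out.loc[0, "stop_s"] == 2.04

    def test_consensus_subset_of_power(self):
        power = table_from([(1.0, 1.05), (2.0, 2.04)])
        cycle = table_from([(1.02, 1.06), (5.0, 5.03)])
        out = ev.consensus_ripples(power, cycle)
        merged = out.merge(power, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


class TestCoupling:
    @staticmethod
    def spw_table(peak=2.0, halfwidth=0.06):
        return make_events(
            [dict(kind="spw", start_s=peak - halfwidth, stop_s=peak + halfwidth,
                  peak_s=peak, peak_amp=-300.0, halfwidth_s=halfwidth)]
        )

    def test_ripple_inside_window_coupled(self):
        spwr, solo = ev.couple_to_spw(table_from([(1.99, 2.01)]), self.spw_table())
        assert len(spwr) == 1 and solo.empty
        assert spwr.loc[0, "kind"] == "spwr"

    def test_ripple_before_window_solo(self):
        spwr, solo = ev.couple_to_spw(table_from([(1.0, 1.05)]), self.spw_table())
        assert spwr.empty and len(solo) == 1
        assert solo.loc[0, "kind"] == "solo_ripple"

    def test_boundary_sample_not_coupled_half_open(self):
        # window is [peak - hw/2, peak + hw/2); a ripple ENDING exactly at
        # the window start shares only the boundary -> not coupled
        window_start = 2.0 - 0.03
        spwr, solo = ev.couple_to_spw(
            table_from([(1.9, window_start)]), self.spw_table()
        )
        assert spwr.empty and len(solo) == 1

    def test_partition_is_disjoint_and_complete(self):
        ripples = table_from([(1.0, 1.04), (1.99, 2.02), (3.0, 3.03)])
        spwr, solo = ev.couple_to_spw(ripples, self.spw_table())
        assert len(spwr) + len(solo) == len(ripples)


class TestLengthClass:
    def test_boundary_and_arithmetic(self):
        t = table_from([(0.0, 0.030)], freq=100.0)  # 3.0 cycles -> long
        t2 = table_from([(0.0, 0.020)], freq=100.0)  # 2 cycles -> short
        t3 = table_from([(0.0, 0.045)], freq=150.0)  # 6.75 cycles -> long
        assert ev.classify_ripple_length(t).tolist() == ["long"]
        assert ev.classify_ripple_length(t2).tolist() == ["short"]
        assert ev.classify_ripple_length(t3).tolist() == ["long"]

    def test_missing_frequency_rejected(self):
        t = table_from([(0.0, 0.03)])
        t.loc[0, "peak_freq_hz"] = np.nan
        with pytest.raises(ValueError, match="peak_freq"):
            ev.classify_ripple_length(t)


class TestIhfo:
    def test_fraction_of_windows_with_events(self, rng):
        x = rng.normal(0, 1.0, int(40 * FS))
        windows = [(1.0 + k, 1.12 + k) for k in range(30)]
        w = make_ripple_waveform(150.0, 9, 30.0, FS)  # 60 ms burst
        for k in range(15):
            inject(x, w, 1.03 + k)
        table, frac = ev.detect_ihfo(x, FS, windows)
        assert frac == pytest.approx(0.5, abs=0.1)
        assert (table["kind"] == "ihfo").all()

    def test_no_events_fraction_zero(self, rng):
        x = rng.normal(0, 1.0, int(10 * FS))
        _, frac = ev.detect_ihfo(x, FS, [(1.0, 1.12), (2.0, 2.12)])
        assert frac == 0.0

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ev.detect_ihfo(np.zeros(5000), FS, [])


class TestMovement:
    def test_static_coordinates_empty(self):
        xy = np.zeros((100, 6, 2))
        assert ev.detect_movement(xy).empty

    def test_single_jump_single_frame_interval(self):
        xy = np.zeros((100, 2, 2))
        xy[50:, 0, 0] = 30.0  # one 30 px jump at frame transition 49->50
        table = ev.detect_movement(xy, frame_rate_hz=10.0)
        assert len(table) == 1
        assert table.loc[0, "stop_s"] - table.loc[0, "start_s"] == pytest.approx(0.2)

    def test_exactly_25px_not_movement(self):
        xy = np.zeros((100, 1, 2))
        xy[50:, 0, 0] = 25.0
        assert ev.detect_movement(xy).empty

    def test_single_frame_input_empty(self):
        assert ev.detect_movement(np.zeros((1, 6, 2))).empty


# ---------------------------------------------------------------------------
# end-to-end recovery on synthetic recordings


class TestRecovery:
    def test_consensus_recovers_injected_ripples(self, default_recording):
        spec, ts, _, truth = default_recording
        rip_p = ev.detect_ripples_power(ts.channel(0), ts.fs)
        rip_b, _ = ev.detect_ripples_bycycle(ts.channel(0), ts.fs)
        cons = ev.consensus_ripples(rip_p, rip_b)
        true_r = truth.events[truth.events["kind"] == "ripple"]
        assert len(true_r) >= 5
        hits = sum(
            overlaps_any(cons, r.start_s, r.stop_s) for r in true_r.itertuples()
        )
        assert hits / len(true_r) >= 0.9
        n_fp = sum(
            not overlaps_any(true_r, c.start_s, c.stop_s)
            for c in cons.itertuples()
        )
        assert n_fp / (spec.duration_s / 60.0) <= 1.0

    def test_all_injected_spws_recovered(self, default_recording):
        _, ts, _, truth = default_recording
        diff, fs_d = ev.radial_difference(ts, 0, 1)
        mult = ev.adaptive_spw_multiplier(float(np.std(diff)))
        spws = ev.detect_spw(diff, fs_d, multiplier=mult)
        true_s = truth.events[truth.events["kind"] == "spw"]
        det = spws["peak_s"].to_numpy()
        assert all(np.min(np.abs(det - t)) < 0.05 for t in true_s["peak_s"])

    def test_detection_is_deterministic(self, default_recording):
        _, ts, _, _ = default_recording
        a = ev.detect_ripples_power(ts.channel(0), ts.fs)
        b = ev.detect_ripples_power(ts.channel(0), ts.fs)
        assert a.equals(b)
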