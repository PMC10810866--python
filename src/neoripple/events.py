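"""Time-domain event detectors for developing hippocampal recordings.

Covers: active (oscillatory) periods, sharp waves (SPWs) on the radial
difference signal with an adaptive threshold, ripples by two independent
methods (band-power thresholding and cycle-by-cycle burst detection) plus
their consensus, SPW-ripple coupling, ripple length classes, induced
high-frequency oscillations (iHFOs) inside stimulation windows, and the
movement rule on tracked coordinates.

All intervals are half-open [start_s, stop_s) in seconds from recording
start.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import TimeSeries, empty_events, make_events


# ---------------------------------------------------------------------------
# small shared helpers


def bandpass(x: np.ndarray, fs: float, f_lo: float, f_hi: float,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    nyq = fs / 2.0
    hi = min(f_hi, 0.99 * nyq)
    sos = sps.butter(order, [f_lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def resample_to(x: np.ndarray, fs: float, fs_target: float) -> np.ndarray:
    """Polyphase resampling to fs_target (rational approximation of ratio)."""
    if fs == fs_target:
        return np.asarray(x, dtype=np.float64)
    frac = Fraction(fs_target / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index runs where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_gaps(intervals: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge intervals whose separating gap is strictly below max_gap samples."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for i0, i1 in intervals[1:]:
        if i0 - merged[-1][1] < max_gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    return [tuple(iv) for iv in merged]


def _overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
    """Non-zero overlap of half-open intervals [a0,a1) and [b0,b1)."""
    return a0 < b1 and b0 < a1


# ---------------------------------------------------------------------------
# active periods


def detect_active_periods(
    ts: TimeSeries | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = (4.0, 12.0),
    fs_det: float = 250.0,
    boxcar_s: float = 0.5,
    label_z: float = 1.0,
    label_uv: float = 50.0,
    peak_z: float = 2.0,
    peak_uv: float = 100.0,
    merge_gap_s: float = 1.0,
    min_len_s: float = 0.3,
) -> pd.DataFrame:
    """Detect oscillatory (active) LFP periods on the reversal channel.

    Pre-processing: band-pass 4-12 Hz, downsample to 250 Hz, square,
    boxcar-smooth over 500 ms. Thresholding on the RMS envelope (square
    root of the smoothed power, so the microvolt criteria are meaningful):
    label > 1 SD or 50 uV, merge gaps < 1 s, discard events whose peak
    reaches neither 2 SD nor 100 uV, drop events shorter than 300 ms.
    """
    if isinstance(ts, TimeSeries):
        x, fs = ts.channel(0), ts.fs
    else:
        x = np.asarray(ts, dtype=np.float64)
        if fs is None:
            raise ValueError("fs required for array input")
    if fs < 2.0 * band[1]:
        raise ValueError(f"fs = {fs} too low for the {band} Hz band")
    xf = bandpass(x, fs, *band)
    xd = resample_to(xf, fs, fs_det)
    power = xd ** 2
    win = max(1, int(round(boxcar_s * fs_det)))
    env = np.sqrt(np.convolve(power, np.ones(win) / win, mode="same"))
    mu, sd = env.mean(), env.std()
    z = (env - mu) / sd if sd > 0 else np.zeros_like(env)

    labeled = (z > label_z) | (env > label_uv)
    # the boxcar smears a suprathreshold burst by ~win/2 on each side;
    # shrink the labeled intervals correspondingly so the duration rule
    # applies to the underlying burst, not the smear
    shrink = win // 2
    intervals = []
    for i0, i1 in _mask_to_intervals(labeled):
        if i1 - i0 > 2 * shrink:
            intervals.append((i0 + shrink, i1 - shrink))
    intervals = _merge_gaps(intervals, int(round(merge_gap_s * fs_det)))
    rows = []
    for i0, i1 in intervals:
        if (i1 - i0) / fs_det < min_len_s:
            continue
        seg_z = z[i0:i1]
        seg_env = env[i0:i1]
        if seg_z.max() < peak_z and seg_env.max() < peak_uv:
            continue
        i_pk = i0 + int(np.argmax(seg_env))
        rows.append(
            dict(kind="active", start_s=i0 / fs_det, stop_s=i1 / fs_det,
                 peak_s=i_pk / fs_det, peak_amp=env[i_pk])
        )
    return make_events(rows)


# ---------------------------------------------------------------------------
# sharp waves


def radial_difference(
    ts: TimeSeries,
    above_idx: int,
    below_idx: int,
    band: tuple[float, float] = (1.0, 100.0),
    fs_det: float = 250.0,
) -> tuple[np.ndarray, float]:
    """SPW detection signal: (above - below) across the pyramidal layer.

    Both channels are band-pass filtered (1-100 Hz, phase preserving) and
    downsampled to 250 Hz before subtraction. Returns (signal, fs_det).
    """
    if max(above_idx, below_idx) >= ts.n_channels or min(above_idx, below_idx) < 0:
        raise ValueError(
            f"channel index out of range for {ts.n_channels}-channel signal"
        )
    out = []
    for idx in (above_idx, below_idx):
        xd = resample_to(ts.channel(idx), ts.fs, fs_det)
        out.append(bandpass(xd, fs_det, *band))
    return out[0] - out[1], fs_det


def adaptive_spw_multiplier(
    signal_sd: float, sd_low: float = 20.0, sd_high: float = 100.0
) -> float:
    """Threshold multiplier in [3, 5], inversely related to the signal SD.

    Low-variance (young, quiet) signals get the strict 5-SD multiplier,
    high-variance (older) signals 3 SD, linear in between; this compensates
    the developmental growth of overall LFP amplitude.
    """
    if signal_sd < 0:
        raise ValueError("signal_sd must be >= 0")
    if not sd_low < sd_high:
        raise ValueError("sd_low must be < sd_high")
    frac = np.clip((signal_sd - sd_low) / (sd_high - sd_low), 0.0, 1.0)
    return float(5.0 - 2.0 * frac)


def detect_spw(
    diff_signal: np.ndarray,
    fs: float = 250.0,
    multiplier: float = 4.0,
    max_width_ms: float = 100.0,
) -> pd.DataFrame:
    """Detect SPWs as prominent peaks of the radial difference signal.

    A peak qualifies if it exceeds mean + multiplier*SD, its half-height
    width is at most 100 ms, and its prominence is at least half the
    threshold. Event bounds are the half-height crossings; halfwidth_s is
    the full width at half prominence.
    """
    x = np.asarray(diff_signal, dtype=np.float64)
    if x.size == 0:
        return empty_events()
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return empty_events()
    height = mu + multiplier * sd
    peaks, _ = sps.find_peaks(x, height=height, prominence=multiplier * sd / 2.0)
    max_w = max_width_ms / 1000.0
    rows = []
    for p in peaks:
        # full width at half height, walking out from the peak
        half = x[p] / 2.0
        left = p
        while left > 0 and x[left - 1] >= half:
            left -= 1
        right = p
        while right < x.size - 1 and x[right + 1] >= half:
            right += 1
        w = (right - left + 1) / fs
        if w > max_w:
            continue
        rows.append(
            dict(
                kind="spw",
                start_s=left / fs,
                stop_s=(right + 1) / fs,
                peak_s=p / fs,
                peak_amp=x[p],
                halfwidth_s=w,
            )
        )
    return make_events(rows)


# ---------------------------------------------------------------------------
# ripples, method 1: band power


def _event_cycle_stats(xf: np.ndarray, fs: float, i0: int, i1: int) -> tuple[float, float]:
    """(n_cycles, peak_freq_hz) of a band-passed snippet: complete cycles
    between the first and last rising zero-crossing."""
    seg = xf[i0:i1]
    crossings = np.where((seg[:-1] < 0) & (seg[1:] >= 0))[0]
    if crossings.size < 2:
        return float(crossings.size), np.nan
    n_cycles = crossings.size - 1
    span = (crossings[-1] - crossings[0]) / fs
    return float(n_cycles), float(n_cycles / span)


def detect_ripples_power(
    pyr_signal: np.ndarray,
    fs: float,
    band: tuple[float, float] = (80.0, 200.0),
    smooth_ms: float = 16.0,
    label_sd: float = 3.0,
    peak_sd: float = 6.0,
    merge_gap_ms: float = 30.0,
    min_len_ms: float = 20.0,
    max_len_ms: float = 100.0,
) -> pd.DataFrame:
    """Band-power ripple detector (four-step thresholding).

    The pyramidale-channel signal is band-limited (default 80-200 Hz),
    squared and boxcar-smoothed (~two ripple cycles). Steps: (1) label
    periods exceeding 3 SD of the smoothed power, (2) merge gaps shorter
    than 30 ms, (3) drop events whose power peak stays below 6 SD,
    (4) keep events with duration strictly between 20 and max_len_ms
    (100 ms for spontaneous ripples, 120 ms in iHFO mode).
    """
    x = np.asarray(pyr_signal, dtype=np.float64)
    if x.size < 16:
        return empty_events()
    xf = bandpass(x, fs, *band)
    p_raw = xf ** 2
    win = max(1, int(round(smooth_ms / 1000.0 * fs)))
    p = np.convolve(p_raw, np.ones(win) / win, mode="same")
    mu, sd = p.mean(), p.std()
    if sd == 0:
        return empty_events()
    # boxcar smoothing smears each burst by ~win/2 per side, so refine the
    # labeled boundaries to the first/last instantaneous-power exceedance
    # inside the smeared interval (brief noise blips then fail the
    # duration bounds on their true extent)
    thr = mu + label_sd * sd
    intervals = []
    for i0, i1 in _mask_to_intervals(p > thr):
        above = np.where(p_raw[i0:i1] > thr)[0]
        if above.size:
            intervals.append((i0 + above[0], i0 + above[-1] + 1))
    intervals = _merge_gaps(intervals, int(round(merge_gap_ms / 1000.0 * fs)))
    rows = []
    for i0, i1 in intervals:
        if p[i0:i1].max() < mu + peak_sd * sd:
            continue
        len_ms = (i1 - i0) / fs * 1000.0
        if not (min_len_ms < len_ms < max_len_ms):
            continue
        i_pk = i0 + int(np.argmax(p[i0:i1]))
        n_cycles, freq = _event_cycle_stats(xf, fs, i0, i1)
        rows.append(
            dict(
                kind="ripple",
                start_s=i0 / fs,
                stop_s=i1 / fs,
                peak_s=i_pk / fs,
                peak_amp=np.abs(xf[i0:i1]).max(),
                n_cycles=n_cycles,
                peak_freq_hz=freq,
            )
        )
    return make_events(rows)


# ---------------------------------------------------------------------------
# ripples, method 2: cycle-by-cycle


@dataclass
class CycleFeatures:
    """Per-cycle waveform features used for burst labeling."""

    start_s: np.ndarray
    stop_s: np.ndarray
    period_s: np.ndarray
    amplitude: np.ndarray
    rise_decay_symmetry: np.ndarray
    peak_trough_symmetry: np.ndarray
    monotonicity: np.ndarray
    is_burst: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.start_s.size


DEFAULT_CYCLE_THRESHOLDS = {
    "amplitude_consistency": 0.6,
    "period_consistency": 0.6,
    "monotonicity": 0.6,
}


def _ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise min/max ratio in [0, 1] (0 where either is <= 0)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((hi > 0) & (lo > 0), lo / hi, 0.0)
    return r


def _neighbor_consistency(v: np.ndarray) -> np.ndarray:
    """Per element, the worst min/max ratio against its existing neighbors."""
    n = v.size
    out = np.ones(n)
    if n == 0:
        return out
    left = np.r_[1.0, _ratio(v[1:], v[:-1])]
    right = np.r_[_ratio(v[:-1], v[1:]), 1.0]
    out = np.minimum(left, right)
    return out


def detect_ripples_bycycle(
    pyr_signal: np.ndarray,
    fs: float,
    thresholds: dict | None = None,
    locate_band: tuple[float, float] = (80.0, 200.0),
    min_cycles: int = 2,
    min_amplitude: float = 0.0,
) -> tuple[pd.DataFrame, CycleFeatures]:
    """Cycle-by-cycle (time-domain) ripple burst detector.

    The signal is segmented into cycles delimited by rising zero-crossings
    of a narrow-band (80-200 Hz) copy; peak and trough positions are then
    refined on the broadband input and the features amplitude, period,
    rise-decay symmetry, peak-trough symmetry and flank monotonicity are
    computed per cycle. A cycle belongs to a burst iff its amplitude and
    period are consistent with the adjacent cycles and its flanks are
    sufficiently monotonic (each criterion in [0, 1] against its
    threshold). Events are maximal runs of >= min_cycles burst cycles.
    """
    thr = dict(DEFAULT_CYCLE_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(thr)
        if unknown:
            raise ValueError(f"unknown thresholds: {sorted(unknown)}")
        thr.update(thresholds)
    for k, v in thr.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"threshold {k} must be in [0, 1], got {v}")

    x = np.asarray(pyr_signal, dtype=np.float64)
    empty = CycleFeatures(*(np.empty(0),) * 7, np.empty(0, dtype=bool))
    if x.size < 32:
        return empty_events(), empty
    # the method operates at 2 kHz regardless of the acquisition rate, so
    # cycle features have a stable sample count per cycle
    fs_proc = 2000.0
    if fs != fs_proc:
        x = resample_to(x, fs, fs_proc)
    fs = fs_proc
    # the narrow-band copy determines where cycle troughs and peaks OUGHT
    # to be; features are then measured on the broadband input at those
    # positions. A genuine in-band oscillation has matching extrema on both
    # versions, so flanks are large and monotone; broadband noise measured
    # at narrow-band extrema gives small, erratic, non-monotone flanks.
    xn = bandpass(x, fs, *locate_band)
    rises = np.where((xn[:-1] < 0) & (xn[1:] >= 0))[0] + 1
    if rises.size < 4:
        return empty_events(), empty
    troughs = np.array([
        a + int(np.argmin(xn[a:b])) for a, b in zip(rises[:-1], rises[1:])
    ])
    troughs = np.unique(troughs)
    if troughs.size < 3:
        return empty_events(), empty
    n_cyc = troughs.size - 1
    peaks = np.array([
        t0 + int(np.argmax(xn[t0:t1 + 1]))
        for t0, t1 in zip(troughs[:-1], troughs[1:])
    ])

    period = (troughs[1:] - troughs[:-1]) / fs
    rise_amp = x[peaks] - x[troughs[:-1]]
    decay_amp = x[peaks] - x[troughs[1:]]
    amp = (rise_amp + decay_amp) / 2.0
    rise_t = (peaks - troughs[:-1]) / fs
    rd_sym = np.clip(rise_t / period, 0.0, 1.0)
    mono = np.empty(n_cyc)
    pt_sym = np.empty(n_cyc)
    for i in range(n_cyc):
        t0, pk, t1 = troughs[i], peaks[i], troughs[i + 1]
        # monotonicity as directed fraction of total variation: a clean
        # flank moves all its variation in one direction, a noise flank
        # wanders (robust even with few samples per cycle)
        rise_steps = np.diff(x[t0: pk + 1])
        decay_steps = np.diff(x[pk: t1 + 1])
        tv_r = np.abs(rise_steps).sum()
        tv_d = np.abs(decay_steps).sum()
        mono_r = max(rise_steps.sum(), 0.0) / tv_r if tv_r > 0 else 0.0
        mono_d = max(-decay_steps.sum(), 0.0) / tv_d if tv_d > 0 else 0.0
        mono[i] = min(mono_r, mono_d)
        seg = x[t0: t1 + 1]
        mid = (x[pk] + (x[t0] + x[t1]) / 2.0) / 2.0
        pt_sym[i] = np.mean(seg > mid)

    # amplitude consistency: the cycle's rise and decay must match each
    # other, and at least one neighboring flank must match too (so a
    # smoothly tapered burst keeps its core cycles while erratic noise
    # fails the within-cycle ratio)
    within = _ratio(rise_amp, decay_amp)
    left = np.r_[1.0, _ratio(decay_amp[:-1], rise_amp[1:])]
    right = np.r_[_ratio(decay_amp[:-1], rise_amp[1:]), 1.0]
    amp_cons = np.minimum(within, np.maximum(left, right))
    per_cons = _neighbor_consistency(period)

    is_burst = (
        (amp_cons >= thr["amplitude_consistency"])
        & (per_cons >= thr["period_consistency"])
        & (mono >= thr["monotonicity"])
        & (amp >= min_amplitude)
    )
    start = troughs[:-1] / fs
    stop = troughs[1:] / fs
    feats = CycleFeatures(start, stop, period, amp, rd_sym, pt_sym, mono, is_burst)

    rows = []
    for i0, i1 in _mask_to_intervals(is_burst):
        if i1 - i0 < min_cycles:
            continue
        seg_amp = amp[i0:i1]
        k_pk = i0 + int(np.argmax(seg_amp))
        dur = stop[i1 - 1] - start[i0]
        rows.append(
            dict(
                kind="ripple",
                start_s=start[i0],
                stop_s=stop[i1 - 1],
                peak_s=(start[k_pk] + stop[k_pk]) / 2.0,
                peak_amp=seg_amp.max(),
                n_cycles=float(i1 - i0),
                peak_freq_hz=(i1 - i0) / dur if dur > 0 else np.nan,
            )
        )
    return make_events(rows), feats


# ---------------------------------------------------------------------------
# consensus, coupling, classes


def consensus_ripples(
    events_power: pd.DataFrame, events_bycycle: pd.DataFrame
) -> pd.DataFrame:
    """Events found by both methods: each power-method event that overlaps
    any cycle-method event by at least one sample; boundaries come from the
    power method."""
    if events_power.empty or events_bycycle.empty:
        return empty_events()
    b_start = events_bycycle["start_s"].to_numpy()
    b_stop = events_bycycle["stop_s"].to_numpy()
    keep = [
        any(_overlaps(r.start_s, r.stop_s, b0, b1)
            for b0, b1 in zip(b_start, b_stop))
        for r in events_power.itertuples()
    ]
    return events_power.loc[keep].reset_index(drop=True)


def couple_to_spw(
    ripples: pd.DataFrame, spws: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition ripples into SPW-coupled (spwr) and solo.

    A ripple is coupled iff it has non-zero overlap with any SPW window
    [peak - halfwidth/2, peak + halfwidth/2), half-open.
    """
    if ripples.empty:
        return empty_events(), empty_events()
    w0 = (spws["peak_s"] - spws["halfwidth_s"] / 2.0).to_numpy() if not spws.empty else np.empty(0)
    w1 = (spws["peak_s"] + spws["halfwidth_s"] / 2.0).to_numpy() if not spws.empty else np.empty(0)
    coupled = np.array([
        any(_overlaps(r.start_s, r.stop_s, a, b) for a, b in zip(w0, w1))
        for r in ripples.itertuples()
    ])
    spwr = ripples.loc[coupled].assign(kind="spwr").reset_index(drop=True)
    solo = ripples.loc[~coupled].assign(kind="solo_ripple").reset_index(drop=True)
    return spwr, solo


def classify_ripple_length(
    ripples: pd.DataFrame, long_min_cycles: float = 3.0
) -> pd.Series:
    """Label each ripple 'long' iff duration x peak frequency reaches
    long_min_cycles (the adult 3-9 cycle definition), else 'short'."""
    if ripples.empty:
        return pd.Series(dtype="object")
    freq = ripples["peak_freq_hz"].to_numpy()
    if np.any(~np.isfinite(freq)):
        raise ValueError("peak_freq_hz missing for some ripples")
    cycles = (ripples["stop_s"] - ripples["start_s"]).to_numpy() * freq
    return pd.Series(
        np.where(cycles >= long_min_cycles, "long", "short"),
        index=ripples.index,
    )


def detect_ihfo(
    pyr_signal: np.ndarray,
    fs: float,
    stim_windows: list[tuple[float, float]],
    thresholds: dict | None = None,
    band: tuple[float, float] = (80.0, 200.0),
) -> tuple[pd.DataFrame, float]:
    """Induced high-frequency oscillations inside stimulation windows.

    Both ripple detectors run on the full signal with the iHFO length
    bound (120 ms); consensus events are assigned to the stimulation
    windows they overlap. Returns the event table (kind 'ihfo') and the
    fraction of windows containing at least one event.
    """
    if not stim_windows:
        raise ValueError("stim_windows must be non-empty")
    ev_p = detect_ripples_power(pyr_signal, fs, band=band, max_len_ms=120.0)
    ev_b, _ = detect_ripples_bycycle(pyr_signal, fs, thresholds=thresholds,
                                     locate_band=band)
    cons = consensus_ripples(ev_p, ev_b)
    hit = np.zeros(len(stim_windows), dtype=bool)
    rows = []
    for r in cons.itertuples():
        for k, (w0, w1) in enumerate(stim_windows):
            if _overlaps(r.start_s, r.stop_s, w0, w1):
                hit[k] = True
                d = r._asdict()
                d.pop("Index", None)
                d["kind"] = "ihfo"
                rows.append(d)
                break
    table = make_events(rows) if rows else empty_events()
    return table, float(hit.mean())


# ---------------------------------------------------------------------------
# movement


def detect_movement(
    xy_traces: np.ndarray,
    frame_rate_hz: float = 14.3,
    px_threshold: float = 25.0,
) -> pd.DataFrame:
    """Movement periods from tracked reference points.

    xy_traces has shape (n_frames, n_points, 2) in pixels. A frame is
    flagged if any point displaces strictly more than px_threshold pixels
    from the previous frame; consecutive flagged frames merge into one
    interval.
    """
    xy = np.asarray(xy_traces, dtype=np.float64)
    if xy.ndim == 2:
        xy = xy[:, None, :]
    if xy.ndim != 3 or xy.shape[-1] != 2:
        raise ValueError("xy_traces must have shape (n_frames, n_points, 2)")
    if xy.shape[0] < 2:
        return empty_events()
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=-1)  # (n_frames-1, n_points)
    moving = np.any(disp > px_threshold, axis=1)
    rows = []
    for i0, i1 in _mask_to_intervals(moving):
        # flag i covers the transition from frame i to i+1
        rows.append(
            dict(
                kind="movement",
                start_s=i0 / frame_rate_hz,
                stop_s=(i1 + 1) / frame_rate_hz,
                peak_s=(i0 + i1 + 1) / 2.0 / frame_rate_hz,
                peak_amp=float(disp[i0:i1].max()),
            )
        )
    return make_events(rows)
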