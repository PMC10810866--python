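"""Ground-truthed synthetic neonatal CA1 recordings.

Emulates the signal statistics of developing hippocampal LFP: a
discontinuous 1/f^chi aperiodic background, sharp waves (SPWs) that reverse
polarity across the pyramidal cell layer, ripple bursts (80-200 Hz) riding
on a subset of SPWs, and SPW-modulated Poisson spike trains. Every injected
event is returned in a ground-truth table so detector sensitivity and false
positives can be measured exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpikeTrainSet, TimeSeries, empty_events, make_events

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Amplitudes in microvolts, times in seconds, rates as stated. The SPW
    waveform is Gaussian with the given full width at half maximum; ripples
    are Hann-windowed sinusoids centered on SPW peaks.
    """

    duration_s: float = 600.0
    fs: float = 1000.0
    aperiodic_exponent: float = 2.0
    aperiodic_offset: float = 2.0
    active_fraction: float = 0.5
    spw_rate: float = 2.0           # events / min
    spw_amplitude_uV: float = -300.0
    spw_halfwidth_ms: float = 60.0
    ripple_prob: float = 0.5
    ripple_freq_hz: float = 140.0
    ripple_cycles: float = 6.0
    ripple_amplitude_uV: float = 50.0
    n_units: int = 20
    baseline_rate_hz: float = 1.0
    spw_modulation_z: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        pos = {
            "duration_s": self.duration_s,
            "fs": self.fs,
            "spw_rate": self.spw_rate,
            "spw_halfwidth_ms": self.spw_halfwidth_ms,
            "ripple_freq_hz": self.ripple_freq_hz,
            "ripple_cycles": self.ripple_cycles,
            "ripple_amplitude_uV": self.ripple_amplitude_uV,
            "baseline_rate_hz": self.baseline_rate_hz,
        }
        for name, v in pos.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.spw_amplitude_uV == 0 or not np.isfinite(self.spw_amplitude_uV):
            raise ValueError("spw_amplitude_uV must be nonzero and finite")
        for name, v in (
            ("active_fraction", self.active_fraction),
            ("ripple_prob", self.ripple_prob),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fs < 4.0 * self.ripple_freq_hz:
            raise ValueError(
                f"fs = {self.fs} must be >= 4 x ripple_freq_hz = {self.ripple_freq_hz}"
            )
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass
class GroundTruth:
    """True injected events plus the per-unit SPW firing gain."""

    events: pd.DataFrame
    unit_modulation: np.ndarray = field(default_factory=lambda: np.empty(0))


def make_aperiodic_noise(
    duration_s: float,
    fs: float,
    exponent: float,
    offset: float = 0.0,
    seed: int | None = None,
) -> TimeSeries:
    """Gaussian noise whose one-sided PSD follows 10**offset / f**exponent.

    Synthesized in the frequency domain: independent complex-Gaussian
    Fourier coefficients scaled by the target amplitude spectrum, inverse
    transformed. The expected Welch PSD therefore has log-log slope exactly
    -exponent, with offset the log10 power density at 1 Hz.
    """
    for name, v in (("duration_s", duration_s), ("fs", fs),
                    ("exponent", exponent), ("offset", offset)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if exponent < 0:
        raise ValueError(f"exponent must be >= 0, got {exponent}")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target_psd = np.zeros_like(freqs)
    target_psd[1:] = 10.0 ** offset / freqs[1:] ** exponent
    # one-sided PSD S relates to rfft coefficients by E|X_k|^2 = S_k * fs * n / 2
    amp = np.sqrt(target_psd * fs * n / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    x = np.fft.irfft(coeff, n=n)
    return TimeSeries(data=x[:, None], fs=fs)


def make_spw_waveform(amplitude_uV: float, halfwidth_ms: float, fs: float) -> np.ndarray:
    """Gaussian deflection with extremum amplitude_uV and FWHM halfwidth_ms."""
    if amplitude_uV == 0:
        raise ValueError("amplitude_uV must be nonzero")
    if halfwidth_ms <= 0:
        raise ValueError("halfwidth_ms must be positive")
    if fs * halfwidth_ms / 1000.0 < 8:
        raise ValueError(
            f"fs = {fs} Hz resolves fewer than 8 samples across a "
            f"{halfwidth_ms} ms FWHM"
        )
    sd_s = halfwidth_ms / 1000.0 / _FWHM_TO_SD
    half_span = int(np.ceil(4.0 * sd_s * fs))
    t = np.arange(-half_span, half_span + 1) / fs
    return amplitude_uV * np.exp(-0.5 * (t / sd_s) ** 2)


def make_ripple_waveform(
    freq_hz: float, n_cycles: float, amplitude_uV: float, fs: float
) -> np.ndarray:
    """Hann-windowed sinusoid: n_cycles cycles at freq_hz, peak amplitude_uV."""
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    if fs < 4.0 * freq_hz:
        raise ValueError(
            f"fs = {fs} Hz would alias a {freq_hz} Hz carrier (need fs >= 4 x f)"
        )
    duration_s = n_cycles / freq_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    window = np.hanning(n)
    return amplitude_uV * window * np.sin(2.0 * np.pi * freq_hz * t)


def _activity_mask(
    n: int, fs: float, active_fraction: float, rng: np.random.Generator,
    mean_active_s: float = 5.0,
) -> np.ndarray:
    """Binary on/off mask from alternating exponential durations.

    Mean on-duration is mean_active_s; the mean off-duration is set so the
    expected on-fraction equals active_fraction.
    """
    if active_fraction >= 1.0:
        return np.ones(n, dtype=bool)
    if active_fraction <= 0.0:
        return np.zeros(n, dtype=bool)
    mean_off_s = mean_active_s * (1.0 - active_fraction) / active_fraction
    mask = np.zeros(n, dtype=bool)
    pos = 0
    state_on = rng.random() < active_fraction
    while pos < n:
        mean = mean_active_s if state_on else mean_off_s
        span = max(1, int(round(rng.exponential(mean) * fs)))
        if state_on:
            mask[pos: pos + span] = True
        pos += span
        state_on = not state_on
    return mask


def _calibrated_spw_gain(
    spec: SyntheticSpec, n_events: int, bin_s: float = 0.01
) -> float:
    """Peak extra per-unit rate (Hz) needed to hit spw_modulation_z.

    Uses the Poisson PETH arithmetic: with lambda = n_units * r0 * bin_s
    expected counts per bin per event, the SD of a PETH averaged over
    n_events anchors is sqrt(lambda / n_events) counts, so the extra count
    at the peak bin must be z * sqrt(lambda / n_events).
    """
    lam = spec.n_units * spec.baseline_rate_hz * bin_s
    extra_counts = spec.spw_modulation_z * np.sqrt(lam / max(n_events, 1))
    return extra_counts / (spec.n_units * bin_s)


def make_recording(
    spec: SyntheticSpec,
) -> tuple[TimeSeries, SpikeTrainSet, GroundTruth]:
    """Generate a two-channel recording (pyramidale, radiale) with truth.

    SPWs appear with opposite polarity on the two channels (the polarity
    reversal across stratum pyramidale); ripples are added on the pyramidale
    channel at a fraction ripple_prob of SPW peaks; spike trains are
    inhomogeneous Poisson with a Gaussian rate gain under each SPW
    calibrated to the requested population z-score.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))

    expected_spws = spec.spw_rate * spec.duration_s / 60.0
    if expected_spws < 1.0 and spec.ripple_prob > 0:
        warnings.warn(
            "expected SPW count < 1 while ripple_prob > 0; the recording "
            "may contain no events",
            stacklevel=2,
        )

    # background: independent shaped noise per channel, gated by activity mask
    chans = []
    for k in range(2):
        bg = make_aperiodic_noise(
            spec.duration_s, spec.fs, spec.aperiodic_exponent,
            spec.aperiodic_offset, seed=int(rng.integers(2**31)),
        ).channel(0)[:n]
        chans.append(bg)
    mask = _activity_mask(n, spec.fs, spec.active_fraction, rng)
    data = np.stack(chans, axis=1)
    # near-isoelectric epochs: gain ramps smoothly (~150 ms) between quiet
    # (0.05) and active (1), so the gating itself adds no broadband clicks
    gain = 0.05 + 0.95 * mask.astype(np.float64)
    ramp = np.hanning(max(3, int(round(0.15 * spec.fs))))
    gain = np.convolve(gain, ramp / ramp.sum(), mode="same")
    data *= gain[:, None]

    # SPW times: homogeneous Poisson, kept clear of the edges
    guard = 2.0 * spec.spw_halfwidth_ms / 1000.0
    n_spw = rng.poisson(expected_spws)
    spw_times = np.sort(rng.uniform(guard, spec.duration_s - guard, size=n_spw))
    # enforce a minimal separation so events never overlap
    min_sep = 4.0 * spec.spw_halfwidth_ms / 1000.0
    keep = np.ones(spw_times.size, dtype=bool)
    for i in range(1, spw_times.size):
        prev = spw_times[:i][keep[:i]]
        if prev.size and spw_times[i] - prev[-1] < min_sep:
            keep[i] = False
    spw_times = spw_times[keep]

    spw_wave = make_spw_waveform(
        spec.spw_amplitude_uV, spec.spw_halfwidth_ms, spec.fs
    )
    half = spw_wave.size // 2
    rows = []
    halfwidth_s = spec.spw_halfwidth_ms / 1000.0
    for t0 in spw_times:
        c = int(round(t0 * spec.fs))
        sl = slice(c - half, c + half + 1)
        data[sl, 0] -= spw_wave  # pyramidale: opposite sign
        data[sl, 1] += spw_wave  # radiale: carries the stated amplitude
        rows.append(
            dict(
                kind="spw",
                start_s=t0 - halfwidth_s,
                stop_s=t0 + halfwidth_s,
                peak_s=t0,
                peak_amp=spec.spw_amplitude_uV,
                halfwidth_s=halfwidth_s,
            )
        )

    # ripples on a ripple_prob fraction of SPWs, centered on the peak
    has_ripple = rng.random(spw_times.size) < spec.ripple_prob
    ripple_wave = make_ripple_waveform(
        spec.ripple_freq_hz, spec.ripple_cycles, spec.ripple_amplitude_uV, spec.fs
    )
    rip_dur = spec.ripple_cycles / spec.ripple_freq_hz
    for t0 in spw_times[has_ripple]:
        c = int(round((t0 - rip_dur / 2.0) * spec.fs))
        data[c: c + ripple_wave.size, 0] += ripple_wave
        rows.append(
            dict(
                kind="ripple",
                start_s=t0 - rip_dur / 2.0,
                stop_s=t0 + rip_dur / 2.0,
                peak_s=t0,
                peak_amp=spec.ripple_amplitude_uV,
                n_cycles=spec.ripple_cycles,
                peak_freq_hz=spec.ripple_freq_hz,
            )
        )

    events = make_events(rows) if rows else empty_events()

    # spikes: per-unit inhomogeneous Poisson with Gaussian SPW gain
    gain_peak = _calibrated_spw_gain(spec, spw_times.size)
    sd_s = halfwidth_s / _FWHM_TO_SD
    dt = 1.0 / spec.fs
    rate = np.full(n, float(spec.baseline_rate_hz))
    t_axis = np.arange(n) * dt
    for t0 in spw_times:
        c = int(round(t0 * spec.fs))
        span = int(np.ceil(4 * sd_s * spec.fs))
        sl = slice(max(0, c - span), min(n, c + span + 1))
        rate[sl] += gain_peak * np.exp(-0.5 * ((t_axis[sl] - t0) / sd_s) ** 2)
    trains: dict[int, np.ndarray] = {}
    unit_mod = np.full(spec.n_units, gain_peak)
    for uid in range(spec.n_units):
        p = rate * dt
        spikes_mask = rng.random(n) < p
        trains[uid] = t_axis[spikes_mask]
    ts = TimeSeries(data=data, fs=spec.fs, depths_um=[0.0, 100.0])
    spikes = SpikeTrainSet(trains=trains, duration_s=spec.duration_s)
    return ts, spikes, GroundTruth(events=events, unit_modulation=unit_mod)


def make_age_trend_table(
    slopes: tuple[float, ...],
    breakpoints: tuple[float, ...],
    noise_sd: float,
    n_per_x: int = 12,
    x_range: tuple[float, float] = (4.0, 12.0),
    intercept: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Piecewise-linear developmental trend with Gaussian noise.

    x is sampled at integer ages across x_range, n_per_x points per age.
    Returns (table, truth) where truth records the generating parameters.
    """
    slopes = tuple(float(s) for s in slopes)
    breakpoints = tuple(float(b) for b in breakpoints)
    if len(slopes) != len(breakpoints) + 1:
        raise ValueError("need exactly one more slope than breakpoints")
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    lo, hi = x_range
    if any(not lo < b < hi for b in breakpoints):
        raise ValueError("breakpoints must lie strictly inside x_range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    xs = np.repeat(np.arange(lo, hi + 0.5), n_per_x)
    y = np.full(xs.size, intercept) + slopes[0] * (xs - lo)
    for slope_next, slope_prev, b in zip(slopes[1:], slopes, breakpoints):
        y += (slope_next - slope_prev) * np.clip(xs - b, 0.0, None)
    y = y + rng.normal(0.0, noise_sd, size=xs.size)
    table = pd.DataFrame({"x": xs, "y": y})
    truth = {
        "slopes": slopes,
        "breakpoints": breakpoints,
        "intercept": intercept,
        "noise_sd": noise_sd,
    }
    return table, truth
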