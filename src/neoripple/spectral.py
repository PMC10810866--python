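"""Power spectra and their periodic/aperiodic parameterization.

The power spectrum of an LFP is modeled in log10 space as an aperiodic
component — a straight line of slope -chi over log10 frequency ("fixed"
mode, no knee) — plus at most one Gaussian peak in linear frequency. The
1/f exponent chi tracks the network excitation/inhibition ratio (steeper =
more inhibition); the Gaussian captures a genuine band-limited oscillation
such as a ripple peak. Fits below an R-squared floor are rejected rather
than interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .io import TimeSeries


@dataclass
class PSD:
    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band(self, f_lo: float, f_hi: float) -> "PSD":
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return PSD(self.freqs[m], self.power[m])


@dataclass
class SpectralFit:
    """Aperiodic offset/exponent, optional single peak, and fit quality.

    offset is log10 power at 1 Hz; exponent is chi of the 1/f^chi aperiodic
    form; peaks hold (center_freq_hz, peak_power in log10 units above the
    aperiodic line, bandwidth_hz as the Gaussian 2*SD width).
    """

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    r2: float = np.nan

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Model log10 power at the given frequencies."""
        freqs = np.asarray(freqs, dtype=np.float64)
        y = self.offset - self.exponent * np.log10(freqs)
        for cf, ph, bw in self.peaks:
            y += ph * np.exp(-0.5 * ((freqs - cf) / (bw / 2.0)) ** 2)
        return y


def welch_psd(
    ts: TimeSeries | np.ndarray,
    fs: float | None = None,
    window_s: float = 1.0,
    overlap_s: float = 0.25,
    channel: int = 0,
) -> PSD:
    """Welch PSD with Hann-tapered overlapping windows (1 s / 250 ms default)."""
    if isinstance(ts, TimeSeries):
        x = ts.channel(channel)
        fs = ts.fs
    else:
        x = np.asarray(ts, dtype=np.float64)
        if fs is None:
            raise ValueError("fs required for array input")
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal length {x.size} shorter than one {window_s} s window"
        )
    freqs, power = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap_s * fs)),
    )
    return PSD(freqs, power)


def notch_line(
    ts: TimeSeries,
    base_hz: float = 50.0,
    n_harmonics: int = 3,
    q: float = 35.0,
) -> TimeSeries:
    """Attenuate the line frequency and its harmonics with narrow IIR notches.

    Applied forward-backward (phase preserving), which doubles the stopband
    attenuation; the default Q keeps the -1 dB band well inside +-5 Hz.
    """
    nyq = ts.fs / 2.0
    if base_hz >= nyq:
        raise ValueError(f"base_hz {base_hz} not below Nyquist {nyq}")
    data = ts.data.copy()
    for k in range(1, n_harmonics + 1):
        f0 = base_hz * k
        if f0 >= nyq:
            break
        b, a = signal.iirnotch(f0, Q=q, fs=ts.fs)
        data = signal.filtfilt(b, a, data, axis=0)
    return TimeSeries(data=data, fs=ts.fs, depths_um=ts.depths_um, units=ts.units)


def _robust_aperiodic(
    logf: np.ndarray, logp: np.ndarray, sd_thresh: float = 2.5,
    n_iter: int = 3,
) -> tuple[float, float]:
    """Line fit of log power vs log frequency, iteratively ignoring bins
    that sit far above the line (oscillatory peaks must not bias the slope).

    Returns (offset, exponent)."""
    mask = np.ones(logf.size, dtype=bool)
    slope, intercept = 0.0, float(np.mean(logp))
    for _ in range(n_iter):
        coeffs = np.polyfit(logf[mask], logp[mask], 1)
        slope, intercept = coeffs[0], coeffs[1]
        resid = logp - (intercept + slope * logf)
        sd = np.std(resid[mask])
        if sd == 0:
            break
        new_mask = resid < sd_thresh * sd
        if new_mask.sum() < max(4, logf.size // 4) or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return intercept, -slope


def _gauss(f: np.ndarray, cf: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((f - cf) / sd) ** 2)


def fit_spectrum(
    psd: PSD,
    f_range: tuple[float, float],
    max_peaks: int = 1,
    peak_width_limits: tuple[float, float] = (2.0, 60.0),
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.15,
) -> SpectralFit:
    """Parameterize a PSD into aperiodic (offset, exponent) + <=1 peak.

    Procedure: (1) robust line fit of log10 power on log10 f; (2) if
    max_peaks == 1, fit one Gaussian (in linear frequency, log power) to
    the largest positive residual provided it exceeds both
    peak_threshold_sd residual SDs and min_peak_height log10 units
    (an absolute floor, since the largest of many noise residuals always
    clears a purely relative threshold), respecting the width limits;
    (3) refit the aperiodic component on the peak-subtracted spectrum.
    R-squared is computed between model and data in log space.
    """
    if max_peaks not in (0, 1):
        raise ValueError("max_peaks must be 0 or 1")
    sub = psd.band(*f_range)
    if sub.freqs.size < 10:
        raise ValueError(
            f"need >= 10 bins in {f_range}, got {sub.freqs.size}"
        )
    if np.any(sub.power <= 0):
        raise ValueError("non-positive power bins in fit range")
    logf = np.log10(sub.freqs)
    logp = np.log10(sub.power)

    offset, exponent = _robust_aperiodic(logf, logp)
    peaks: list[tuple[float, float, float]] = []

    if max_peaks == 1:
        resid = logp - (offset - exponent * logf)
        sd = np.std(resid)
        i_max = int(np.argmax(resid))
        if sd > 0 and resid[i_max] > max(peak_threshold_sd * sd, min_peak_height):
            cf0 = sub.freqs[i_max]
            h0 = resid[i_max]
            sd_lo = peak_width_limits[0] / 2.0
            sd_hi = peak_width_limits[1] / 2.0
            try:
                popt, _ = optimize.curve_fit(
                    _gauss, sub.freqs, resid,
                    p0=[cf0, h0, np.clip(5.0, sd_lo, sd_hi)],
                    bounds=(
                        [f_range[0], 0.0, sd_lo],
                        [f_range[1], 10.0 * max(h0, 0.1), sd_hi],
                    ),
                    maxfev=2000,
                )
                cf, height, gsd = popt
                if height >= min_peak_height:
                    peaks.append((float(cf), float(height), float(2.0 * gsd)))
            except RuntimeError:
                return SpectralFit(offset=offset, exponent=exponent, r2=np.nan)
        if peaks:
            cf, height, bw = peaks[0]
            peak_log = _gauss(sub.freqs, cf, height, bw / 2.0)
            offset, exponent = _robust_aperiodic(logf, logp - peak_log)

    model = SpectralFit(offset=offset, exponent=exponent, peaks=peaks).model(sub.freqs)
    ss_res = np.sum((logp - model) ** 2)
    ss_tot = np.sum((logp - np.mean(logp)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return SpectralFit(offset=offset, exponent=exponent, peaks=peaks, r2=float(r2))


def quality_gate(fit: SpectralFit, r2_min: float = 0.95) -> bool:
    """Accept a fit iff its R-squared is at least r2_min (NaN rejects)."""
    return bool(np.isfinite(fit.r2) and fit.r2 >= r2_min)
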