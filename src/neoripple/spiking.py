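"""Event-locked spiking metrics and developmental trend fits.

Peri-event time histograms (PETHs) z-scored against random-baseline
anchors, per-event modulation, first-spike offsets, spikes-per-event
categories, participation, the symmetric modulation index for
interventions, cross-region (e.g. hippocampus -> prefrontal) event-locked
contrasts, and continuous piecewise-linear ("segmented") regression with
grid-searched breakpoints for developmental trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SpikeTrainSet


@dataclass
class PETH:
    """Population peri-event time histogram.

    bin_centers_s are relative to the event anchor; rate_hz is the mean
    population rate per bin across events; z is the rate z-scored against
    the mean/SD of a random-anchor baseline PETH.
    """

    bin_centers_s: np.ndarray
    rate_hz: np.ndarray
    z: np.ndarray
    n_events: int
    baseline_mean_hz: float
    baseline_sd_hz: float
    degenerate: bool = False


def _event_windows(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start, stop, peak) arrays for the spike-metric window of each event:
    [peak - halfwidth, peak + halfwidth], falling back to the event bounds
    when no halfwidth is recorded."""
    peak = events["peak_s"].to_numpy(dtype=float)
    hw = events["halfwidth_s"].to_numpy(dtype=float) if "halfwidth_s" in events else np.full(peak.size, np.nan)
    start = np.where(np.isfinite(hw), peak - hw, events["start_s"].to_numpy(dtype=float))
    stop = np.where(np.isfinite(hw), peak + hw, events["stop_s"].to_numpy(dtype=float))
    return start, stop, peak


def _pop_counts(
    spikes: SpikeTrainSet, anchors: np.ndarray, window_s: float, bin_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-event population spike counts per bin around anchors."""
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2.0
    pooled = spikes.all_spikes()
    counts = np.zeros(centers.size)
    for a in anchors:
        idx = np.searchsorted(pooled, [a + edges[0], a + edges[-1]])
        rel = pooled[idx[0]: idx[1]] - a
        counts += np.histogram(rel, bins=edges)[0]
    return centers, counts / max(anchors.size, 1)


def draw_baseline_anchors(
    n: int, duration_s: float, exclude: pd.DataFrame | None,
    margin_s: float, rng: np.random.Generator,
) -> np.ndarray:
    """Random anchor times outside all event windows (rejection sampling)."""
    if exclude is not None and not exclude.empty:
        ex0 = exclude["start_s"].to_numpy() - margin_s
        ex1 = exclude["stop_s"].to_numpy() + margin_s
    else:
        ex0 = ex1 = np.empty(0)
    out: list[float] = []
    attempts = 0
    while len(out) < n and attempts < 1000 * n:
        t = rng.uniform(margin_s, duration_s - margin_s)
        attempts += 1
        if not np.any((t >= ex0) & (t < ex1)):
            out.append(t)
    return np.asarray(out)


def peth_z(
    spikes: SpikeTrainSet,
    anchors: np.ndarray,
    window_s: float = 0.2,
    bin_s: float = 0.01,
    baseline_anchors: np.ndarray | None = None,
    exclude_events: pd.DataFrame | None = None,
    seed: int | None = None,
) -> PETH:
    """Population PETH around anchors, z-scored against random baselines.

    The baseline is a PETH built at as many random anchors as there are
    events (drawn outside the event windows when exclude_events is given);
    z per bin = (rate - baseline mean) / baseline SD, where mean and SD
    pool all baseline bins. An empty spike set yields a flagged degenerate
    PETH with NaN z.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.size == 0:
        raise ValueError("need at least one anchor")
    centers, counts = _pop_counts(spikes, anchors, window_s, bin_s)
    rate = counts / (bin_s * max(spikes.n_units, 1))

    if baseline_anchors is None:
        rng = np.random.default_rng(seed)
        baseline_anchors = draw_baseline_anchors(
            anchors.size, spikes.duration_s, exclude_events, window_s, rng
        )
    _, bl_counts = _pop_counts(spikes, np.asarray(baseline_anchors, dtype=float),
                               window_s, bin_s)
    bl_rate = bl_counts / (bin_s * max(spikes.n_units, 1))
    mu, sd = float(np.mean(bl_rate)), float(np.std(bl_rate))
    if sd == 0 or not np.isfinite(sd):
        return PETH(centers, rate, np.full(centers.size, np.nan),
                    anchors.size, mu, sd, degenerate=True)
    return PETH(centers, rate, (rate - mu) / sd, anchors.size, mu, sd)


def fraction_modulated_events(
    spikes: SpikeTrainSet,
    spws: pd.DataFrame,
    z_crit: float = 2.0,
    window_s: float = 0.05,
    bin_s: float = 0.01,
    seed: int | None = None,
) -> float:
    """Fraction of SPWs whose population spiking is positively modulated.

    Per event, spike counts are binned within +-window_s of the peak and
    z-scored against the pooled random-baseline bin distribution; an event
    is modulated iff its maximum bin z reaches z_crit.
    """
    if z_crit <= 0:
        raise ValueError("z_crit must be positive")
    if spws.empty:
        raise ValueError("no events supplied")
    peaks = spws["peak_s"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    bl_anchors = draw_baseline_anchors(
        max(len(peaks), 50), spikes.duration_s, spws, window_s, rng
    )
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    pooled = spikes.all_spikes()
    bl_counts = np.concatenate(
        [np.histogram(pooled[np.searchsorted(pooled, a + edges[0]):
                             np.searchsorted(pooled, a + edges[-1])] - a,
                      bins=edges)[0] for a in bl_anchors]
    )
    mu, sd = bl_counts.mean(), bl_counts.std()
    if sd == 0:
        sd = np.sqrt(max(mu, 1e-12))  # Poisson fallback for sparse baselines
    n_mod = 0
    for a in peaks:
        c = np.histogram(
            pooled[np.searchsorted(pooled, a + edges[0]):
                   np.searchsorted(pooled, a + edges[-1])] - a, bins=edges
        )[0]
        if ((c - mu) / sd).max() >= z_crit:
            n_mod += 1
    return n_mod / len(peaks)


def first_spike_offsets(
    spikes: SpikeTrainSet, spw_events: pd.DataFrame
) -> np.ndarray:
    """First-spike offset per (unit, event): the time of the unit's first
    spike inside the event window minus the SPW peak time. Units silent
    during an event contribute nothing."""
    start, stop, peak = _event_windows(spw_events)
    offsets = []
    for train in spikes.trains.values():
        for s0, s1, pk in zip(start, stop, peak):
            i0, i1 = np.searchsorted(train, [s0, s1])
            if i1 > i0:
                offsets.append(train[i0] - pk)
    return np.asarray(offsets)


def empirical_cdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted values, cumulative fraction)."""
    v = np.sort(np.asarray(values, dtype=float))
    return v, np.arange(1, v.size + 1) / v.size


def spikes_per_event_categories(
    spikes: SpikeTrainSet, events: pd.DataFrame
) -> dict[str, float]:
    """Percentage of participating (unit, event) pairs contributing 1, 2-3,
    or >=4 spikes inside the event window. Percentages sum to 100."""
    start, stop, _ = _event_windows(events)
    cats = {"1": 0, "2-3": 0, ">=4": 0}
    for train in spikes.trains.values():
        i0 = np.searchsorted(train, start)
        i1 = np.searchsorted(train, stop)
        for n in (i1 - i0):
            if n == 1:
                cats["1"] += 1
            elif 2 <= n <= 3:
                cats["2-3"] += 1
            elif n >= 4:
                cats[">=4"] += 1
    total = sum(cats.values())
    if total == 0:
        return {k: np.nan for k in cats}
    return {k: 100.0 * v / total for k, v in cats.items()}


def participation_metrics(
    spikes: SpikeTrainSet, events: pd.DataFrame
) -> tuple[dict[int, float], np.ndarray]:
    """(per-unit participation fraction, per-event participating-unit count).

    A unit participates in an event iff it fires at least one spike inside
    the event window."""
    start, stop, _ = _event_windows(events)
    n_ev = len(events)
    per_unit: dict[int, float] = {}
    per_event = np.zeros(n_ev, dtype=int)
    for uid, train in spikes.trains.items():
        hits = np.searchsorted(train, stop) > np.searchsorted(train, start)
        per_unit[uid] = hits.mean() if n_ev else np.nan
        per_event += hits.astype(int)
    return per_unit, per_event


def rate_peak_timing(peth: PETH) -> tuple[float, bool]:
    """Offset (s) of the PETH maximum from the anchor; negative = before.

    Returns (offset_s, flagged); flagged is True when the maximum is a
    plateau (tie broken to the earliest bin) or the PETH is flat."""
    z = peth.z if np.all(np.isfinite(peth.z)) else peth.rate_hz
    if np.ptp(z) == 0:
        return np.nan, True
    i = int(np.argmax(z))
    flagged = bool(np.sum(z == z[i]) > 1)
    return float(peth.bin_centers_s[i]), flagged


def modulation_index(rate_pre: float, rate_post: float) -> float:
    """Symmetric modulation index (post - pre) / (post + pre) in [-1, 1]."""
    if rate_pre < 0 or rate_post < 0:
        raise ValueError("rates must be nonnegative")
    total = rate_pre + rate_post
    if total == 0:
        return np.nan
    return (rate_post - rate_pre) / total


def coupled_region_contrast(
    target_spikes: SpikeTrainSet,
    spw_events: pd.DataFrame,
    spwr_events: pd.DataFrame,
    window_s: float = 0.1,
    bin_s: float = 0.01,
    seed: int | None = None,
) -> tuple[PETH, PETH, float]:
    """Event-locked firing of a second region: SPWs without ripples vs
    SPW-ripple events.

    Returns (peth_spw, peth_spwr, contrast) where contrast is the mean z
    inside the event window for SPW-Rs minus that for plain SPWs; both
    PETHs share one baseline drawn outside all events.
    """
    if spw_events.empty or spwr_events.empty:
        raise ValueError("both event sets must be non-empty")
    rng = np.random.default_rng(seed)
    all_events = pd.concat([spw_events, spwr_events], ignore_index=True)
    n_bl = max(len(spw_events), len(spwr_events))
    bl = draw_baseline_anchors(n_bl, target_spikes.duration_s, all_events,
                               window_s, rng)
    p_spw = peth_z(target_spikes, spw_events["peak_s"].to_numpy(),
                   window_s, bin_s, baseline_anchors=bl)
    p_spwr = peth_z(target_spikes, spwr_events["peak_s"].to_numpy(),
                    window_s, bin_s, baseline_anchors=bl)
    half = window_s / 2.0
    m = np.abs(p_spw.bin_centers_s) <= half
    contrast = float(np.nanmean(p_spwr.z[m]) - np.nanmean(p_spw.z[m]))
    return p_spw, p_spwr, contrast


# ---------------------------------------------------------------------------
# piecewise-linear ("segmented") regression


@dataclass
class PiecewiseFit:
    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    intercept: float
    sse: float
    n_breakpoints: int
    bic: float
    breakpoint_ci: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = self.intercept + self.slopes[0] * x
        for s_next, s_prev, b in zip(self.slopes[1:], self.slopes, self.breakpoints):
            y += (s_next - s_prev) * np.clip(x - b, 0.0, None)
        return y


def _fit_given_breaks(
    x: np.ndarray, y: np.ndarray, breaks: tuple[float, ...]
) -> tuple[float, tuple[float, ...], float]:
    """Least squares for a continuous piecewise-linear model with fixed
    breakpoints (hinge basis). Returns (intercept, slopes, sse)."""
    cols = [np.ones_like(x), x]
    cols += [np.clip(x - b, 0.0, None) for b in breaks]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sse = float(resid @ resid)
    slopes = [coef[1]]
    for d in coef[2:]:
        slopes.append(slopes[-1] + d)
    return float(coef[0]), tuple(float(s) for s in slopes), sse


def _grid(x: np.ndarray, resolution: float) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    margin = 0.05 * (hi - lo)
    g = np.arange(lo + margin, hi - margin + resolution / 2, resolution)
    return np.round(g / resolution) * resolution


def _best_fit(
    x: np.ndarray, y: np.ndarray, k: int, resolution: float
) -> PiecewiseFit:
    n = x.size
    if k == 0:
        ic, slopes, sse = _fit_given_breaks(x, y, ())
        best = ((), ic, slopes, sse)
    else:
        grid = _grid(x, resolution)
        best = None
        if k == 1:
            for b in grid:
                ic, slopes, sse = _fit_given_breaks(x, y, (b,))
                if best is None or sse < best[3]:
                    best = ((float(b),), ic, slopes, sse)
        else:  # k == 2
            for i, b1 in enumerate(grid):
                for b2 in grid[i + 1:]:
                    ic, slopes, sse = _fit_given_breaks(x, y, (b1, b2))
                    if best is None or sse < best[3]:
                        best = ((float(b1), float(b2)), ic, slopes, sse)
        if best is None:
            raise ValueError("breakpoint grid is empty; x-range too narrow")
    breaks, ic, slopes, sse = best
    n_par = 2 + 2 * k  # intercept, base slope, (position + slope change) per break
    bic = n * np.log(max(sse / n, 1e-300)) + n_par * np.log(n)
    return PiecewiseFit(breaks, slopes, ic, sse, k, float(bic))


def piecewise_linear_fit(
    x: np.ndarray,
    y: np.ndarray,
    n_breakpoints: int | None = 1,
    n_boot: int = 0,
    resolution: float = 0.05,
    seed: int | None = None,
) -> PiecewiseFit:
    """Continuous piecewise-linear least squares with grid-searched breaks.

    Breakpoints are scanned over the interior of the x-range at the given
    resolution, choosing minimal SSE. When n_breakpoints is None the model
    order (0, 1 or 2 breaks) is selected by BIC. Optional case-resampling
    bootstrap gives percentile confidence intervals for the breakpoints.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is degenerate (all values equal)")
    if n_breakpoints is not None and n_breakpoints not in (0, 1, 2):
        raise ValueError("n_breakpoints must be 0, 1, 2 or None")
    k_cands = (0, 1, 2) if n_breakpoints is None else (n_breakpoints,)
    if x.size < 4 + 2 * max(k_cands):
        raise ValueError("too few points for the requested model order")

    fits = [_best_fit(x, y, k, resolution) for k in k_cands]
    fit = min(fits, key=lambda f: f.bic)

    if n_boot > 0 and fit.n_breakpoints > 0:
        rng = np.random.default_rng(seed)
        boot = np.full((n_boot, fit.n_breakpoints), np.nan)
        for i in range(n_boot):
            idx = rng.integers(0, x.size, size=x.size)
            try:
                bf = _best_fit(x[idx], y[idx], fit.n_breakpoints, resolution)
                boot[i] = bf.breakpoints
            except (ValueError, np.linalg.LinAlgError):
                continue
        fit.breakpoint_ci = [
            (float(np.nanpercentile(boot[:, j], 2.5)),
             float(np.nanpercentile(boot[:, j], 97.5)))
            for j in range(fit.n_breakpoints)
        ]
    return fit
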