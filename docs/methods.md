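# Methods

## Scope

`neoripple` implements two coupled pieces of machinery used to study how
sharp wave-ripples (SPW-Rs) emerge in the developing hippocampal CA1
circuit:

1. a spiking network model of CA1 in which the strength of perisomatic
   inhibition is the experimental dial, and
2. the complete LFP/spike analysis pipeline — active-period, SPW and
   dual-method ripple detection, aperiodic/periodic spectral
   parameterization, event-locked spiking metrics, and segmented
   (piecewise-linear) developmental trend fits — exercised on synthetic
   recordings with exact ground truth.

## The network model

Two leaky integrate-and-fire populations: 12000 excitatory pyramidal
cells (E) and 200 inhibitory PV+ basket cells (I), the anatomical 60:1
ratio for a slice holding ~4% of the hippocampus (221 cells from the
5530-cell whole-structure estimate, 184 from layer density; 200 is the
adopted compromise). Connectivity is an Erdős–Rényi graph per ordered
class with p_EE = 0.0164, p_IE = 0.1 (onto I from E), p_EI = 0.1,
p_II = 0.2, no self- or duplicate connections. Synapses are
conductance-based biexponentials normalized so the peak equals the stated
peak conductance — this normalization is what makes the inhibition
multipliers well defined: c_gei scales the I→E peak conductance, c_gii
the I→I one, and 1 is the "adult" circuit.

Membrane equations are integrated with Euler–Maruyama at dt = 0.1 ms.
Additive voltage noise is scaled from the Ornstein–Uhlenbeck stationary
variance so the free membrane's voltage SD equals σ = 5 mV; at this level
the network spikes spontaneously without input. Voltages start from
N(E_L, 0.1 mV). To mimic the CA3 excitatory volley during a sharp wave, a
random 10% of E cells receive Gaussian current pulses (SD 10 ms) with
per-cell center jitter (SD 5 ms) and amplitude 1000 pA; the pulse length
was chosen so a 100 ms run contains enough ripple cycles for a resolvable
spectral peak. The LFP proxy is the sum of absolute AMPA and GABA
currents over all E cells.

### Parameter provenance

Neuron and synapse constants (capacitance, leak, thresholds, kinetics,
delays) follow the adult CA1 ripple-model lineage (fast I cells,
GABA_A decay near 1 ms, ~1 ms conduction delays) and were then calibrated
as a set against the target behaviors rather than constant-by-constant:

- adult network (c_gei = c_gii = 1) oscillates near 150 Hz upon drive;
- an E→I conductance sweep leaves frequency near 150 Hz while power grows;
- an I→I sweep keeps the oscillation at every level and moves frequency
  from ~110 Hz (c_gii = 0.05) to ~160–180 Hz (c_gii = 2);
- runaway activity (E rate pinned near the refractory ceiling for
  > 20 ms) appears only below c_gei ≈ 0.095, making 0.095 the smallest
  usable multiplier. The recurrent E→E peak conductance (0.25 nS) is the
  constant that places this boundary.

All constants are plain dataclass fields and can be overridden from YAML.

### Spectral readout

The model PSD is the squared FFT magnitude of the Hann-windowed,
mean-subtracted LFP, zero-padded 4× and median-filtered with a kernel of
3 pre-padding frequency bins (the kernel is specified in independent bins
so it genuinely suppresses the exponential single-realization
periodogram fluctuations). `extract_peak` takes the maximal 80–250 Hz
bin; an oscillation is declared present only when that maximum is
interior to the band (a monotone background peaks at an edge) and exceeds
5× a robust aperiodic baseline — a log-log line fitted over 30–400 Hz
with iterative down-weighting of bins far above the line, so a broad
in-band hump cannot inflate its own baseline.

### Known limitations of the model

- No spatial structure, gap junctions, or additional interneuron classes.
- The fine timing effect of inhibition on the E-rate peak relative to the
  drive center (earlier peaks at stronger I→E inhibition) is not robustly
  reproduced by this parameter set: with 0.5 ms rate smoothing the peak
  locks to single ripple volleys, and on envelope scales the symmetric
  drive dominates. `rate_peak_offset_vs_drive` measures the quantity; we
  make no claim about its direction here.

## Synthetic recordings

`synth.make_recording` composes, with exact ground truth:

- a 1/f^χ Gaussian background per channel, synthesized in the frequency
  domain (complex-Gaussian coefficients scaled to the target PSD, so the
  expected log-log slope is exactly −χ and the offset is the log10 power
  density at 1 Hz);
- discontinuity: an on/off activity mask with exponential dwell times
  (mean active bout 5 s) tuned to the requested active fraction; the gain
  ramps over ~150 ms between quiet (×0.05) and active (×1) so the gating
  itself introduces no broadband clicks;
- SPWs: Gaussian deflections (default −300 µV, FWHM 60 ms) at Poisson
  times, appearing with opposite polarity on the two channels (pyramidale
  vs radiale) to emulate the laminar polarity reversal; a minimum
  separation of four half-widths prevents overlap;
- ripples: Hann-windowed sinusoids (default 140 Hz, 6 cycles, 50 µV) on
  the pyramidale channel, centered on a `ripple_prob` fraction of SPW
  peaks;
- spikes: per-unit inhomogeneous Poisson trains whose rate gains a
  Gaussian bump under each SPW. The gain is calibrated analytically from
  the Poisson PETH arithmetic so the population PETH at true SPW peaks
  reads `spw_modulation_z` baseline SDs (default 3). Note the per-seed
  *read-out* of that z has ~1 SD estimator noise by construction — tests
  therefore average over seeds.

What the generator does not emulate: the 7-channel laminar geometry (two
channels suffice for the detectors), electrode artifacts, non-Poisson
spike statistics (bursting, refractoriness), movement artifacts, and any
age-dependence — developmental trends are provided separately by
`make_age_trend_table` as piecewise-linear series with Gaussian noise.
Passing recovery tests on this corpus demonstrates correctness of the
detector logic at realistic SNR, not performance on real neonatal data,
where threshold choices are per-animal.

## Detection pipeline

All intervals are half-open `[start, stop)` in seconds; thresholds that
the pipeline actually uses are logged in the run manifest.

- **Active periods**: 4–12 Hz band-pass, downsample to 250 Hz, square,
  500 ms boxcar. Thresholds act on the RMS envelope (square root of the
  smoothed power) so the microvolt criteria are meaningful: label
  > 1 SD or 50 µV, merge gaps < 1 s, discard peaks reaching neither 2 SD
  nor 100 µV, drop events < 300 ms. Because the boxcar smears any burst
  by ~250 ms per side, labeled intervals are shrunk by half the window
  before the duration rule — otherwise a 200 ms burst would pass.
- **SPWs**: detected on the radial difference (above − below the
  pyramidal layer; each channel downsampled to 250 Hz then band-passed
  1–100 Hz). Peaks above mean + m·SD with prominence ≥ half the threshold
  qualify; the full width at half the peak height (measured by walking
  out from the peak, matching the halfheight width convention) must be
  ≤ 100 ms. The multiplier m maps linearly from 5 (quiet, low-SD signals)
  to 3 (high-SD signals) between configurable calibration bounds — the
  adaptive compensation for developmental amplitude growth.
- **Ripples, power method**: band-limit to 80–200 Hz (alternatives
  100–200/100–300/80–250/100–250 are config), square, 16 ms boxcar
  (~two ripple cycles; at 8 ms the noise floor violates the
  false-positive budget), then: label > 3 SD, merge gaps < 30 ms, drop
  events whose smoothed-power peak stays below 6 SD, keep durations
  strictly between 20 and 100 ms (120 ms in iHFO mode). Event boundaries
  are refined to the first/last instantaneous-power exceedance inside
  each smeared interval, which also makes brief noise blips fail the
  duration bound on their true extent.
- **Ripples, cycle-by-cycle method**: runs at 2 kHz regardless of input
  rate. A narrow-band (80–200 Hz) copy locates candidate troughs and
  peaks; features are then measured on the broadband signal at those
  positions. A genuine oscillation has matching extrema in both versions
  (large, monotone flanks); broadband noise read at narrow-band extrema
  gives small, erratic flanks. Per cycle: period (trough-to-trough),
  amplitude (mean of rise and decay flanks), rise-decay and peak-trough
  symmetry, and monotonicity as the directed fraction of each flank's
  total variation (the worst of the two flanks). A cycle is part of a
  burst iff period consistency vs both neighbors, amplitude consistency
  (the cycle's two flanks must match each other and at least one
  neighboring flank — tolerant of a smoothly tapered burst envelope,
  intolerant of erratic jumps), and monotonicity all reach their
  thresholds (defaults 0.6 each, per-animal in practice). Events are runs
  of ≥ 2 burst cycles: with a tapered ripple envelope only the core
  cycles are mutually consistent, so demanding 3 would discard short
  (4-cycle) ripples entirely.
- **Consensus**: power-method events overlapping ≥ 1 sample with any
  cycle-method event; boundaries from the power method. Coupling to SPWs
  uses the window [peak − halfwidth/2, peak + halfwidth/2), non-zero
  overlap, half-open semantics. Length classes: long iff
  duration × peak frequency ≥ 3 cycles (the adult 3–9 cycle definition;
  the exact cutoff is not canonical and is configurable).
- **iHFOs**: both detectors with the 120 ms bound; the reported fraction
  is stimulation windows containing ≥ 1 consensus event.
- **Movement**: any tracked point displacing strictly more than 25 px
  between consecutive frames flags the frame; runs merge into intervals.

## Spectral parameterization

Welch PSD (1 s Hann windows, 250 ms overlap), narrow IIR notches at the
line frequency and harmonics (forward-backward, ≥ 20 dB at center,
< 1 dB at ±5 Hz). The parameterization fits, in log10-power space, an
aperiodic line over log10 frequency ("fixed" mode — no knee) with
iterative down-weighting of bins > 2.5 residual SDs above the line, plus
at most one Gaussian (linear frequency, width limits 2–60 Hz) fitted to
the largest positive residual. A peak must clear both 2 residual SDs and
an absolute floor of 0.15 log10 units — the floor exists because the
largest of a hundred noise residuals always clears a purely relative
threshold. The aperiodic component is refit on the peak-subtracted
spectrum; R² is computed in log space and fits below 0.95 are rejected by
the quality gate (boundary inclusive).

A practical note on accuracy: a single noise realization carries
irreducible per-frequency power fluctuations, so the fitted exponent of
one 600 s realization scatters with SD ≈ 0.07 over the 25–45 Hz range;
averaging a handful of realizations recovers χ to ±0.1.

## Event-locked spiking metrics

Population PETHs bin pooled spikes around event anchors; z-scoring uses
the mean and SD pooled over the bins of a random-anchor baseline PETH
built from as many anchors as there are events, drawn outside all event
windows. The spike-metric window per SPW is [peak − halfwidth,
peak + halfwidth]. "Modulated" means the per-event binned z reaches 2
within ±50 ms of the peak (the criterion is configurable; no canonical
value exists). First-spike offsets, spikes-per-event categories (1, 2–3,
≥ 4, percentages over participating unit-event pairs), participation
fractions and the cross-region contrast (mean in-window z at SPW-R
anchors minus that at ripple-free SPW anchors, shared baseline) follow
directly. The modulation index is the standard symmetric
(post − pre)/(post + pre).

## Piecewise-linear ("segmented") trend fits

Continuous piecewise-linear least squares via a hinge basis; breakpoints
are grid-searched over the interior of the x-range at 0.05 resolution
(5% margins), choosing minimal SSE; model order (0/1/2 breakpoints) by
BIC when not forced; confidence intervals by case-resampling bootstrap
percentiles. On the synthetic age-trend fixture (slopes 0 → 0.8, break at
9.75, noise SD 0.2, 12 points per age 4–12) recovery has |bias| < 0.1 and
RMSE < 0.1 age-days.

## Problem sizes used in tests and the acceptance script

Sweeps use 8 multiplier levels × 5 seeded realizations of 100 ms each
(the full 12000/200 network; a run takes well under a second with the
vectorized integrator and geometric-skip connectivity sampling).
Synthetic-recording tests use 300–600 s at 1 kHz. These sizes give stable
medians while keeping a full run of the suite in the low minutes; all of
them are arguments, not constants.
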