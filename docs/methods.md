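# Methods

This note documents the models, conventions, parameter defaults, and design
choices behind `alphalock`, and what the synthetic-data tests do and do not
demonstrate about real EEG.

## Conventions

All phases are cosine-convention degrees in [0, 360): 0° is the oscillation
peak, 180° the trough. Signed circular differences wrap to (−180°, 180°];
phase error is `actual − target`, so a negative value means the stimulus
fired early. Times are seconds, amplitudes microvolts, sampling rates Hz. The
default sampling rate is 501 Hz.

## The virtual subject (`synthgen`)

A recording is a 1/f aperiodic background plus a narrowband alpha oscillator:

- **Oscillator**: `alpha_amp · cos(φ(t))` with `φ(t)` advancing at
  `360·IAF` deg/s from a seed-drawn start phase. The per-sample phase is kept
  as ground truth, so every phase estimator in the package can be scored
  exactly. IAF is accepted in 7.5–16 Hz. An optional slow (0.1 Hz) amplitude
  modulation emulates waxing/waning; it is off by default so amplitude-based
  assertions stay deterministic.
- **Background**: white Gaussian noise spectrally shaped to power ∝ 1/f^χ
  (default χ = 1), rescaled to a target RMS (`noise_amp`, default 3 µV
  against 8 µV alpha in high-alpha regimes and 1.5 µV alpha in the
  random-phase task — mirroring the task-dependent prestimulus alpha levels
  the paradigm is built on).
- **Second channel**: "Fz" is a scaled (0.8) copy of "Fpz" lagging by 10° of
  alpha phase, emulating the small inter-electrode phase shift; analyses
  target Fpz.
- **Event schedules**: ISIs are discrete uniform draws — 878–1,634 ms at 1 ms
  steps (random-phase task), 1,628–1,650 ms at 10 ms steps (trough/peak
  task) — after a 30 s baseline.
- **Evoked responses**: five components (Pa 25 ms, P1 60 ms, N1 102 ms,
  P2 160 ms, N2 260 ms by default, each inside its conventional search
  window) shaped as half-cosines under a Gaussian taper with peak value equal
  to the signed amplitude. Phase-dependent modulation enters as per-condition
  multiplicative gains; the defaults encode the trough/peak amplitude ratios
  of typical frontal recordings (Pa smaller, P1/N1/P2 larger for trough
  delivery).

What the generator does **not** emulate: eye-blink/EMG artifacts beyond
injected spikes, non-stationary IAF drift, inter-trial alpha amplitude
correlations, volume-conduction mixtures, or the previous trial's evoked
tail in the prestimulus window (responses are embedded after the closed-loop
tracking run, so the tracker sees only the ongoing background). Passing tests
therefore demonstrate correctness of the algorithms under stationary,
well-specified conditions — not robustness to every property of human EEG.

## Endpoint-corrected Hilbert transform (`echt`)

For a trailing window of N samples: (1) DFT; (2) one-sided analytic spectrum
(zero the negative-frequency bins, double the strictly positive ones, leave
DC/Nyquist); (3) multiply by the complex frequency response of a causal
Butterworth bandpass evaluated at the bin frequencies; (4) inverse DFT;
(5) read the final sample. The causal filter's one-sided impulse response
displaces the wraparound (Gibbs) error away from the endpoint. The
standard-Hilbert comparator applies the same causal filter in the time domain
followed by the ordinary analytic construction; its endpoint carries a
~25–30° distortion even on noise-free alpha, which is the phenomenon the
correction removes.

Engineering choices (the device's internals are proprietary; these are ours):

- **Filter**: 2nd-order Butterworth, passband IAF·(1 ± 0.25). Low order keeps
  the group delay short; the fractional band tracks the IAF.
- **Window**: 512 ms (256 samples at 501 Hz), widened automatically to cover
  at least 4 cycles at the center frequency. Configurable.
- **Phase calibration**: both readouts divide out the filter's phase response
  at the center frequency. A digital Butterworth's zero-phase point is the
  geometric band center, not the arithmetic one, so an uncalibrated readout
  would carry a constant ~10° bias at the IAF — a calibrated device nulls
  this against its own filter.
- **Trigger**: after the drawn ISI elapses the trigger arms and fires at the
  first sample where the predicted time to target — assuming phase advances
  at the filter center frequency, not the instantaneous estimate — is at most
  one sample period. Prediction at the center frequency is simpler and
  robust; it is a documented limitation when the true frequency drifts. If
  the target is not reached within one cycle past arming the trial fires at
  best approach and is flagged. Firing "when within one sample" makes the
  loop systematically slightly early: a few degrees of negative phase error
  at PLV ≈ 0.99+ on clean input.
- **Audio-path latency** compensation is a configurable phase advance,
  default 0 (no hardware in the loop).
- Warm-up samples (the first window−1) are flagged and excluded downstream.

## Spectral analyses (`spectral`)

- **Multitaper spectrogram**: 4 DPSS tapers (NW = 2.5) on a 6 s window
  stepped by 150 ms; power in µV²/Hz.
- **IAF**: third-order polynomial fit to log10 power over 1–40 Hz (excluding
  7–14 Hz so the alpha bump does not pull the trend) is subtracted; the IAF
  is the largest local maximum of the residual in 7.5–16 Hz, refined to the
  power-weighted centroid of the contiguous half-power extent around the
  peak. The refinement matters because the multitaper main lobe (±0.42 Hz) is
  wider than the 1/6 Hz bin: a pure tone appears as a flat-topped plateau
  whose argmax bin is arbitrary, while its centroid is the tone frequency.
  The fit span and log/linear choice are exposed; a second detrending method
  ("aperiodic", a straight-line fit of log power against log frequency — a
  minimal offset+exponent aperiodic model) is available under the same
  interface for the prestimulus-power analyses.
- **Morlet transform**: kernels `e^{−i2πft}·e^{−t²/(2σ²)}` with
  `σ = c/(2πf)`; 140 linearly spaced frequencies 1–70 Hz, cycles linearly
  5–12. Two reading notes: the transform is the *inner product* with the
  wavelet, so the convolution kernel is the conjugate (otherwise phases would
  rotate backward); and the Gaussian denominator is `2σ²` (the common
  convention consistent with the cycle definition). Kernels are truncated at
  ±3.5σ and normalized so a unit in-band cosine has unit envelope. Epochs are
  reflect-padded by half the longest kernel support (capped at the epoch
  length, with a warning when the cap bites — at 1 Hz the kernel is longer
  than a standard epoch) and the padding discarded.
- **Instantaneous frequency**: causal IAF±25% bandpass, then either the full
  analytic signal (`sht`) or the per-sample ecHT endpoint track; phase
  unwrapped, differenced, scaled by fs/2π. Unsmoothed by default; an optional
  median filter (width in ms) suppresses the sample-level ripple the endpoint
  readout shows on frequency-modulated signals. Samples with envelope below a
  floor are flagged undefined.
- **Prestimulus PSD**: per-trial periodograms over a −500 ms (or −700 ms)
  window, averaged, then aperiodic-detrended (method-tagged). The **evoked
  spectrum** transforms the trial *average* instead, cancelling activity that
  is not time- and phase-locked to onset.

## ERP analysis (`erp`)

Preprocessing is a zero-phase 0.2–70 Hz Butterworth bandpass applied as a
highpass+lowpass cascade: a single 4th-order bandpass with a 0.2 Hz cutoff at
fs = 501 Hz has near-unit-circle poles whose edge transients leak through
filtfilt's default padding (measured −18 dB at 100 Hz instead of the nominal
−30 dB); the cascade keeps both stages well conditioned. Epochs span −0.25 to
0.5 s (ERP) or −0.25 to 0.9 s (power analyses). Artifact rejection removes
trials whose per-sample squared amplitude strictly exceeds 100 µV² (i.e.
|x| > 10 µV anywhere; the alternative epoch-variance reading is configurable).
ERPs are 2–34 Hz smoothed per trial (a flag filters the average instead) and
averaged over kept trials; components are the largest interior local extremum
in fixed windows — Pa 1–45, P1 45–80, N1 80–150, P2 150–220, N2 220–400 ms —
with boundary extrema flagged and ties broken to the earliest latency.

Note on amplitude fidelity: the 2–34 Hz smoothing attenuates the narrow
Pa/P1 deflections by 35–48% (their energy extends above 34 Hz), so absolute
template amplitudes are recovered only on the unsmoothed average; on the
smoothed ERP, amplitudes are meaningful *across conditions*, which is how
they are used.

## Evoked/induced decomposition (`evoked_induced`)

ITPC = |mean of unit phase vectors| per (frequency, time); group ITPC is
Fisher-z averaged per subject map before any band averaging. Total power =
mean |φ|², evoked power = |mean φ|², induced power = mean |φ̂|² where φ̂ are
coefficients of trials after subtracting the subject's trial-average signal
in the time domain (before the wavelet transform — not a spectral
subtraction). Baseline normalization subtracts the per-frequency mean over
−250 to −50 ms from total and induced power (so both are comparable);
negative values read as desynchronization. Identities used as tests: evoked ≤
total pointwise; identical trials give ITPC = 1 and zero induced power; when
the ERP estimate is exact, total = evoked + induced.

The alpha ERO is the complex trial-average at the wavelet nearest the IAF;
with phase-locked delivery the prestimulus alpha survives averaging, and its
envelope drop after peak-locked sounds is the signature effect.

## Phase metrics (`phase_metrics`)

PLV and phase error are the resultant length and circular mean of per-trial
target-vs-actual differences. Phase stationarity correlates pre- and
post-stimulus half-cycle phases per subject (Jammalamadaka–SenGupta circular
correlation, cross-checked against pingouin), Fisher-z, absolute value,
averaged, transformed back. One caveat: under tightly phase-locked delivery
the across-trial phase variance is small, so this correlation is dominated by
estimator noise and lands well below 1 even for a perfectly stationary
oscillator — with naturally variable delivery phases it approaches 1. P1–alpha
alignment samples the causal phase track at t = P1 latency per trial and
reports the circular mean, SD, and the angular lead to the expected landmark
(the true peak for trough delivery, the true trough for peak delivery).

## Statistics (`stats`)

The cluster permutation test swaps paired condition means within subject
(random sign flips), z-scores the observed mean difference per point against
the permutation distribution, thresholds |z| at the two-sided voxel α, forms
contiguous supra-threshold runs, and takes the 95th percentile of
per-permutation maximum cluster sizes as the corrected threshold. Cluster
size is extent (point count) by default with cluster mass (summed |z|) as an
option. Extent sizes are integers and tie heavily on short grids, which makes
the `> 95th percentile` rule strictly conservative (measured family-wise
error 0.000–0.005 at nominal 0.05 on 40–150-point grids); the continuous mass
statistic achieves the nominal rate (0.050 over 200 null replicates).
Two-sided testing throughout.

Rayleigh's test comes from pingouin; Watson's two-sample U² is implemented
here (statistic per Watson 1962; asymptotic p from the alternating
exponential series, permutation fallback forced below n = 5). The
Wald–Wolfowitz runs test z-scores the run count against the exact null
moments. Benjamini–Hochberg adjustment delegates to statsmodels.

## Pipeline and simulation sizes

`run_experiment` chains, per subject: eyes-closed baseline → multitaper PSD →
IAF; random-phase task → ERP → P1 latency; targeting formula → profile;
closed-loop interleaved trough/peak run → event table; then the analysis
battery and group statistics (cluster contrasts of ERP and ERO envelope,
paired t + BH across components, runs tests on condition sequences). The run
is deterministic under a fixed seed (per-subject seeds spawn from a
SeedSequence).

Default simulation sizes are desk-scale: 5 subjects, 60 s baseline, 150 s
random task, 240 s trough/peak task, 500 permutations. The human study's
sizes (19 subjects, 900 s tasks, 1000 permutations) are reachable through the
same configuration object. The verification battery uses: a 6-point SNR sweep
(−5…20 dB, 200 windows each) for the ecHT/sHT ordering; 5 IAFs × 20 seeds on
40 s baselines for IAF recovery; 200 null replicates × 1000 permutations on
19×40 grids for error control; and 20 replicates × 6 subjects × 80 s runs for
the end-to-end modulation recovery.

One design point in that last check: with equal component gains, trough- and
peak-locked delivery still produce genuinely different ERPs, because each
condition's trial average carries the phase-locked alpha at opposite phase —
the same mechanism that makes the ERO condition-dependent. A "modulation off"
null must therefore also randomize the delivery phase (flat gains, random
targets, arbitrary condition labels); with that true null the cluster test
stays silent at its nominal rate.

## Known limitations

- The loop is simulated sample-synchronously; no DAC/audio latency, jitter,
  or device I/O. Audio-path latency is a configurable phase advance only.
- The trigger predicts phase advance at the filter center frequency; with
  detuned oscillators (estimate ≠ truth) the phase error grows accordingly.
- The ecHT filter order/window defaults are engineering choices, not device
  facts; both are configurable.
- EDF export is not provided; recordings persist in a documented two-file
  plain-text exchange format (signal TSV + JSON sidecar) plus event TSVs.
- The aperiodic "FOOOF-style" detrending is a minimal offset+exponent model,
  not a full peak-parameterization with goodness-of-fit reporting.
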