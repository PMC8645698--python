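# Methods

This note documents the models and numerical choices behind `seegenc`:
what each stage computes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Neural preprocessing

Raw voltage (nominally 2 kHz) is transformed to z-scored high-gamma
frames at 100 Hz in five steps, all zero-phase so that latency
estimates downstream are unbiased by filter delay:

1. **Notch.** Second-order IIR notches (quality factor 30) at 60, 120,
   and 180 Hz, applied forward–backward. The narrow notch leaves the
   70–150 Hz analysis band essentially untouched; measured attenuation
   at 60 Hz exceeds 20 dB.
2. **Common average reference (CAR).** Each sample's across-channel
   mean is subtracted; afterwards the instantaneous channel mean is
   identically zero. Requires at least two channels.
3. **Multiband high-gamma amplitude.** Eight sub-bands with center
   frequencies geometrically spaced over 70–150 Hz (endpoints
   inclusive); each sub-band's edges sit at the geometric means of
   neighboring centers, with the outermost edges pinned to 70 and
   150 Hz, so the sub-bands tile the band without overlap. Each
   sub-band is isolated by a 4th-order zero-phase Butterworth bandpass
   and its analytic amplitude taken as `|hilbert|`. Per-band amplitudes
   are **summed** (not individually normalized). The sum equals the
   across-band mean up to the fixed factor 8; it is preferred because a
   pure tone anywhere in the band then retains its physical amplitude
   (within ~5 %, measured) — under the mean convention a tone would
   register at ~1/8 of its amplitude since it excites exactly one tiled
   sub-band. The constant is immaterial after z-scoring. A switch for
   per-band normalization before combining is deliberately *not*
   provided: normalization interacts with the noise floor and is not
   part of the standard recipe implemented here.
4. **Downsampling.** Polyphase resampling (`resample_poly`, linear-fit
   edge padding) from the acquisition rate to 100 Hz; 2000→100 is the
   clean rational factor 1/20.
5. **z-scoring.** Per electrode, population (1/N) standard deviation
   over the full series. Computing the moments over the full recording
   (train and test frames alike) mirrors common practice for this
   analysis; the mild train/test leakage it admits affects scale only,
   not correlations.

Manual artifact review is replaced by `flag_artifacts`, a reproducible
amplitude flagger: 1 s windows whose absolute peak exceeds 6 robust
standard deviations (1.4826·MAD) are flagged, never deleted.

## Stimulus features

The acoustic envelope is `|hilbert(audio)|` low-pass filtered with a
zero-phase 3rd-order Butterworth at 25 Hz and clipped at zero (an
envelope is an amplitude; the clip only removes small zero-phase
undershoots). Stereo is downmixed by averaging. The envelope is then
resampled onto the 100 Hz neural frame grid — safe by Nyquist, since
its content is already below 25 Hz. A one-frame length mismatch from
rounding is trimmed or pad-extended; anything larger raises, because it
indicates misaligned recordings. The first and last 0.5 s are flagged
as edge frames (`edge_frame_mask`) where the zero-phase filters use
reflected data.

## Encoding model

- **Design.** One feature (envelope) at 60 delays. The delay grid is
  {0.00, 0.01, …, 0.59} s: 60 points at 100 Hz resolution starting at
  0, the maximum delay (0.6 s) exclusive. An inclusive grid would hold
  61 points; the count of 60 is the constraint honored. Columns are
  causally zero-padded.
- **Split.** Frames are cut into contiguous 5 s chunks and whole chunks
  are randomly assigned 80/20 to train/test. Chunk-level assignment
  limits the leakage that per-frame sampling would allow through the
  response autocorrelation. 5 s is several times the high-gamma
  autocorrelation length yet leaves ≥ 12 chunks even on a 1 min
  recording.
- **Ridge fit.** Weights minimize ‖y − Sw‖² + α‖w‖² on the training
  frames, solved through the SVD of the centered training design
  (response and columns centered on training means — the intercept).
  α is selected from a log-spaced grid 10⁻²…10⁶, rescaled by
  n·(mean column variance) so the grid brackets the Gram-matrix
  eigenvalue magnitude regardless of stimulus units, by 5-fold inner
  cross-validation on contiguous blocks of the training frames
  (best mean held-out correlation). The SVD is computed once per
  (design, training-set) pair and shared across channels, alphas, and
  permutations; a fit then costs one matrix–vector product.
- **Scoring.** Pearson correlation between prediction and response on
  the held-out frames. A zero-variance prediction or response yields
  r = 0 with a warning rather than NaN.
- **Permutation test.** The training response is shuffled in contiguous
  5 s chunks (same granularity as the split; the shuffle permutes chunk
  order, preserving the multiset of values and local autocorrelation),
  a null model is refit at the true model's α, and its held-out
  correlation recorded; 100 shuffles by default. p is the fraction of
  null correlations ≥ the true one (ties count as exceedance —
  conservative), floored at 1/n_perm. Re-selecting α per shuffle is
  available (`alpha_policy="per_shuffle"`) but changes little: the null
  fits have no signal to regularize toward.

Measured calibration: over 200 synthetic null channels (autocorrelated
noise, no stimulus dependence) the fraction reaching p ≤ 0.05 lies
within the 95 % binomial interval around 0.05 (the acceptance suite and
`scripts/acceptance.py` recompute this).

## Synthetic sessions

The generator produces sessions with the statistical structure the
analysis assumes, not a biophysical simulation:

- **Envelope.** Rectified Gaussian noise low-passed at 8 Hz (4th-order
  zero-phase Butterworth), shifted non-negative — speech/soundtrack
  modulation rates, comfortably inside the 25 Hz envelope passband.
- **Response kernel.** Gamma-density shape with mode at
  `kernel_peak_latency` (default 0.1 s) and spread `kernel_width`
  (default 0.05 s), sampled on the 0–0.6 s delay grid, peak normalized
  to 1. Non-responsive channels have identically zero kernels.
- **Carrier.** Eight sinusoids at the same log-spaced center
  frequencies the analysis uses, exciting every sub-band. Phases are
  equally spaced across the channels of each response group (with a
  random per-band base phase), so each group's carriers sum to zero.
  This makes the CAR exactly signal-transparent: since all responsive
  channels share one modulation, any non-cancelling phase assignment
  would leak the modulated carrier coherently into every other channel
  through the subtracted mean — at realistic channel counts (tens) a
  purely random-phase design makes truly non-responsive channels test
  significant, which would defeat calibration measurements. A group
  with a single channel gets ±2 Hz frequency jitter instead
  (leakage then incoherent and second order). Real high gamma is
  likewise incoherent across electrodes; the phase structure is the
  deterministic idealization of that fact.
- **Modulation.** Responsive channels multiply the carrier by
  `1 + 0.3·z(kernel ⊛ envelope)` (clipped at 0.05); the modulation
  depth of 0.3 represents a strong but not saturating envelope-following
  response.
- **Noise and snr.** Pink (1/f-amplitude) noise with a 20 % white
  floor, plus line noise at 60/120/180 Hz (amplitudes 1 : 0.5 : 0.25).
  `snr` is the variance of the modulated in-band component divided by
  the noise variance within 70–150 Hz; the noise realization is scaled
  per channel to hit it exactly. The default snr 4 describes a clearly
  responsive electrode; calibration runs use `responsive_fraction=0`.
- **Events.** Uniform times with ≥ 200 ms separation; identical button
  sequences on three clocks — behavioral truth, neural TTL
  (+2 ms fixed marker latency, codes as prime pulse widths in ms), and
  audio tones (times mapped through the configured offset and drift).

Everything derives deterministically from the config seed; writing a
session twice produces byte-identical containers (HDF5 timestamps
disabled).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: epileptiform and movement
artifacts, non-stationary noise, electrode drift and contact failures,
cross-electrode correlated physiology, reference-montage pathologies,
genuinely broadband (stochastic-envelope) high gamma, and any
structured relationship between electrode location and responsiveness.
A known fidelity limit: narrow sub-bands (≈4 Hz at the low end of
70–150 Hz) clip modulation sidebands beyond ~2 Hz, so even a noiseless
channel demodulates to r ≈ 0.985–0.99 against its true modulation, not
1.0.

## Event synchronization

- **Pulse codec.** The k-th button maps to the k-th prime (2, 3, 5, …,
  47 ms), a convention chosen for its self-documenting uniqueness; up
  to 15 buttons. Decoding accepts measured widths within ±0.4 ms of
  exactly one prime; a width near two primes (or near none) is flagged
  undecodable, never guessed.
- **Tones.** Per-button pure tones (400 Hz + k·100 Hz, 50 ms bursts,
  5 ms cosine ramps — an artifact convention). Detection mixes the
  audio down at each listed frequency, smooths over half a burst, and
  takes rising half-maximum crossings as onsets (±5 ms at SNR 10,
  measured); a refractory of one burst length prevents double counting,
  and a floor at 25 % of the peak broadband envelope rejects tones at
  unlisted frequencies.
- **Matching and clock fit.** Same-code events are paired greedily by
  nearest neighbor after removing the median same-code time difference
  (so large constant offsets do not defeat the window). The clock map
  t_b = offset + (1+drift)·t_a is fit by least squares with
  Tukey-bisquare reweighting (3 iterations, c = 4.685), tolerating a
  minority of spurious or missed events; if most residuals are exactly
  zero the exact-fitting majority is kept outright. The fixed 2 ms TTL
  marker latency is subtracted as a constant (`remove_marker_latency`)
  before fitting.

## Problem sizes in the shipped checks

The acceptance suite and `scripts/acceptance.py` use: a 600 s,
6-channel session (3 responsive) at snr 4 for kernel recovery with 100
permutations per channel; 200 null channels of 6000 frames for
calibration, 100 permutations each (the shared-SVD solver makes a
permutation cost one matrix–vector product, which is what makes these
sizes cheap); 10 s tones/sinusoids for the signal-processing limits;
and 100 events over an hour with offset 1.5 s and drift 10⁻⁴ for clock
recovery. These sizes give stable statistics (kernel correlations vary
by < 0.01 across seeds) while keeping a full run around one minute.

## Known limitations

- Single stimulus feature; no spectrogram, phonetic, semantic, or
  visual models, and no banded or time-varying ridge.
- The inner CV folds are contiguous blocks of training frames, not a
  re-chunked split; with the outer split already chunk-wise this is an
  accepted approximation.
- z-scoring over the full series leaks scale information across the
  split (kept deliberately, see above).
- The permutation p floor (1/n_perm) makes p-values below 0.01
  unobservable at the default 100 shuffles.
- CLI `sync detect-tones` assumes tones are the loudest narrowband
  events in the track; soundtrack-embedded tones may need the
  threshold adjusted.
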