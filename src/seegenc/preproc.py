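"""Raw voltage → z-scored high-gamma frames.

The standard pipeline is

    notch (60/120/180 Hz) → common average reference →
    multiband Hilbert high-gamma amplitude (70–150 Hz, 8 log-spaced
    sub-bands) → downsample to 100 Hz → per-electrode z-score

All filtering is zero-phase (forward–backward IIR or FFT-based), so
response-latency estimates downstream are not biased by filter delay.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from seegenc.core import HighGammaSeries, RawNeural

DEFAULT_NOTCH_FREQS = (60.0, 120.0, 180.0)
DEFAULT_BAND = (70.0, 150.0)
DEFAULT_N_BANDS = 8
DEFAULT_FRAME_RATE = 100.0


def notch_line(raw: RawNeural, freqs=DEFAULT_NOTCH_FREQS, q: float = 30.0) -> RawNeural:
    """Zero-phase IIR notch at each line frequency.

    Each notch is a second-order filter of quality factor ``q`` applied
    forward and backward (``filtfilt``), attenuating the line while
    leaving the 70–150 Hz band essentially untouched.
    """
    nyq = raw.fs / 2.0
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
    data = raw.data
    for f0 in freqs:
        b, a = signal.iirnotch(f0, q, fs=raw.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return raw.copy_with(data)


def common_average_reference(raw: RawNeural) -> RawNeural:
    """Subtract the instantaneous mean across all electrodes.

    After referencing, the across-channel mean is identically zero at
    every sample.
    """
    if raw.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return raw.copy_with(raw.data - raw.data.mean(axis=0, keepdims=True))


def log_spaced_centers(band: tuple[float, float] = DEFAULT_BAND,
                       n_bands: int = DEFAULT_N_BANDS) -> np.ndarray:
    """Geometrically spaced center frequencies, endpoints inclusive."""
    return np.geomspace(band[0], band[1], n_bands)


def band_edges(centers: np.ndarray,
               band: tuple[float, float] = DEFAULT_BAND) -> list[tuple[float, float]]:
    """Sub-band edges at geometric means of neighboring centers.

    The outermost edges are pinned to the analysis band limits so the
    union of sub-bands covers the band exactly without overlap.
    """
    mids = np.sqrt(centers[:-1] * centers[1:])
    lows = np.concatenate([[band[0]], mids])
    highs = np.concatenate([mids, [band[1]]])
    return list(zip(lows, highs))


def high_gamma_amplitude(raw: RawNeural, band: tuple[float, float] = DEFAULT_BAND,
                         n_bands: int = DEFAULT_N_BANDS,
                         filter_order: int = 4) -> np.ndarray:
    """Multiband analytic amplitude over log-spaced sub-bands of 70–150 Hz.

    Each sub-band is isolated with a zero-phase Butterworth bandpass and
    its analytic amplitude taken as ``|hilbert(x)|`` (no per-band
    normalization). The per-band amplitudes are combined by summation —
    the across-band average up to the fixed factor ``n_bands``, scaled
    so that a pure tone anywhere in the band retains its amplitude
    (the sub-bands tile the band, so a tone registers in exactly one).
    The constant factor is immaterial after per-electrode z-scoring.

    Returns a ``(n_channels, n_samples)`` non-negative array at the raw
    sampling rate.
    """
    if raw.fs <= 2 * band[1]:
        raise ValueError(
            f"fs={raw.fs} Hz too low to represent the {band[1]} Hz band edge")
    centers = log_spaced_centers(band, n_bands)
    amp = np.zeros_like(raw.data)
    # pad the FFT to a power of two: hilbert() is O(n log n) only for fast n
    n = raw.data.shape[-1]
    nfft = int(2 ** np.ceil(np.log2(n))) if n & (n - 1) else n
    for lo, hi in band_edges(centers, band):
        sos = signal.butter(filter_order, [lo, hi], btype="bandpass",
                            fs=raw.fs, output="sos")
        bp = signal.sosfiltfilt(sos, raw.data, axis=-1)
        analytic = signal.hilbert(bp, N=nfft, axis=-1)[..., :n]
        amp += np.abs(analytic)
    return amp


def downsample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased polyphase resampling along the last axis."""
    if target_fs > fs:
        raise ValueError(f"target_fs {target_fs} exceeds current fs {fs}")
    if target_fs == fs:
        return np.asarray(data, dtype=np.float64)
    from fractions import Fraction

    frac = Fraction(float(target_fs) / float(fs)).limit_denominator(10000)
    return signal.resample_poly(np.asarray(data, dtype=np.float64),
                                frac.numerator, frac.denominator, axis=-1,
                                padtype="line")


def zscore_channels(data: np.ndarray,
                    channel_labels: list[str] | None = None) -> np.ndarray:
    """Center and scale each channel to mean 0, population SD 1."""
    data = np.asarray(data, dtype=np.float64)
    sd = data.std(axis=-1, keepdims=True)  # population (1/N) convention
    flat = np.where(sd.ravel() == 0)[0]
    if flat.size:
        labels = channel_labels or [f"ch{i}" for i in range(data.shape[0])]
        names = ", ".join(labels[i] for i in flat)
        raise ValueError(f"zero-variance channel(s): {names}")
    return (data - data.mean(axis=-1, keepdims=True)) / sd


def flag_artifacts(raw: RawNeural, threshold_sd: float = 6.0,
                   window_sec: float = 1.0) -> np.ndarray:
    """Flag windows whose peak amplitude is extreme, without deleting them.

    Splits each channel into ``window_sec`` windows and marks those whose
    absolute peak exceeds ``threshold_sd`` robust SDs (1.4826·MAD) of the
    channel. Returns a ``(n_channels, n_windows)`` boolean mask. A
    reproducible stand-in for manual artifact review.
    """
    win = max(1, int(round(window_sec * raw.fs)))
    n_win = raw.n_samples // win
    x = raw.data[:, : n_win * win].reshape(raw.n_channels, n_win, win)
    mad = np.median(np.abs(raw.data - np.median(raw.data, axis=-1, keepdims=True)),
                    axis=-1, keepdims=True)
    robust_sd = 1.4826 * mad + 1e-12
    return (np.abs(x).max(axis=-1) > threshold_sd * robust_sd)


def preprocess(raw: RawNeural, notch_freqs=DEFAULT_NOTCH_FREQS,
               band: tuple[float, float] = DEFAULT_BAND,
               n_bands: int = DEFAULT_N_BANDS,
               frame_rate: float = DEFAULT_FRAME_RATE,
               zscore: bool = True) -> HighGammaSeries:
    """Full standard pipeline: notch → CAR → high-gamma → downsample → z-score."""
    ref = common_average_reference(notch_line(raw, notch_freqs))
    amp = high_gamma_amplitude(ref, band, n_bands)
    frames = downsample(amp, raw.fs, frame_rate)
    if zscore:
        frames = zscore_channels(frames, raw.channel_labels)
    return HighGammaSeries(data=frames, fs=frame_rate, zscored=zscore,
                           band=band, n_bands=n_bands,
                           channel_labels=list(raw.channel_labels),
                           device_labels=list(raw.device_labels))
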