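"""Acoustic envelope features.

The envelope is the analytic amplitude of the (mono) audio waveform,
zero-phase low-pass filtered with a third-order Butterworth at 25 Hz and
clipped at zero, then resampled onto the 100 Hz neural frame grid.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from seegenc.core import EnvelopeSeries
from seegenc.preproc import downsample

DEFAULT_CUTOFF = 25.0
DEFAULT_ORDER = 3
EDGE_SECONDS = 0.5  # first/last frames contaminated by filter edge effects


def acoustic_envelope(samples: np.ndarray, fs: float,
                      cutoff: float = DEFAULT_CUTOFF,
                      order: int = DEFAULT_ORDER) -> EnvelopeSeries:
    """Analytic amplitude of the audio, low-passed and rectified.

    Parameters
    ----------
    samples
        Audio waveform; stereo ``(n, 2)`` input is downmixed by averaging.
    fs
        Audio sampling rate in Hz.
    cutoff, order
        Butterworth low-pass cutoff (Hz) and order applied zero-phase
        (``sosfiltfilt`` with reflect padding) to the analytic amplitude.

    Small negative values produced by the zero-phase low-pass are
    clipped to 0: an envelope is an amplitude.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if samples.size == 0:
        raise ValueError("empty audio")
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {fs / 2} Hz")
    n = samples.size
    nfft = int(2 ** np.ceil(np.log2(n))) if n & (n - 1) else n
    amplitude = np.abs(signal.hilbert(samples, N=nfft)[:n])
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, amplitude)
    return EnvelopeSeries(values=np.clip(env, 0.0, None), fs=fs)


def to_neural_grid(env: EnvelopeSeries, target_fs: float = 100.0,
                   n_frames: int | None = None) -> EnvelopeSeries:
    """Resample an envelope onto the neural frame grid.

    Anti-alias resampling (safe: content is already below 25 Hz), then
    trim or zero-pad by at most one frame so the output has exactly
    ``n_frames`` values; a larger mismatch raises, because it indicates
    misaligned recordings rather than rounding.
    """
    if target_fs > env.fs:
        raise ValueError("target_fs must not exceed the envelope rate")
    values = downsample(env.values, env.fs, target_fs)
    if n_frames is not None:
        if abs(values.size - n_frames) > 1:
            raise ValueError(
                f"envelope yields {values.size} frames but {n_frames} requested; "
                "difference exceeds one frame — check recording alignment")
        if values.size > n_frames:
            values = values[:n_frames]
        elif values.size < n_frames:
            values = np.concatenate([values, values[-1:]])
    return EnvelopeSeries(values=np.clip(values, 0.0, None), fs=target_fs)


def edge_frame_mask(env: EnvelopeSeries,
                    edge_sec: float = EDGE_SECONDS) -> np.ndarray:
    """Boolean mask of frames within ``edge_sec`` of either end."""
    k = int(round(edge_sec * env.fs))
    mask = np.zeros(len(env), dtype=bool)
    if k > 0:
        mask[:k] = True
        mask[-k:] = True
    return mask
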