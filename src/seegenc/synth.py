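"""Synthetic recording sessions with known ground truth.

Real naturalistic sEEG sessions are rarely shareable, so every stage of
the analysis is exercised against simulated sessions that possess the
statistical structure the analysis assumes:

- a speech-like stimulus envelope (rectified noise, modulation power
  below ~8 Hz);
- responsive channels whose high-gamma amplitude follows the envelope
  through a causal gamma-shaped kernel peaking near 100 ms;
- a high-gamma carrier exciting the full 70–150 Hz analysis band,
  1/f ("pink") background noise with a white floor, and 60 Hz line
  noise with harmonics;
- button events carried on three clocks (behavioral truth, neural TTL
  with a fixed +2 ms marker latency, audio tones with configurable
  offset and drift).

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal

from seegenc import io as seg_io
from seegenc.core import EnvelopeSeries, EventStream, RawNeural
from seegenc.preproc import log_spaced_centers
from seegenc.sync import MARKER_LATENCY_S, pulse_codec, synthesize_tones, tone_table

# 63-contact bilateral temporal-lobe montage used by the bundled demo
BILATERAL_TEMPORAL_MONTAGE = {
    "LAH": 14, "LAI": 4, "LPH": 7, "LTP": 8, "RAH": 12, "RPH": 8, "RTP": 10,
}

DEFAULT_BUTTONS = ("cross", "circle", "square", "triangle")

_ENVELOPE_LOWPASS_HZ = 8.0   # speech-band modulation rate
_MODULATION_DEPTH = 0.3      # fractional high-gamma modulation on responsive chans
_MODULATION_FLOOR = 0.05     # amplitude cannot go negative
_WHITE_FLOOR_FRAC = 0.2      # white noise amplitude relative to pink


def montage_labels(montage: dict[str, int]) -> tuple[list[str], list[str]]:
    """Expand per-device contact counts into channel and device labels."""
    channels, devices = [], []
    for device, count in montage.items():
        for k in range(1, count + 1):
            channels.append(f"{device}{k}")
            devices.append(device)
    return channels, devices


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    ``snr`` is the variance of the envelope-driven high-gamma component
    divided by the variance of the additive background noise within the
    70–150 Hz band; ``clock_drift`` is the fractional rate difference of
    the audio clock (1e-4 ≡ 100 ppm).
    """

    duration: float = 120.0
    neural_fs: float = 2000.0
    audio_fs: float = 44100.0
    n_channels: int = 8
    responsive_fraction: float = 0.5
    kernel_peak_latency: float = 0.1
    kernel_width: float = 0.05
    snr: float = 4.0
    line_noise_amp: float = 1.0
    n_events: int = 20
    clock_offset: float = 0.0
    clock_drift: float = 0.0
    seed: int = 0
    frame_rate: float = 100.0
    montage: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ValueError("responsive_fraction must lie in [0, 1]")
        if self.neural_fs <= 300.0:
            raise ValueError("neural_fs must exceed 300 Hz to represent "
                             "the 150 Hz band edge")
        if self.montage is not None:
            self.n_channels = sum(self.montage.values())


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    kernels: np.ndarray            # (n_channels, n_delays) true w(f=env, tau)
    kernel_delays: np.ndarray      # delay grid in seconds
    responsive_mask: np.ndarray
    true_envelope: EnvelopeSeries
    modulation: np.ndarray         # (n_channels, n_frames) true high-gamma drive
    event_times: dict[str, np.ndarray] = field(default_factory=dict)
    clock_map_true: tuple[float, float] = (0.0, 0.0)


@dataclass
class SyntheticSession:
    config: SessionConfig
    raw: RawNeural
    envelope: EnvelopeSeries
    events: dict[str, EventStream]
    truth: GroundTruth
    audio: np.ndarray | None = None


def simulate_envelope(duration: float, fs: float, seed: int) -> EnvelopeSeries:
    """Speech-like stimulus envelope: rectified Gaussian noise low-passed
    at 8 Hz, shifted to be non-negative."""
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    noise = np.abs(rng.standard_normal(n))
    sos = signal.butter(4, _ENVELOPE_LOWPASS_HZ, btype="lowpass", fs=fs,
                        output="sos")
    env = signal.sosfiltfilt(sos, noise)
    return EnvelopeSeries(values=env - env.min(), fs=fs)


def response_kernel(peak_latency: float, width: float, fs: float = 100.0,
                    support: float = 0.6) -> tuple[np.ndarray, np.ndarray]:
    """Gamma-density kernel with mode at ``peak_latency`` and spread
    ``width`` (s), sampled on the delay grid [0, support), peak scaled
    to 1."""
    delays = np.arange(0.0, support, 1.0 / fs)
    # gamma(k, theta): mode (k-1)theta = peak, sd sqrt(k) theta = width
    theta = (-peak_latency + np.sqrt(peak_latency ** 2 + 4 * width ** 2)) / 2
    k = peak_latency / theta + 1.0
    from scipy.stats import gamma as gamma_dist

    kernel = gamma_dist.pdf(delays, a=k, scale=theta)
    peak = kernel.max()
    return delays, kernel / peak if peak > 0 else kernel


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit variance."""
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = shape * (rng.standard_normal(freqs.size)
                        + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def simulate_neural(envelope: EnvelopeSeries,
                    config: SessionConfig) -> tuple[RawNeural, GroundTruth]:
    """Simulate raw voltage whose responsive channels' high-gamma
    amplitude is (baseline + kernel ⊛ envelope), plus pink/white noise
    and line noise."""
    n_frames = int(round(config.duration * config.frame_rate))
    if len(envelope) < n_frames:
        raise ValueError(
            f"envelope has {len(envelope)} frames but the session needs "
            f"{n_frames}")
    env = envelope.values[:n_frames]
    n_samples = int(round(config.duration * config.neural_fs))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    delays, kernel = response_kernel(config.kernel_peak_latency,
                                     config.kernel_width, config.frame_rate)
    n_responsive = int(round(config.responsive_fraction * config.n_channels))
    responsive = np.zeros(config.n_channels, dtype=bool)
    responsive[:n_responsive] = True

    centers = log_spaced_centers()
    t = np.arange(n_samples) / config.neural_fs
    t_frames = np.arange(n_frames) / config.frame_rate
    line = config.line_noise_amp * (np.sin(2 * np.pi * 60 * t)
                                    + 0.5 * np.sin(2 * np.pi * 120 * t)
                                    + 0.25 * np.sin(2 * np.pi * 180 * t))

    drive = signal.fftconvolve(env, kernel)[:n_frames]
    drive_n = (drive - drive.mean()) / drive.std()

    kernels = np.zeros((config.n_channels, delays.size))
    modulation = np.zeros((config.n_channels, n_frames))
    data = np.empty((config.n_channels, n_samples))
    band_sos = signal.butter(4, [70.0, 150.0], btype="bandpass",
                             fs=config.neural_fs, output="sos")
    # Carrier phases are equally spaced within each response group so the
    # group's carriers sum to zero: the common average reference then
    # cannot leak one channel's modulated carrier into another (all
    # responsive channels share the same modulation, so exact phase
    # cancellation removes the modulated part from the channel mean).
    # A singleton group gets frequency jitter instead, which makes its
    # leakage incoherent (second-order only).
    freqs_ch = np.tile(centers, (config.n_channels, 1))
    phases_ch = np.empty_like(freqs_ch)
    for group in (np.flatnonzero(responsive), np.flatnonzero(~responsive)):
        if group.size == 0:
            continue
        base = rng.uniform(0, 2 * np.pi, centers.size)
        if group.size == 1:
            freqs_ch[group[0]] += rng.uniform(-2.0, 2.0, centers.size)
            phases_ch[group[0]] = base
        else:
            for j, c in enumerate(group):
                phases_ch[c] = base + 2 * np.pi * j / group.size

    for c in range(config.n_channels):
        carrier = np.sum([np.sin(2 * np.pi * f * t + ph)
                          for f, ph in zip(freqs_ch[c], phases_ch[c])], axis=0)
        carrier /= np.sqrt(centers.size / 2)  # unit variance
        if responsive[c]:
            kernels[c] = kernel
            m = 1.0 + _MODULATION_DEPTH * drive_n
        else:
            m = np.ones(n_frames)
        m = np.clip(m, _MODULATION_FLOOR, None)
        modulation[c] = m
        m_up = np.interp(t, t_frames, m)
        sig = m_up * carrier
        if np.isfinite(config.snr) and config.snr > 0:
            noise = _pink_noise(n_samples, rng)
            noise += _WHITE_FLOOR_FRAC * rng.standard_normal(n_samples)
            # reference signal power: the modulated in-band component,
            # identical across channels by construction
            sig_band_var = (_MODULATION_DEPTH ** 2) * 1.0
            noise_band_var = signal.sosfiltfilt(band_sos, noise).var()
            noise *= np.sqrt(sig_band_var / (config.snr * noise_band_var))
        else:
            noise = 0.0
        data[c] = sig + noise + line

    if config.montage is not None:
        channel_labels, device_labels = montage_labels(config.montage)
    else:
        channel_labels = [f"ch{i}" for i in range(config.n_channels)]
        device_labels = ["simdev"] * config.n_channels
    raw = RawNeural(data=data, fs=config.neural_fs,
                    channel_labels=channel_labels, device_labels=device_labels)
    truth = GroundTruth(kernels=kernels, kernel_delays=delays,
                        responsive_mask=responsive,
                        true_envelope=EnvelopeSeries(env, config.frame_rate),
                        modulation=modulation,
                        clock_map_true=(config.clock_offset, config.clock_drift))
    return raw, truth


def simulate_events(config: SessionConfig,
                    button_set: tuple = DEFAULT_BUTTONS) -> dict[str, EventStream]:
    """Three parallel event streams for one button sequence.

    ``truth`` is the behavioral log; ``ttl`` is the neural-clock stream
    (times + 2 ms marker latency, codes = prime pulse widths in ms);
    ``audio`` is the tone-clock stream (times mapped through the
    configured offset/drift, codes = buttons).
    """
    if config.n_events > 0 and not button_set:
        raise ValueError("button_set must be non-empty when n_events > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if config.n_events == 0:
        empty = np.array([])
        return {clock: EventStream(times=empty.copy(), codes=[], clock=clock)
                for clock in ("truth", "ttl", "audio")}
    lo, hi = 1.0, max(config.duration - 1.0, 1.5)
    times = np.sort(rng.uniform(lo, hi, config.n_events))
    # enforce >= 200 ms separation so tone bursts never merge
    for i in range(1, times.size):
        times[i] = max(times[i], times[i - 1] + 0.2)
    buttons = [button_set[i] for i in
               rng.integers(0, len(button_set), config.n_events)]
    codec = pulse_codec(list(button_set))
    widths = [float(codec.encode(b)) for b in buttons]
    return {
        "truth": EventStream(times=times, codes=buttons, clock="truth"),
        "ttl": EventStream(times=times + MARKER_LATENCY_S, codes=widths,
                           clock="neural"),
        "audio": EventStream(
            times=config.clock_offset + (1.0 + config.clock_drift) * times,
            codes=buttons, clock="audio"),
    }


def simulate_session(config: SessionConfig,
                     button_set: tuple = DEFAULT_BUTTONS,
                     render_audio: bool = False) -> SyntheticSession:
    """Generate a full mutually consistent session from one seed."""
    envelope = simulate_envelope(config.duration, config.frame_rate,
                                 int(np.random.SeedSequence(
                                     [config.seed, 0]).generate_state(1)[0]
                                     % (2 ** 31)))
    raw, truth = simulate_neural(envelope, config)
    events = simulate_events(config, button_set)
    truth.event_times = {k: v.times.copy() for k, v in events.items()}
    audio = None
    if render_audio:
        table = tone_table(list(button_set))
        audio = synthesize_tones(events["audio"], table, config.audio_fs,
                                 config.duration + abs(config.clock_offset) + 1.0)
    return SyntheticSession(config=config, raw=raw, envelope=envelope,
                            events=events, truth=truth, audio=audio)


def save_session(session: SyntheticSession, out_dir: str | os.PathLike) -> dict:
    """Write a session to standard containers; returns the path map."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "raw": os.path.join(out, "raw_neural.h5"),
        "envelope": os.path.join(out, "envelope.h5"),
        "envelope_tsv": os.path.join(out, "envelope.tsv"),
        "truth": os.path.join(out, "ground_truth.h5"),
    }
    seg_io.save_raw(paths["raw"], session.raw)
    seg_io.save_envelope(paths["envelope"], session.envelope)
    seg_io.save_envelope_tsv(paths["envelope_tsv"], session.envelope)
    for clock, stream in session.events.items():
        p = os.path.join(out, f"events_{clock}.tsv")
        paths[f"events_{clock}"] = p
        seg_io.save_events_tsv(p, stream)
    if session.audio is not None:
        paths["audio"] = os.path.join(out, "audio.wav")
        seg_io.save_wav(paths["audio"], session.audio, int(session.config.audio_fs))
    with h5py.File(paths["truth"], "w") as f:
        f.create_dataset("kernels", data=session.truth.kernels, track_times=False)
        f.create_dataset("kernel_delays", data=session.truth.kernel_delays, track_times=False)
        f.create_dataset("responsive_mask",
                         data=session.truth.responsive_mask.astype(np.int8),
                         track_times=False)
        f.create_dataset("modulation", data=session.truth.modulation, track_times=False)
        f.attrs["clock_offset"] = session.truth.clock_map_true[0]
        f.attrs["clock_drift"] = session.truth.clock_map_true[1]
    return paths
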