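"""Event-code arithmetic and clock alignment.

Button presses reach each recording device through a different channel:
the behavioral logger records the press itself, the neural amplifier
records a TTL pulse whose *width in milliseconds is a prime number
unique to the button* (with a fixed +2 ms marker latency), and the
audiovisual recorder receives a short pure tone unique to the button.
Decoding both streams and pairing same-button events gives the affine
clock map (offset + drift) between any two devices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from seegenc.core import ClockMap, EventStream

PRIMES_MS = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47)
WIDTH_TOLERANCE_MS = 0.4
MARKER_LATENCY_S = 0.002  # fixed TTL delay in the neural recording

# artifact convention: 50 ms bursts at 100 Hz steps from 400 Hz
DEFAULT_TONE_BASE_HZ = 400.0
DEFAULT_TONE_STEP_HZ = 100.0
DEFAULT_TONE_DUR_S = 0.05


@dataclass(frozen=True)
class PulseCodec:
    """Bijection between buttons and prime pulse widths (ms)."""

    buttons: tuple
    widths_ms: tuple

    def encode(self, button) -> float:
        return self.widths_ms[self.buttons.index(button)]

    def decode(self, width_ms: float, tolerance: float = WIDTH_TOLERANCE_MS):
        """Nearest configured prime within tolerance; None if no prime
        qualifies or two are equally close / both within tolerance."""
        widths = np.asarray(self.widths_ms, dtype=float)
        dist = np.abs(widths - width_ms)
        hits = np.flatnonzero(dist <= tolerance)
        if hits.size != 1:
            return None
        return self.buttons[int(hits[0])]


def pulse_codec(buttons: list) -> PulseCodec:
    """Assign the k-th button the k-th prime width in milliseconds."""
    if not buttons:
        raise ValueError("button set must be non-empty")
    if len(buttons) > len(PRIMES_MS):
        raise ValueError(f"at most {len(PRIMES_MS)} buttons supported "
                         f"(primes {PRIMES_MS[0]}..{PRIMES_MS[-1]} ms)")
    if len(set(buttons)) != len(buttons):
        raise ValueError("buttons must be unique")
    return PulseCodec(buttons=tuple(buttons),
                      widths_ms=tuple(PRIMES_MS[: len(buttons)]))


def decode_ttl(stream: EventStream, codec: PulseCodec,
               tolerance: float = WIDTH_TOLERANCE_MS) -> tuple[EventStream, list[int]]:
    """Decode measured pulse widths to buttons.

    Returns the decoded stream (undecodable events dropped) and the
    indices of undecodable events — flagged, never guessed.
    """
    decoded, times, bad = [], [], []
    for i, (t, width) in enumerate(zip(stream.times, stream.codes)):
        button = codec.decode(float(width), tolerance)
        if button is None:
            bad.append(i)
        else:
            times.append(t)
            decoded.append(button)
    return EventStream(times=np.array(times), codes=decoded,
                       clock=stream.clock), bad


def tone_table(buttons: list, base_hz: float = DEFAULT_TONE_BASE_HZ,
               step_hz: float = DEFAULT_TONE_STEP_HZ) -> dict:
    """Per-button tone frequency: base + k·step Hz."""
    return {b: base_hz + k * step_hz for k, b in enumerate(buttons)}


def synthesize_tones(stream: EventStream, table: dict, fs: float,
                     duration: float, tone_dur: float = DEFAULT_TONE_DUR_S,
                     amplitude: float = 0.5) -> np.ndarray:
    """Render an audio track containing one tone burst per event."""
    n = int(round(duration * fs))
    audio = np.zeros(n)
    n_tone = int(round(tone_dur * fs))
    ramp = min(n_tone // 10, int(0.005 * fs))
    window = np.ones(n_tone)
    if ramp > 0:
        edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        window[:ramp] = edge
        window[-ramp:] = edge[::-1]
    t = np.arange(n_tone) / fs
    for t0, button in zip(stream.times, stream.codes):
        start = int(round(t0 * fs))
        stop = min(start + n_tone, n)
        if start >= n:
            continue
        burst = amplitude * np.sin(2 * np.pi * table[button] * t) * window
        audio[start:stop] += burst[: stop - start]
    return audio


def detect_tones(audio: np.ndarray, fs: float, table: dict,
                 tone_dur: float = DEFAULT_TONE_DUR_S,
                 threshold: float = 0.25) -> EventStream:
    """Detect per-button tone bursts by narrowband quadrature demodulation.

    For each configured frequency the audio is mixed down with a complex
    exponential and smoothed over ~half the burst length, giving a
    sliding single-frequency amplitude estimate. Burst onsets are the
    rising half-maximum crossings of that estimate; simultaneous bursts
    at different frequencies are each reported.

    ``threshold`` is the detection floor as a fraction of the peak
    *broadband* envelope of the audio: a genuine burst's narrowband
    amplitude is comparable to the broadband envelope, while a tone at
    an unlisted frequency leaks almost nothing into bins 50+ Hz away
    and stays below the floor.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim == 2:
        audio = audio.mean(axis=1)
    freqs = list(table.values())
    if len(set(freqs)) != len(freqs):
        raise ValueError("tone frequencies must be distinct")
    if any(f >= fs / 2 for f in freqs):
        raise ValueError("tone frequencies must be below Nyquist")
    if len(freqs) > 1 and np.min(np.diff(np.sort(freqs))) < 50.0:
        raise ValueError("tone frequencies must be separated by >= 50 Hz")
    n = audio.size
    t = np.arange(n) / fs
    smooth = max(1, int(round(tone_dur * fs / 2)))
    kernel = np.ones(smooth) / smooth
    amps = {}
    for button, f in table.items():
        mixed = audio * np.exp(-2j * np.pi * f * t)
        amps[button] = 2 * np.abs(signal.fftconvolve(mixed, kernel, mode="same"))
    broadband = np.sqrt(2 * np.clip(
        signal.fftconvolve(audio ** 2, kernel, mode="same"), 0, None))
    global_peak = float(broadband.max())
    events: list[tuple[float, object]] = []
    if global_peak > 0:
        floor = threshold * global_peak
        for button, amp in amps.items():
            peak = amp.max()
            if peak < floor:
                continue
            above = amp >= peak / 2
            # centered smoothing puts the rising half-max crossing at the
            # physical burst onset (plus half the amplitude ramp)
            onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
            last = -np.inf
            for k in onsets:
                if k / fs - last >= tone_dur:  # refractory: one burst, one event
                    events.append((k / fs, button))
                    last = k / fs
    events.sort(key=lambda e: e[0])
    times = np.array([e[0] for e in events])
    # strictly-increasing times: nudge exact ties by one sample
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + 1.0 / fs
    return EventStream(times=times, codes=[e[1] for e in events], clock="audio")


def match_events(a: EventStream, b: EventStream,
                 window: float = 0.5) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy nearest-neighbor pairing of same-code events.

    A coarse offset (median same-code time difference, pairing the k-th
    occurrence of each code across streams) is removed before matching,
    so a large constant clock offset does not defeat the window.

    Returns (pairs, unmatched_a, unmatched_b) as index lists.
    """
    diffs = []
    for code in set(a.codes) & set(b.codes):
        ia = [i for i, c in enumerate(a.codes) if c == code]
        ib = [i for i, c in enumerate(b.codes) if c == code]
        diffs.extend(b.times[j] - a.times[i] for i, j in zip(ia, ib))
    coarse = float(np.median(diffs)) if diffs else 0.0
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i in range(len(a)):
        best, best_dist = None, window
        for j in range(len(b)):
            if j in used_b or b.codes[j] != a.codes[i]:
                continue
            dist = abs((b.times[j] - coarse) - a.times[i])
            if dist <= best_dist:
                best, best_dist = j, dist
        if best is not None:
            used_b.add(best)
            pairs.append((i, best))
    unmatched_a = [i for i in range(len(a)) if i not in {p[0] for p in pairs}]
    unmatched_b = [j for j in range(len(b)) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def estimate_clock_map(a: EventStream, b: EventStream,
                       pairs: list[tuple[int, int]],
                       n_iter: int = 3, tukey_c: float = 4.685) -> ClockMap:
    """Robust affine fit t_b ≈ offset + (1+drift)·t_a over paired events.

    Ordinary least squares refined by Tukey-bisquare reweighting
    (``n_iter`` rounds), tolerating a minority of mismatched pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to estimate a clock map")
    ta = a.times[[p[0] for p in pairs]]
    tb = b.times[[p[1] for p in pairs]]
    w = np.ones(ta.size)
    slope, intercept = 1.0, 0.0
    for _ in range(n_iter + 1):
        wsum = w.sum()
        ma, mb = (w * ta).sum() / wsum, (w * tb).sum() / wsum
        var = (w * (ta - ma) ** 2).sum()
        if var == 0:
            raise ValueError("degenerate pairs: all source times identical")
        slope = (w * (ta - ma) * (tb - mb)).sum() / var
        intercept = mb - slope * ma
        resid = tb - (intercept + slope * ta)
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            # majority of pairs fit exactly; keep only those and refit once
            dev = np.abs(resid - np.median(resid))
            w = (dev <= 1e-9 * max(1.0, float(np.abs(resid).max()))).astype(float)
            if w.sum() < 2:
                w = np.ones(ta.size)
                break
            continue
        u = np.clip(resid / (tukey_c * scale), -1, 1)
        w = (1 - u ** 2) ** 2
        if w.sum() < 2:
            w = np.ones(ta.size)
            break
    resid = tb - (intercept + slope * ta)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return ClockMap(offset=float(intercept), drift=float(slope - 1.0),
                    rms_residual=rms)


def remove_marker_latency(stream: EventStream,
                          latency: float = MARKER_LATENCY_S) -> EventStream:
    """Subtract the fixed TTL marker latency from neural-clock event times."""
    return EventStream(times=stream.times - latency, codes=list(stream.codes),
                       clock=stream.clock)
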