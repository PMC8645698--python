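"""Shared data containers.

All time series carry an explicit sampling rate; event streams carry an
explicit clock label so that cross-device alignment is always deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class RawNeural:
    """Multichannel voltage time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, volts.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel (e.g. ``"LAH3"``).
    device_labels
        Per-channel device/probe name (e.g. ``"LAH"``); groups contacts
        that share a physical electrode shank.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    device_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n_ch = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        if not self.device_labels:
            self.device_labels = ["dev0"] * n_ch
        if len(self.channel_labels) != n_ch or len(self.device_labels) != n_ch:
            raise ValueError("label lengths must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "RawNeural":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass
class HighGammaSeries:
    """Per-electrode high-gamma analytic amplitude on a frame grid.

    ``band`` is the analysis band in Hz and ``n_bands`` the number of
    log-spaced sub-bands whose analytic amplitudes were averaged.
    """

    data: np.ndarray
    fs: float
    zscored: bool = False
    band: tuple[float, float] = (70.0, 150.0)
    n_bands: int = 8
    channel_labels: list[str] = field(default_factory=list)
    device_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x frames)")
        n_ch = self.data.shape[0]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        if not self.device_labels:
            self.device_labels = ["dev0"] * n_ch

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class EnvelopeSeries:
    """One-dimensional non-negative stimulus amplitude trajectory."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass
class EventStream:
    """Timestamped event codes on a single named clock.

    ``codes`` may hold button identifiers (strings) or raw measurements
    (pulse width in ms, tone frequency); the interpretation is up to the
    codec that produced them.
    """

    times: np.ndarray
    codes: list
    clock: str = "unknown"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        self.codes = list(self.codes)
        if self.times.size != len(self.codes):
            raise ValueError("times and codes must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ClockMap:
    """Affine map between two device timelines: t_b = offset + (1+drift) t_a."""

    offset: float
    drift: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.drift <= -1.0:
            raise ValueError("drift must exceed -1 for a monotone mapping")

    def apply(self, times: np.ndarray) -> np.ndarray:
        return self.offset + (1.0 + self.drift) * np.asarray(times, dtype=np.float64)

    def invert(self) -> "ClockMap":
        scale = 1.0 + self.drift
        return ClockMap(offset=-self.offset / scale, drift=1.0 / scale - 1.0,
                        rms_residual=self.rms_residual / scale)
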