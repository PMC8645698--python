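"""Container I/O.

Neural data live in a simple HDF5 layout::

    /data            float64, (n_channels, n_samples)
    /fs              scalar float
    /channel_labels  fixed-length UTF-8 strings
    /device_labels   fixed-length UTF-8 strings

Envelopes and high-gamma frames use the same layout with an extra
``kind`` attribute. Audio is PCM16/float32 WAV; events are TSV with a
header row (``time_s``, ``code`` and optionally ``button``/``code_ms``).
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from seegenc.core import EnvelopeSeries, EventStream, HighGammaSeries, RawNeural


def _write_labels(f: h5py.File, name: str, labels: list[str]) -> None:
    f.create_dataset(name, data=np.array(labels, dtype=h5py.string_dtype("utf-8")),
                     track_times=False)


def _read_labels(f: h5py.File, name: str) -> list[str]:
    raw = f[name][()]
    return [x.decode("utf-8") if isinstance(x, bytes) else str(x) for x in raw]


def save_raw(path: str | os.PathLike, raw: RawNeural) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "raw_neural"
        f.create_dataset("data", data=raw.data, track_times=False)
        f.create_dataset("fs", data=float(raw.fs), track_times=False)
        _write_labels(f, "channel_labels", raw.channel_labels)
        _write_labels(f, "device_labels", raw.device_labels)


def load_raw(path: str | os.PathLike) -> RawNeural:
    with h5py.File(path, "r") as f:
        return RawNeural(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            channel_labels=_read_labels(f, "channel_labels"),
            device_labels=_read_labels(f, "device_labels"),
        )


def save_high_gamma(path: str | os.PathLike, hg: HighGammaSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "high_gamma"
        f.attrs["zscored"] = bool(hg.zscored)
        f.attrs["band_low"] = float(hg.band[0])
        f.attrs["band_high"] = float(hg.band[1])
        f.attrs["n_bands"] = int(hg.n_bands)
        f.create_dataset("data", data=hg.data, track_times=False)
        f.create_dataset("fs", data=float(hg.fs), track_times=False)
        _write_labels(f, "channel_labels", hg.channel_labels)
        _write_labels(f, "device_labels", hg.device_labels)


def load_high_gamma(path: str | os.PathLike) -> HighGammaSeries:
    with h5py.File(path, "r") as f:
        return HighGammaSeries(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            zscored=bool(f.attrs.get("zscored", False)),
            band=(float(f.attrs.get("band_low", 70.0)),
                  float(f.attrs.get("band_high", 150.0))),
            n_bands=int(f.attrs.get("n_bands", 8)),
            channel_labels=_read_labels(f, "channel_labels"),
            device_labels=_read_labels(f, "device_labels"),
        )


def save_envelope_tsv(path: str | os.PathLike, env: EnvelopeSeries) -> None:
    # TSV carries values only; the HDF5 container is the fs-carrying format
    pd.DataFrame({"envelope": env.values}).to_csv(path, sep="\t", index=False)


def save_envelope(path: str | os.PathLike, env: EnvelopeSeries) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "envelope"
        f.create_dataset("data", data=env.values, track_times=False)
        f.create_dataset("fs", data=float(env.fs), track_times=False)


def load_envelope(path: str | os.PathLike) -> EnvelopeSeries:
    with h5py.File(path, "r") as f:
        return EnvelopeSeries(values=f["data"][()], fs=float(f["fs"][()]))


def save_wav(path: str | os.PathLike, samples: np.ndarray, fs: int) -> None:
    wavfile.write(path, int(fs), np.asarray(samples, dtype=np.float32))


def load_wav(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 in [-1, 1], downmixing stereo to mono."""
    fs, samples = wavfile.read(path)
    samples = np.asarray(samples)
    if samples.dtype == np.int16:
        samples = samples / 32768.0
    elif samples.dtype == np.int32:
        samples = samples / 2147483648.0
    samples = samples.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return samples, float(fs)


def save_events_tsv(path: str | os.PathLike, stream: EventStream,
                    code_ms: list[float] | None = None) -> None:
    cols = {"time_s": stream.times, "button": stream.codes}
    if code_ms is not None:
        cols["code_ms"] = code_ms
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | os.PathLike, clock: str = "unknown") -> EventStream:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    code_col = next((c for c in ("button", "code", "code_ms") if c in df.columns), None)
    if code_col is None:
        raise ValueError(f"{path}: no code column (button/code/code_ms)")
    return EventStream(times=df["time_s"].to_numpy(),
                       codes=df[code_col].tolist(), clock=clock)


def load_raw_fif(path: str | os.PathLike) -> RawNeural:
    """Import a FIF recording (requires the optional ``mne`` dependency)."""
    import mne

    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    devices = ["".join(c for c in lab if not c.isdigit()) or "dev0" for lab in labels]
    return RawNeural(data=raw.get_data(), fs=float(raw.info["sfreq"]),
                     channel_labels=labels, device_labels=devices)
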