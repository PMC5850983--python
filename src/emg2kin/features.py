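"""RMS feature extraction from multichannel surface EMG.

The control pipeline does not consume raw EMG directly: every downstream
stage (autoencoder fitting, calibration, online control) operates on the
root-mean-square amplitude of each channel computed over short,
non-overlapping processing windows.  With the nominal 100 ms window the
feature stream updates at 10 Hz, which is also the control update rate.

Two containers are defined here and used throughout the package:

``EMGRecording``
    Raw samples, R channels x T samples, with a sampling rate.
``FeatureSeries``
    RMS amplitudes, R channels x N windows, with a frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "EMGRecording",
    "FeatureSeries",
    "compute_rms_features",
    "concatenate_features",
    "butterworth_bandpass",
    "read_emg_csv",
    "write_emg_csv",
    "read_features_csv",
    "write_features_csv",
]


@dataclass
class EMGRecording:
    """Raw multichannel surface-EMG recording.

    Parameters
    ----------
    samples
        Array of shape ``(R, T)``: R channels by T time samples, in
        arbitrary amplitude units.
    sampling_rate
        Sampling rate in Hz (nominally 2048).
    channel_labels
        Optional channel identifiers; defaults to ``ch01 .. chRR``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("recording needs at least 1 channel and 1 sample")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_labels:
            self.channel_labels = [
                f"ch{i + 1:02d}" for i in range(self.samples.shape[0])
            ]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class FeatureSeries:
    """RMS feature series P(t): one nonnegative amplitude per channel per window."""

    values: np.ndarray
    frame_rate: float
    window_seconds: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (channels x windows) array")
        if self.values.shape[1] < 1:
            raise ValueError("feature series needs at least one window")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("RMS features must be nonnegative")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [
                f"ch{i + 1:02d}" for i in range(self.values.shape[0])
            ]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """End-of-window timestamps in seconds."""
        return (np.arange(self.n_frames) + 1) / self.frame_rate

    def frame(self, n: int) -> np.ndarray:
        """Feature vector of window ``n`` (length R)."""
        return self.values[:, n]


def compute_rms_features(
    rec: EMGRecording, window_seconds: float = 0.1
) -> FeatureSeries:
    """Compute per-channel RMS over non-overlapping windows.

    The window length in samples is ``floor(window_seconds * sampling_rate)``;
    a trailing partial window is discarded.  With the default 100 ms window a
    2048 Hz recording yields 204-sample windows at 10 Hz (the ~10.04 Hz exact
    frame rate is reported as ``1 / window_seconds``).
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    win = int(np.floor(window_seconds * rec.sampling_rate))
    if win < 1:
        raise ValueError(
            "window shorter than one sample: need window_seconds >= "
            f"{1.0 / rec.sampling_rate:.6g} s at {rec.sampling_rate} Hz"
        )
    if rec.n_samples < win:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{win}-sample window; need at least {win} samples "
            f"({win / rec.sampling_rate:.3g} s at {rec.sampling_rate} Hz)"
        )
    n_win = rec.n_samples // win
    trimmed = rec.samples[:, : n_win * win]
    blocks = trimmed.reshape(rec.n_channels, n_win, win)
    rms = np.sqrt(np.mean(blocks**2, axis=2))
    return FeatureSeries(
        values=rms,
        frame_rate=1.0 / window_seconds,
        window_seconds=window_seconds,
        channel_labels=list(rec.channel_labels),
    )


def concatenate_features(series_list: Sequence[FeatureSeries]) -> FeatureSeries:
    """Concatenate feature series along time (e.g. pooled calibration contractions)."""
    if not series_list:
        raise ValueError("need at least one feature series")
    first = series_list[0]
    for s in series_list[1:]:
        if s.n_channels != first.n_channels:
            raise ValueError(
                f"channel count mismatch: {s.n_channels} != {first.n_channels}"
            )
        if not np.isclose(s.frame_rate, first.frame_rate):
            raise ValueError(
                f"frame rate mismatch: {s.frame_rate} != {first.frame_rate}"
            )
    values = np.concatenate([s.values for s in series_list], axis=1)
    return FeatureSeries(
        values=values,
        frame_rate=first.frame_rate,
        window_seconds=first.window_seconds,
        channel_labels=list(first.channel_labels),
    )


def butterworth_bandpass(
    rec: EMGRecording,
    low_hz: float = 3.0,
    high_hz: float = 900.0,
    order: int = 6,
) -> EMGRecording:
    """Optional software band-pass stage (off by default in the pipeline).

    Surface-EMG front ends typically band-pass in hardware; this digital
    Butterworth filter is provided for recordings that arrive unfiltered.
    ``high_hz`` is reduced to just below Nyquist when necessary.
    """
    nyq = rec.sampling_rate / 2.0
    high = min(high_hz, 0.99 * nyq)
    if not 0 < low_hz < high:
        raise ValueError("need 0 < low_hz < high_hz < Nyquist")
    sos = _signal.butter(order, [low_hz, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = _signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EMGRecording(
        samples=filtered,
        sampling_rate=rec.sampling_rate,
        channel_labels=list(rec.channel_labels),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O.  Raw EMG: one column per channel, one row per sample.
# Features: a leading "time" column (end-of-window seconds) then one column
# per channel, one row per window.
# ---------------------------------------------------------------------------

def read_emg_csv(path: str | Path, sampling_rate: float) -> EMGRecording:
    """Read raw EMG from CSV (header row of channel labels, samples as rows)."""
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: no EMG data found")
    return EMGRecording(
        samples=df.to_numpy(dtype=float).T,
        sampling_rate=sampling_rate,
        channel_labels=[str(c) for c in df.columns],
    )


def write_emg_csv(rec: EMGRecording, path: str | Path) -> None:
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.9g")


def read_features_csv(path: str | Path) -> FeatureSeries:
    """Read a feature series written by :func:`write_features_csv`."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    times = df["time"].to_numpy(dtype=float)
    if len(times) < 1:
        raise ValueError(f"{path}: empty feature file")
    if len(times) > 1:
        dt = float(np.median(np.diff(times)))
    else:
        dt = float(times[0])
    if dt <= 0:
        raise ValueError(f"{path}: non-increasing timestamps")
    chans = [c for c in df.columns if c != "time"]
    return FeatureSeries(
        values=df[chans].to_numpy(dtype=float).T,
        frame_rate=1.0 / dt,
        window_seconds=dt,
        channel_labels=chans,
    )


def write_features_csv(fs: FeatureSeries, path: str | Path) -> None:
    df = pd.DataFrame(fs.values.T, columns=fs.channel_labels)
    df.insert(0, "time", fs.times)
    df.to_csv(path, index=False, float_format="%.9g")
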