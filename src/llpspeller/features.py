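"""Preprocessing and interval-mean feature extraction for ERP epochs.

Continuous multichannel recordings are band-pass filtered (Chebyshev II,
0.5–8 Hz), decimated to 100 Hz, cut into [-200, 700] ms epochs around each
stimulus onset, baseline-corrected on [-200, 0] ms, and summarized per
channel by the mean amplitude in six latency intervals — the classic
interval-mean ERP feature set. With the study's 29 retained channels this
yields 6 · 29 = 174 features per epoch.

Sampling conventions: millisecond boundaries are converted to sample
indices by truncation toward zero (one central utility), epoch windows are
half-open ``[start, end)`` in samples, and interval boundaries are
inclusive millisecond specifications clipped to the window — at 100 Hz the
six study intervals tile [50, 700) ms without overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.signal

from ._utils import ms_to_sample

__all__ = [
    "ContinuousRecording",
    "FeatureConfig",
    "preprocess",
    "extract_epochs",
    "baseline_correct",
    "window_times",
    "interval_means",
    "feature_names",
    "peak_statistics",
]

STUDY_INTERVALS_MS = (
    (50, 120),
    (121, 200),
    (201, 280),
    (281, 380),
    (381, 530),
    (531, 700),
)


@dataclass
class ContinuousRecording:
    """C×T multichannel signal with stimulus onsets (sample indices)."""

    samples: np.ndarray  # (C, T), microvolts
    sampling_rate: float
    event_onsets: np.ndarray  # (E,), strictly increasing sample indices
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.event_onsets = np.asarray(self.event_onsets, dtype=int)
        if np.any(np.diff(self.event_onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if len(self.event_onsets) and (
            self.event_onsets[0] < 0 or self.event_onsets[-1] >= self.samples.shape[1]
        ):
            raise ValueError("event onsets must lie within the recording")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("need one channel name per row")

    # simple binary-array + JSON-header container
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".samples.npy"), self.samples)
        header = {
            "sampling_rate": self.sampling_rate,
            "event_onsets": self.event_onsets.tolist(),
            "channel_names": list(self.channel_names),
        }
        prefix.with_suffix(".header.json").write_text(json.dumps(header))

    @classmethod
    def load(cls, prefix: str | Path) -> "ContinuousRecording":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".header.json").read_text())
        return cls(
            samples=np.load(prefix.with_suffix(".samples.npy")),
            sampling_rate=header["sampling_rate"],
            event_onsets=header["event_onsets"],
            channel_names=tuple(header["channel_names"]),
        )


@dataclass(frozen=True)
class FeatureConfig:
    """Preprocessing and feature-extraction settings (study defaults)."""

    band: tuple[float, float] = (0.5, 8.0)
    filter_order: int = 3
    stopband_atten_db: float = 40.0  # Chebyshev II design constant
    # Chebyshev II is specified by its stopband edges; placing them one
    # octave outside the nominal band keeps [0.5, 8] Hz an actual passband
    # (an order-3 design with stopband edges *at* the band would attenuate
    # most of it).
    stopband_factor: float = 2.0
    target_rate: float = 100.0
    epoch_window_ms: tuple[float, float] = (-200.0, 700.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    intervals_ms: tuple[tuple[float, float], ...] = STUDY_INTERVALS_MS
    excluded_channels: tuple[str, ...] = ("Fp1", "Fp2")

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_rate / 2):
            raise ValueError("need 0 < low < high < target_rate / 2")
        w0, w1 = self.epoch_window_ms
        for a, b in (self.baseline_window_ms, *self.intervals_ms):
            if a < w0 or b > w1:
                raise ValueError("baseline and intervals must lie inside the epoch window")


def preprocess(
    recording: ContinuousRecording, config: FeatureConfig, zero_phase: bool = False
) -> ContinuousRecording:
    """Band-pass filter and decimate to the working rate.

    The filter is a Chebyshev type II band pass (order ``filter_order`` per
    band edge, ``stopband_atten_db`` stopband attenuation), applied
    causally by default (online-compatible); ``zero_phase=True`` uses
    forward-backward filtering instead. Decimation is integer subsampling
    — the 8 Hz band edge is far below the decimated Nyquist, so the band
    pass is the anti-alias stage. Event onsets are re-indexed.
    """
    factor = recording.sampling_rate / config.target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_rate must divide the sampling rate")
    factor = int(round(factor))
    edges = (
        config.band[0] / config.stopband_factor,
        config.band[1] * config.stopband_factor,
    )
    sos = scipy.signal.cheby2(
        config.filter_order,
        config.stopband_atten_db,
        edges,
        btype="bandpass",
        fs=recording.sampling_rate,
        output="sos",
    )
    apply = scipy.signal.sosfiltfilt if zero_phase else scipy.signal.sosfilt
    filtered = apply(sos, recording.samples, axis=1)
    return ContinuousRecording(
        samples=np.ascontiguousarray(filtered[:, ::factor]),
        sampling_rate=config.target_rate,
        event_onsets=recording.event_onsets // factor,
        channel_names=recording.channel_names,
    )


def _window_samples(config: FeatureConfig, sampling_rate: float) -> tuple[int, int]:
    return (
        ms_to_sample(config.epoch_window_ms[0], sampling_rate),
        ms_to_sample(config.epoch_window_ms[1], sampling_rate),
    )


def window_times(config: FeatureConfig, sampling_rate: float | None = None) -> np.ndarray:
    """Sample times (ms, relative to onset) of the epoch window."""
    rate = config.target_rate if sampling_rate is None else sampling_rate
    lo, hi = _window_samples(config, rate)
    return np.arange(lo, hi) * 1000.0 / rate


def extract_epochs(
    recording: ContinuousRecording, config: FeatureConfig
) -> np.ndarray:
    """Cut baseline-corrected (E, C, S) epoch windows around each onset.

    The window is half-open in samples; per channel, the mean over the
    baseline window is subtracted. Windows of nearby events may overlap
    (the 250 ms SOA is shorter than the 900 ms window).
    """
    lo, hi = _window_samples(config, recording.sampling_rate)
    n_time = recording.samples.shape[1]
    epochs = np.empty(
        (len(recording.event_onsets), recording.samples.shape[0], hi - lo)
    )
    for i, onset in enumerate(recording.event_onsets):
        if onset + lo < 0 or onset + hi > n_time:
            raise ValueError(
                f"epoch window of event {i} (onset sample {onset}) exceeds the recording"
            )
        epochs[i] = recording.samples[:, onset + lo : onset + hi]
    times = window_times(config, recording.sampling_rate)
    return baseline_correct(epochs, times, config.baseline_window_ms)


def baseline_correct(
    epochs: np.ndarray,
    times_ms: np.ndarray,
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
) -> np.ndarray:
    """Subtract each channel's mean over the baseline window (half-open).

    Idempotent: the baseline of a corrected epoch is zero, so applying the
    correction twice equals applying it once.
    """
    a, b = baseline_window_ms
    mask = (times_ms >= a) & (times_ms < b)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    return epochs - epochs[..., mask].mean(axis=-1, keepdims=True)


def _interval_slices(
    config: FeatureConfig, sampling_rate: float
) -> list[np.ndarray]:
    times = window_times(config, sampling_rate)
    slices = []
    for a, b in config.intervals_ms:
        idx = np.flatnonzero((times >= a) & (times <= b))
        if len(idx) == 0:
            raise ValueError(
                f"interval [{a}, {b}] ms is empty at {sampling_rate} Hz"
            )
        slices.append(idx)
    return slices


def interval_means(
    epochs: np.ndarray,
    config: FeatureConfig,
    channel_names: Sequence[str],
) -> np.ndarray:
    """Mean amplitude per retained channel and latency interval.

    Channels in ``config.excluded_channels`` are dropped; feature order is
    channel-major (all intervals of channel 1, then channel 2, ...), so
    D = n_channels_kept × n_intervals.
    """
    keep = [i for i, c in enumerate(channel_names) if c not in config.excluded_channels]
    slices = _interval_slices(config, config.target_rate)
    n_epochs = epochs.shape[0]
    out = np.empty((n_epochs, len(keep) * len(slices)))
    for ci, ch in enumerate(keep):
        for ii, idx in enumerate(slices):
            out[:, ci * len(slices) + ii] = epochs[:, ch, :][:, idx].mean(axis=1)
    return out


def feature_names(config: FeatureConfig, channel_names: Sequence[str]) -> list[str]:
    keep = [c for c in channel_names if c not in config.excluded_channels]
    return [
        f"{ch}:{int(a)}-{int(b)}ms" for ch in keep for a, b in config.intervals_ms
    ]


def peak_statistics(
    average_epoch: np.ndarray,
    times_ms: np.ndarray,
    channel_names: Sequence[str],
    channel: str,
    interval_ms: tuple[float, float],
    mode: str = "min",
) -> tuple[float, float]:
    """(amplitude µV, latency ms) of the extremum in a search interval.

    Operates on a class-averaged (C, S) epoch; ``mode='min'`` finds the
    trough (e.g. the early occipital negativity), ``'max'`` the peak
    (e.g. the late central positivity). Latency ties break earliest.
    """
    names = list(channel_names)
    if channel not in names:
        raise ValueError(f"channel {channel!r} not present")
    row = average_epoch[names.index(channel)]
    a, b = interval_ms
    idx = np.flatnonzero((times_ms >= a) & (times_ms <= b))
    if len(idx) == 0:
        raise ValueError("search interval contains no samples")
    values = row[idx]
    if mode == "min":
        k = int(np.argmin(values))
    elif mode == "max":
        k = int(np.argmax(values))
    else:
        raise ValueError("mode must be 'min' or 'max'")
    return float(values[k]), float(times_ms[idx[k]])
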