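"""Spectrogram-based least/largest spectral-density feature extraction.

The pipeline per analysis window is:

1. segment each 6-axis stream into 3-s windows with 50 % overlap;
2. compute a one-sided squared-magnitude STFT (Hann taper, each taper
   segment zero-padded to a 512-point FFT block) per channel;
3. pool every (frequency bin, time shift) cell of the three accelerometer
   spectrograms into one multiset, sort ascending, keep the S smallest and
   L largest values; repeat for the gyroscope axes;
4. concatenate the four blocks SA ‖ LeA ‖ SG ‖ LG into one feature vector
   (each block stored in ascending order).

With S = L = 25 this yields the 100-feature vector; with S = L = 50 the
200-feature vector.  The least block captures quasi-DC structure (gravity,
noise floor), the largest block the dominant motion energy.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.signal.windows import hann

from .simulate import ImuStream

__all__ = [
    "AnalysisWindow",
    "SpectrogramSet",
    "FeatureVector",
    "FeatureSet",
    "segment_stream",
    "spectrogram",
    "window_spectrograms",
    "extract_features",
    "build_feature_set",
    "extract_feature_set",
]

logger = logging.getLogger(__name__)

DEFAULT_FFT_LENGTH = 512
DEFAULT_SEGMENT_CAP = 128

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")


@dataclass(frozen=True)
class AnalysisWindow:
    """One fixed-length 6-channel segment of an IMU stream."""

    data: np.ndarray  # (n, 6)
    fs: float
    start_time: float = 0.0
    label: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 6:
            raise ValueError("AnalysisWindow data must have shape (n, 6)")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class SpectrogramSet:
    """Per-channel squared-magnitude STFT matrices for one window.

    Each matrix is ``(fft_length // 2 + 1, n_frames)`` — one-sided
    frequency bins by time shifts.  Entries are |STFT|² ≥ 0.
    """

    channels: tuple[np.ndarray, ...]  # length 6, order CHANNEL_NAMES
    fs: float
    fft_length: int
    window: np.ndarray  # the taper W[n]

    @property
    def accel(self) -> tuple[np.ndarray, ...]:
        return self.channels[:3]

    @property
    def gyro(self) -> tuple[np.ndarray, ...]:
        return self.channels[3:]


@dataclass(frozen=True)
class FeatureVector:
    """Ordered least/largest spectral-density abstraction of one window.

    Layout: SA (S least accelerometer values, ascending) ‖ LeA (L largest,
    ascending) ‖ SG (S least gyroscope values) ‖ LG (L largest).
    """

    values: np.ndarray
    S: int
    L: int
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (2 * (self.S + self.L),):
            raise ValueError("FeatureVector length must be 2*(S+L)")
        object.__setattr__(self, "values", v)

    @property
    def sa(self) -> np.ndarray:
        return self.values[: self.S]

    @property
    def lea(self) -> np.ndarray:
        return self.values[self.S: self.S + self.L]

    @property
    def sg(self) -> np.ndarray:
        return self.values[self.S + self.L: 2 * self.S + self.L]

    @property
    def lg(self) -> np.ndarray:
        return self.values[2 * self.S + self.L:]


@dataclass
class FeatureSet:
    """A labelled matrix of feature vectors (rows = samples).

    ``provenance`` tracks the augmentation stage: ``OR`` (original
    extracted features), then ``OR+LA1``, ``OR+LA1+SH``, ``OR+LA1+SH+LA2``.
    """

    X: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,), activity codes
    provenance: str = "OR"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            self.X = self.X.reshape(len(self.labels), -1)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("X and labels must have the same number of rows")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(str(lab))
        return seen

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}

    def subset(self, mask: np.ndarray) -> "FeatureSet":
        return FeatureSet(self.X[mask], self.labels[mask], self.provenance)


def segment_stream(stream: ImuStream, window_seconds: float = 3.0,
                   overlap_fraction: float = 0.5) -> list[AnalysisWindow]:
    """Slice a stream into overlapping fixed-length analysis windows.

    Consecutive windows advance by ``window_seconds * (1 - overlap_fraction)``;
    a trailing partial window is discarded.  Returns an empty list (with a
    logged warning) when the stream is shorter than one window.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    if window_seconds <= 0:
        raise ValueError("window_seconds must be > 0")
    n_win = int(round(window_seconds * stream.fs))
    hop = int(round(n_win * (1 - overlap_fraction)))
    hop = max(hop, 1)
    n = stream.n_samples
    if n < n_win:
        logger.warning("stream of %.3f s shorter than %.3f s window; no windows",
                       stream.duration_s, window_seconds)
        return []
    windows = []
    for start in range(0, n - n_win + 1, hop):
        windows.append(AnalysisWindow(
            data=stream.data[start: start + n_win],
            fs=stream.fs,
            start_time=start / stream.fs,
            label=stream.label,
        ))
    return windows


def _resolve_stft_params(n_samples: int, fft_length: int,
                         segment_length: int | None,
                         hop: int | None) -> tuple[int, int]:
    if segment_length is None:
        segment_length = min(n_samples, DEFAULT_SEGMENT_CAP)
    if hop is None:
        hop = max(segment_length // 2, 1)
    return segment_length, hop


def spectrogram(channel: np.ndarray, fs: float, fft_length: int = DEFAULT_FFT_LENGTH,
                segment_length: int | None = None,
                hop: int | None = None) -> np.ndarray:
    """Squared-magnitude one-sided STFT of a single channel.

    Each length-``segment_length`` frame is tapered by a periodic Hann
    window and zero-padded to ``fft_length`` points before the FFT; frames
    advance by ``hop`` samples.  Returns a ``(fft_length//2 + 1, n_frames)``
    matrix of |STFT|² values.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel must be 1-D")
    segment_length, hop = _resolve_stft_params(len(x), fft_length, segment_length, hop)
    if segment_length > fft_length:
        raise ValueError("segment_length must not exceed fft_length")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    if len(x) < segment_length:
        raise ValueError(
            f"channel of {len(x)} samples shorter than segment_length {segment_length}")
    taper = hann(segment_length, sym=False)
    starts = range(0, len(x) - segment_length + 1, hop)
    frames = np.stack([x[s: s + segment_length] * taper for s in starts])
    spec = np.abs(np.fft.rfft(frames, n=fft_length, axis=1)) ** 2
    return spec.T  # (freq bins, time shifts)


def window_spectrograms(window: AnalysisWindow, fft_length: int = DEFAULT_FFT_LENGTH,
                        segment_length: int | None = None,
                        hop: int | None = None) -> SpectrogramSet:
    """Per-channel spectrograms for one analysis window."""
    segment_length, hop = _resolve_stft_params(window.n_samples, fft_length,
                                               segment_length, hop)
    mats = tuple(
        spectrogram(window.data[:, c], window.fs, fft_length, segment_length, hop)
        for c in range(6)
    )
    return SpectrogramSet(channels=mats, fs=window.fs, fft_length=fft_length,
                          window=hann(segment_length, sym=False))


def _select_least_largest(pool: np.ndarray, S: int, L: int) -> np.ndarray:
    flat = np.sort(pool, kind="stable")
    if S + L > flat.size:
        raise ValueError(
            f"S + L = {S + L} exceeds pooled bin count {flat.size}")
    return np.concatenate([flat[:S], flat[flat.size - L:]])


def extract_features(window: AnalysisWindow, S: int = 25, L: int = 25,
                     fft_length: int = DEFAULT_FFT_LENGTH,
                     segment_length: int | None = None,
                     hop: int | None = None) -> FeatureVector:
    """Least/largest spectral-density feature vector for one window.

    All (frequency, time) cells of the three accelerometer spectrograms
    are pooled into one multiset and sorted ascending; the first S and
    last L values form SA and LeA.  The gyroscope axes are pooled the same
    way into SG and LG.  Output layout SA ‖ LeA ‖ SG ‖ LG, length 2(S+L).
    """
    if S < 0 or L < 0 or S + L == 0:
        raise ValueError("S and L must be non-negative with S + L >= 1")
    specs = window_spectrograms(window, fft_length, segment_length, hop)
    accel_pool = np.concatenate([m.ravel() for m in specs.accel])
    gyro_pool = np.concatenate([m.ravel() for m in specs.gyro])
    values = np.concatenate([
        _select_least_largest(accel_pool, S, L),
        _select_least_largest(gyro_pool, S, L),
    ])
    return FeatureVector(values=values, S=S, L=L, label=window.label)


def extract_feature_set(windows: list[AnalysisWindow], S: int = 25, L: int = 25,
                        fft_length: int = DEFAULT_FFT_LENGTH,
                        segment_length: int | None = None,
                        hop: int | None = None) -> FeatureSet:
    """Stack per-window feature vectors into a labelled FeatureSet."""
    if not windows:
        return FeatureSet(X=np.empty((0, 2 * (S + L))), labels=np.empty((0,), dtype="<U2"))
    rows = []
    labels = []
    for w in windows:
        fv = extract_features(w, S, L, fft_length, segment_length, hop)
        rows.append(fv.values)
        labels.append(fv.label if fv.label is not None else "")
    return FeatureSet(X=np.stack(rows), labels=np.asarray(labels), provenance="OR")


def build_feature_set(streams: list[ImuStream], S: int = 25, L: int = 25,
                      window_seconds: float = 3.0, overlap_fraction: float = 0.5,
                      fft_length: int = DEFAULT_FFT_LENGTH,
                      segment_length: int | None = None,
                      hop: int | None = None) -> FeatureSet:
    """Segment every stream and extract one feature row per window.

    Row order is stream order, then window order within each stream;
    labels are inherited from the streams.
    """
    if not streams:
        raise ValueError("streams must be non-empty")
    windows: list[AnalysisWindow] = []
    for stream in streams:
        windows.extend(segment_stream(stream, window_seconds, overlap_fraction))
    return extract_feature_set(windows, S, L, fft_length, segment_length, hop)
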