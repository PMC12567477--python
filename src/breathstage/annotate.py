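"""Ground-truth frame labels from an abdominal respiratory-effort trace.

An effort belt produces a slow quasi-periodic trace whose extrema mark the
turning points of the respiratory cycle.  The annotation procedure smooths the
trace with a short moving average, locates alternating maxima/minima with a
prominence- and distance-constrained peak finder, and converts the extrema into
a dense frame-label sequence over the classes ``inhale`` / ``exhale`` /
``silence`` on the audio frame clock.  These labels supervise (and, through the
oracle backend, stand in for) the acoustic frame classifier.

Polarity convention
-------------------
By default local *maxima* of the effort trace are taken as inhale onsets and
local *minima* as exhale onsets (``max_is_inhale``).  Belt sensors differ in
sign, so the opposite reading is available via ``polarity="min_is_inhale"``,
which simply swaps the two extrema lists before label construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidArgumentError

__all__ = [
    "CLASSES",
    "INHALE",
    "EXHALE",
    "SILENCE",
    "EffortSignal",
    "FrameLabelSequence",
    "smooth_effort",
    "detect_effort_extrema",
    "effort_to_frame_labels",
    "annotate_effort",
]

#: Fixed class inventory of the frame classifier; integer codes index into it.
CLASSES: Tuple[str, str, str] = ("inhale", "exhale", "silence")
INHALE, EXHALE, SILENCE = 0, 1, 2

#: Fraction of the minimum-to-next-maximum interval labelled exhale; the
#: remainder is silence.  The silent gap between breaths is a construction of
#: this package, not a property measured from data.
DEFAULT_EXHALE_FRACTION = 0.7


@dataclass
class EffortSignal:
    """A respiratory-effort trace on the episode clock.

    Parameters
    ----------
    samples : array-like
        Amplitude samples (arbitrary units).
    rate : float
        Sampling rate in Hz, must be positive.
    start_time : float
        Time of the first sample in seconds on the episode clock.
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise InvalidArgumentError("effort sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidArgumentError("effort signal must be 1-D with length >= 2")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @classmethod
    def from_csv(cls, path) -> "EffortSignal":
        """Load a (time_s, amplitude) CSV; the rate is inferred from the grid."""
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise InvalidArgumentError("effort CSV must contain at least 2 rows")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidArgumentError("effort CSV must be on a uniform time grid")
        return cls(df["amplitude"].to_numpy(float), rate=1.0 / dt[0], start_time=t[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "amplitude": self.samples}).to_csv(
            path, index=False
        )


@dataclass
class FrameLabelSequence:
    """Per-frame labels (and optional posteriors) over inhale/exhale/silence.

    ``labels`` holds integer codes into :data:`CLASSES`; ``posteriors`` is an
    optional (n_frames, 3) matrix of class probabilities, each row summing to 1
    within 1e-9.
    """

    frame_rate: float
    labels: np.ndarray
    posteriors: Optional[np.ndarray] = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame rate must be positive")
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind in "USO":
            codes = {name: i for i, name in enumerate(CLASSES)}
            try:
                self.labels = np.array([codes[str(x)] for x in self.labels], dtype=np.int8)
            except KeyError as exc:  # pragma: no cover - defensive
                raise InvalidArgumentError(f"unknown frame label {exc}") from exc
        else:
            self.labels = self.labels.astype(np.int8)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 2):
            raise InvalidArgumentError("frame label codes must be in {0, 1, 2}")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if self.posteriors.shape != (self.labels.size, len(CLASSES)):
                raise InvalidArgumentError(
                    "posteriors must have shape (n_frames, 3) matching labels"
                )
            if self.posteriors.size and not np.allclose(
                self.posteriors.sum(axis=1), 1.0, atol=1e-9
            ):
                raise InvalidArgumentError("posterior rows must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.labels.size) / self.frame_rate

    @property
    def label_names(self) -> np.ndarray:
        return np.asarray(CLASSES, dtype=object)[self.labels]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "time_s": self.times,
                "label": self.label_names,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: Optional[float] = None) -> "FrameLabelSequence":
        df = pd.read_csv(path)
        if frame_rate is None:
            t = df["time_s"].to_numpy(float)
            if t.size < 2:
                raise InvalidArgumentError("need >= 2 frames to infer the frame rate")
            frame_rate = 1.0 / (t[1] - t[0])
        start = float(df["time_s"].iloc[0]) if len(df) else 0.0
        return cls(frame_rate=frame_rate, labels=df["label"].to_numpy(), start_time=start)


def smooth_effort(signal: EffortSignal, window_samples: int = 25) -> EffortSignal:
    """Centred moving average with shrinking windows at the edges.

    ``window_samples`` must be odd so the window is symmetric; the output has
    the same length as the input.  Near the edges the window shrinks to the
    available samples, so constants are reproduced exactly everywhere.
    """
    if window_samples < 1 or window_samples % 2 == 0:
        raise InvalidArgumentError("window_samples must be a positive odd integer")
    x = signal.samples
    if window_samples > x.size:
        raise InvalidArgumentError("smoothing window exceeds the signal length")
    half = window_samples // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return EffortSignal(out, rate=signal.rate, start_time=signal.start_time)


def _prune_alternating(
    extrema: list[tuple[float, int, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict max/min alternation, keeping the more prominent of
    consecutive same-kind extrema.  Items are (time, kind, prominence) with
    kind +1 for maxima, -1 for minima."""
    pruned: list[tuple[float, int, float]] = []
    for item in sorted(extrema):
        if pruned and pruned[-1][1] == item[1]:
            if item[2] > pruned[-1][2]:
                pruned[-1] = item
        else:
            pruned.append(item)
    maxima = np.array([t for t, k, _ in pruned if k == +1])
    minima = np.array([t for t, k, _ in pruned if k == -1])
    return maxima, minima


def detect_effort_extrema(
    signal: EffortSignal,
    min_prominence: Optional[float] = None,
    min_distance_s: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Locate alternating local maxima and minima of a (smoothed) effort trace.

    Defaults follow the physiological ceiling of ~60 breaths/min: extrema of
    the same kind must be at least ``min_distance_s`` apart, and must rise
    above the noise floor via a prominence threshold (default 0.1 x signal SD).
    Between any two returned maxima lies at least one returned minimum and vice
    versa; where the raw peak finder emits two same-kind neighbours the less
    prominent one is pruned.

    Returns ``(maxima_times, minima_times)`` in seconds on the episode clock.
    A flat signal yields two empty arrays.
    """
    if min_distance_s <= 0:
        raise InvalidArgumentError("min_distance_s must be positive")
    x = signal.samples
    sd = float(np.std(x))
    if sd == 0.0:
        return np.array([]), np.array([])
    if min_prominence is None:
        min_prominence = 0.1 * sd
    distance = max(1, int(round(min_distance_s * signal.rate)))
    peaks, props = find_peaks(x, prominence=min_prominence, distance=distance)
    troughs, tprops = find_peaks(-x, prominence=min_prominence, distance=distance)
    items = [
        (signal.start_time + p / signal.rate, +1, float(pr))
        for p, pr in zip(peaks, props["prominences"])
    ] + [
        (signal.start_time + p / signal.rate, -1, float(pr))
        for p, pr in zip(troughs, tprops["prominences"])
    ]
    return _prune_alternating(items)


def effort_to_frame_labels(
    maxima_times,
    minima_times,
    frame_rate: float,
    episode_duration: float,
    exhale_fraction: float = DEFAULT_EXHALE_FRACTION,
) -> FrameLabelSequence:
    """Map inhale/exhale anchor times to a dense frame-label sequence.

    Frames from a maximum (inhale onset) to the next minimum are ``inhale``;
    from a minimum over the first ``exhale_fraction`` of the gap to the next
    maximum are ``exhale``; everything else (including frames before the first
    and after the last extremum) is ``silence``.  Frame *i* covers time
    ``[i/frame_rate, (i+1)/frame_rate)``; intervals are half-open.
    """
    if frame_rate <= 0:
        raise InvalidArgumentError("frame_rate must be positive")
    if not 0.0 <= exhale_fraction <= 1.0:
        raise InvalidArgumentError("exhale_fraction must lie in [0, 1]")
    maxima = np.asarray(maxima_times, dtype=float)
    minima = np.asarray(minima_times, dtype=float)
    if np.any(np.diff(maxima) <= 0) or np.any(np.diff(minima) <= 0):
        raise InvalidArgumentError("extrema times must be strictly increasing")
    n_frames = int(round(episode_duration * frame_rate))
    labels = np.full(n_frames, SILENCE, dtype=np.int8)

    def fill(t0: float, t1: float, code: int) -> None:
        lo = int(np.ceil(t0 * frame_rate - 1e-9))
        hi = int(np.ceil(t1 * frame_rate - 1e-9))
        labels[max(lo, 0) : min(hi, n_frames)] = code

    for m in maxima:
        nxt = minima[minima > m]
        if nxt.size:
            fill(m, nxt[0], INHALE)
    for m in minima:
        nxt = maxima[maxima > m]
        if nxt.size:
            fill(m, m + exhale_fraction * (nxt[0] - m), EXHALE)
    return FrameLabelSequence(frame_rate=frame_rate, labels=labels)


def annotate_effort(
    signal: EffortSignal,
    frame_rate: float = 100.0,
    smoothing_window: int = 25,
    min_prominence: Optional[float] = None,
    min_distance_s: float = 1.0,
    exhale_fraction: float = DEFAULT_EXHALE_FRACTION,
    polarity: str = "max_is_inhale",
) -> FrameLabelSequence:
    """Full annotation pass: smooth, find extrema, emit frame labels.

    ``polarity`` selects which extrema anchor inhalation (see module docstring).
    """
    if polarity not in ("max_is_inhale", "min_is_inhale"):
        raise InvalidArgumentError("polarity must be max_is_inhale or min_is_inhale")
    smoothed = smooth_effort(signal, smoothing_window)
    maxima, minima = detect_effort_extrema(smoothed, min_prominence, min_distance_s)
    if polarity == "min_is_inhale":
        maxima, minima = minima, maxima
    return effort_to_frame_labels(
        maxima, minima, frame_rate, signal.start_time + signal.duration_s, exhale_fraction
    )
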