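"""Inhale-onset parsing and per-window respiratory metrics.

The fused frame-label sequence is parsed into discrete, validated inhale
onsets: consecutive identical labels are merged into runs; very short
non-inhale runs sandwiched between inhale runs are absorbed (hysteresis, so a
single breath is not split in two); inhale runs shorter than a minimum
duration are dropped; a candidate onset is recorded at every transition from
{silence, exhale} into a surviving inhale run (an inhale run at the very start
of the sequence also counts); and finally a refractory period suppresses
duplicate detections.  From the resulting onset train two metrics are computed
per analysis window:

* Respiratory Count (RC) — inhale onsets inside the window, expressed in
  breaths per minute.
* Respiratory Period (RP) — the median interval between consecutive onsets
  within (or near) the window, in seconds; the median makes the estimate
  robust to isolated irregular cycles.  Windows with fewer than two qualifying
  onsets carry an explicit undefined flag rather than a fabricated value.

All windows and frames are half-open intervals ``[start, end)`` on a 0-based
episode clock in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotate import EXHALE, INHALE, SILENCE, FrameLabelSequence
from .errors import InvalidArgumentError

__all__ = [
    "PostProcessRules",
    "OnsetTrain",
    "WindowMetricSeries",
    "merge_runs",
    "detect_inhale_onsets",
    "parse_labels",
    "respiratory_count",
    "respiratory_period",
    "compute_window_metrics",
]


@dataclass(frozen=True)
class PostProcessRules:
    """Thresholds for onset validation, all in seconds and all >= 0.

    ``min_inhale_s``: inhale runs shorter than this are discarded.
    ``min_gap_s``: non-inhale runs shorter than this that are flanked by
    inhale runs on both sides are absorbed into one inhale run (hysteresis).
    ``refractory_s``: an accepted onset suppresses further onsets for this
    long.  Defaults are physiological-plausibility choices of this package
    (the thresholds have no published values).
    """

    min_inhale_s: float = 0.3
    min_gap_s: float = 0.2
    refractory_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_inhale_s, self.min_gap_s, self.refractory_s) < 0:
            raise InvalidArgumentError("post-processing thresholds must be >= 0")


@dataclass
class OnsetTrain:
    """Strictly increasing inhale-onset timestamps on the episode clock."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise InvalidArgumentError("onset times must be a 1-D array")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OnsetTrain":
        return cls(pd.read_csv(path)["time_s"].to_numpy(float))


@dataclass
class WindowMetricSeries:
    """Per-window RC (breaths/min) and RP (s) with an undefined-RP mask.

    ``rp`` holds NaN where ``defined`` is False; the mask, not the NaN, is the
    authoritative sentinel and is propagated by downstream consumers.
    """

    window_starts: np.ndarray
    window_s: float
    rc: np.ndarray
    rp: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        self.rp = np.asarray(self.rp, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        n = self.window_starts.size
        if not (self.rc.size == self.rp.size == self.defined.size == n):
            raise InvalidArgumentError("window metric arrays must share one length")
        if np.any(self.rc < 0):
            raise InvalidArgumentError("respiratory count must be >= 0")
        if np.any(self.rp[self.defined] <= 0):
            raise InvalidArgumentError("defined respiratory periods must be > 0")

    def __len__(self) -> int:
        return int(self.window_starts.size)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "window_start_s": self.window_starts,
                "rc_bpm": self.rc,
                "rp_s": self.rp,
                "defined": self.defined,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, window_s: float = 20.0) -> "WindowMetricSeries":
        df = pd.read_csv(path)
        return cls(
            window_starts=df["window_start_s"].to_numpy(float),
            window_s=window_s,
            rc=df["rc_bpm"].to_numpy(float),
            rp=df["rp_s"].to_numpy(float),
            defined=df["defined"].to_numpy(bool),
        )


def merge_runs(labels: FrameLabelSequence) -> List[Tuple[int, int, int]]:
    """Collapse the label sequence into maximal runs.

    Returns ``(label_code, start_frame, length)`` triples that partition the
    sequence; adjacent runs always differ in label.
    """
    codes = labels.labels
    if codes.size == 0:
        raise InvalidArgumentError("cannot merge runs of an empty label sequence")
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [codes.size]))
    return [(int(codes[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _remerge(runs: List[Tuple[int, int, int]]) -> List[Tuple[int, int, int]]:
    merged: List[List[int]] = []
    for lab, start, length in runs:
        if merged and merged[-1][0] == lab:
            merged[-1][2] += length
        else:
            merged.append([lab, start, length])
    return [tuple(r) for r in merged]


def detect_inhale_onsets(
    runs: List[Tuple[int, int, int]],
    rules: PostProcessRules,
    frame_rate: float,
) -> OnsetTrain:
    """Validate runs against the post-processing rules and emit onsets.

    Steps, in order: (1) hysteresis — repeatedly absorb non-inhale runs whose
    duration is strictly below ``min_gap_s`` and whose neighbours on both
    sides are inhale runs, re-merging after each pass until stable; (2) drop
    inhale runs strictly shorter than ``min_inhale_s`` (relabelled to the
    preceding run's label, or the following run's, or silence); (3) candidate
    onsets at every {silence, exhale} → inhale transition, including an inhale
    run that opens the sequence; (4) accept candidates left to right, skipping
    any within ``refractory_s`` of the last accepted onset.  Onset time is the
    first frame of the validated run divided by the frame rate.
    """
    if frame_rate <= 0:
        raise InvalidArgumentError("frame_rate must be positive")
    runs = list(runs)
    if not runs:
        return OnsetTrain(np.array([]))

    # (1) hysteresis to fixpoint
    changed = True
    while changed:
        changed = False
        out: List[Tuple[int, int, int]] = []
        for i, (lab, start, length) in enumerate(runs):
            absorb = (
                lab != INHALE
                and length / frame_rate < rules.min_gap_s
                and 0 < i < len(runs) - 1
                and runs[i - 1][0] == INHALE
                and runs[i + 1][0] == INHALE
            )
            if absorb:
                out.append((INHALE, start, length))
                changed = True
            else:
                out.append((lab, start, length))
        runs = _remerge(out)

    # (2) minimum inhale duration
    out = []
    for i, (lab, start, length) in enumerate(runs):
        if lab == INHALE and length / frame_rate < rules.min_inhale_s:
            if i > 0:
                lab = runs[i - 1][0]
            elif len(runs) > 1:
                lab = runs[i + 1][0]
            else:
                lab = SILENCE
        out.append((lab, start, length))
    runs = _remerge(out)

    # (3) candidate transitions into inhale
    candidates = [
        start / frame_rate
        for i, (lab, start, _) in enumerate(runs)
        if lab == INHALE and (i == 0 or runs[i - 1][0] in (SILENCE, EXHALE))
    ]

    # (4) refractory acceptance
    accepted: List[float] = []
    for t in candidates:
        if not accepted or t - accepted[-1] >= rules.refractory_s:
            accepted.append(t)
    return OnsetTrain(np.array(accepted))


def parse_labels(
    labels: FrameLabelSequence, rules: Optional[PostProcessRules] = None
) -> OnsetTrain:
    """Convenience wrapper: merge runs then detect onsets."""
    if rules is None:
        rules = PostProcessRules()
    if len(labels) == 0:
        return OnsetTrain(np.array([]))
    return detect_inhale_onsets(merge_runs(labels), rules, labels.frame_rate)


def respiratory_count(
    onsets: OnsetTrain, window_start: float, window_s: float
) -> float:
    """Inhale onsets in ``[window_start, window_start + window_s)``, scaled to
    breaths per minute."""
    if window_s <= 0:
        raise InvalidArgumentError("window_s must be positive")
    t = onsets.times
    count = int(np.count_nonzero((t >= window_start) & (t < window_start + window_s)))
    return count * (60.0 / window_s)


def respiratory_period(
    onsets: OnsetTrain,
    window_start: float,
    window_s: float,
    margin_s: float = 2.0,
) -> Optional[float]:
    """Median inhale-to-inhale interval for one window, or None if undefined.

    Onsets within ``margin_s`` of the window edges also qualify, so an
    interval straddling the boundary is still captured.  With fewer than two
    qualifying onsets the period is undefined.
    """
    if window_s <= 0:
        raise InvalidArgumentError("window_s must be positive")
    if margin_s < 0:
        raise InvalidArgumentError("margin_s must be >= 0")
    t = onsets.times
    sel = t[(t >= window_start - margin_s) & (t < window_start + window_s + margin_s)]
    if sel.size < 2:
        return None
    return float(np.median(np.diff(sel)))


def compute_window_metrics(
    onsets: OnsetTrain,
    window_starts,
    window_s: float = 20.0,
    margin_s: float = 2.0,
) -> WindowMetricSeries:
    """RC and RP for a series of analysis windows."""
    window_starts = np.asarray(window_starts, dtype=float)
    rc = np.array([respiratory_count(onsets, s, window_s) for s in window_starts])
    rp_vals = [respiratory_period(onsets, s, window_s, margin_s) for s in window_starts]
    defined = np.array([v is not None for v in rp_vals])
    rp = np.array([v if v is not None else np.nan for v in rp_vals])
    return WindowMetricSeries(window_starts, window_s, rc, rp, defined)
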