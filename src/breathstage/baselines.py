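"""Classical signal-processing comparators for respiratory-rate estimation.

Two widely used non-learned estimators serve as reference points for the
segmentation pipeline:

* :func:`fft_rate_estimate` — band-pass the audio to the respiration-relevant
  band, extract an amplitude envelope (rectify + low-pass), dynamically
  compress it (log1p), smooth with a Gaussian kernel, detrend, and take the
  periodogram argmax inside a plausible breaths-per-minute band.
* :func:`peak_envelope_estimate` — compute a log-Mel spectrogram, collapse it
  to an intensity envelope, smooth with a Gaussian kernel, detect prominent
  peaks, and refine each peak by quasi-Newton maximisation of a cubic-spline
  interpolation of the envelope (constrained to ±1 frame around the discrete
  peak).

Every filter cutoff, compression law, smoothing width and the refinement
objective is a documented default of this package; the literature the
estimators descend from specifies only the overall sketch.  Both estimators
are deterministic given their input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize
from scipy.signal import butter, detrend, find_peaks, sosfiltfilt

from .errors import InvalidArgumentError
from .segment import LogMelParams, WindowingConfig, compute_logmel, window_audio

__all__ = [
    "BaselineEstimate",
    "fft_rate_estimate",
    "peak_envelope_estimate",
    "baseline_metric_series",
]

MIN_WAVEFORM_S = 10.0


@dataclass
class BaselineEstimate:
    """A classical estimate of respiratory rate and period.

    ``rp_s`` is NaN when no period is defined (zero detected breaths);
    ``confidence`` lies in [0, 1].
    """

    rc_bpm: float
    rp_s: float
    confidence: float

    def __post_init__(self) -> None:
        if self.rc_bpm < 0:
            raise InvalidArgumentError("rc_bpm must be >= 0")
        if self.rc_bpm > 0 and not (np.isnan(self.rp_s) or self.rp_s > 0):
            raise InvalidArgumentError("rp_s must be positive when rc_bpm > 0")


def _envelope(waveform: np.ndarray, rate: float, env_rate: float = 50.0,
              band: Tuple[float, float] = (300.0, 2000.0)) -> Tuple[np.ndarray, float]:
    """Band-pass + rectify + low-pass + decimate to an amplitude envelope."""
    nyq = rate / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    x = sosfiltfilt(sos, waveform)
    rect = np.abs(x)
    lp = butter(4, min(env_rate / 2.0, 0.45 * rate) / nyq, btype="low", output="sos")
    smooth = sosfiltfilt(lp, rect)
    step = max(1, int(round(rate / env_rate)))
    return smooth[::step], rate / step


def fft_rate_estimate(
    waveform: np.ndarray,
    audio_rate: float,
    band_bpm: Tuple[float, float] = (4.0, 40.0),
) -> BaselineEstimate:
    """Spectral respiratory-rate estimate from the audio amplitude envelope.

    The envelope is log1p-compressed, Gaussian-smoothed (sigma 0.2 s),
    detrended and zero-padded (8x) before the periodogram argmax restricted
    to ``band_bpm``.  Confidence is the share of band power within ±10% of
    the winning frequency.
    """
    waveform = np.asarray(waveform, dtype=float)
    n_s = waveform.size / audio_rate
    if n_s < MIN_WAVEFORM_S:
        raise InvalidArgumentError("need at least 10 s of audio for the FFT baseline")
    f_lo, f_hi = band_bpm[0] / 60.0, band_bpm[1] / 60.0
    if n_s < 2.0 / f_lo / 2.0:  # at least ~one cycle of the slowest rate
        raise InvalidArgumentError("audio too short to resolve the requested band")
    env, env_rate = _envelope(waveform, audio_rate)
    comp = np.log1p(env)
    smooth = gaussian_filter1d(comp, sigma=0.2 * env_rate)
    x = detrend(smooth)
    nfft = int(2 ** np.ceil(np.log2(x.size * 8)))
    spec = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / env_rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(in_band):
        raise InvalidArgumentError("band_bpm falls outside the resolvable range")
    band_power = spec[in_band]
    band_freqs = freqs[in_band]
    k = int(np.argmax(band_power))
    f_star = float(band_freqs[k])
    near = np.abs(band_freqs - f_star) <= 0.1 * f_star
    total = float(band_power.sum())
    confidence = float(band_power[near].sum() / total) if total > 0 else 0.0
    rc = 60.0 * f_star
    return BaselineEstimate(rc_bpm=rc, rp_s=60.0 / rc, confidence=min(confidence, 1.0))


def peak_envelope_estimate(
    waveform: np.ndarray,
    audio_rate: float,
    logmel_params: Optional[LogMelParams] = None,
    smooth_sigma_s: float = 0.3,
    min_distance_s: float = 1.0,
    prominence_factor: float = 0.1,
) -> BaselineEstimate:
    """Breath counting by refined peak detection on the log-Mel intensity
    envelope.

    Peaks must be at least ``min_distance_s`` apart with prominence at least
    ``prominence_factor`` x envelope SD.  Each discrete peak is refined by
    L-BFGS-B maximisation of a cubic spline through the smoothed envelope,
    bounded to ±1 frame, so refinement can never move a peak further than one
    frame.  With no detected peaks the estimate is 0 breaths/min and an
    undefined (NaN) period.
    """
    waveform = np.asarray(waveform, dtype=float)
    duration_s = waveform.size / audio_rate
    if duration_s < MIN_WAVEFORM_S:
        raise InvalidArgumentError("need at least 10 s of audio for the peak baseline")
    if logmel_params is None:
        logmel_params = LogMelParams(n_mels=40, fmax=min(2000.0, audio_rate / 2.0))
    spec = compute_logmel(waveform, audio_rate, logmel_params)
    envelope = spec.data.mean(axis=1)
    fr = spec.frame_rate
    smooth = gaussian_filter1d(envelope, sigma=smooth_sigma_s * fr)
    sd = float(np.std(smooth))
    if sd == 0.0:
        return BaselineEstimate(rc_bpm=0.0, rp_s=float("nan"), confidence=0.0)
    peaks, props = find_peaks(
        smooth,
        distance=max(1, int(round(min_distance_s * fr))),
        prominence=prominence_factor * sd,
    )
    if peaks.size == 0:
        return BaselineEstimate(rc_bpm=0.0, rp_s=float("nan"), confidence=0.0)
    spline = CubicSpline(np.arange(smooth.size), smooth)
    refined = []
    for p in peaks:
        res = minimize(
            lambda z: -spline(float(z[0])),
            x0=[float(p)],
            method="L-BFGS-B",
            bounds=[(max(0.0, p - 1.0), min(smooth.size - 1.0, p + 1.0))],
        )
        refined.append(float(res.x[0]) / fr)
    refined = np.sort(np.asarray(refined))
    rc = 60.0 * refined.size / duration_s
    rp = float(np.median(np.diff(refined))) if refined.size >= 2 else float("nan")
    confidence = float(min(1.0, np.mean(props["prominences"]) / (3.0 * sd)))
    return BaselineEstimate(rc_bpm=rc, rp_s=rp, confidence=confidence)


def baseline_metric_series(
    waveform: np.ndarray,
    audio_rate: float,
    method: str = "fft",
    windowing: Optional[WindowingConfig] = None,
):
    """Apply a baseline estimator per analysis window.

    Returns ``(window_starts, rc_bpm, rp_s)`` arrays; windows where the
    estimator yields no breaths carry rc 0 and NaN rp.
    """
    if windowing is None:
        windowing = WindowingConfig(audio_rate=audio_rate)
    if method not in ("fft", "peaks"):
        raise InvalidArgumentError("method must be 'fft' or 'peaks'")
    starts, rcs, rps = [], [], []
    for w in window_audio(waveform, windowing):
        if method == "fft":
            est = fft_rate_estimate(w.waveform, audio_rate)
        else:
            est = peak_envelope_estimate(w.waveform, audio_rate)
        starts.append(w.start_s)
        rcs.append(est.rc_bpm)
        rps.append(est.rp_s)
    return np.asarray(starts), np.asarray(rcs), np.asarray(rps)
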