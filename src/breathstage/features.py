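"""Episode-level aggregation of window metrics into 76 named features.

The overnight series of Respiratory Count (RC) and Respiratory Period (RP)
values is summarised by a fixed, ordered, named feature vector covering five
families: time-domain statistics, temporal dynamics, frequency-domain
descriptors, distribution-shape statistics, and RC/RP cross-interactions.
The published description fixes the count (76) and the families but not the
individual definitions; the enumeration below — 34 statistics per series plus
8 cross-features — is this package's canonical, stable contract.

Per series (namespaces ``rc.`` and ``rp.``), in order::

    mean, std, min, max, range, median, q1, q3, iqr, mad, cv,
    skewness, kurtosis, zcr, slope_ma5, slope_ma15,
    autocorr_lag1 .. autocorr_lag5,
    dom_freq, dom_power, spectral_entropy, spectral_centroid,
    rms_diff, mean_abs_diff, frac_above_mean,
    p5, p10, p90, p95, trimmed_mean_10, longest_run_halfsd

Cross-features (namespace ``cross.``)::

    corr_rc_rp, cov_rc_rp, mean_ratio, median_ratio, sd_ratio,
    cv_ratio, iqr_ratio, dom_freq_ratio

Numeric conventions (all chosen so every vector entry is finite):

* moments use population normalisation (ddof = 0); skewness is m3/m2^1.5 and
  kurtosis is excess (m4/m2^2 - 3);
* on a constant series, skewness, kurtosis, autocorrelations, CV, dominant
  frequency/power, spectral entropy/centroid and the RC/RP correlation are
  all defined as 0; ratios with a zero denominator are 0;
* autocorrelation at lag k is the Pearson correlation of the series with its
  k-shifted copy (bounded in [-1, 1]);
* the periodogram is P_k = |X_k|^2 / n over the one-sided DFT, frequencies in
  cycles/window; the DC bin is excluded from the dominant-frequency search,
  the spectral entropy (normalised, base 2) and the centroid;
* slopes are OLS slopes of the centred moving average (shrinking edge
  windows) against the window index, in units per window;
* windows with undefined RP are dropped before any RP statistic; the
  cross-features pair RC with RP on the RP-defined windows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidArgumentError
from .events import WindowMetricSeries

__all__ = ["EpisodeFeatureVector", "feature_names", "aggregate_features"]

N_FEATURES = 76

_SERIES_STATS: Tuple[str, ...] = (
    "mean", "std", "min", "max", "range", "median", "q1", "q3", "iqr", "mad",
    "cv", "skewness", "kurtosis", "zcr", "slope_ma5", "slope_ma15",
    "autocorr_lag1", "autocorr_lag2", "autocorr_lag3", "autocorr_lag4",
    "autocorr_lag5", "dom_freq", "dom_power", "spectral_entropy",
    "spectral_centroid", "rms_diff", "mean_abs_diff", "frac_above_mean",
    "p5", "p10", "p90", "p95", "trimmed_mean_10", "longest_run_halfsd",
)

_CROSS_STATS: Tuple[str, ...] = (
    "corr_rc_rp", "cov_rc_rp", "mean_ratio", "median_ratio", "sd_ratio",
    "cv_ratio", "iqr_ratio", "dom_freq_ratio",
)


def feature_names() -> Tuple[str, ...]:
    """The 76 feature identifiers, in their canonical, version-stable order."""
    names = [f"rc.{s}" for s in _SERIES_STATS]
    names += [f"rp.{s}" for s in _SERIES_STATS]
    names += [f"cross.{s}" for s in _CROSS_STATS]
    assert len(names) == N_FEATURES
    return tuple(names)


@dataclass
class EpisodeFeatureVector:
    """Named, ordered, all-finite 76-dimensional episode descriptor."""

    names: Tuple[str, ...]
    values: np.ndarray
    provenance: Dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != N_FEATURES or self.values.size != N_FEATURES:
            raise InvalidArgumentError(f"feature vector must have {N_FEATURES} entries")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("feature values must all be finite")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def to_frame(self) -> pd.DataFrame:
        row = self.as_dict()
        row.update({f"provenance.{k}": v for k, v in self.provenance.items()})
        return pd.DataFrame([row])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, x.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _ols_slope(y: np.ndarray) -> float:
    if y.size < 2:
        return 0.0
    t = np.arange(y.size, dtype=float)
    tc = t - t.mean()
    denom = float(np.sum(tc * tc))
    return float(np.sum(tc * (y - y.mean())) / denom) if denom else 0.0


def _autocorr(x: np.ndarray, lag: int) -> float:
    if x.size <= lag + 1:
        return 0.0
    a, b = x[:-lag], x[lag:]
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _periodogram(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided P_k = |X_k|^2 / n at frequencies k/n in cycles/window."""
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n)
    return freqs, spec


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def _series_features(x: np.ndarray) -> Dict[str, float]:
    n = x.size
    mean = float(np.mean(x))
    std = float(np.std(x))
    median = float(np.median(x))
    q1, q3 = (float(v) for v in np.percentile(x, [25, 75]))
    out: Dict[str, float] = {
        "mean": mean,
        "std": std,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "range": float(np.max(x) - np.min(x)),
        "median": median,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "mad": float(np.median(np.abs(x - median))),
        "cv": std / mean if mean != 0.0 else 0.0,
        "skewness": float(sps.skew(x)) if std > 0 else 0.0,
        "kurtosis": float(sps.kurtosis(x)) if std > 0 else 0.0,
    }
    centered = x - mean
    signs = centered >= 0
    out["zcr"] = float(np.count_nonzero(signs[:-1] != signs[1:]) / (n - 1))
    out["slope_ma5"] = _ols_slope(_moving_average(x, 5))
    out["slope_ma15"] = _ols_slope(_moving_average(x, 15))
    for lag in range(1, 6):
        out[f"autocorr_lag{lag}"] = _autocorr(x, lag)

    freqs, spec = _periodogram(centered)
    body, fbody = spec[1:], freqs[1:]
    total = float(body.sum())
    if total > 0.0 and body.size:
        k = int(np.argmax(body))
        out["dom_freq"] = float(fbody[k])
        out["dom_power"] = float(body[k])
        p = body / total
        nz = p[p > 0]
        ent = float(-(nz * np.log2(nz)).sum())
        out["spectral_entropy"] = ent / np.log2(body.size) if body.size > 1 else 0.0
        out["spectral_centroid"] = float((fbody * p).sum())
    else:
        out["dom_freq"] = out["dom_power"] = 0.0
        out["spectral_entropy"] = out["spectral_centroid"] = 0.0

    d = np.diff(x)
    out["rms_diff"] = float(np.sqrt(np.mean(d * d))) if d.size else 0.0
    out["mean_abs_diff"] = float(np.mean(np.abs(d))) if d.size else 0.0
    out["frac_above_mean"] = float(np.count_nonzero(x > mean) / n)
    for p_, name in ((5, "p5"), (10, "p10"), (90, "p90"), (95, "p95")):
        out[name] = float(np.percentile(x, p_))
    out["trimmed_mean_10"] = float(sps.trim_mean(x, 0.1))
    out["longest_run_halfsd"] = float(_longest_run(np.abs(x - median) <= 0.5 * std))
    return out


def aggregate_features(series: WindowMetricSeries) -> EpisodeFeatureVector:
    """Compute the 76-dimensional episode feature vector from window metrics.

    Windows with undefined RP are excluded from all RP and cross statistics;
    their count is recorded in the provenance.  Raises
    :class:`DegenerateInputError` if either series has fewer than 2 usable
    windows.
    """
    if len(series) == 0:
        raise DegenerateInputError("window metric series is empty")
    rc = series.rc
    rp = series.rp[series.defined]
    problems = [name for name, arr in (("rc", rc), ("rp", rp)) if arr.size < 2]
    if problems:
        raise DegenerateInputError(
            f"fewer than 2 defined windows in series: {', '.join(problems)}"
        )

    rc_stats = _series_features(rc)
    rp_stats = _series_features(rp)

    # Cross-features on windows where RP is defined, pairing RC with RP.
    rc_pair = series.rc[series.defined]
    rp_pair = rp
    src, srp = np.std(rc_pair), np.std(rp_pair)
    if src > 0 and srp > 0:
        corr = float(
            np.mean((rc_pair - rc_pair.mean()) * (rp_pair - rp_pair.mean()))
            / (src * srp)
        )
    else:
        corr = 0.0

    def ratio(a: float, b: float) -> float:
        return a / b if b != 0.0 else 0.0

    cross = {
        "corr_rc_rp": corr,
        "cov_rc_rp": float(
            np.mean((rc_pair - rc_pair.mean()) * (rp_pair - rp_pair.mean()))
        ),
        "mean_ratio": ratio(rc_stats["mean"], rp_stats["mean"]),
        "median_ratio": ratio(rc_stats["median"], rp_stats["median"]),
        "sd_ratio": ratio(rc_stats["std"], rp_stats["std"]),
        "cv_ratio": ratio(rc_stats["cv"], rp_stats["cv"]),
        "iqr_ratio": ratio(rc_stats["iqr"], rp_stats["iqr"]),
        "dom_freq_ratio": ratio(rc_stats["dom_freq"], rp_stats["dom_freq"]),
    }

    values = (
        [rc_stats[s] for s in _SERIES_STATS]
        + [rp_stats[s] for s in _SERIES_STATS]
        + [cross[s] for s in _CROSS_STATS]
    )
    provenance = {
        "n_windows": len(series),
        "n_rp_defined": int(np.count_nonzero(series.defined)),
        "n_rp_excluded": int(np.count_nonzero(~series.defined)),
    }
    return EpisodeFeatureVector(feature_names(), np.array(values), provenance)
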