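"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit Python loops, O(n^2) DFT,
restart-on-change scanning) and shares no code with the package, so
agreement between the two is meaningful.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

INHALE, EXHALE, SILENCE = 0, 1, 2


# ---------------------------------------------------------------------------
# Onset parser
# ---------------------------------------------------------------------------


def _runs(labels: Sequence[int]) -> List[Tuple[int, int, int]]:
    runs = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        runs.append((labels[i], i, j - i))
        i = j
    return runs


def reference_parse(
    labels: Sequence[int],
    frame_rate: float,
    min_inhale_s: float,
    min_gap_s: float,
    refractory_s: float,
) -> List[float]:
    """Naive re-derivation of the onset-validation rules.

    Hysteresis: repeatedly convert to inhale any maximal non-inhale run that
    is strictly shorter than min_gap_s and has inhale frames on both sides,
    restarting the scan after each change.  Then relabel inhale runs shorter
    than min_inhale_s to the preceding run's label (else the following run's,
    else silence).  Candidates are starts of inhale runs preceded by silence/
    exhale or opening the sequence; a candidate within refractory_s of the
    last accepted onset is discarded.
    """
    lab = list(labels)
    if not lab:
        return []

    changed = True
    while changed:
        changed = False
        for run_lab, start, length in _runs(lab):
            if (
                run_lab != INHALE
                and length / frame_rate < min_gap_s
                and start > 0
                and start + length < len(lab)
                and lab[start - 1] == INHALE
                and lab[start + length] == INHALE
            ):
                for i in range(start, start + length):
                    lab[i] = INHALE
                changed = True
                break

    runs = _runs(lab)
    new_lab = list(lab)
    for idx, (run_lab, start, length) in enumerate(runs):
        if run_lab == INHALE and length / frame_rate < min_inhale_s:
            if idx > 0:
                repl = runs[idx - 1][0]
            elif len(runs) > 1:
                repl = runs[idx + 1][0]
            else:
                repl = SILENCE
            for i in range(start, start + length):
                new_lab[i] = repl
    lab = new_lab

    onsets = []
    last = None
    for idx, (run_lab, start, _) in enumerate(_runs(lab)):
        if run_lab != INHALE:
            continue
        if idx > 0 and _runs(lab)[idx - 1][0] not in (SILENCE, EXHALE):
            continue
        t = start / frame_rate
        if last is None or t - last >= refractory_s:
            onsets.append(t)
            last = t
    return onsets


# ---------------------------------------------------------------------------
# Majority-vote ballot counting
# ---------------------------------------------------------------------------


def reference_vote(
    windows: List[Tuple[int, List[List[float]]]],
    n_frames: int,
    priority: Sequence[int] = (SILENCE, EXHALE, INHALE),
) -> List[int]:
    """Per-frame ballot count over (start_frame, posterior-rows) windows.

    Each window votes its per-frame argmax; ties go to the larger mean
    posterior among tied classes, then to the fixed class priority.
    """
    out = []
    for g in range(n_frames):
        votes = [0, 0, 0]
        sums = [0.0, 0.0, 0.0]
        n_cov = 0
        for start, post in windows:
            if start <= g < start + len(post):
                row = post[g - start]
                best = max(range(3), key=lambda c: (row[c], -c))
                votes[best] += 1
                for c in range(3):
                    sums[c] += row[c]
                n_cov += 1
        assert n_cov > 0, "reference_vote: uncovered frame"
        top = max(votes)
        tied = [c for c in range(3) if votes[c] == top]
        if len(tied) > 1:
            best_mean = max(sums[c] / n_cov for c in tied)
            tied = [c for c in tied if sums[c] / n_cov >= best_mean - 1e-12]
        if len(tied) > 1:
            tied = [min(tied, key=lambda c: priority.index(c))]
        out.append(tied[0])
    return out


# ---------------------------------------------------------------------------
# Episode feature statistics
# ---------------------------------------------------------------------------


def _mean(x):
    return sum(x) / len(x)


def _std(x):
    m = _mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def _percentile(x, p):
    s = sorted(x)
    h = (len(s) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _moving_average(x, window):
    half = window // 2
    out = []
    for i in range(len(x)):
        lo = max(i - half, 0)
        hi = min(i + half + 1, len(x))
        out.append(sum(x[lo:hi]) / (hi - lo))
    return out


def _ols_slope(y):
    n = len(y)
    if n < 2:
        return 0.0
    tbar = (n - 1) / 2.0
    ybar = _mean(y)
    num = sum((i - tbar) * (y[i] - ybar) for i in range(n))
    den = sum((i - tbar) ** 2 for i in range(n))
    return num / den if den else 0.0


def _pearson(a, b):
    sa, sb = _std(a), _std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    ma, mb = _mean(a), _mean(b)
    return sum((x - ma) * (y - mb) for x, y in zip(a, b)) / (len(a) * sa * sb)


def _dft_power(x):
    """One-sided P_k = |X_k|^2 / n via the naive O(n^2) DFT."""
    n = len(x)
    out = []
    for k in range(n // 2 + 1):
        re = sum(x[i] * math.cos(2 * math.pi * k * i / n) for i in range(n))
        im = -sum(x[i] * math.sin(2 * math.pi * k * i / n) for i in range(n))
        out.append((re * re + im * im) / n)
    return out


def reference_series_features(x: Sequence[float]) -> Dict[str, float]:
    x = [float(v) for v in x]
    n = len(x)
    mean = _mean(x)
    std = _std(x)
    med = _percentile(x, 50)
    q1, q3 = _percentile(x, 25), _percentile(x, 75)
    out = {
        "mean": mean,
        "std": std,
        "min": min(x),
        "max": max(x),
        "range": max(x) - min(x),
        "median": med,
        "q1": q1,
        "q3": q3,
        "iqr": q3 - q1,
        "mad": _percentile([abs(v - med) for v in x], 50),
        "cv": std / mean if mean != 0 else 0.0,
    }
    if std > 0:
        m2 = sum((v - mean) ** 2 for v in x) / n
        m3 = sum((v - mean) ** 3 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        out["skewness"] = m3 / m2**1.5
        out["kurtosis"] = m4 / m2**2 - 3.0
    else:
        out["skewness"] = out["kurtosis"] = 0.0
    signs = [v - mean >= 0 for v in x]
    out["zcr"] = sum(1 for i in range(n - 1) if signs[i] != signs[i + 1]) / (n - 1)
    out["slope_ma5"] = _ols_slope(_moving_average(x, 5))
    out["slope_ma15"] = _ols_slope(_moving_average(x, 15))
    for lag in range(1, 6):
        out[f"autocorr_lag{lag}"] = (
            _pearson(x[:-lag], x[lag:]) if n > lag + 1 else 0.0
        )

    centered = [v - mean for v in x]
    power = _dft_power(centered)
    body = power[1:]
    total = sum(body)
    if total > 0 and body:
        k = max(range(len(body)), key=lambda i: body[i])
        out["dom_freq"] = (k + 1) / n
        out["dom_power"] = body[k]
        probs = [p / total for p in body if p > 0]
        ent = -sum(p * math.log2(p) for p in probs)
        out["spectral_entropy"] = ent / math.log2(len(body)) if len(body) > 1 else 0.0
        out["spectral_centroid"] = sum(
            ((i + 1) / n) * (p / total) for i, p in enumerate(body)
        )
    else:
        out["dom_freq"] = out["dom_power"] = 0.0
        out["spectral_entropy"] = out["spectral_centroid"] = 0.0

    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    out["rms_diff"] = math.sqrt(_mean([d * d for d in diffs])) if diffs else 0.0
    out["mean_abs_diff"] = _mean([abs(d) for d in diffs]) if diffs else 0.0
    out["frac_above_mean"] = sum(1 for v in x if v > mean) / n
    for p, name in ((5, "p5"), (10, "p10"), (90, "p90"), (95, "p95")):
        out[name] = _percentile(x, p)
    cut = int(0.1 * n)
    out["trimmed_mean_10"] = _mean(sorted(x)[cut : n - cut])
    best = run = 0
    for v in x:
        run = run + 1 if abs(v - med) <= 0.5 * std else 0
        best = max(best, run)
    out["longest_run_halfsd"] = float(best)
    return out


def reference_cross_features(rc_pair, rp_pair, rc_stats, rp_stats):
    def ratio(a, b):
        return a / b if b != 0 else 0.0

    n = len(rc_pair)
    mrc, mrp = _mean(rc_pair), _mean(rp_pair)
    return {
        "corr_rc_rp": _pearson(rc_pair, rp_pair),
        "cov_rc_rp": sum((a - mrc) * (b - mrp) for a, b in zip(rc_pair, rp_pair)) / n,
        "mean_ratio": ratio(rc_stats["mean"], rp_stats["mean"]),
        "median_ratio": ratio(rc_stats["median"], rp_stats["median"]),
        "sd_ratio": ratio(rc_stats["std"], rp_stats["std"]),
        "cv_ratio": ratio(rc_stats["cv"], rp_stats["cv"]),
        "iqr_ratio": ratio(rc_stats["iqr"], rp_stats["iqr"]),
        "dom_freq_ratio": ratio(rc_stats["dom_freq"], rp_stats["dom_freq"]),
    }


def reference_coverage_bound(abs_errors: Sequence[float], c: float) -> float:
    """Exhaustive scan over candidate half-widths."""
    cand = sorted(abs(e) for e in abs_errors)
    n = len(cand)
    for b in cand:
        covered = sum(1 for e in cand if e <= b)
        if 100.0 * covered / n >= c:
            return b
    return cand[-1]
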