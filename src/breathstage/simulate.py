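"""Synthetic overnight episodes and cohorts with known ground truth.

No generative description of real overnight tracheal audio is available, so
everything here is an explicitly labelled stand-in built from the physiology
the pipeline exploits: respiration is slower and more regular in deep (N3)
sleep and faster/more irregular during REM and wakefulness.  The simulator
produces, for a configurable episode,

* an AASM-style hypnogram (30 s epochs over W/N1/N2/N3/REM) from a
  first-order Markov chain with configurable mean bout durations — the
  simplest model with realistic stage runs and an analytically known
  stationary distribution;
* ground-truth inhale-onset times whose inter-onset intervals follow the
  stage the sleeper is in (per-stage mean rate and coefficient of variation),
  never closer than 1 s (a ~60 breaths/min physiological ceiling);
* a tracheal-audio stand-in — band-limited noise bursts on a noise floor at a
  configurable SNR, with inhale bursts (500–2000 Hz) at each onset and
  softer, lower-band exhale bursts (200–700 Hz) mid-cycle so the classes are
  acoustically separable;
* a synchronized abdominal-effort stand-in — a smooth unit-amplitude
  quasi-sinusoid whose local maxima sit at the inhale onsets (matching the
  annotation module's default ``max_is_inhale`` polarity) plus small sensor
  noise;
* reference frame labels derived directly from the true onsets, for oracle
  segmentation and supervised backend training.

Cohort generation draws 76-dimensional feature tables with standard-normal
marginals and maps them to stage-proportion targets through a configurable
(by default linear) mapping followed by simplex normalisation, enabling exact
parameter-recovery tests of the staging regressors.

Everything is seeded: identical config + seed reproduces label, onset and
signal outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from .annotate import EXHALE, INHALE, SILENCE, FrameLabelSequence
from .errors import ConfigurationError, InvalidArgumentError
from .events import OnsetTrain
from .features import feature_names
from .staging import STAGE_NAMES, StageProportions, hypnogram_to_proportions, simplex_normalize

__all__ = [
    "EPOCH_S",
    "SLEEP_STAGES",
    "StageBreathProfile",
    "DEFAULT_STAGE_PROFILES",
    "HypnogramModel",
    "SyntheticEpisodeConfig",
    "SyntheticEpisode",
    "generate_hypnogram",
    "generate_breath_onsets",
    "onsets_to_reference_labels",
    "synthesize_signals",
    "generate_episode",
    "LinearProportionMapping",
    "default_linear_mapping",
    "generate_cohort",
    "write_wav",
    "read_wav",
]

EPOCH_S = 30.0
SLEEP_STAGES: Tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
MIN_ONSET_SPACING_S = 1.0


@dataclass(frozen=True)
class StageBreathProfile:
    """Breathing statistics for one sleep stage.

    ``rate_bpm``: mean respiratory rate in breaths/min (allowed 4–40).
    ``rate_cv``: coefficient of variation of the inter-onset interval —
    small in deep sleep, large in REM/wake.
    """

    rate_bpm: float
    rate_cv: float

    def __post_init__(self) -> None:
        if not 4.0 <= self.rate_bpm <= 40.0:
            raise InvalidArgumentError("stage mean rate must lie in [4, 40] bpm")
        if self.rate_cv < 0:
            raise InvalidArgumentError("rate CV must be >= 0")


#: Adult overnight defaults: slow/regular in N3, fast/irregular in REM and wake.
DEFAULT_STAGE_PROFILES: Dict[str, StageBreathProfile] = {
    "W": StageBreathProfile(15.0, 0.22),
    "N1": StageBreathProfile(14.0, 0.14),
    "N2": StageBreathProfile(13.0, 0.10),
    "N3": StageBreathProfile(11.5, 0.05),
    "REM": StageBreathProfile(15.5, 0.25),
}


@dataclass(frozen=True)
class HypnogramModel:
    """First-order Markov chain over 30 s epochs.

    The self-transition probability of stage *s* is ``1 - EPOCH_S /
    mean_bout_s[s]``; the complementary mass is distributed over the other
    stages proportionally to ``transition_weights[s]``.  The initial epoch is
    drawn from the chain's stationary distribution so that expected stage
    proportions equal the stationary distribution at every episode length.
    """

    stages: Tuple[str, ...] = SLEEP_STAGES
    mean_bout_s: Dict[str, float] = field(
        default_factory=lambda: {
            "W": 150.0, "N1": 90.0, "N2": 540.0, "N3": 420.0, "REM": 480.0
        }
    )
    transition_weights: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "W": {"N1": 0.70, "N2": 0.20, "REM": 0.10},
            "N1": {"W": 0.25, "N2": 0.60, "REM": 0.15},
            "N2": {"W": 0.15, "N1": 0.20, "N3": 0.40, "REM": 0.25},
            "N3": {"W": 0.15, "N1": 0.10, "N2": 0.75},
            "REM": {"W": 0.35, "N1": 0.25, "N2": 0.40},
        }
    )

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigurationError("hypnogram model needs at least one stage")
        for s in self.stages:
            if s not in SLEEP_STAGES:
                raise ConfigurationError(f"unknown sleep stage {s!r}")
            if len(self.stages) > 1:
                if self.mean_bout_s.get(s, 0) <= 0:
                    raise ConfigurationError(f"mean bout duration missing for {s!r}")

    def transition_matrix(self) -> np.ndarray:
        k = len(self.stages)
        if k == 1:
            return np.ones((1, 1))
        P = np.zeros((k, k))
        for i, s in enumerate(self.stages):
            stay = max(0.0, 1.0 - EPOCH_S / self.mean_bout_s[s])
            weights = np.array(
                [
                    self.transition_weights.get(s, {}).get(t, 0.0)
                    if t != s else 0.0
                    for t in self.stages
                ]
            )
            if weights.sum() <= 0:
                # absorbing fallback: stay forever
                P[i, i] = 1.0
                continue
            P[i] = (1.0 - stay) * weights / weights.sum()
            P[i, i] = stay
        return P

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        P = self.transition_matrix()
        vals, vecs = np.linalg.eig(P.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass(frozen=True)
class SyntheticEpisodeConfig:
    """Full configuration for one synthetic overnight episode."""

    duration_s: float = 8 * 3600.0
    audio_rate: float = 16000.0
    effort_rate: float = 10.0
    stage_profiles: Dict[str, StageBreathProfile] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROFILES)
    )
    hypnogram_model: HypnogramModel = field(default_factory=HypnogramModel)
    snr_db: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidArgumentError("duration_s must be positive")
        if self.audio_rate <= 0 or self.effort_rate <= 0:
            raise InvalidArgumentError("sampling rates must be positive")


@dataclass
class SyntheticEpisode:
    """One simulated night with full ground truth attached."""

    config: SyntheticEpisodeConfig
    hypnogram: List[str]
    true_onsets: OnsetTrain
    true_proportions: StageProportions
    audio: Optional[np.ndarray] = None
    effort: Optional[np.ndarray] = None


def generate_hypnogram(config: SyntheticEpisodeConfig) -> List[str]:
    """Sample one 30 s-epoch hypnogram from the configured Markov chain."""
    if config.duration_s < EPOCH_S:
        raise InvalidArgumentError("episode must span at least one 30 s epoch")
    model = config.hypnogram_model
    n_epochs = int(config.duration_s // EPOCH_S)
    stages = model.stages
    if len(stages) == 1:
        return [stages[0]] * n_epochs
    rng = np.random.default_rng(config.seed)
    P = model.transition_matrix()
    cum = np.cumsum(P, axis=1)
    pi = model.stationary_distribution()
    u = rng.random(n_epochs)
    state = int(np.searchsorted(np.cumsum(pi), u[0]))
    out = [stages[state]]
    for t in range(1, n_epochs):
        state = int(np.searchsorted(cum[state], u[t]))
        out.append(stages[state])
    return out


def generate_breath_onsets(
    hypnogram: Sequence[str],
    stage_profiles: Optional[Dict[str, StageBreathProfile]] = None,
    seed: int = 0,
) -> OnsetTrain:
    """Draw strictly increasing inhale-onset times driven by the hypnogram.

    Each inter-onset interval is drawn from a normal distribution whose mean
    is ``60 / rate_bpm`` and whose SD is ``rate_cv`` times the mean, for the
    stage of the epoch the previous onset falls in; intervals are floored at
    1 s.  The first onset sits one drawn interval after lights-off, so every
    night opens with silence.
    """
    if stage_profiles is None:
        stage_profiles = dict(DEFAULT_STAGE_PROFILES)
    hypnogram = list(hypnogram)
    if not hypnogram:
        return OnsetTrain(np.array([]))
    missing = sorted({s for s in hypnogram if s not in stage_profiles})
    if missing:
        raise ConfigurationError(f"no stage profile for hypnogram label(s): {missing}")
    duration = len(hypnogram) * EPOCH_S
    rng = np.random.default_rng(seed)
    times: List[float] = []
    t = 0.0
    while True:
        stage = hypnogram[min(int(t // EPOCH_S), len(hypnogram) - 1)]
        prof = stage_profiles[stage]
        mean = 60.0 / prof.rate_bpm
        dt = rng.normal(mean, prof.rate_cv * mean) if prof.rate_cv > 0 else mean
        t += max(MIN_ONSET_SPACING_S, dt)
        if t >= duration:
            break
        times.append(t)
    return OnsetTrain(np.array(times))


def _intervals(onsets: np.ndarray, duration: float) -> np.ndarray:
    """Cycle length attached to each onset (last one extends to its median)."""
    if onsets.size == 0:
        return np.array([])
    d = np.diff(onsets)
    last = float(np.median(d)) if d.size else min(5.0, duration - onsets[-1])
    return np.concatenate([d, [max(last, MIN_ONSET_SPACING_S)]])


def onsets_to_reference_labels(
    onsets: OnsetTrain,
    frame_rate: float,
    duration_s: float,
) -> FrameLabelSequence:
    """Ground-truth frame labels implied by the true onset train.

    Cycle layout per onset (interval Δ to the next onset): inhale for
    ``min(1.2 s, 0.35 Δ)``, silence, exhale over ``[0.45 Δ, 0.85 Δ)``, then
    silence until the next inhale — the same layout the audio synthesiser
    uses for its bursts.
    """
    if frame_rate <= 0 or duration_s <= 0:
        raise InvalidArgumentError("frame_rate and duration_s must be positive")
    n_frames = int(round(duration_s * frame_rate))
    labels = np.full(n_frames, SILENCE, dtype=np.int8)
    t = onsets.times
    ivals = _intervals(t, duration_s)

    def fill(t0: float, t1: float, code: int) -> None:
        lo = int(np.ceil(t0 * frame_rate - 1e-9))
        hi = int(np.ceil(t1 * frame_rate - 1e-9))
        labels[max(lo, 0) : min(hi, n_frames)] = code

    for tk, dk in zip(t, ivals):
        fill(tk, tk + min(1.2, 0.35 * dk), INHALE)
        fill(tk + 0.45 * dk, tk + 0.85 * dk, EXHALE)
    return FrameLabelSequence(frame_rate=frame_rate, labels=labels)


def _band_noise(rng: np.random.Generator, n: int, band: Tuple[float, float],
                rate: float) -> np.ndarray:
    noise = rng.standard_normal(n)
    nyq = rate / 2.0
    # compress the band under Nyquist for low sample rates, keeping its order
    hi = min(band[1] / nyq, 0.99)
    lo = min(band[0] / nyq, 0.5 * hi)
    sos = butter(4, [lo, hi], btype="band", output="sos")
    out = sosfiltfilt(sos, noise)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def synthesize_signals(
    onsets: OnsetTrain, config: SyntheticEpisodeConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Render the audio and effort stand-ins for a given onset train.

    Audio: white-noise floor plus Hann-enveloped band-noise bursts —
    inhale (500–2000 Hz) at each onset, exhale (200–700 Hz, 0.7x amplitude)
    mid-cycle; burst RMS is set ``snr_db`` above the floor RMS.  Effort:
    ``cos`` of a piecewise-linear phase that passes through a multiple of 2π
    at every onset, so local maxima sit at the onsets (±0.1 s), with small
    additive sensor noise.
    """
    t = onsets.times
    if t.size and (t.min() < 0 or t.max() >= config.duration_s):
        raise InvalidArgumentError("onsets must lie within [0, duration_s)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sr = config.audio_rate
    n_audio = int(round(config.duration_s * sr))
    noise_rms = 0.01
    audio = rng.standard_normal(n_audio) * noise_rms
    burst_rms = noise_rms * 10.0 ** (config.snr_db / 20.0)
    ivals = _intervals(t, config.duration_s)
    for tk, dk in zip(t, ivals):
        for start, dur, band, gain in (
            (tk, min(1.2, 0.35 * dk), (500.0, 2000.0), 1.0),
            (tk + 0.45 * dk, min(1.5, 0.40 * dk), (200.0, 700.0), 0.7),
        ):
            i0 = int(round(start * sr))
            n = int(round(dur * sr))
            if n < 8 or i0 >= n_audio:
                continue
            n = min(n, n_audio - i0)
            burst = _band_noise(rng, n, band, sr) * np.hanning(n)
            brms = float(np.sqrt(np.mean(burst**2)))
            if brms > 0:
                audio[i0 : i0 + n] += gain * burst_rms / brms * burst

    n_eff = int(round(config.duration_s * config.effort_rate))
    tt = np.arange(n_eff) / config.effort_rate
    if t.size >= 2:
        phase_knots = 2.0 * np.pi * np.arange(t.size)
        slope0 = 2.0 * np.pi / (t[1] - t[0])
        slope1 = 2.0 * np.pi / (t[-1] - t[-2])
        phase = np.interp(tt, t, phase_knots)
        before, after = tt < t[0], tt > t[-1]
        phase[before] = phase_knots[0] - slope0 * (t[0] - tt[before])
        phase[after] = phase_knots[-1] + slope1 * (tt[after] - t[-1])
        effort = np.cos(phase)
    elif t.size == 1:
        period = 5.0
        effort = np.cos(2.0 * np.pi * (tt - t[0]) / period)
    else:
        effort = np.zeros(n_eff)
    effort = effort + rng.standard_normal(n_eff) * 0.02
    return audio, effort


def generate_episode(
    config: SyntheticEpisodeConfig, with_signals: bool = True
) -> SyntheticEpisode:
    """Generate a full synthetic episode (hypnogram, onsets, signals)."""
    hyp = generate_hypnogram(config)
    onsets = generate_breath_onsets(hyp, config.stage_profiles, seed=config.seed)
    audio = effort = None
    if with_signals:
        audio, effort = synthesize_signals(onsets, config)
    return SyntheticEpisode(
        config=config,
        hypnogram=hyp,
        true_onsets=onsets,
        true_proportions=hypnogram_to_proportions(hyp),
        audio=audio,
        effort=effort,
    )


# ---------------------------------------------------------------------------
# Cohorts with known feature -> proportion mappings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearProportionMapping:
    """Raw stage score = intercept_s + sum_f coef_s[f] * x[f], then simplex.

    Feature names must come from :func:`breathstage.features.feature_names`.
    """

    intercepts: Dict[str, float]
    coefficients: Dict[str, Dict[str, float]]
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        known = set(feature_names())
        for stage in STAGE_NAMES:
            if stage not in self.intercepts:
                raise ConfigurationError(f"mapping lacks an intercept for {stage!r}")
            for f in self.coefficients.get(stage, {}):
                if f not in known:
                    raise ConfigurationError(f"mapping references unknown feature {f!r}")

    def raw(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros((len(X), len(STAGE_NAMES)))
        for j, stage in enumerate(STAGE_NAMES):
            out[:, j] = self.intercepts[stage]
            for f, c in self.coefficients.get(stage, {}).items():
                out[:, j] += c * X[f].to_numpy(float)
        return out

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        return np.vstack([simplex_normalize(r, self.epsilon) for r in self.raw(X)])


def default_linear_mapping() -> LinearProportionMapping:
    """Modest-signal linear mapping used by the recovery benchmarks.

    Per-feature coefficients sum to zero across stages and intercepts sum to
    one, so raw scores already sum to 1 and the simplex projection is the
    identity on noiseless data — making linear-regression recovery exact.
    """
    return LinearProportionMapping(
        intercepts={"wake": 0.15, "light": 0.50, "deep": 0.20, "rem": 0.15},
        coefficients={
            "wake": {"rc.mean": 0.02, "rc.cv": 0.02},
            "light": {"rc.cv": -0.02, "rp.mean": -0.02, "rp.cv": -0.02},
            "deep": {"rc.mean": -0.02, "rc.cv": -0.02, "rp.mean": 0.02},
            "rem": {"rc.cv": 0.02, "rp.cv": 0.02},
        },
    )


#: Latent dimensionality of the cohort feature model.  Episode feature
#: vectors are deterministic functionals of two underlying series, so their
#: 76 components are strongly collinear; the generator mirrors that by
#: drawing each subject's features as a fixed linear image of a small latent
#: respiratory state (rate level, variability, trend, ...).
COHORT_LATENT_DIM = 8
_COHORT_LOADING_SEED = 20_240_915


def _cohort_loadings() -> np.ndarray:
    """Fixed (76, COHORT_LATENT_DIM) loading matrix with unit-norm rows, so
    every feature marginal is standard normal."""
    rng = np.random.default_rng(_COHORT_LOADING_SEED)
    W = rng.standard_normal((len(feature_names()), COHORT_LATENT_DIM))
    return W / np.linalg.norm(W, axis=1, keepdims=True)


def generate_cohort(
    n_subjects: int,
    mapping_spec: Optional[LinearProportionMapping] = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort of (feature vector, stage proportions) pairs.

    Each subject's 76 features are a fixed unit-norm linear image of
    ``COHORT_LATENT_DIM`` standard-normal latent factors, so every feature
    has a standard-normal marginal while the table carries the strong
    collinearity of real episode descriptors.  Targets are the mapping
    output plus stage-wise Gaussian noise, re-projected onto the simplex.
    Returns ``(X, Y)`` indexed by ``subject_id``.
    """
    if n_subjects < 2:
        raise InvalidArgumentError("a cohort needs at least 2 subjects")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if mapping_spec is None:
        mapping_spec = default_linear_mapping()
    rng = np.random.default_rng(seed)
    names = list(feature_names())
    latents = rng.standard_normal((n_subjects, COHORT_LATENT_DIM))
    X = pd.DataFrame(
        latents @ _cohort_loadings().T,
        columns=names,
        index=pd.Index([f"subj{i:04d}" for i in range(n_subjects)], name="subject_id"),
    )
    clean = mapping_spec(X)
    noisy = clean + rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else clean
    Y = pd.DataFrame(
        np.vstack([simplex_normalize(r, mapping_spec.epsilon) for r in noisy]),
        columns=list(STAGE_NAMES),
        index=X.index,
    )
    return X, Y


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_wav(path, audio: np.ndarray, rate: float) -> None:
    wavfile.write(path, int(round(rate)), np.asarray(audio, dtype=np.float32))


def read_wav(path) -> Tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)
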