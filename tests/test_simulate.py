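"""Synthetic-generator behaviour: determinism, physiology, known mappings."""

import numpy as np
import pandas as pd
import pytest

from breathstage.errors import ConfigurationError, InvalidArgumentError
from breathstage.simulate import (
    DEFAULT_STAGE_PROFILES,
    EPOCH_S,
    HypnogramModel,
    LinearProportionMapping,
    StageBreathProfile,
    SyntheticEpisodeConfig,
    default_linear_mapping,
    generate_breath_onsets,
    generate_cohort,
    generate_episode,
    generate_hypnogram,
    onsets_to_reference_labels,
    synthesize_signals,
)
from breathstage.staging import hypnogram_to_proportions


class TestGenerateHypnogram:
    def test_single_state_chain_emits_only_that_stage(self):
        config = SyntheticEpisodeConfig(
            duration_s=300.0, hypnogram_model=HypnogramModel(stages=("N3",)), seed=1
        )
        assert generate_hypnogram(config) == ["N3"] * 10

    def test_seed_determinism(self):
        config = SyntheticEpisodeConfig(duration_s=3600.0, seed=5)
        assert generate_hypnogram(config) == generate_hypnogram(config)

    def test_different_seeds_differ(self):
        a = generate_hypnogram(SyntheticEpisodeConfig(duration_s=3600.0, seed=1))
        b = generate_hypnogram(SyntheticEpisodeConfig(duration_s=3600.0, seed=2))
        assert a != b

    def test_invalid_duration_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SyntheticEpisodeConfig(duration_s=0.0)
        with pytest.raises(InvalidArgumentError):
            generate_hypnogram(SyntheticEpisodeConfig(duration_s=10.0))

    def test_empirical_proportions_match_stationary_distribution(self):
        """Mean stage occupancy over many 8 h nights matches the chain's
        stationary distribution (computed independently by matrix power)."""
        model = HypnogramModel()
        P = model.transition_matrix()
        power = np.linalg.matrix_power(P, 4096)
        stationary = power[0]
        np.testing.assert_allclose(power[1], stationary, atol=1e-10)

        counts = np.zeros(len(model.stages))
        n_seeds = 1000
        for seed in range(n_seeds):
            config = SyntheticEpisodeConfig(duration_s=8 * 3600.0, seed=seed)
            hyp = generate_hypnogram(config)
            for i, s in enumerate(model.stages):
                counts[i] += hyp.count(s)
        empirical = counts / counts.sum()
        np.testing.assert_allclose(empirical, stationary, atol=0.03)

    def test_transition_rows_are_distributions(self):
        P = HypnogramModel().transition_matrix()
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestGenerateBreathOnsets:
    def test_zero_jitter_gives_exact_spacing(self, regular_onsets_1h):
        diffs = np.diff(regular_onsets_1h.times)
        np.testing.assert_allclose(diffs, 5.0, atol=1e-9)

    def test_empty_hypnogram_gives_empty_train(self):
        assert len(generate_breath_onsets([], seed=0)) == 0

    def test_missing_profile_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            generate_breath_onsets(["REM"], {"W": StageBreathProfile(12.0, 0.1)}, seed=0)

    def test_strictly_increasing_with_floor_spacing(self):
        hyp = ["REM"] * 120
        onsets = generate_breath_onsets(hyp, seed=3)
        diffs = np.diff(onsets.times)
        assert np.all(diffs > 0)
        assert diffs.min() >= 1.0 - 1e-12

    def test_rem_intervals_more_variable_than_deep(self):
        """Interval CV is higher for the REM profile than the Deep profile in
        >= 99/100 seeds (Monte Carlo)."""
        hyp = ["N3"] * 120
        wins = 0
        for seed in range(100):
            deep = generate_breath_onsets(
                hyp, {"N3": DEFAULT_STAGE_PROFILES["N3"]}, seed=seed
            )
            rem = generate_breath_onsets(
                ["REM"] * 120, {"REM": DEFAULT_STAGE_PROFILES["REM"]}, seed=seed
            )
            cv = lambda t: np.std(np.diff(t)) / np.mean(np.diff(t))
            wins += cv(rem.times) > cv(deep.times)
        assert wins >= 99

    def test_rate_recovery_within_cv_band(self):
        """Counting onsets over >= 30 min of one stage recovers the configured
        rate within 3 * CV * rate."""
        for stage in ("N3", "REM"):
            prof = DEFAULT_STAGE_PROFILES[stage]
            hyp = [stage] * 120
            onsets = generate_breath_onsets(hyp, seed=9)
            rate = len(onsets) / 60.0
            assert abs(rate - prof.rate_bpm) <= max(3 * prof.rate_cv * prof.rate_bpm, 0.5)

    def test_seed_determinism(self):
        hyp = ["N2"] * 40
        a = generate_breath_onsets(hyp, seed=4).times
        b = generate_breath_onsets(hyp, seed=4).times
        np.testing.assert_array_equal(a, b)


class TestSynthesizeSignals:
    def test_effort_autocorrelation_peaks_at_breath_period(self, regular_onsets_1h):
        config = SyntheticEpisodeConfig(
            duration_s=3600.0, effort_rate=10.0, audio_rate=1000.0, seed=0
        )
        _, effort = synthesize_signals(regular_onsets_1h, config)
        x = effort - effort.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        lo, hi = 30, 70  # search 3-7 s
        lag = lo + int(np.argmax(ac[lo:hi]))
        assert abs(lag - 50) <= 1  # 5 s at 10 Hz, +- 1 sample

    def test_high_snr_bursts_dominate_background(self, regular_onsets_1h):
        config = SyntheticEpisodeConfig(
            duration_s=120.0, audio_rate=4000.0, snr_db=40.0, seed=2
        )
        onsets = regular_onsets_1h.times[regular_onsets_1h.times < 110.0]
        from breathstage.events import OnsetTrain

        audio, _ = synthesize_signals(OnsetTrain(onsets), config)
        sr = config.audio_rate

        def rms(t0, t1):
            seg = audio[int(t0 * sr) : int(t1 * sr)]
            return np.sqrt(np.mean(seg**2))

        onset_rms = np.mean([rms(t, t + 0.5) for t in onsets[:10]])
        background_rms = rms(0.0, 2.0)  # before the first onset at 5 s
        assert onset_rms > 3.0 * background_rms

    def test_empty_onsets_give_pure_noise(self):
        from breathstage.events import OnsetTrain

        config = SyntheticEpisodeConfig(duration_s=30.0, audio_rate=2000.0, seed=1)
        audio, effort = synthesize_signals(OnsetTrain(np.array([])), config)
        assert np.std(audio) < 0.02  # only the 0.01-RMS floor
        assert abs(np.mean(effort)) < 0.01 and np.std(effort) < 0.05

    def test_onsets_outside_duration_rejected(self):
        from breathstage.events import OnsetTrain

        config = SyntheticEpisodeConfig(duration_s=30.0, audio_rate=2000.0, seed=1)
        with pytest.raises(InvalidArgumentError):
            synthesize_signals(OnsetTrain(np.array([31.0])), config)

    def test_signal_determinism(self):
        config = SyntheticEpisodeConfig(duration_s=60.0, audio_rate=2000.0, seed=8)
        a1 = generate_episode(config)
        a2 = generate_episode(config)
        np.testing.assert_array_equal(a1.audio, a2.audio)
        np.testing.assert_array_equal(a1.effort, a2.effort)


class TestReferenceLabels:
    def test_onset_frames_marked_inhale(self, regular_onsets_1h):
        labels = onsets_to_reference_labels(regular_onsets_1h, 100.0, 3600.0)
        for t in regular_onsets_1h.times[:50]:
            frame = int(np.ceil(t * 100.0 - 1e-9))
            assert labels.labels[frame] == 0  # inhale

    def test_all_three_classes_present(self, regular_onsets_1h):
        labels = onsets_to_reference_labels(regular_onsets_1h, 100.0, 3600.0)
        assert set(np.unique(labels.labels)) == {0, 1, 2}


class TestEpisodeInvariants:
    def test_true_proportions_match_hypnogram_counts_exactly(self):
        config = SyntheticEpisodeConfig(duration_s=3600.0, seed=13)
        episode = generate_episode(config, with_signals=False)
        assert episode.true_proportions == hypnogram_to_proportions(episode.hypnogram)
        assert abs(episode.true_proportions.as_array().sum() - 1.0) < 1e-12

    def test_hypnogram_covers_full_duration(self):
        config = SyntheticEpisodeConfig(duration_s=3605.0, seed=13)
        episode = generate_episode(config, with_signals=False)
        assert len(episode.hypnogram) == int(3605.0 // EPOCH_S)

    def test_onsets_inside_episode(self):
        config = SyntheticEpisodeConfig(duration_s=1800.0, seed=21)
        episode = generate_episode(config, with_signals=False)
        t = episode.true_onsets.times
        assert np.all((t >= 0) & (t < 1800.0))
        assert np.all(np.diff(t) >= 1.0 - 1e-12)


class TestGenerateCohort:
    def test_noiseless_targets_reproduce_mapping(self):
        X, Y = generate_cohort(20, noise_sd=0.0, seed=1)
        mapped = default_linear_mapping()(X)
        np.testing.assert_allclose(Y.to_numpy(), mapped, atol=1e-12)

    def test_seed_determinism(self):
        X1, Y1 = generate_cohort(100, seed=5)
        X2, Y2 = generate_cohort(100, seed=5)
        pd.testing.assert_frame_equal(X1, X2)
        pd.testing.assert_frame_equal(Y1, Y2)

    def test_injected_noise_sd_in_documented_band(self):
        """Per-stage SD of (target - mapping) stays near the configured 0.02
        after simplex re-normalization."""
        X, Y = generate_cohort(100, noise_sd=0.02, seed=7)
        resid = Y.to_numpy() - default_linear_mapping()(X)
        for j in range(4):
            assert 0.015 <= np.std(resid[:, j]) <= 0.025

    def test_targets_on_simplex(self):
        _, Y = generate_cohort(50, noise_sd=0.05, seed=3)
        arr = Y.to_numpy()
        assert np.all(arr >= 0)
        np.testing.assert_allclose(arr.sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_feature_name_rejected(self):
        with pytest.raises(ConfigurationError):
            LinearProportionMapping(
                intercepts={"wake": 0.25, "light": 0.25, "deep": 0.25, "rem": 0.25},
                coefficients={"wake": {"not.a.feature": 1.0}},
            )

    def test_too_small_cohort_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_cohort(1)
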