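"""Windowing, log-Mel front-end, backends, cross-entropy and vote fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathstage.annotate import EXHALE, INHALE, SILENCE, FrameLabelSequence
from breathstage.errors import InternalError, InvalidArgumentError, StateError
from breathstage.segment import (
    EnergyHeuristicBackend,
    LogMelParams,
    LogMelSpectrogram,
    OracleBackend,
    TrainableBackend,
    WindowPrediction,
    WindowingConfig,
    classify_frames,
    compute_logmel,
    cross_entropy,
    fuse_majority_vote,
    mel_center_frequencies,
    segment_with_oracle,
    window_audio,
)
from breathstage.simulate import (
    StageBreathProfile,
    SyntheticEpisodeConfig,
    generate_breath_onsets,
    onsets_to_reference_labels,
    synthesize_signals,
)

from _reference import reference_vote


class TestWindowAudio:
    def test_sixty_seconds_five_windows(self):
        config = WindowingConfig(20.0, 10.0, audio_rate=100.0)
        windows = window_audio(np.zeros(6000), config)
        assert [w.start_s for w in windows] == [0.0, 10.0, 20.0, 30.0, 40.0]
        assert not any(w.padded for w in windows)

    def test_no_overlap_tiling(self):
        config = WindowingConfig(20.0, 20.0, audio_rate=100.0)
        windows = window_audio(np.zeros(6000), config)
        assert [w.start_s for w in windows] == [0.0, 20.0, 40.0]

    def test_final_partial_window_padded(self):
        config = WindowingConfig(20.0, 10.0, audio_rate=100.0)
        windows = window_audio(np.arange(6500, dtype=float), config)
        assert windows[-1].start_s == 50.0
        assert windows[-1].padded and windows[-1].n_valid == 1500
        assert np.all(windows[-1].waveform[1500:] == 0.0)

    def test_every_sample_covered(self):
        config = WindowingConfig(20.0, 15.0, audio_rate=10.0)
        windows = window_audio(np.zeros(730), config)
        covered = np.zeros(730, dtype=bool)
        for w in windows:
            s = int(w.start_s * 10)
            covered[s : s + w.n_valid] = True
        assert covered.all()

    def test_audio_shorter_than_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            window_audio(np.zeros(10), WindowingConfig(20.0, 10.0, audio_rate=100.0))


class TestComputeLogmel:
    def test_all_zero_waveform_hits_log_floor(self):
        spec = compute_logmel(np.zeros(4000), 4000.0)
        np.testing.assert_allclose(spec.data, np.log(1e-10))

    def test_pure_tone_lands_in_the_right_mel_bin(self):
        sr = 16000.0
        t = np.arange(int(2 * sr)) / sr
        tone = np.sin(2 * np.pi * 440.0 * t)
        spec = compute_logmel(tone, sr)
        centers = mel_center_frequencies(80, 0.0, sr / 2)
        spacing = np.diff(centers)
        for frame in spec.data[2:-2]:
            k = int(np.argmax(frame))
            assert abs(centers[k] - 440.0) <= spacing[max(k - 1, 0)]

    def test_deterministic(self, rng):
        x = rng.standard_normal(8000)
        a = compute_logmel(x, 8000.0).data
        b = compute_logmel(x, 8000.0).data
        np.testing.assert_array_equal(a, b)

    def test_empty_waveform_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compute_logmel(np.array([]), 16000.0)

    def test_frame_clock(self):
        spec = compute_logmel(np.zeros(16000), 16000.0)
        assert spec.frame_rate == 100.0
        assert spec.n_frames == 100


def _one_hot(labels):
    post = np.zeros((len(labels), 3))
    post[np.arange(len(labels)), labels] = 1.0
    return post


class TestBackends:
    def test_oracle_reproduces_reference(self):
        reference = FrameLabelSequence(
            frame_rate=100.0, labels=np.array([0, 1, 2, 2, 1] * 20, dtype=np.int8)
        )
        spec = LogMelSpectrogram(np.zeros((100, 1)), frame_rate=100.0, window_start=0.0)
        seq = classify_frames(OracleBackend(reference), spec)
        np.testing.assert_array_equal(seq.labels, reference.labels)
        np.testing.assert_array_equal(seq.posteriors, _one_hot(reference.labels))

    def test_energy_heuristic_calls_silence_on_burst_free_audio(self):
        config = SyntheticEpisodeConfig(duration_s=30.0, audio_rate=4000.0, seed=3)
        from breathstage.events import OnsetTrain

        audio, _ = synthesize_signals(OnsetTrain(np.array([])), config)
        spec = compute_logmel(audio, 4000.0, LogMelParams(n_mels=40, fmax=2000.0))
        seq = classify_frames(EnergyHeuristicBackend(), spec)
        assert np.mean(seq.labels == SILENCE) >= 0.95

    def test_untrained_backend_is_state_error(self):
        spec = LogMelSpectrogram(np.zeros((10, 4)), frame_rate=100.0)
        with pytest.raises(StateError):
            classify_frames(TrainableBackend(), spec)

    def test_trainable_backend_beats_three_quarters_frame_accuracy(self):
        """Fit on 200 synthetic 20 s windows, evaluate on 50 held out."""
        sr, window_s = 4000.0, 20.0
        params = LogMelParams(n_mels=40, fmax=2000.0)
        hyp = ["N2"] * 6  # 3 minutes per episode chunk
        specs, labels = [], []
        for seed in range(29):  # 29 chunks x 9 windows = 261 windows
            onsets = generate_breath_onsets(hyp, seed=seed)
            config = SyntheticEpisodeConfig(
                duration_s=180.0, audio_rate=sr, snr_db=15.0, seed=seed
            )
            audio, _ = synthesize_signals(onsets, config)
            reference = onsets_to_reference_labels(onsets, 100.0, 180.0)
            for w in window_audio(audio, WindowingConfig(window_s, window_s, sr)):
                spec = compute_logmel(w.waveform, sr, params, w.start_s)
                specs.append(spec)
                g0 = int(round(w.start_s * 100.0))
                labels.append(reference.labels[g0 : g0 + spec.n_frames])
        train_s, train_l = specs[:200], labels[:200]
        test_s, test_l = specs[200:250], labels[200:250]
        backend = TrainableBackend(seed=0).fit(train_s, train_l)
        correct = total = 0
        for spec, lab in zip(test_s, test_l):
            pred = classify_frames(backend, spec).labels
            correct += int(np.sum(pred == lab))
            total += lab.size
        assert correct / total > 0.75


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        labels = FrameLabelSequence(100.0, np.array([0, 1, 2, 1]))
        post = FrameLabelSequence(
            100.0, np.array([0, 1, 2, 1]), posteriors=_one_hot([0, 1, 2, 1])
        )
        assert cross_entropy(labels, post) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_posteriors_give_ln3(self):
        labels = FrameLabelSequence(100.0, np.array([0, 2, 1, 0, 2]))
        post = FrameLabelSequence(
            100.0, np.array([0] * 5), posteriors=np.full((5, 3), 1 / 3)
        )
        assert cross_entropy(labels, post) == pytest.approx(np.log(3.0), rel=1e-12)

    def test_two_frame_hand_value(self):
        labels = FrameLabelSequence(100.0, np.array([0, 1]))
        post = FrameLabelSequence(
            100.0,
            np.array([0, 1]),
            posteriors=np.array([[0.5, 0.3, 0.2], [0.5, 0.25, 0.25]]),
        )
        expected = -(np.log(0.5) + np.log(0.25)) / 2.0
        assert cross_entropy(labels, post) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.0397, abs=5e-5)

    def test_length_mismatch_rejected(self):
        a = FrameLabelSequence(100.0, np.array([0, 1]))
        b = FrameLabelSequence(
            100.0, np.array([0]), posteriors=np.array([[1.0, 0.0, 0.0]])
        )
        with pytest.raises(InvalidArgumentError):
            cross_entropy(a, b)

    def test_nonnegative_and_zero_only_when_correct(self, rng):
        labels = FrameLabelSequence(100.0, rng.integers(0, 3, 50))
        post = rng.dirichlet(np.ones(3), size=50)
        seq = FrameLabelSequence(100.0, post.argmax(1), posteriors=post)
        assert cross_entropy(labels, seq) > 0.0


def _prediction(start_frames, post_rows, fr=100.0):
    return WindowPrediction(
        window_start=start_frames / fr,
        frame_rate=fr,
        posteriors=np.asarray(post_rows, dtype=float),
        n_valid_frames=len(post_rows),
    )


class TestFuseMajorityVote:
    def test_simple_majority(self):
        rows_i = [[0.8, 0.1, 0.1]]
        rows_s = [[0.1, 0.1, 0.8]]
        fused = fuse_majority_vote(
            [_prediction(0, rows_i), _prediction(0, rows_i), _prediction(0, rows_s)]
        )
        assert fused.labels[0] == INHALE

    def test_single_window_identity(self, rng):
        post = rng.dirichlet(np.ones(3), size=40)
        fused = fuse_majority_vote([_prediction(0, post)])
        np.testing.assert_array_equal(fused.labels, post.argmax(1))

    def test_tie_broken_by_mean_posterior(self):
        inhale_win = [[0.6, 0.2, 0.2]]
        silence_win = [[0.4, 0.1, 0.5]]
        fused = fuse_majority_vote([_prediction(0, inhale_win), _prediction(0, silence_win)])
        assert fused.labels[0] == INHALE  # mean posterior 0.5 vs 0.35

    def test_exact_tie_falls_back_to_priority(self):
        a = [[0.5, 0.0, 0.5]]
        b = [[0.5, 0.0, 0.5]]
        # both windows vote inhale (argmax picks class 0 on ties), so force
        # differing hard votes via asymmetric rows with equal means
        a = [[0.6, 0.0, 0.4]]
        b = [[0.4, 0.0, 0.6]]
        fused = fuse_majority_vote([_prediction(0, a), _prediction(0, b)])
        assert fused.labels[0] == SILENCE  # priority silence > inhale

    def test_padded_frames_excluded(self):
        good = _prediction(0, [[0.1, 0.1, 0.8]] * 4)
        padded = WindowPrediction(
            window_start=0.0,
            frame_rate=100.0,
            posteriors=np.array([[0.8, 0.1, 0.1]] * 4),
            n_valid_frames=2,
        )
        fused = fuse_majority_vote([good, padded])
        assert np.all(fused.labels[2:] == SILENCE)

    def test_uncovered_frame_is_internal_error(self):
        with pytest.raises(InternalError):
            fuse_majority_vote([_prediction(2, [[1.0, 0.0, 0.0]])], n_frames=4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_frame_ballot_counting(self, seed):
        rng = np.random.default_rng(seed)
        n_frames = int(rng.integers(20, 100))
        n_windows = int(rng.integers(1, 10))
        preds, ref_windows = [], []
        covered = np.zeros(n_frames, dtype=bool)
        for _ in range(n_windows):
            length = int(rng.integers(5, n_frames))
            start = int(rng.integers(0, n_frames - length + 1))
            post = rng.dirichlet(np.ones(3), size=length)
            preds.append(_prediction(start, post))
            ref_windows.append((start, post.tolist()))
            covered[start : start + length] = True
        if not covered.all():
            fill = _prediction(0, rng.dirichlet(np.ones(3), size=n_frames))
            preds.append(fill)
            ref_windows.append((0, fill.posteriors.tolist()))
        fused = fuse_majority_vote(preds, n_frames=n_frames)
        expected = reference_vote(ref_windows, n_frames)
        np.testing.assert_array_equal(fused.labels, expected)


class TestOraclePipeline:
    def test_fusion_reproduces_reference_exactly(self):
        hyp = ["N2"] * 10
        onsets = generate_breath_onsets(hyp, seed=23)
        reference = onsets_to_reference_labels(onsets, 100.0, 300.0)
        fused = segment_with_oracle(reference, WindowingConfig(20.0, 10.0))
        np.testing.assert_array_equal(fused.labels, reference.labels)

    def test_no_overlap_fusion_is_identity(self):
        hyp = ["N3"] * 4
        onsets = generate_breath_onsets(hyp, seed=2)
        reference = onsets_to_reference_labels(onsets, 100.0, 120.0)
        fused = segment_with_oracle(reference, WindowingConfig(20.0, 20.0))
        np.testing.assert_array_equal(fused.labels, reference.labels)
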