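import numpy as np
import pytest

from breathstage.annotate import FrameLabelSequence
from breathstage.simulate import (
    HypnogramModel,
    StageBreathProfile,
    SyntheticEpisodeConfig,
    generate_breath_onsets,
    generate_episode,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def labels_from_string():
    """Build a FrameLabelSequence from a compact 'SIIE...' string."""

    codes = {"I": 0, "E": 1, "S": 2}

    def _make(s: str, frame_rate: float = 10.0) -> FrameLabelSequence:
        return FrameLabelSequence(
            frame_rate=frame_rate, labels=np.array([codes[c] for c in s], dtype=np.int8)
        )

    return _make


@pytest.fixture(scope="session")
def short_episode():
    """A 5-minute synthetic episode with audio at a reduced sample rate."""
    config = SyntheticEpisodeConfig(
        duration_s=300.0, audio_rate=4000.0, snr_db=25.0, seed=11
    )
    return generate_episode(config, with_signals=True)


@pytest.fixture(scope="session")
def regular_onsets_1h():
    """One hour of metronomic 12 breaths/min (5 s spacing, zero jitter)."""
    model = HypnogramModel(stages=("N3",))
    config = SyntheticEpisodeConfig(duration_s=3600.0, hypnogram_model=model, seed=0)
    hyp = ["N3"] * 120
    profiles = {"N3": StageBreathProfile(12.0, 0.0)}
    return generate_breath_onsets(hyp, profiles, seed=0)
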