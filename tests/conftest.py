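import numpy as np
import pytest

from motioncues.recording import (
    LANDMARKS,
    LandmarkTrajectory,
    RecordingMetadata,
    SpeakerRecording,
)
from motioncues.simulate import ScenarioConfig, generate_scenario


def make_recording(
    points: dict[str, np.ndarray] | None = None,
    n: int = 10,
    lectern_y: float = 400.0,
    speaker_id: str = "spk",
    seed: int = 0,
) -> SpeakerRecording:
    """A small well-formed recording; unspecified landmarks get jittered tracks."""
    rng = np.random.default_rng(seed)
    bases = {
        "forehead": (150.0, 80.0),
        "right_shoulder": (180.0, 160.0),
        "right_hand": (220.0, 240.0),
        "left_hand": (120.0, 240.0),
    }
    trajectories = {}
    for lm in LANDMARKS:
        if points is not None and lm in points:
            pts = np.asarray(points[lm], dtype=float)
        else:
            pts = np.asarray(bases[lm]) + rng.uniform(-5, 5, size=(n, 2))
        trajectories[lm] = LandmarkTrajectory(lm, pts)
    meta = RecordingMetadata(speaker_id=speaker_id, lectern_y=lectern_y)
    return SpeakerRecording(meta, trajectories)


@pytest.fixture(scope="session")
def small_scenario():
    """A 12-speaker synthetic study shared by the slower association tests."""
    return generate_scenario(ScenarioConfig(n_speakers=12, seed=42))
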