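import numpy as np
import pandas as pd
import pytest

from ethousv.classify import BEHAVIORS
from ethousv.pipeline import analyze_study, train_default_bundle
from ethousv.pose import PoseTrack, _columns
from ethousv.study import plan_study
from ethousv.synthetic import SyntheticSessionSpec, generate_pose_track


def make_track(coords_a: np.ndarray, coords_b: np.ndarray, fps: float = 12.0,
               lik: float = 1.0) -> PoseTrack:
    """Build a PoseTrack from explicit (n, 12, 2) coordinate arrays."""
    n = len(coords_a)
    data = np.empty((n, 72))
    col = 0
    for arr in (coords_a, coords_b):
        for j in range(12):
            data[:, col] = arr[:, j, 0]
            data[:, col + 1] = arr[:, j, 1]
            data[:, col + 2] = lik
            col += 3
    return PoseTrack(pd.DataFrame(data, columns=_columns()), fps=fps)


def clean_spec(**kwargs) -> SyntheticSessionSpec:
    """Session spec with all stochastic corruption switched off."""
    kwargs.setdefault("noise_px", 0.0)
    kwargs.setdefault("missing_fraction", 0.0)
    kwargs.setdefault("seed", 0)
    return SyntheticSessionSpec(**kwargs)


@pytest.fixture(scope="session")
def all_behaviors_session():
    """One clean session scripting each of the 11 behaviors for 5 s."""
    script = []
    t = 2.0
    for b in BEHAVIORS:
        script.append((b, t, t + 5.0))
        t += 7.0
    spec = clean_spec(
        video_duration=t + 2, audio_duration=t + 2, seed=3, episode_script=script
    )
    track, truth = generate_pose_track(spec)
    return spec, track, truth


@pytest.fixture(scope="session")
def trained_bundle():
    """The default 11-behavior classifier bundle (seeded)."""
    return train_default_bundle(seed=0)


@pytest.fixture(scope="session")
def truth_study():
    """Full 6-box x 6-day x 2-session study analysed on scripted truth."""
    sessions, index = plan_study(seed=7)
    result = analyze_study(sessions, use_truth=True)
    result["sessions"] = sessions
    result["index"] = index
    return result
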