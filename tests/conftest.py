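import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/reference.py importable

settings.register_profile("default", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def compliant_series(n_frames=50, frame_rate_hz=25.0, elongation=40.0, activity=0.5,
                     nose=(30.0, 22.0), center=(26.0, 22.0), in_feeder=False):
    """A constant series whose every frame satisfies both default criteria
    (unless placed in the feeder zone)."""
    from iitr.tracking import TrackingSeries

    frames = pd.DataFrame({
        "t_s": np.arange(n_frames) / frame_rate_hz,
        "nose_x": nose[0], "nose_y": nose[1],
        "center_x": center[0], "center_y": center[1],
        "elongation": float(elongation), "activity": float(activity),
    })
    frames["in_feeder"] = bool(in_feeder)
    return TrackingSeries(frame_rate_hz, frames)


def random_series(rng, n_frames, frame_rate_hz=25.0):
    """A randomized series whose channels hover around the detection
    thresholds so that masks flip often."""
    elong = rng.uniform(44.0, 50.0, n_frames)
    act = rng.uniform(0.0, 0.5, n_frames)
    nose = np.cumsum(rng.normal(0.0, 0.05, (n_frames, 2)), axis=0) + 30.0
    center = nose + np.array([-4.0, 0.0]) + rng.normal(0, 0.02, (n_frames, 2))
    # occasional missing samples
    miss = rng.uniform(size=n_frames) < 0.01
    elong[miss] = np.nan
    from iitr.tracking import TrackingSeries

    frames = pd.DataFrame({
        "t_s": np.arange(n_frames) / frame_rate_hz,
        "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "center_x": center[:, 0], "center_y": center[:, 1],
        "elongation": elong, "activity": act,
    })
    frames["in_feeder"] = rng.uniform(size=n_frames) < 0.05
    return TrackingSeries(frame_rate_hz, frames)
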