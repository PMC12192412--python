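import numpy as np
import pytest

from iristrack.synthetic import SceneConfig, TaskSpec, render_sequence
from iristrack.video_io import FrameRecord, Trajectory, TrajectoryPoint


def frame_records(frames, interval=10, fps=30.0):
    """Sample a rendered frame list the way video_io would."""
    return [
        FrameRecord(index=i, time_s=i / fps, image=frames[i])
        for i in range(0, len(frames), interval)
    ]


def truth_trajectory(truth, fps=30.0):
    """Ground-truth table -> Trajectory (blink rows invalid)."""
    points = [
        TrajectoryPoint(
            frame_index=int(r.frame_index),
            time_s=int(r.frame_index) / fps,
            x=None if r.blink else float(r.x),
            y=None if r.blink else float(r.y),
            valid=not bool(r.blink),
        )
        for r in truth.itertuples()
    ]
    return Trajectory(points)


def render_disc(shape=(200, 200), cx=100, cy=100, r=30, fg=60, bg=220):
    """Noise-free dark disc on a light field."""
    h, w = shape
    yy, xx = np.ogrid[0:h, 0:w]
    img = np.full((h, w), bg, dtype=np.uint8)
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = fg
    return img


@pytest.fixture(scope="session")
def default_scene():
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def open_eye_frame(default_scene):
    """A single clean open-eye frame at the resting centre."""
    frames, truth = render_sequence(
        default_scene, TaskSpec(task="fixation", duration_s=1.0)
    )
    return frames[0], (float(truth.iloc[0].x), float(truth.iloc[0].y))


@pytest.fixture(scope="session")
def horizontal_video(default_scene):
    """5 s horizontal-task video with its ground truth (150 frames)."""
    frames, truth = render_sequence(
        default_scene, TaskSpec(task="horizontal", duration_s=5.0)
    )
    return frames, truth
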